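# Methods

## The weight-support model

All three behaviours reduce to one aerodynamic kernel: the lift produced by
flapping wings, expressed as the fraction of body weight it offsets,

    bw = 0.5 · Cl · ρ · (f·Amp + U)² · S / (g · M).

The model treats the wing pair as a single planform of area `S` moving at
an effective airspeed `f·Amp + U`: the wingtip arc per beat (`Amp`) times
beat frequency, plus the translation of the body.  It deliberately ignores
drag, unsteady effects, spanwise velocity gradients, and wing–body
interaction; the compensating choices (upper-bound wing areas, maximal
flap angles, adult-bird speeds and frequencies) all push `bw` upward, so
specimens that still fail a benchmark fail it robustly.

**Amp = θ·L.**  The per-beat excursion is reconstructed as flap angle
(radians) × wing length — the wingtip arc length.  Two independent checks
pin this down.  (1) Back-solving the extant-bird validation rows for the
one unpublished input, wing length, returns plausible lengths for every
species and strictly increasing lengths across Chukar ontogenetic stages
I→III (0.058, 0.190, 0.239 m).  (2) Inverting the published fossil
weight-support table under this convention reproduces, to within rounding,
the handful of wingbeat frequencies that the source text quotes
independently (6 Hz for the large *Similicaudipteryx*, ~10 Hz for
*Yulong*, 7–8 Hz for *Yixianosaurus*).  Chord-based or `2L·sin(θ/2)`
readings fail both checks and are not implemented.

**Constants.**  ρ = 1.225 kg/m³ (sea-level standard; not knowable for the
Mesozoic, config-overridable), g = 9.8 m/s².  Lift coefficients are
behaviour-specific measurements from extant birds: 1.0 (WAIR, juvenile
Chukar), 1.2 (flap running), 1.5 (takeoff), 1.6 (takeoff validation rows).
Flap angles 50/70/90°; 90° exceeds the shoulder mobility of most non-avian
theropods and brackets the optimistic end.  Body speeds: 0.6 and 1.5 m/s
for WAIR (juvenile and adult Chukar), 2 m/s flap-run start, 3.8/4.1/5.1 m/s
leaping-takeoff launch speeds.  Classification thresholds 0.06 / 0.5 / 1.0
are the empirical WAIR stage-I minimum, the sub-vertical ascent
requirement, and full weight support.

## Wing reconstruction

Wing length = humerus + ulna + metacarpal II + longest primary, in a
straight line; span = 2.1 × wing length (the inflation absorbs the body
between the wing roots, checked against furcular widths); chord = 0.65 ×
longest primary; area = span × chord.  The rectangle over-estimates a real
tapered planform by design.  Embryo forelimbs are reconstructed from the
humerus alone via near-constant humerus/forelimb ratios (0.43 troodontids,
0.41 oviraptorids).  Body-mass allometries (femur-based for non-avians,
humerus-based for birds) are configuration data, not package constants:
the shipped coefficients are labelled illustrative and should be replaced
with the published regressions for real use; literature mass bounds bypass
the regression entirely.

In the packaged specimen table the printed wing areas are rounded to two
decimals while the integer wing loadings were computed from unrounded
areas, so the loading column is authoritative: analyses use
`S = g·M / loading`.  Three printed rows fail internal-consistency checks
(span vs 2.1×length, area vs loading) and are flagged; flagged rows are
excluded from regression calibration but kept, as printed, everywhere
else.

## Wingbeat-frequency models and calibration

Maximum takeoff wingbeat frequency falls log-linearly with body mass.
Three regression variants are carried (ALL / GF / MOD, the last
galliform-extended and phylogenetically corrected).  Their original
coefficients are unavailable, so `calibrate_from_reference` recovers each
line from the published per-specimen weight-support table: every usable
cell (bw > 0; zero cells carry no information after rounding) is inverted
to an implied frequency and a weighted least-squares line is fitted in
log-log space.  Weights are the inverse variance of log10 f under the
±0.005 display-rounding band of each bw cell, so heavily degraded
small-bw cells do not swamp the fit; both speed blocks contribute, since
each is an independent reading of the same frequency.  The recovered
models (slopes −0.39, −0.40, −0.24; R² 0.93–0.95) reproduce the usable
table cells with RMS error 0.007 bw.  Worst-case cell error is 0.046,
concentrated in two 0.6 m/s cells that are arithmetically inconsistent
with their own 1.5 m/s partners (the airspeed difference between the two
speed blocks must be exactly 0.9 m/s for the same specimen and estimator;
those cells imply 1.8 and 1.4) — transcription artefacts we preserve as
printed.  Per-cell agreement tighter than ~±0.02 is not attainable from
display-rounded inputs: wing-length rounding alone (±0.005 m) moves bw by
~±0.02 at bw ≈ 0.7.

Direct fitting is also provided: ordinary least squares on log-log data,
and phylogenetically independent contrasts for comparative datasets with
Brownian-motion signal.  Contrasts are computed with dendropy; the slope
is the origin regression of standardized frequency contrasts on mass
contrasts (contrast signs are arbitrary, so no intercept exists at that
level), and the tip-scale intercept is recovered by passing the line
through the root ancestral estimates.  dendropy requires bifurcating
trees; polytomies should be resolved with zero-length-epsilon branches.

## Flap running

From a 2 m/s start, each of ten wingbeats applies an aerodynamic force
`0.5·ρ·Cl·S·V_eff²` at the current effective airspeed; a fraction `k` of
it acts as thrust whose impulse over one beat period (1/f) increments the
ground speed.  `k = 1` by default — the source's stated (and flagged as
optimistic) assumption that essentially all lift can be reoriented as
thrust — making the outputs upper bounds: body drag, hindlimb gait limits,
and the weight-support cost of unreoriented lift are not modelled.
Absolute percentage increases are therefore reconstruction-dependent; the
robust outputs are orderings (small-bodied paravians outrank every
non-paravian under all permutations) and threshold crossings (whether the
final speed reaches `v = sqrt(2gM/(ρ·Cl·S))`, the speed at which lift
equals weight).

## Leaping

The launch itself is hindlimb-powered: burst power
P = 360 W/kg × (0.30·M) × 2.4, where 2.4 is an elastic pre-loading
amplification within the range measured in extant tetrapods.  With
push-off duration approximated as 2d/v₀ over leg-extension distance d
(default 0.25 m), the energy balance gives v₀ = (4·P·d/M)^(1/3) —
independent of mass, because P scales with M.  This closed form is a
reconstruction of an unpublished bipedal-launch formulation; all constants
are exposed.  Three wing contributions are evaluated: (1) height gain,
with maximum wing output at the apex directed vertically, where supporting
a fraction bw₀ of weight stretches the apex by bw₀/(1−bw₀) (the
reduced-effective-gravity reading; it diverges as bw₀→1, at which point
the vertical-takeoff path applies); (2) horizontal gain, wing thrust
during push-off adding Δv to v₀, with the percent gain identical at 30°
and 45° because ballistic range `v²·sin 2θ/g` scales with v²; (3)
standing vertical takeoff, flagged when bw ≥ 1 at an extant-bird launch
speed.  The forelimb muscle fraction (10%) is carried for documentation
but does not enter the kinematic bw model.

## Chukar ontogeny

Four cubics (mass from age; pectoral muscle %, wing loading, and maximum
WAIR angle from mass) and one linear model (max WAIR angle =
100.17 − 20.824 × loading in g/cm², with 65° demarcating quadrupedal
crawling from true WAIR and predictions capped at 100°) summarise
published Chukar growth data over the first ~70 days post hatching.  The
printed R² values are stored as metadata, not recomputed (the raw data
are not packaged).  The age→mass cubic is provably monotone on the fitted
domain (its derivative has negative discriminant).  A loading bridge maps
fossil wing loadings below 196 N/m² (2.0 g/cm²) onto the Chukar
performance scale; heavier loadings are outside the fitted range and are
refused rather than extrapolated.  One caption token in the source's
pectoral-mass polynomial is corrupt; it is read as `+5.9340e-7·x³`, the
only reading consistent with a cubic fit.

## Synthetic data

Generators mirror the statistical structure the analysis assumes, for
testing without downloads.  (1) Frequency datasets: a random bifurcating
tree (sequential random joins, exponential branch lengths), log10 mass
evolved by Brownian motion, and log10 frequency = intercept + slope·log10
mass + an independent Brownian residual (per-unit-time sd `noise_sd`) —
the exact generating model assumed by independent contrasts.  (2) Specimen
sets: masses log-uniform on [0.03, 20] kg (the observed range), wing
length ∝ M^(1/3) with lognormal scatter, primaries 30–60% of wing length;
derived loadings span roughly 40–12,000 N/m² and straddle the 170 N/m²
chick benchmark at moderate n.  (3) Ontogeny samples: polynomial values
plus additive gaussian noise.  Every generator is a pure function of its
spec (seeded NumPy generator); identical specs give identical output.
What passing tests on these data show is that the estimators recover known
structure of the assumed form; they cannot show that real comparative data
meet those assumptions (measurement error in masses, non-Brownian
evolution, and taxon sampling biases are not emulated).

## Numerical choices and problem sizes

Regression fits use `scipy.stats.linregress`/`numpy.polyfit`; the
extant-row wing-length back-solve minimises the worst-cell error
(bounded scalar minimisation on [0.001, 2] m) so that the result directly
answers whether one wing length reproduces every printed cell; printed
mass ranges are honoured as intervals rather than forced into a pairing.
Classification bands are closed on the left (bw = 0.06 is level 1,
bw = 0.5 is level 2) as defined.  bw has no ceiling; validation takeoff
rows legitimately exceed 1.  Recovery simulations in the test suite use
200 replicates (n = 50 OLS; 64-tip trees for contrasts), sized to keep
the full suite under a minute while leaving Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

Single-planform, lift-only aerodynamics; no drag or power budget linking
muscle mass to achievable frequency (frequencies come from extant-bird
allometries that likely overestimate non-avian theropods, as the source
argues); the launch v₀ closed form stands in for an unpublished
formulation; calibrated frequency models inherit the rounding noise of the
published tables and are faithful to those tables rather than to the
unavailable originals; mass-allometry coefficients are user-supplied
configuration.  Conclusions drawn from the packaged data are therefore
upper bounds on flap-based locomotor performance, which is the analysis's
intended logic: behaviours that fail under these assumptions can be
excluded with confidence, while behaviours that pass are merely not
excluded.
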