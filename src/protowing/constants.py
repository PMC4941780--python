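"""Physical constants and behavioural defaults shared across the models.

All quantities are SI unless the name says otherwise.  The lift coefficients
are behaviour-specific: WAIR uses the value measured in juvenile Chukar
partridges at early stage II, flap running a slightly higher late-stage
value, and leaping takeoff the minimum adult high-angle value.
"""

from __future__ import annotations

import math

#: Gravitational acceleration used throughout the weight-support equation.
GRAVITY: float = 9.8  # m/s^2

#: Sea-level standard air density.  Not a measured quantity for the Mesozoic;
#: overridable through :class:`protowing.pipeline.AnalysisConfig`.
AIR_DENSITY: float = 1.225  # kg/m^3

#: Wingspan as a multiple of single-wing length (feathers included).  The
#: inflation covers the contribution of the body between the wing roots.
SPAN_FACTOR: float = 2.1

#: Mean wing chord as a fraction of the longest primary feather length.
CHORD_FACTOR: float = 0.65

#: Wing-loading unit conversion: 1 g/cm^2 = 98 N/m^2 (10 kg/m^2 x g).
N_PER_M2_PER_G_CM2: float = 98.0

# Behaviour-specific lift coefficients.
CL_WAIR: float = 1.0
CL_FLAPRUN: float = 1.2
CL_TAKEOFF: float = 1.5
CL_VALIDATION: float = 1.6  # extant-bird takeoff validation rows

#: Downstroke / flap angle grid, degrees.  90 deg is an upper bracket; most
#: non-avian theropod shoulders could not abduct the humerus that far.
FLAP_ANGLES_DEG: tuple[float, ...] = (50.0, 70.0, 90.0)
FLAP_ANGLES_RAD: tuple[float, ...] = tuple(math.radians(a) for a in FLAP_ANGLES_DEG)

#: Centre-of-mass speeds for WAIR: stage-I juvenile and adult Chukar.
WAIR_SPEEDS: tuple[float, ...] = (0.6, 1.5)

#: Starting ground speed for the flap-running iteration.
FLAPRUN_START_SPEED: float = 2.0

#: Leaping-takeoff launch speeds recorded in extant birds.
TAKEOFF_SPEEDS: tuple[float, ...] = (3.8, 4.1, 5.1)

# Body-weight-support classification thresholds.
BW_LEVEL1: float = 0.06  # minimal recorded WAIR weight support
BW_LEVEL2: float = 0.50  # sub-vertical to vertical incline ascent
BW_TAKEOFF: float = 1.0  # wings alone support the whole body weight

# Leaping launch model.
PRELOAD_SCALAR: float = 2.4  # elastic power amplification during push-off
SPECIFIC_POWER: float = 360.0  # W/kg of burst muscle output
HINDLIMB_MUSCLE_FRACTION: float = 0.30
FORELIMB_MUSCLE_FRACTION: float = 0.10

#: Embryo forelimb reconstruction: humerus/forelimb ratios by clade.
EMBRYO_HUMERUS_RATIO_TROODONTID: float = 0.43
EMBRYO_HUMERUS_RATIO_OVIRAPTORID: float = 0.41
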