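"""Synthetic data generators for end-to-end testing without downloads.

Three generators mirror the statistical structure the analysis assumes:

* an extant-bird mass -> takeoff-wingbeat-frequency dataset with Brownian
  phylogenetic signal on a random tree (for regression and contrasts
  recovery tests),
* fossil-specimen measurement sets with proportions spanning the observed
  mass (0.03-20 kg) and wing-loading (~40-12,000 N/m^2) ranges,
* Chukar-style ontogenetic trajectories sampled from the growth
  polynomials with additive noise.

Every generator is a pure function of its :class:`GeneratorSpec`: the same
seed and parameters reproduce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .datasets import Group, LifeStage, MassEstimate, MassMethod, SpecimenRecord
from .morphometrics import build_planform, wing_loading
from .ontogeny import OntogenyModel, default_ontogeny_model, ontogeny_predict


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters shared by the generators.

    ``noise_sd`` is the Brownian per-unit-time standard deviation of the
    frequency residual (frequency generator), or the additive gaussian
    standard deviation (ontogeny generator, applied on each response's own
    scale).
    """

    seed: int = 0
    n: int = 50
    n_tips: int = 32
    noise_sd: float = 0.05
    true_slope: float = -0.30
    true_intercept: float = 1.0
    branch_rate: float = 1.0  # exponential rate for branch lengths
    mass_log10_range: tuple[float, float] = (math.log10(0.03), math.log10(20.0))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_tree(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Random rooted bifurcating tree with exponential branch lengths."""
    if spec.n_tips < 4:
        raise ValueError("need at least 4 tips")
    rng = rng if rng is not None else spec.rng()
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(spec.n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for taxon in taxa:
        leaf = dendropy.Node(taxon=taxon)
        nodes.append(leaf)
    # sequential random joins produce a uniform-ish bifurcating topology
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    tree.seed_node = nodes[0]
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(1.0 / spec.branch_rate)) + 1e-3
    return tree


def _evolve_brownian(
    tree: dendropy.Tree, root_state: float, rate_sd: float, rng: np.random.Generator
) -> dict[str, float]:
    """Brownian motion along the tree; returns tip label -> state."""
    states: dict[dendropy.Node, float] = {tree.seed_node: root_state}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[node.parent_node]
        step_sd = rate_sd * math.sqrt(node.edge.length)
        states[node] = parent_state + float(rng.normal(0.0, step_sd))
    return {leaf.taxon.label: states[leaf] for leaf in tree.leaf_node_iter()}


def generate_frequency_dataset(
    spec: GeneratorSpec,
) -> tuple[dendropy.Tree, list[tuple[str, float, float]]]:
    """Tree plus (tip, mass_kg, frequency_Hz) rows with phylogenetic signal.

    log10 mass evolves by Brownian motion; log10 frequency is the linear
    allometry plus an independent Brownian residual whose per-unit-time sd
    is ``noise_sd`` (zero noise puts every tip exactly on the line).
    """
    rng = spec.rng()
    tree = random_tree(spec, rng)
    lo, hi = spec.mass_log10_range
    log_mass = _evolve_brownian(tree, root_state=(lo + hi) / 2, rate_sd=0.5, rng=rng)
    if spec.noise_sd > 0:
        deviation = _evolve_brownian(tree, root_state=0.0, rate_sd=spec.noise_sd, rng=rng)
    else:
        deviation = {tip: 0.0 for tip in log_mass}
    rows = []
    for leaf in tree.leaf_node_iter():
        tip = leaf.taxon.label
        lm = log_mass[tip]
        lf = spec.true_intercept + spec.true_slope * lm + deviation[tip]
        rows.append((tip, 10.0**lm, 10.0**lf))
    return tree, rows


def generate_specimen_set(spec: GeneratorSpec) -> list[SpecimenRecord]:
    """Plausible fossil-specimen records spanning the observed data ranges.

    Masses are log-uniform on [0.03, 20] kg; wing length scales with the
    cube root of mass with lognormal scatter, and the longest primary is a
    uniform fraction of wing length, so that the derived loadings span
    roughly 40-12,000 N/m^2 and straddle the 170 N/m^2 Chukar-chick
    benchmark for moderate sample sizes.
    """
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    rng = spec.rng()
    lo, hi = spec.mass_log10_range
    records = []
    for i in range(spec.n):
        mass = 10.0 ** float(rng.uniform(lo, hi))
        wing_l = 0.30 * mass ** (1.0 / 3.0) * 10.0 ** float(rng.normal(0.0, 0.25))
        primary_frac = float(rng.uniform(0.30, 0.60))
        primary = primary_frac * wing_l
        planform = build_planform(wing_l, primary)
        loading = wing_loading(mass, planform.area_m2)
        records.append(
            SpecimenRecord(
                taxon=f"Synthetictaxon sp{i}",
                specimen_label=f"SYN-{i:04d}",
                source_ref="synthetic generator",
                group=Group.NONAVIAN,
                life_stage=LifeStage.ADULT,
                wing_length_m=wing_l,
                span_m=planform.span_m,
                mass_estimates=(MassEstimate(MassMethod.LITERATURE, mass, label="syn"),),
                area_m2=planform.area_m2,
                loading_N_m2=loading,
                feathers_estimated=True,
            )
        )
    return records


def generate_ontogeny_sample(
    spec: GeneratorSpec,
    model: OntogenyModel | None = None,
    max_age_dph: float = 70.0,
) -> list[tuple[float, float, float, float, float]]:
    """(age, mass_g, pectoral_pct, loading_g_cm2, wair_angle_deg) rows.

    Ages are uniform on [0, max_age); each response carries independent
    gaussian noise of sd ``noise_sd`` on its own scale (zero noise returns
    the exact polynomial values).
    """
    model = model or default_ontogeny_model()
    rng = spec.rng()
    rows = []
    for _ in range(spec.n):
        age = float(rng.uniform(0.0, max_age_dph))
        pred = ontogeny_predict(model, age)
        noise = rng.normal(0.0, spec.noise_sd, size=4) if spec.noise_sd > 0 else np.zeros(4)
        rows.append(
            (
                age,
                pred["mass_g"] + float(noise[0]),
                pred["pectoral_pct"] + float(noise[1]),
                pred["loading_g_cm2"] + float(noise[2]),
                pred["wair_angle_deg"] + float(noise[3]),
            )
        )
    return rows
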