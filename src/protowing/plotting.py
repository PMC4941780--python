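"""Diagnostic plots: wing-loading spectrum and Chukar ontogeny trajectory."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .datasets import SpecimenRecord
from .ontogeny import OntogenyModel, default_ontogeny_model, ontogeny_predict


def plot_wing_loading(records: list[SpecimenRecord], thresholds=(160.0, 170.0), ax=None):
    """Log-scale wing-loading scatter by mass, with benchmark lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for group, marker in (("nonavian", "o"), ("avialan", "^")):
        rows = [r for r in records if r.group.value == group and r.loading_N_m2]
        ax.scatter(
            [r.mass_kg for r in rows],
            [r.loading_N_m2 for r in rows],
            marker=marker,
            label=group,
            alpha=0.7,
        )
    for thr in thresholds:
        ax.axhline(thr, ls="--", lw=0.8, color="grey")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("body mass (kg)")
    ax.set_ylabel("wing loading (N/m$^2$)")
    ax.legend()
    return ax


def plot_ontogeny(model: OntogenyModel | None = None, max_age: float = 70.0, ax=None):
    """Predicted Chukar mass, loading, and max WAIR angle against age."""
    model = model or default_ontogeny_model()
    ages = np.linspace(0, max_age, 200)
    preds = [ontogeny_predict(model, a) for a in ages]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(ages, [p["wair_angle_deg"] for p in preds], label="max WAIR angle (deg)")
    ax.plot(ages, [p["mass_g"] / 10 for p in preds], label="mass (10 g)")
    ax.plot(ages, [p["loading_g_cm2"] * 10 for p in preds], label="loading (0.1 g/cm$^2$)")
    ax.set_xlabel("age (days post hatching)")
    ax.legend()
    return ax
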