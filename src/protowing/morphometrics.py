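"""Wing planform, wing loading, and body mass from skeletal measurements.

The wing is reconstructed as a straight-line chain of humerus + ulna +
metacarpal II + longest primary feather.  Span is 2.1 x that single-wing
length (the inflation absorbs the body between the wing roots), mean chord
is 65% of the longest primary, and planform area is span x chord — a
deliberate upper-bound rectangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import CHORD_FACTOR, GRAVITY, SPAN_FACTOR


@dataclass(frozen=True)
class WingPlanform:
    """Reconstructed rectangular wing planform (all metres / m^2)."""

    length_m: float
    chord_m: float
    span_m: float
    area_m2: float


@dataclass(frozen=True)
class AllometricModel:
    """Log-log single-predictor mass regression: log10(kg) = a + b log10(mm)."""

    name: str
    predictor: str  # "femur_mm" or "humerus_mm"
    intercept_a: float
    slope_b: float
    citation: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope_b):
            raise ValueError("slope must be finite")


def wing_length(humerus_mm: float, ulna_mm: float, mcII_mm: float, primary_mm: float) -> float:
    """Single-wing length (m): skeletal elements plus longest primary, in line.

    A zero primary gives the skeletal-only length (no preserved feathers).
    """
    parts = (humerus_mm, ulna_mm, mcII_mm, primary_mm)
    if any(p < 0 for p in parts):
        raise ValueError("measurements must be non-negative")
    total = sum(parts)
    if total == 0:
        raise ValueError("at least one measurement must be positive")
    return total / 1000.0


def build_planform(wing_length_m: float, primary_m: float) -> WingPlanform:
    """Rectangle planform from wing length and longest-primary length (m)."""
    if not wing_length_m > 0 or not primary_m > 0:
        raise ValueError("wing length and primary length must be positive")
    if primary_m > wing_length_m:
        raise ValueError(
            f"primary ({primary_m} m) cannot exceed wing length ({wing_length_m} m)"
        )
    chord = CHORD_FACTOR * primary_m
    span = SPAN_FACTOR * wing_length_m
    return WingPlanform(length_m=wing_length_m, chord_m=chord, span_m=span, area_m2=span * chord)


def wing_loading(mass_kg: float, area_m2: float) -> float:
    """Wing loading (N/m^2): body weight over planform area, g = 9.8."""
    if not mass_kg > 0 or not area_m2 > 0:
        raise ValueError("mass and area must be positive")
    return GRAVITY * mass_kg / area_m2


def estimate_mass(model: AllometricModel, measurement_mm: float) -> float:
    """Body mass (kg) from a limb-bone length via the given allometry."""
    if model is None:
        raise ValueError("no allometric model configured")
    if not measurement_mm > 0:
        raise ValueError("measurement must be positive")
    return 10.0 ** (model.intercept_a + model.slope_b * math.log10(measurement_mm))


def embryo_forelimb_from_humerus(humerus_mm: float, ratio: float) -> float:
    """Total forelimb length (mm) from the humerus and a humerus/forelimb ratio.

    The humerus/forelimb ratio is near-constant through ontogeny (~0.43 in
    troodontids, 0.41 in oviraptorids), letting incomplete embryos be
    reconstructed from the humerus alone.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    if not humerus_mm > 0:
        raise ValueError("humerus length must be positive")
    return humerus_mm / ratio
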