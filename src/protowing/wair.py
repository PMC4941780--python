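"""Body-weight support during wing-assisted incline running (WAIR).

The central quantity is the fraction of body weight offset by wing lift,

    bw = 0.5 Cl rho (f Amp + U)^2 S / (g M),

with Amp the per-beat wingtip arc (flap angle x wing length).  Observed
WAIR performance bands in extant birds give the classification thresholds:
bw in [0.06, 0.5) supports low-angle (level 1) WAIR, bw >= 0.5 supports
sub-vertical to vertical (level 2) WAIR, and bw >= 1.0 means the wings can
support the whole body weight (vertical takeoff regime).
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

from .constants import (
    AIR_DENSITY,
    BW_LEVEL1,
    BW_LEVEL2,
    CL_WAIR,
    FLAP_ANGLES_DEG,
    GRAVITY,
    WAIR_SPEEDS,
)
from .datasets import SpecimenRecord
from .kinematics import FrequencyModel, effective_airspeed, predict_frequency


@dataclass(frozen=True)
class Scenario:
    """One kinematic permutation of the weight-support model."""

    flap_angle_rad: float
    body_speed_m_s: float
    cl: float = CL_WAIR
    rho: float = AIR_DENSITY
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if not 0 < self.flap_angle_rad <= math.pi:
            raise ValueError(f"flap angle must be in (0, pi], got {self.flap_angle_rad}")
        if min(self.body_speed_m_s, self.cl, self.rho, self.gravity) < 0:
            raise ValueError("scenario parameters must be non-negative")

    @classmethod
    def from_degrees(cls, flap_angle_deg: float, body_speed_m_s: float, **kw) -> "Scenario":
        return cls(math.radians(flap_angle_deg), body_speed_m_s, **kw)


class WairClass(str, enum.Enum):
    NONE = "none"
    LEVEL1 = "level1"
    LEVEL2 = "level2"


@dataclass(frozen=True)
class BWResult:
    """Weight support for one specimen x scenario x frequency model cell."""

    specimen_key: tuple[str, str, str]
    scenario: Scenario
    model_label: str
    f_hz: float
    v_eff_m_s: float
    bw: float
    wair_class: WairClass


def body_weight_support(
    mass_kg: float,
    area_m2: float,
    cl: float,
    rho: float,
    v_eff_m_s: float,
    gravity: float = GRAVITY,
) -> float:
    """bw = 0.5 Cl rho V^2 S / (g M); dimensionless, no ceiling applied."""
    if not mass_kg > 0 or not area_m2 > 0:
        raise ValueError("mass and area must be positive")
    if min(cl, rho, v_eff_m_s) < 0:
        raise ValueError("Cl, rho, and airspeed must be non-negative")
    return 0.5 * cl * rho * v_eff_m_s**2 * area_m2 / (gravity * mass_kg)


def classify_wair(bw: float) -> WairClass:
    """Map a weight-support fraction onto the observed WAIR ability bands."""
    if bw < 0:
        raise ValueError(f"bw must be non-negative, got {bw}")
    if bw >= BW_LEVEL2:
        return WairClass.LEVEL2
    if bw >= BW_LEVEL1:
        return WairClass.LEVEL1
    return WairClass.NONE


def specimen_bw(
    record: SpecimenRecord,
    model: FrequencyModel,
    scenario: Scenario,
) -> BWResult:
    """Evaluate the weight-support model for one specimen under one scenario."""
    f = predict_frequency(model, record.mass_kg)
    v = effective_airspeed(f, scenario.flap_angle_rad, record.wing_length_m, scenario.body_speed_m_s)
    bw = body_weight_support(
        record.mass_kg, record.best_area_m2, scenario.cl, scenario.rho, v, scenario.gravity
    )
    return BWResult(
        specimen_key=record.key,
        scenario=scenario,
        model_label=model.label,
        f_hz=f,
        v_eff_m_s=v,
        bw=bw,
        wair_class=classify_wair(bw),
    )


def permutation_grid(
    record: SpecimenRecord,
    models: dict[str, FrequencyModel],
    angles_deg: tuple[float, ...] = FLAP_ANGLES_DEG,
    speeds: tuple[float, ...] = WAIR_SPEEDS,
    cl: float = CL_WAIR,
    rho: float = AIR_DENSITY,
) -> list[BWResult]:
    """The full flap-angle x speed x frequency-model grid for one specimen.

    With the default three angles, two speeds, and three models this is 18
    cells.  bw is monotone non-decreasing in both flap angle and speed.
    """
    results = []
    for angle, speed, label in itertools.product(angles_deg, speeds, sorted(models)):
        scenario = Scenario.from_degrees(angle, speed, cl=cl, rho=rho)
        results.append(specimen_bw(record, models[label], scenario))
    return results
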