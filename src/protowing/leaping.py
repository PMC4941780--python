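"""Wing contributions to ballistic leaping and standing vertical takeoff.

The leap itself is powered by the hindlimbs: burst muscle power (360 W/kg
of hindlimb muscle, 30% of body mass) amplified by elastic pre-loading
(scalar 2.4) accelerates the body over the leg-extension distance, giving
a launch velocity v0.  Three wing contributions are then evaluated:

* height gain at the top of the arc, where vertically-directed wing force
  offsets weight (a bw fraction) and stretches the ballistic apex by
  bw / (1 - bw);
* horizontal distance gain from wing thrust added during push-off,
  identical at any launch angle because range scales with v^2;
* standing vertical takeoff, deemed possible when bw >= 1 at an
  extant-bird launch speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (
    AIR_DENSITY,
    CL_TAKEOFF,
    CL_WAIR,
    FORELIMB_MUSCLE_FRACTION,
    GRAVITY,
    HINDLIMB_MUSCLE_FRACTION,
    PRELOAD_SCALAR,
    SPECIFIC_POWER,
    TAKEOFF_SPEEDS,
)
from .datasets import SpecimenRecord
from .kinematics import FrequencyModel, effective_airspeed, predict_frequency
from .wair import body_weight_support


class VerticalTakeoffRegime(ArithmeticError):
    """Apex weight support reached 1.0: height gain is unbounded.

    Raised by :func:`flap_height_gain`; such specimens should be routed to
    :func:`vertical_takeoff_possible` instead.
    """


@dataclass(frozen=True)
class LaunchParams:
    """Hindlimb launch model settings."""

    hindlimb_muscle_fraction: float = HINDLIMB_MUSCLE_FRACTION
    forelimb_muscle_fraction: float = FORELIMB_MUSCLE_FRACTION
    specific_power_w_kg: float = SPECIFIC_POWER
    preload_scalar: float = PRELOAD_SCALAR
    extension_length_m: float = 0.25
    launch_angles_deg: tuple[float, ...] = (30.0, 45.0)
    takeoff_speeds_m_s: tuple[float, ...] = TAKEOFF_SPEEDS
    cl_takeoff: float = CL_TAKEOFF
    rho: float = AIR_DENSITY

    def __post_init__(self) -> None:
        for frac in (self.hindlimb_muscle_fraction, self.forelimb_muscle_fraction):
            if not 0 < frac < 1:
                raise ValueError("muscle fractions must be in (0, 1)")
        if min(self.specific_power_w_kg, self.preload_scalar, self.extension_length_m) <= 0:
            raise ValueError("power, preload, and extension length must be positive")


@dataclass(frozen=True)
class LeapResult:
    """Wing contribution summary for one specimen x frequency model."""

    specimen_key: tuple[str, str, str]
    model_label: str
    v0_m_s: float
    height_m: float
    height_gain_pct: float | None  # None when in the vertical-takeoff regime
    distance_m: dict[float, float]
    distance_gain_pct: float
    vertical_takeoff: dict[float, bool]


def ballistic_takeoff_velocity(mass_kg: float, params: LaunchParams) -> float:
    """Hindlimb-powered launch speed from burst power and leg extension.

    Burst power P = specific_power x (hindlimb fraction x M) x preload.
    With push-off duration ~ 2 d / v0 over extension distance d, the energy
    balance 0.5 M v0^2 = P t gives v0 = (4 P d / M)^(1/3).  Because P is
    proportional to M, v0 is independent of mass at fixed extension length.
    """
    if not mass_kg > 0:
        raise ValueError("mass must be positive")
    power = params.specific_power_w_kg * params.hindlimb_muscle_fraction * mass_kg * params.preload_scalar
    return (4.0 * power * params.extension_length_m / mass_kg) ** (1.0 / 3.0)


def jump_distance(v_m_s: float, theta_rad: float) -> float:
    """Ballistic range over level ground: D = v^2 sin(2 theta) / g."""
    if v_m_s < 0:
        raise ValueError("speed must be non-negative")
    if not 0 <= theta_rad <= math.pi / 2:
        raise ValueError("launch angle must be in [0, pi/2]")
    return v_m_s**2 * math.sin(2.0 * theta_rad) / GRAVITY


def apex_weight_support(
    record: SpecimenRecord,
    model: FrequencyModel,
    flap_angle_rad: float,
    cl: float = CL_WAIR,
    rho: float = AIR_DENSITY,
) -> float:
    """bw with maximum wing output at the top of the leap arc (U = 0)."""
    f = predict_frequency(model, record.mass_kg)
    v = effective_airspeed(f, flap_angle_rad, record.wing_length_m, 0.0)
    return body_weight_support(record.mass_kg, record.best_area_m2, cl, rho, v)


def flap_height_gain(
    record: SpecimenRecord,
    model: FrequencyModel,
    flap_angle_rad: float,
    cl: float = CL_WAIR,
    rho: float = AIR_DENSITY,
) -> float:
    """Percent increase in maximum leap height from flapping at the apex.

    Vertically-directed wing force supporting a fraction bw0 of body
    weight reduces effective gravity to (1 - bw0) g, stretching the apex
    height by bw0 / (1 - bw0).  Raises :class:`VerticalTakeoffRegime` when
    bw0 >= 1 (the animal no longer needs the leap).
    """
    bw0 = apex_weight_support(record, model, flap_angle_rad, cl, rho)
    if bw0 >= 1.0:
        raise VerticalTakeoffRegime(
            f"{record.taxon} {record.specimen_label}: apex bw = {bw0:.2f} >= 1"
        )
    return bw0 / (1.0 - bw0) * 100.0


def horizontal_gain(
    record: SpecimenRecord,
    model: FrequencyModel,
    params: LaunchParams,
    flap_angle_rad: float,
    cl: float = CL_WAIR,
    thrust_fraction: float = 1.0,
) -> float:
    """Percent increase in jump distance from wing thrust during push-off.

    Wing force at the launch-point effective airspeed, applied over the
    push-off duration, adds dv to the launch speed; the distance gain is
    ((v0 + dv)^2 - v0^2) / v0^2 and is the same at every launch angle
    because ballistic range is proportional to v^2.
    """
    v0 = ballistic_takeoff_velocity(record.mass_kg, params)
    f = predict_frequency(model, record.mass_kg)
    v_eff = effective_airspeed(f, flap_angle_rad, record.wing_length_m, v0)
    force = 0.5 * params.rho * cl * record.best_area_m2 * v_eff**2
    t_push = 2.0 * params.extension_length_m / v0
    dv = thrust_fraction * force * t_push / record.mass_kg
    return ((v0 + dv) ** 2 - v0**2) / v0**2 * 100.0


def vertical_takeoff_possible(
    record: SpecimenRecord,
    model: FrequencyModel,
    launch_speed_m_s: float,
    flap_angle_rad: float,
    cl: float = CL_TAKEOFF,
    rho: float = AIR_DENSITY,
) -> tuple[bool, float]:
    """Standing takeoff check: bw at the given launch speed, flag bw >= 1."""
    f = predict_frequency(model, record.mass_kg)
    v = effective_airspeed(f, flap_angle_rad, record.wing_length_m, launch_speed_m_s)
    bw = body_weight_support(record.mass_kg, record.best_area_m2, cl, rho, v)
    return bw >= 1.0, bw


def leap_summary(
    record: SpecimenRecord,
    model: FrequencyModel,
    params: LaunchParams,
    flap_angle_rad: float,
) -> LeapResult:
    """Bundle the three leaping analyses for one specimen x model."""
    v0 = ballistic_takeoff_velocity(record.mass_kg, params)
    try:
        h_gain: float | None = flap_height_gain(record, model, flap_angle_rad)
    except VerticalTakeoffRegime:
        h_gain = None
    d_gain = horizontal_gain(record, model, params, flap_angle_rad)
    distances = {
        ang: jump_distance(v0, math.radians(ang)) for ang in params.launch_angles_deg
    }
    vt = {
        u: vertical_takeoff_possible(record, model, u, flap_angle_rad, params.cl_takeoff, params.rho)[0]
        for u in params.takeoff_speeds_m_s
    }
    return LeapResult(
        specimen_key=record.key,
        model_label=model.label,
        v0_m_s=v0,
        height_m=v0**2 / (2.0 * GRAVITY),
        height_gain_pct=h_gain,
        distance_m=distances,
        distance_gain_pct=d_gain,
        vertical_takeoff=vt,
    )
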