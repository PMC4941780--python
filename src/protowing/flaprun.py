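"""Iterative flap-running velocity augmentation.

Starting from a 2 m/s run, each wingbeat produces an aerodynamic force at
the current effective airspeed; a fraction k of that force is reoriented as
thrust, whose impulse over one beat period (1/f) increments the ground
speed.  Ten wingbeats are iterated by default.  k = 1 (all lift available
as thrust) is the deliberately optimistic default; body drag and hindlimb
gait limits are not modelled, so the resulting speeds are upper bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import AIR_DENSITY, CL_FLAPRUN, CL_TAKEOFF, FLAPRUN_START_SPEED, GRAVITY
from .datasets import SpecimenRecord
from .kinematics import FrequencyModel, effective_airspeed, predict_frequency


@dataclass(frozen=True)
class FlapRunParams:
    """Settings for the flap-running iteration."""

    cl: float = CL_FLAPRUN
    start_speed_m_s: float = FLAPRUN_START_SPEED
    n_iterations: int = 10
    thrust_fraction: float = 1.0
    downstroke_angle_rad: float = math.pi / 2
    rho: float = AIR_DENSITY

    def __post_init__(self) -> None:
        if not 0 < self.thrust_fraction <= 1:
            raise ValueError("thrust fraction must be in (0, 1]")
        if self.n_iterations < 0 or min(self.cl, self.start_speed_m_s, self.rho) < 0:
            raise ValueError("parameters must be non-negative")


@dataclass(frozen=True)
class FlapRunResult:
    """Velocity sequence over the wingbeat iterations."""

    velocities_m_s: tuple[float, ...]
    pct_increase: float
    takeoff_speed_m_s: float
    reaches_takeoff: bool

    @property
    def final_speed_m_s(self) -> float:
        return self.velocities_m_s[-1]


def steady_takeoff_speed(
    mass_kg: float, area_m2: float, cl: float = CL_TAKEOFF, rho: float = AIR_DENSITY
) -> float:
    """Airspeed at which wing lift equals body weight: v = sqrt(2gM / (rho Cl S))."""
    if min(mass_kg, area_m2, cl, rho) <= 0:
        raise ValueError("all inputs must be positive")
    return math.sqrt(2.0 * GRAVITY * mass_kg / (rho * cl * area_m2))


def flap_run_step(
    v_m_s: float,
    mass_kg: float,
    area_m2: float,
    f_hz: float,
    params: FlapRunParams,
    wing_length_m: float,
) -> float:
    """One wingbeat: thrust impulse over the beat period added to speed."""
    v_eff = effective_airspeed(f_hz, params.downstroke_angle_rad, wing_length_m, v_m_s)
    force = 0.5 * params.rho * params.cl * area_m2 * v_eff**2
    thrust = params.thrust_fraction * force
    return v_m_s + thrust / (mass_kg * f_hz)


def flap_run_trajectory(
    record: SpecimenRecord,
    model: FrequencyModel,
    params: FlapRunParams | None = None,
) -> FlapRunResult:
    """Run the wingbeat iteration for one specimen.

    The wingbeat frequency is held at the model's prediction for the
    specimen's mass; each of the ``n_iterations`` beats contributes a
    thrust impulse at the then-current effective airspeed, so the velocity
    sequence rises convexly.
    """
    params = params or FlapRunParams()
    mass = record.mass_kg
    area = record.best_area_m2
    f = predict_frequency(model, mass)
    velocities = [params.start_speed_m_s]
    for _ in range(params.n_iterations):
        velocities.append(
            flap_run_step(velocities[-1], mass, area, f, params, record.wing_length_m)
        )
    v0, v_final = velocities[0], velocities[-1]
    pct = (v_final - v0) / v0 * 100.0 if v0 > 0 else float("nan")
    v_to = steady_takeoff_speed(mass, area, rho=params.rho)
    return FlapRunResult(
        velocities_m_s=tuple(velocities),
        pct_increase=pct,
        takeoff_speed_m_s=v_to,
        reaches_takeoff=v_final >= v_to,
    )
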