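"""Chukar partridge WAIR ontogeny models.

Growth of WAIR performance in the Chukar partridge (*Alectoris chukar*) is
summarised by four cubic polynomials fitted to published ontogenetic data
(body mass from age in days post hatching, then pectoral muscle fraction,
wing loading, and maximum WAIR angle from mass) plus one linear regression
of maximum WAIR angle on wing loading measured in g/cm^2:

    angle = 100.17 - 20.824 x          (x in g/cm^2)

The 65 deg angle demarcates quadrupedal crawling from true WAIR, and the
predicted maximum angle is capped at 100 deg.  These models bridge fossil
wing loadings onto the empirical Chukar performance scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import convert_loading

#: Crawling-to-WAIR demarcation angle, degrees.
CRAWL_WAIR_ANGLE_DEG: float = 65.0

#: Cap applied to predicted maximum WAIR angle, degrees.
MAX_WAIR_ANGLE_DEG: float = 100.0

#: Upper age bound of the fitted domain, days post hatching.
MAX_AGE_DPH: float = 100.0


@dataclass(frozen=True)
class CubicModel:
    """y = c0 + c1 x + c2 x^2 + c3 x^3 with reference metadata."""

    c0: float
    c1: float
    c2: float
    c3: float
    response: str = ""
    predictor: str = ""
    r_squared: float | None = None  # as published; not recomputed here

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.c0, self.c1, self.c2, self.c3)

    def __call__(self, x: float) -> float:
        return self.c0 + x * (self.c1 + x * (self.c2 + x * self.c3))


@dataclass(frozen=True)
class LinearModel:
    """y = intercept + slope x."""

    intercept: float
    slope: float
    response: str = ""
    predictor: str = ""
    r_squared: float | None = None

    def __call__(self, x: float) -> float:
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class OntogenyModel:
    """The chained Chukar growth models."""

    mass_from_age: CubicModel
    pectoral_pct_from_mass: CubicModel
    loading_from_mass: CubicModel
    wair_angle_from_mass: CubicModel
    wair_angle_from_loading: LinearModel
    angle_cap_deg: float = MAX_WAIR_ANGLE_DEG
    max_age_dph: float = MAX_AGE_DPH


def default_ontogeny_model() -> OntogenyModel:
    """The published Chukar growth polynomials (first ~70 days of growth)."""
    return OntogenyModel(
        mass_from_age=CubicModel(
            5.730818, 3.472647, -0.011605, 0.000661,
            response="body mass (g)", predictor="age (dph)", r_squared=0.9902,
        ),
        pectoral_pct_from_mass=CubicModel(
            0.858022, 0.231592, -0.000658, 5.9340e-7,
            response="pectoral muscle mass (% body mass)", predictor="body mass (g)",
            r_squared=0.92,
        ),
        loading_from_mass=CubicModel(
            1.692164, -0.018717, 8.756264e-5, -9.483335e-8,
            response="wing loading (g/cm^2)", predictor="body mass (g)", r_squared=0.69,
        ),
        wair_angle_from_mass=CubicModel(
            38.119489, 1.137820, -0.007969, 1.925223e-5,
            response="max WAIR angle (deg)", predictor="body mass (g)", r_squared=0.9575,
        ),
        wair_angle_from_loading=LinearModel(
            100.17, -20.824,
            response="max WAIR angle (deg)", predictor="wing loading (g/cm^2)",
            r_squared=0.848,
        ),
    )


def ontogeny_predict(model: OntogenyModel, age_dph: float) -> dict[str, float]:
    """Chukar state at a given age: mass, pectoral %, loading, max WAIR angle.

    The age->mass cubic feeds the three mass-predicated models; the
    predicted angle is capped at ``model.angle_cap_deg``.
    """
    if not 0 <= age_dph < model.max_age_dph:
        raise ValueError(f"age must be in [0, {model.max_age_dph}) dph, got {age_dph}")
    mass = model.mass_from_age(age_dph)
    return {
        "age_dph": age_dph,
        "mass_g": mass,
        "pectoral_pct": model.pectoral_pct_from_mass(mass),
        "loading_g_cm2": model.loading_from_mass(mass),
        "wair_angle_deg": min(model.wair_angle_from_mass(mass), model.angle_cap_deg),
    }


def wair_angle_from_loading(
    loading_g_cm2: float, model: OntogenyModel | None = None
) -> tuple[float, str]:
    """Maximum WAIR angle from wing loading, with crawl/WAIR banding.

    Returns (angle_deg, band) where band is ``"wair"`` when the predicted
    angle clears the 65 deg crawling demarcation, else ``"crawl"``.
    """
    if loading_g_cm2 < 0:
        raise ValueError("loading must be non-negative")
    model = model or default_ontogeny_model()
    angle = model.wair_angle_from_loading(loading_g_cm2)
    band = "wair" if angle >= CRAWL_WAIR_ANGLE_DEG else "crawl"
    return angle, band


def wair_angle_for_specimen_loading(
    loading_N_m2: float, model: OntogenyModel | None = None
) -> tuple[float, str] | None:
    """Bridge a fossil wing loading (N/m^2) onto the Chukar angle scale.

    Only loadings comparable to measured Chukar values (< 196 N/m^2, i.e.
    2.0 g/cm^2) are admitted; heavier loadings return None.
    """
    g_cm2 = convert_loading(loading_N_m2, "N_m2", "g_cm2")
    if g_cm2 >= 2.0:
        return None
    return wair_angle_from_loading(g_cm2, model)


def fit_cubic(data: list[tuple[float, float]], response: str = "", predictor: str = "") -> CubicModel:
    """Least-squares cubic through (x, y) points, with R^2.

    Requires at least four distinct x values (otherwise the normal
    equations are rank deficient).
    """
    x = np.asarray([d[0] for d in data], dtype=float)
    y = np.asarray([d[1] for d in data], dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct x values to fit a cubic")
    # polyfit returns highest degree first
    c3, c2, c1, c0 = np.polyfit(x, y, 3)
    yhat = c0 + x * (c1 + x * (c2 + x * c3))
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CubicModel(
        float(c0), float(c1), float(c2), float(c3),
        response=response, predictor=predictor, r_squared=r2,
    )
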