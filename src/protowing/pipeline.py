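"""End-to-end analysis driver and result summaries.

Runs the WAIR permutation grid, the flap-running iteration, and the
leaping analyses over a specimen table under one configuration, and
reduces results (or a published reference table) to the headline counts:
how many specimens, and how many genera, clear each weight-support or
wing-loading benchmark.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import pandas as pd
import yaml

from . import constants as C
from .datasets import ReferenceBWTable, SpecimenRecord
from .flaprun import FlapRunParams, flap_run_trajectory
from .kinematics import FrequencyModel, calibrate_from_reference, models_from_config
from .leaping import LaunchParams, leap_summary
from .morphometrics import AllometricModel
from .wair import permutation_grid

logger = logging.getLogger("protowing")


class ConfigurationError(ValueError):
    """A required configuration block is missing or malformed."""


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable constants of the analysis, with published defaults."""

    rho: float = C.AIR_DENSITY
    gravity: float = C.GRAVITY
    cl_wair: float = C.CL_WAIR
    cl_flaprun: float = C.CL_FLAPRUN
    cl_takeoff: float = C.CL_TAKEOFF
    cl_validation: float = C.CL_VALIDATION
    flap_angles_deg: tuple[float, ...] = C.FLAP_ANGLES_DEG
    wair_speeds: tuple[float, ...] = C.WAIR_SPEEDS
    flaprun_start_speed: float = C.FLAPRUN_START_SPEED
    takeoff_speeds: tuple[float, ...] = C.TAKEOFF_SPEEDS
    bw_level1: float = C.BW_LEVEL1
    bw_level2: float = C.BW_LEVEL2
    bw_takeoff: float = C.BW_TAKEOFF
    preload_scalar: float = C.PRELOAD_SCALAR
    specific_power_w_kg: float = C.SPECIFIC_POWER
    hindlimb_muscle_fraction: float = C.HINDLIMB_MUSCLE_FRACTION
    forelimb_muscle_fraction: float = C.FORELIMB_MUSCLE_FRACTION
    extension_length_m: float = 0.25
    frequency_models: dict | None = None  # label -> {intercept, slope}; None = calibrate
    allometry: dict | None = None

    def __post_init__(self) -> None:
        if not self.bw_level1 < self.bw_level2 <= self.bw_takeoff:
            raise ConfigurationError("thresholds must satisfy level1 < level2 <= takeoff")
        for name in (
            "rho", "gravity", "cl_wair", "cl_flaprun", "cl_takeoff",
            "preload_scalar", "specific_power_w_kg",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("flap_angles_deg", "wair_speeds", "takeoff_speeds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def allometric_models(self) -> dict[str, AllometricModel]:
        if not self.allometry:
            raise ConfigurationError("config block 'allometry' is missing")
        out = {}
        for name, spec in self.allometry.items():
            try:
                out[name] = AllometricModel(
                    name=name,
                    predictor=spec["predictor"],
                    intercept_a=float(spec["intercept"]),
                    slope_b=float(spec["slope"]),
                    citation=spec.get("citation", ""),
                )
            except (KeyError, TypeError) as exc:
                raise ConfigurationError(
                    f"allometry entry {name!r} must define predictor, intercept, slope"
                ) from exc
        return out

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisBundle:
    """Long-format result tables from one full pipeline run."""

    wair: pd.DataFrame
    flaprun: pd.DataFrame
    leap: pd.DataFrame
    models: dict[str, FrequencyModel]
    config: AnalysisConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.wair.to_csv(out / "wair_grid.csv", index=False)
        self.flaprun.to_csv(out / "flaprun.csv", index=False)
        self.leap.to_csv(out / "leap.csv", index=False)
        coeffs = {
            label: {"intercept": m.intercept, "slope": m.slope, "provenance": m.provenance}
            for label, m in self.models.items()
        }
        (out / "frequency_models.yaml").write_text(yaml.safe_dump(coeffs, sort_keys=True))


def resolve_frequency_models(
    config: AnalysisConfig,
    specimens: list[SpecimenRecord] | None = None,
    reference: ReferenceBWTable | None = None,
) -> dict[str, FrequencyModel]:
    """Frequency models from config coefficients, else by calibration."""
    if config.frequency_models:
        return models_from_config(config.frequency_models)
    if specimens is None or reference is None:
        raise ConfigurationError(
            "config block 'frequency_models' is missing and no reference table "
            "was provided for calibration"
        )
    return calibrate_from_reference(specimens, reference, rho=config.rho, cl=config.cl_wair)


def run_full_analysis(
    specimens: list[SpecimenRecord],
    config: AnalysisConfig,
    models: dict[str, FrequencyModel] | None = None,
    reference: ReferenceBWTable | None = None,
) -> AnalysisBundle:
    """WAIR grid + flap running + leaping for every specimen row.

    Deterministic given config: there is no randomness in the forward
    pipeline.  Any per-specimen failure is re-raised with the specimen key
    attached.
    """
    if models is None:
        models = resolve_frequency_models(config, specimens, reference)
    logger.info("run_full_analysis: %d specimens, config %s", len(specimens), config.digest())

    wair_rows, fr_rows, leap_rows = [], [], []
    launch = LaunchParams(
        hindlimb_muscle_fraction=config.hindlimb_muscle_fraction,
        forelimb_muscle_fraction=config.forelimb_muscle_fraction,
        specific_power_w_kg=config.specific_power_w_kg,
        preload_scalar=config.preload_scalar,
        extension_length_m=config.extension_length_m,
        takeoff_speeds_m_s=config.takeoff_speeds,
        cl_takeoff=config.cl_takeoff,
        rho=config.rho,
    )
    for rec in specimens:
        try:
            for cell in permutation_grid(
                rec, models, config.flap_angles_deg, config.wair_speeds,
                cl=config.cl_wair, rho=config.rho,
            ):
                wair_rows.append(
                    {
                        "taxon": rec.taxon,
                        "specimen_label": rec.specimen_label,
                        "mass_label": rec.mass_label,
                        "group": rec.group.value,
                        "paravian": rec.paravian,
                        "flap_angle_deg": math.degrees(cell.scenario.flap_angle_rad),
                        "speed_m_s": cell.scenario.body_speed_m_s,
                        "model": cell.model_label,
                        "f_hz": cell.f_hz,
                        "v_eff_m_s": cell.v_eff_m_s,
                        "bw": cell.bw,
                        "wair_class": cell.wair_class.value,
                    }
                )
            for label, model in sorted(models.items()):
                for angle in config.flap_angles_deg:
                    fr = flap_run_trajectory(
                        rec,
                        model,
                        FlapRunParams(
                            cl=config.cl_flaprun,
                            start_speed_m_s=config.flaprun_start_speed,
                            downstroke_angle_rad=math.radians(angle),
                            rho=config.rho,
                        ),
                    )
                    fr_rows.append(
                        {
                            "taxon": rec.taxon,
                            "specimen_label": rec.specimen_label,
                            "mass_label": rec.mass_label,
                            "paravian": rec.paravian,
                            "model": label,
                            "flap_angle_deg": angle,
                            "final_speed_m_s": fr.final_speed_m_s,
                            "pct_increase": fr.pct_increase,
                            "takeoff_speed_m_s": fr.takeoff_speed_m_s,
                            "reaches_takeoff": fr.reaches_takeoff,
                        }
                    )
                    lp = leap_summary(rec, model, launch, math.radians(angle))
                    leap_rows.append(
                        {
                            "taxon": rec.taxon,
                            "specimen_label": rec.specimen_label,
                            "mass_label": rec.mass_label,
                            "paravian": rec.paravian,
                            "model": label,
                            "flap_angle_deg": angle,
                            "v0_m_s": lp.v0_m_s,
                            "height_gain_pct": lp.height_gain_pct,
                            "distance_gain_pct": lp.distance_gain_pct,
                            **{
                                f"takeoff_at_{u}": flag
                                for u, flag in lp.vertical_takeoff.items()
                            },
                        }
                    )
        except Exception as exc:
            logger.error("failure at specimen %s: %s", rec.key, exc)
            raise RuntimeError(f"analysis failed for specimen {rec.key}") from exc
    return AnalysisBundle(
        wair=pd.DataFrame(wair_rows),
        flaprun=pd.DataFrame(fr_rows),
        leap=pd.DataFrame(leap_rows),
        models=models,
        config=config,
    )


def _genus(taxon: str) -> str:
    return taxon.split()[0]


def summarize_counts(
    reference: ReferenceBWTable | pd.DataFrame,
    specimens: list[SpecimenRecord],
    level1: float = C.BW_LEVEL1,
    level2: float = C.BW_LEVEL2,
    loading_thresholds: tuple[float, ...] = (170.0, 196.0, 200.0),
) -> dict:
    """Benchmark counts over a weight-support table plus loading thresholds.

    For each speed block, counts non-avian specimens (and genera) whose
    best bw across the three frequency estimators clears the level-1 and
    level-2 benchmarks; separately counts non-avian specimen rows with
    wing loading below each threshold.
    """
    df = reference.df if isinstance(reference, ReferenceBWTable) else reference
    by_key = {r.key: r for r in specimens}
    rows = df.copy()
    rows["group"] = [
        by_key[(t, s, m)].group.value if (t, s, m) in by_key else "unknown"
        for t, s, m in zip(rows["taxon"], rows["specimen_label"], rows["mass_label"])
    ]
    out: dict = {"by_speed": {}, "loading": {}}
    nonav = rows[rows["group"] == "nonavian"]
    for speed, block in nonav.groupby("speed_m_s"):
        best = block[list(ReferenceBWTable.BW_COLUMNS)].max(axis=1)
        hit1 = block[best >= level1]
        hit2 = block[best >= level2]
        out["by_speed"][float(speed)] = {
            "n_specimens": int(len(block)),
            "level1_specimens": int(len(hit1)),
            "level1_genera": int(hit1["taxon"].map(_genus).nunique()),
            "level2_specimens": int(len(hit2)),
            "level2_genera": int(hit2["taxon"].map(_genus).nunique()),
        }
    nonav_recs = [r for r in specimens if r.group.value == "nonavian"]
    for thr in loading_thresholds:
        below = [r for r in nonav_recs if r.loading_N_m2 is not None and r.loading_N_m2 < thr]
        out["loading"][thr] = {
            "specimens_below": len(below),
            "genera_below": len({_genus(r.taxon) for r in below}),
        }
    return out


def annotate_tree(
    tree: dendropy.Tree,
    results: dict[str, float],
    metric: str = "bw",
    clades: dict[str, list[str]] | None = None,
) -> tuple[dendropy.Tree, dict[str, tuple[float, float]]]:
    """Attach metric values as tip comments; report per-clade value ranges.

    ``results`` maps tip labels to values; unmatched tips are left bare.
    ``clades`` maps clade names to member tip labels.  Returns the
    annotated tree (newick comments ``[metric=value]``) and the clade
    name -> (min, max) ranges.
    """
    matched = 0
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label in results:
            leaf.annotations.add_new(metric, results[label])
            matched += 1
    if matched == 0:
        raise ValueError("no result keys match any tree tip")
    ranges = {}
    for name, members in (clades or {}).items():
        vals = [results[m] for m in members if m in results]
        if vals:
            ranges[name] = (min(vals), max(vals))
    return tree, ranges
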