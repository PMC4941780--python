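"""Specimen data model, packaged reference tables, and unit helpers.

The packaged fixtures transcribe three published tables:

``table1_specimens.csv``
    Fossil specimens with reconstructed wing planform, body-mass estimates
    and wing loading.  Specimens with two published mass estimates appear
    once per estimate; the pair shares ``taxon``/``specimen_label`` and is
    distinguished by ``mass_label``.

``table2_extant_validation.csv``
    Extant-bird WAIR and takeoff measurements used to ground-truth the
    weight-support equation (Chukar ontogenetic stages, pigeon WAIR, and
    seven takeoff datasets).

``table3_reference_bw.csv``
    Published body-weight-support fractions per specimen under the three
    wingbeat-frequency estimators (ALL / GF / MOD) at the 90 deg flap angle
    and two centre-of-mass speeds.

Column definitions live in ``data/data_dictionary.md``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .constants import GRAVITY, N_PER_M2_PER_G_CM2, SPAN_FACTOR


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


class SpecimenValidationError(ValueError):
    """A table row violates a hard specimen invariant."""


class Group(str, enum.Enum):
    NONAVIAN = "nonavian"
    AVIALAN = "avialan"


class LifeStage(str, enum.Enum):
    ADULT = "adult"
    JUVENILE = "juvenile"
    EMBRYO = "embryo"


class MassMethod(str, enum.Enum):
    FEMUR_CF = "femur_CF"
    HUMERUS_LIU = "humerus_Liu"
    HUMERUS_FE = "humerus_Fe"
    LITERATURE = "literature"


@dataclass(frozen=True)
class MassEstimate:
    """One body-mass estimate with the regression (or source) that produced it."""

    method: MassMethod
    value_kg: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.value_kg > 0:
            raise SpecimenValidationError(f"mass must be positive, got {self.value_kg}")
        if not self.label:
            object.__setattr__(self, "label", _DEFAULT_MASS_LABEL[self.method])


_DEFAULT_MASS_LABEL = {
    MassMethod.FEMUR_CF: "CF",
    MassMethod.HUMERUS_LIU: "Liu",
    MassMethod.HUMERUS_FE: "Fe",
    MassMethod.LITERATURE: "lit",
}


@dataclass(frozen=True)
class SkeletalMeasures:
    """Raw skeletal and feather measurements, millimetres, each optional."""

    humerus_mm: float | None = None
    ulna_mm: float | None = None
    mcII_mm: float | None = None
    femur_mm: float | None = None
    longest_primary_mm: float | None = None
    furcula_width_mm: float | None = None

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise SpecimenValidationError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen x mass-estimate analysis row.

    ``area_m2`` and ``loading_N_m2`` are reference values as printed; the
    loading column is authoritative for recovering unrounded wing area (see
    :func:`reference_wing_area`), because printed areas are rounded to two
    decimals while loadings are integers computed before rounding.
    """

    taxon: str
    specimen_label: str
    source_ref: str
    group: Group
    life_stage: LifeStage
    wing_length_m: float
    span_m: float
    mass_estimates: tuple[MassEstimate, ...]
    area_m2: float | None = None
    loading_N_m2: float | None = None
    feathers_estimated: bool = False
    paravian: bool = True
    skeletal: SkeletalMeasures | None = None

    def __post_init__(self) -> None:
        if not self.wing_length_m > 0:
            raise SpecimenValidationError(
                f"{self.taxon}: wing length must be positive, got {self.wing_length_m}"
            )
        if not self.span_m > 0:
            raise SpecimenValidationError(f"{self.taxon}: span must be positive")
        if not self.mass_estimates:
            raise SpecimenValidationError(f"{self.taxon}: at least one mass estimate required")
        if self.area_m2 is not None and self.area_m2 < 0:
            raise SpecimenValidationError(f"{self.taxon}: negative wing area")
        if self.loading_N_m2 is not None and not self.loading_N_m2 > 0:
            raise SpecimenValidationError(f"{self.taxon}: loading must be positive")

    @property
    def mass_kg(self) -> float:
        """Body mass of this analysis row (first, i.e. only, estimate)."""
        return self.mass_estimates[0].value_kg

    @property
    def mass_label(self) -> str:
        return self.mass_estimates[0].label

    @property
    def key(self) -> tuple[str, str, str]:
        """Row key: (taxon, specimen_label, mass_label)."""
        return (self.taxon, self.specimen_label, self.mass_label)

    @property
    def reference_area_m2(self) -> float | None:
        """Unrounded wing area recovered from the printed loading."""
        if self.loading_N_m2 is None:
            return None
        return reference_wing_area(self.mass_kg, self.loading_N_m2)

    @property
    def best_area_m2(self) -> float:
        """Wing area for analysis: loading-derived if possible, else printed."""
        area = self.reference_area_m2
        if area is None:
            area = self.area_m2
        if area is None or area <= 0:
            raise SpecimenValidationError(f"{self.taxon}: no usable wing area")
        return area

    def consistency_issues(self, span_rtol: float = 0.05, area_atol: float = 0.005) -> list[str]:
        """Soft internal-consistency checks between the printed columns.

        Returns human-readable descriptions of violations; an empty list
        means the row's span and area/loading columns agree with the
        reconstruction rules to within display-rounding tolerance.  Rows
        that fail are transcription artefacts of the source table and are
        excluded from regression calibration.
        """
        issues: list[str] = []
        expected_span = SPAN_FACTOR * self.wing_length_m
        if abs(self.span_m - expected_span) / expected_span > span_rtol:
            issues.append(
                f"span {self.span_m} differs from {SPAN_FACTOR} x wing length "
                f"({expected_span:.3f}) by more than {span_rtol:.0%}"
            )
        if (
            self.area_m2 is not None
            and self.loading_N_m2 is not None
            and self.area_m2 >= 0.01
            and abs(self.area_m2 - reference_wing_area(self.mass_kg, self.loading_N_m2)) > area_atol
        ):
            issues.append(
                f"printed area {self.area_m2} inconsistent with loading-derived "
                f"area {reference_wing_area(self.mass_kg, self.loading_N_m2):.4f}"
            )
        return issues


_TABLE1_COLUMNS = [
    "taxon",
    "specimen_label",
    "source_ref",
    "group",
    "life_stage",
    "wing_length_m",
    "span_m",
    "mass_method",
    "mass_label",
    "mass_kg",
    "area_m2",
    "loading_N_m2",
    "feathers_estimated",
]


def reference_wing_area(mass_kg: float, loading_N_m2: float) -> float:
    """Recover wing area (m^2) from body mass and wing loading.

    Inverts loading = g M / S with g = 9.8.  Printed areas are rounded to
    two decimals, so the integer loading column preserves more precision.
    """
    if not mass_kg > 0 or not loading_N_m2 > 0:
        raise ValueError("mass and loading must be positive")
    return GRAVITY * mass_kg / loading_N_m2


def convert_loading(value: float, from_unit: str = "N_m2", to_unit: str = "g_cm2") -> float:
    """Convert wing loading between N/m^2 and g/cm^2 (1 g/cm^2 = 98 N/m^2)."""
    if value < 0:
        raise ValueError("loading must be non-negative")
    units = {"N_m2", "g_cm2"}
    if from_unit not in units or to_unit not in units:
        raise ValueError(f"unknown unit: {from_unit!r} -> {to_unit!r}")
    if from_unit == to_unit:
        return value
    if from_unit == "g_cm2":
        return value * N_PER_M2_PER_G_CM2
    return value / N_PER_M2_PER_G_CM2


def _records_from_frame(df: pd.DataFrame, path: str = "<frame>") -> list[SpecimenRecord]:
    missing = [c for c in _TABLE1_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    records: list[SpecimenRecord] = []
    for idx, row in df.iterrows():
        try:
            est = MassEstimate(
                method=MassMethod(row["mass_method"]),
                value_kg=float(row["mass_kg"]),
                label=str(row["mass_label"]),
            )
            records.append(
                SpecimenRecord(
                    taxon=str(row["taxon"]),
                    specimen_label="" if pd.isna(row["specimen_label"]) else str(row["specimen_label"]),
                    source_ref=str(row["source_ref"]),
                    group=Group(row["group"]),
                    life_stage=LifeStage(row["life_stage"]),
                    wing_length_m=float(row["wing_length_m"]),
                    span_m=float(row["span_m"]),
                    mass_estimates=(est,),
                    area_m2=None if pd.isna(row["area_m2"]) else float(row["area_m2"]),
                    loading_N_m2=None if pd.isna(row["loading_N_m2"]) else float(row["loading_N_m2"]),
                    feathers_estimated=bool(row["feathers_estimated"]),
                    paravian=bool(row.get("paravian", True)),
                )
            )
        except (ValueError, SpecimenValidationError) as exc:
            raise SpecimenValidationError(f"{path}, row {idx}: {exc}") from exc
    return records


def load_specimen_table(path: str | Path, dialect: dict | None = None) -> list[SpecimenRecord]:
    """Read a specimen CSV into validated :class:`SpecimenRecord` rows.

    Each CSV row is one specimen x mass-estimate; rows sharing
    taxon/specimen_label are alternative mass reconstructions of the same
    fossil.  ``dialect`` is passed through to :func:`pandas.read_csv`.
    """
    df = pd.read_csv(path, **(dialect or {}))
    return _records_from_frame(df, str(path))


def write_specimen_table(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write records back to the CSV dialect read by :func:`load_specimen_table`."""
    rows = []
    for r in records:
        rows.append(
            {
                "taxon": r.taxon,
                "specimen_label": r.specimen_label,
                "source_ref": r.source_ref,
                "group": r.group.value,
                "life_stage": r.life_stage.value,
                "wing_length_m": r.wing_length_m,
                "span_m": r.span_m,
                "mass_method": r.mass_estimates[0].method.value,
                "mass_label": r.mass_label,
                "mass_kg": r.mass_kg,
                "area_m2": r.area_m2,
                "loading_N_m2": r.loading_N_m2,
                "feathers_estimated": r.feathers_estimated,
                "paravian": r.paravian,
            }
        )
    pd.DataFrame(rows, columns=_TABLE1_COLUMNS + ["paravian"]).to_csv(path, index=False)


@dataclass
class ReferenceBWTable:
    """Published per-specimen weight-support fractions (90 deg flap angle).

    One row per specimen x mass-estimate x speed with the three
    frequency-estimator columns ``bw_ALL``, ``bw_GF``, ``bw_MOD``.
    """

    df: pd.DataFrame
    speeds: tuple[float, float] = (0.6, 1.5)

    BW_COLUMNS = ("bw_ALL", "bw_GF", "bw_MOD")
    KEY_COLUMNS = ("taxon", "specimen_label", "mass_label")

    def __post_init__(self) -> None:
        required = list(self.KEY_COLUMNS) + ["speed_m_s"] + list(self.BW_COLUMNS)
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"reference table missing column(s): {', '.join(missing)}")
        for col in self.BW_COLUMNS:
            if (self.df[col] < 0).any():
                raise SpecimenValidationError(f"negative {col} value in reference table")
        counts = self.df.groupby(list(self.KEY_COLUMNS))["speed_m_s"].nunique()
        if not (counts == 2).all():
            bad = counts[counts != 2].index.tolist()
            raise SpecimenValidationError(f"specimens without both speed blocks: {bad}")

    def at_speed(self, speed: float) -> pd.DataFrame:
        return self.df[self.df["speed_m_s"] == speed].copy()

    def __len__(self) -> int:
        return len(self.df)


def _data_path(name: str):
    return resources.files("protowing.data").joinpath(name)


def load_packaged_specimens() -> list[SpecimenRecord]:
    """The packaged fossil specimen table (58 analysis rows, 34 non-avian)."""
    with resources.as_file(_data_path("table1_specimens.csv")) as p:
        return load_specimen_table(p)


def load_packaged_reference_bw() -> ReferenceBWTable:
    """The packaged published weight-support table."""
    with resources.as_file(_data_path("table3_reference_bw.csv")) as p:
        return ReferenceBWTable(pd.read_csv(p))


def load_packaged_extant_validation() -> pd.DataFrame:
    """Extant-bird WAIR/takeoff validation rows.

    Range-valued cells (pigeon mass, frequency, bw) are split into
    ``*_lo``/``*_hi`` columns; point values have lo == hi.
    """
    with resources.as_file(_data_path("table2_extant_validation.csv")) as p:
        return pd.read_csv(p)


def specimen_frame(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Flatten records into an analysis DataFrame (one row per record)."""
    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in records],
            "specimen_label": [r.specimen_label for r in records],
            "mass_label": [r.mass_label for r in records],
            "group": [r.group.value for r in records],
            "life_stage": [r.life_stage.value for r in records],
            "paravian": [r.paravian for r in records],
            "wing_length_m": [r.wing_length_m for r in records],
            "span_m": [r.span_m for r in records],
            "mass_kg": [r.mass_kg for r in records],
            "loading_N_m2": [r.loading_N_m2 for r in records],
            "area_m2": [r.best_area_m2 for r in records],
        }
    )
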