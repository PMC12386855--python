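"""Domain types, file schemas and validation for cage-trial datasets.

The statistical unit throughout is the cage-cohort (one cage in one
replicate).  Four delimited-text tables describe a trial:

``cohorts.csv``
    cage_id,replicate_id,treatment,eggs_total,eggs_hatched,e_meta,
    l_death,n_death,n_meta,censored
``intervals.csv``
    cage_id,day,stage,deaths,molts
``water.csv``
    cage_id,replicate_id,concentration_ppb,females_present,
    fertile_males_present,s2f,dose_mg_per_200
``design.yaml``
    replicates, horizon_days, observation_interval_days and the cage list.

All counts are stored as integers; fractional counts are rejected at read
time.  Examination days are absolute days since flooding, and events are
attributed to the half-open interval (previous_day, day].
"""

from __future__ import annotations

import enum
import numbers
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "TreatmentLabel",
    "TreatmentCategory",
    "TrialDesign",
    "CageSpec",
    "CohortCounts",
    "IntervalRecord",
    "ConcentrationSample",
    "SchemaError",
    "DesignWarning",
    "TREATMENTS",
    "TREATMENT_ORDER",
    "read_trial",
    "read_cohorts",
    "read_intervals",
    "read_water",
    "read_design",
    "write_trial",
    "validate_design",
]


class SchemaError(ValueError):
    """An input table violates the documented schema or an invariant."""


class DesignWarning(UserWarning):
    """The trial layout deviates from the canonical 5-treatment x 4-replicate design."""


class TreatmentLabel(str, enum.Enum):
    CONTROL = "control"
    SIT1 = "SIT1"
    SIT5 = "SIT5"
    BSIT1 = "bSIT1"
    BSIT5 = "bSIT5"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TreatmentCategory:
    """A release treatment: sterile-to-fertile male ratio plus boosting status."""

    label: str
    s2f: float
    boosted: bool

    def __post_init__(self) -> None:
        if self.s2f < 0:
            raise ValueError(f"s2f must be non-negative, got {self.s2f}")


#: The canonical treatments, in the fixed reporting order.
TREATMENTS: dict[str, TreatmentCategory] = {
    "control": TreatmentCategory("control", 0.0, False),
    "SIT1": TreatmentCategory("SIT1", 1.0, False),
    "SIT5": TreatmentCategory("SIT5", 5.0, False),
    "bSIT1": TreatmentCategory("bSIT1", 1.0, True),
    "bSIT5": TreatmentCategory("bSIT5", 5.0, True),
}

TREATMENT_ORDER: tuple[str, ...] = ("control", "SIT1", "SIT5", "bSIT1", "bSIT5")


@dataclass(frozen=True)
class CageSpec:
    cage_id: str
    replicate_id: str
    treatment: TreatmentCategory
    n_females: int = 0
    n_fertile_males: int = 0
    n_sterile_males: int = 0


@dataclass
class TrialDesign:
    """Cage x replicate x treatment layout with released-insect counts."""

    replicates: int
    cages: list[CageSpec]
    observation_interval_days: int = 2
    horizon_days: int = 15

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if self.observation_interval_days < 1 or self.horizon_days < 1:
            raise ValueError("observation interval and horizon must be positive")
        seen: set[tuple[str, str]] = set()
        for c in self.cages:
            key = (c.cage_id, c.replicate_id)
            if key in seen:
                raise SchemaError(f"duplicate cage {c.cage_id!r} in replicate {c.replicate_id!r}")
            seen.add(key)
            t = c.treatment
            if t.s2f > 0 and c.n_fertile_males > 0:
                if abs(c.n_sterile_males / c.n_fertile_males - t.s2f) > 1e-9:
                    raise SchemaError(
                        f"cage {c.cage_id!r}: sterile/fertile ratio "
                        f"{c.n_sterile_males}/{c.n_fertile_males} != s2f {t.s2f}"
                    )

    @property
    def examination_days(self) -> list[int]:
        days = list(range(self.observation_interval_days, self.horizon_days + 1,
                          self.observation_interval_days))
        if not days or days[-1] != self.horizon_days:
            days.append(self.horizon_days)
        return days

    def cage_index(self) -> dict[str, CageSpec]:
        return {c.cage_id: c for c in self.cages}


@dataclass(frozen=True)
class CohortCounts:
    """Aggregated demographic tallies for one cage-cohort.

    ``e_meta`` is the number of hatched eggs entering immature monitoring;
    ``censored`` counts immatures still alive (larva or pupa) at the horizon.
    """

    cage_id: str
    replicate_id: str
    treatment: str
    eggs_total: int
    eggs_hatched: int
    e_meta: int
    l_death: int
    n_death: int
    n_meta: int
    censored: int

    def __post_init__(self) -> None:
        for name in ("eggs_total", "eggs_hatched", "e_meta",
                     "l_death", "n_death", "n_meta", "censored"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, numbers.Integral):
                raise SchemaError(f"{name} must be an integer, got {v!r} (cage {self.cage_id})")
            object.__setattr__(self, name, int(v))
            if v < 0:
                raise SchemaError(f"{name} must be non-negative, got {v} (cage {self.cage_id})")
        if self.eggs_hatched > self.eggs_total:
            raise SchemaError(
                f"cage {self.cage_id!r}: eggs_hatched {self.eggs_hatched} "
                f"> eggs_total {self.eggs_total}"
            )
        if self.n_meta + self.l_death + self.n_death + self.censored > self.e_meta:
            raise SchemaError(
                f"cage {self.cage_id!r}: event counts exceed e_meta {self.e_meta}"
            )


@dataclass(frozen=True)
class IntervalRecord:
    """Interval-censored stage events observed at one examination day.

    Events are attributed to (previous examination day, ``day``].
    """

    cage_id: str
    day: int
    stage: str  # "larva" | "pupa"
    deaths: int
    molts: int

    def __post_init__(self) -> None:
        if self.stage not in ("larva", "pupa"):
            raise SchemaError(f"unknown stage {self.stage!r} (cage {self.cage_id})")
        if self.deaths < 0 or self.molts < 0:
            raise SchemaError(f"negative event count (cage {self.cage_id}, day {self.day})")
        if self.day < 1:
            raise SchemaError(f"day must be positive (cage {self.cage_id})")


@dataclass(frozen=True)
class ConcentrationSample:
    """One ovitrap water measurement with its cage-condition covariates."""

    cage_id: str
    replicate_id: str
    concentration: float
    females_present: bool
    fertile_males_present: bool
    s2f: float
    boosted_dose_mg_per_200: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise SchemaError(f"negative concentration (cage {self.cage_id})")
        if self.s2f < 0:
            raise SchemaError(f"negative s2f (cage {self.cage_id})")


# ---------------------------------------------------------------------------
# readers / writers

_COHORT_COLUMNS = ["cage_id", "replicate_id", "treatment", "eggs_total", "eggs_hatched",
                   "e_meta", "l_death", "n_death", "n_meta", "censored"]
_INTERVAL_COLUMNS = ["cage_id", "day", "stage", "deaths", "molts"]
_WATER_COLUMNS = ["cage_id", "replicate_id", "concentration_ppb", "females_present",
                  "fertile_males_present", "s2f", "dose_mg_per_200"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _as_int(value, row: int, col: str, path: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"{path} row {row}: non-numeric {col}={value!r}") from None
    if f != int(f):
        raise SchemaError(f"{path} row {row}: fractional count {col}={value!r}")
    return int(f)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)


def read_cohorts(path: str | Path) -> list[CohortCounts]:
    df = pd.read_csv(path)
    _require_columns(df, _COHORT_COLUMNS, str(path))
    out = []
    for i, row in df.iterrows():
        try:
            out.append(CohortCounts(
                cage_id=str(row["cage_id"]),
                replicate_id=str(row["replicate_id"]),
                treatment=str(row["treatment"]),
                **{c: _as_int(row[c], i, c, str(path))
                   for c in ("eggs_total", "eggs_hatched", "e_meta",
                             "l_death", "n_death", "n_meta", "censored")},
            ))
        except SchemaError as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from None
    return out


def read_intervals(path: str | Path) -> list[IntervalRecord]:
    df = pd.read_csv(path)
    if df.empty and set(_INTERVAL_COLUMNS) <= set(df.columns):
        return []
    _require_columns(df, _INTERVAL_COLUMNS, str(path))
    out = []
    for i, row in df.iterrows():
        try:
            out.append(IntervalRecord(
                cage_id=str(row["cage_id"]),
                day=_as_int(row["day"], i, "day", str(path)),
                stage=str(row["stage"]),
                deaths=_as_int(row["deaths"], i, "deaths", str(path)),
                molts=_as_int(row["molts"], i, "molts", str(path)),
            ))
        except SchemaError as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from None
    return out


def read_water(path: str | Path) -> list[ConcentrationSample]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty and set(_WATER_COLUMNS) <= set(df.columns):
        return []
    _require_columns(df, _WATER_COLUMNS, str(path))
    out = []
    for i, row in df.iterrows():
        try:
            out.append(ConcentrationSample(
                cage_id=str(row["cage_id"]),
                replicate_id=str(row["replicate_id"]),
                concentration=float(row["concentration_ppb"]),
                females_present=_as_bool(row["females_present"]),
                fertile_males_present=_as_bool(row["fertile_males_present"]),
                s2f=float(row["s2f"]),
                boosted_dose_mg_per_200=float(row["dose_mg_per_200"]),
            ))
        except SchemaError as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from None
    return out


def read_design(path: str | Path) -> TrialDesign:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    cages = []
    for c in raw.get("cages", []):
        label = str(c["treatment"])
        if label in TREATMENTS:
            treatment = TREATMENTS[label]
        else:
            treatment = TreatmentCategory(label, float(c.get("s2f", 0.0)),
                                          bool(c.get("boosted", False)))
        cages.append(CageSpec(
            cage_id=str(c["cage_id"]),
            replicate_id=str(c["replicate_id"]),
            treatment=treatment,
            n_females=int(c.get("n_females", 0)),
            n_fertile_males=int(c.get("n_fertile_males", 0)),
            n_sterile_males=int(c.get("n_sterile_males", 0)),
        ))
    return TrialDesign(
        replicates=int(raw.get("replicates", 1)),
        cages=cages,
        observation_interval_days=int(raw.get("observation_interval_days", 2)),
        horizon_days=int(raw.get("horizon_days", 15)),
    )


def read_trial(directory: str | Path) -> tuple[
        TrialDesign, list[IntervalRecord], list[CohortCounts], list[ConcentrationSample]]:
    """Read and cross-validate the four trial tables from ``directory``."""
    directory = Path(directory)
    design = read_design(directory / "design.yaml")
    cohorts = read_cohorts(directory / "cohorts.csv")
    intervals_path = directory / "intervals.csv"
    intervals = read_intervals(intervals_path) if intervals_path.exists() else []
    water_path = directory / "water.csv"
    water = read_water(water_path) if water_path.exists() else []

    known = {c.cage_id for c in design.cages}
    for coll, what in ((cohorts, "cohorts"), (intervals, "intervals"), (water, "water")):
        for rec in coll:
            if rec.cage_id not in known:
                raise SchemaError(f"{what}: unknown cage_id {rec.cage_id!r}")

    # Per-cage interval events may never exceed that cage's starting larvae.
    e_meta = {c.cage_id: c.e_meta for c in cohorts}
    totals: dict[str, int] = {}
    for rec in intervals:
        if rec.stage == "larva":
            totals[rec.cage_id] = totals.get(rec.cage_id, 0) + rec.deaths + rec.molts
    for cage_id, total in totals.items():
        if cage_id in e_meta and total > e_meta[cage_id]:
            raise SchemaError(
                f"intervals: larval events {total} exceed e_meta "
                f"{e_meta[cage_id]} for cage {cage_id!r}")
    return design, intervals, cohorts, water


def write_trial(directory: str | Path,
                design: TrialDesign,
                cohorts: Iterable[CohortCounts],
                intervals: Iterable[IntervalRecord] = (),
                water: Iterable[ConcentrationSample] = ()) -> None:
    """Write the four tables; ``read_trial`` round-trips all counts exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "cage_id": c.cage_id, "replicate_id": c.replicate_id, "treatment": c.treatment,
        "eggs_total": c.eggs_total, "eggs_hatched": c.eggs_hatched, "e_meta": c.e_meta,
        "l_death": c.l_death, "n_death": c.n_death, "n_meta": c.n_meta,
        "censored": c.censored,
    } for c in cohorts], columns=_COHORT_COLUMNS).to_csv(directory / "cohorts.csv", index=False)
    pd.DataFrame([{
        "cage_id": r.cage_id, "day": r.day, "stage": r.stage,
        "deaths": r.deaths, "molts": r.molts,
    } for r in intervals], columns=_INTERVAL_COLUMNS).to_csv(
        directory / "intervals.csv", index=False)
    pd.DataFrame([{
        "cage_id": w.cage_id, "replicate_id": w.replicate_id,
        "concentration_ppb": w.concentration,
        "females_present": w.females_present,
        "fertile_males_present": w.fertile_males_present,
        "s2f": w.s2f, "dose_mg_per_200": w.boosted_dose_mg_per_200,
    } for w in water], columns=_WATER_COLUMNS).to_csv(
        directory / "water.csv", index=False,
        float_format=lambda v: format(v, ".17g"))  # exact float round-trip
    with open(directory / "design.yaml", "w") as fh:
        yaml.safe_dump({
            "replicates": design.replicates,
            "observation_interval_days": design.observation_interval_days,
            "horizon_days": design.horizon_days,
            "cages": [{
                "cage_id": c.cage_id, "replicate_id": c.replicate_id,
                "treatment": c.treatment.label, "s2f": c.treatment.s2f,
                "boosted": c.treatment.boosted, "n_females": c.n_females,
                "n_fertile_males": c.n_fertile_males,
                "n_sterile_males": c.n_sterile_males,
            } for c in design.cages],
        }, fh, sort_keys=False)


def validate_design(design: TrialDesign, warn: bool = False) -> list[str]:
    """Check the layout against the canonical 5 x 4 design; return warnings.

    Invariant violations (duplicate cages, ratio mismatches) raise at
    construction; this only reports non-fatal deviations.
    """
    messages: list[str] = []
    labels = {c.treatment.label for c in design.cages}
    if design.replicates != 4:
        messages.append(f"non-canonical replicate count: {design.replicates} (expected 4)")
    if labels != set(TREATMENT_ORDER):
        messages.append(f"non-canonical treatment set: {sorted(labels)}")
    counts: dict[str, int] = {}
    for c in design.cages:
        counts[c.treatment.label] = counts.get(c.treatment.label, 0) + 1
    if labels == set(TREATMENT_ORDER) and any(v != design.replicates for v in counts.values()):
        messages.append(f"unbalanced treatment allocation: {counts}")
    if warn:
        for m in messages:
            warnings.warn(m, DesignWarning, stacklevel=2)
    return messages
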