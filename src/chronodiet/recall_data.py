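"""Data model for two-day 24-h dietary recall surveys.

A survey dataset consists of subjects (demographics) and, per subject, two
recall days, each holding up to eight labelled, timed eating occasions with
their energy and nutrient content.  Occasions arrive already nutrient-resolved
(food-composition lookup is upstream of this package).

Times are stored as integer minutes since midnight; only the *start* of an
eating occasion is recorded, so no durations are modelled, and occasions are
assumed to lie within one calendar day (no post-midnight wrap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "OCCASION_LABELS",
    "MAIN_MEALS",
    "NUTRIENT_FIELDS",
    "AGE_CATEGORIES",
    "SchemaError",
    "RecallValidationError",
    "EatingOccasion",
    "RecallDay",
    "Subject",
    "Dataset",
    "parse_clock",
    "format_clock",
    "assign_age_category",
    "read_recall_table",
    "write_recall_table",
    "read_subject_table",
    "write_subject_table",
    "read_dataset",
    "write_dataset",
]

#: The eight occasion slots a recall day may contain, in canonical day order.
#: Two distinct afternoon-snack slots exist because some subjects report two.
OCCASION_LABELS = (
    "pre_breakfast",
    "breakfast",
    "morning_snack",
    "lunch",
    "afternoon_snack_1",
    "afternoon_snack_2",
    "dinner",
    "after_dinner_snack",
)

MAIN_MEALS = ("breakfast", "lunch", "dinner")

#: Quantity fields carried by every eating occasion.  Units: energy kcal;
#: sodium g; water ml; everything else g.  ``food_mass`` is the mass of foods
#: excluding drinking water and other beverages.
NUTRIENT_FIELDS = (
    "energy",
    "carbohydrate",
    "protein",
    "fat",
    "saturated_fat",
    "sugar",
    "fiber",
    "sodium",
    "fruit",
    "vegetables",
    "water",
    "food_mass",
    "alcohol",
)

#: Default age categories: children 10-17, adult tertiles of 18-64 (unequal
#: because ages repeat), and 65-74 (retirement age in Serbia is 65).
AGE_CATEGORIES = ((10, 17), (18, 29), (30, 47), (48, 64), (65, 74))


class SchemaError(ValueError):
    """A required column is missing or a column cannot be interpreted."""


class RecallValidationError(ValueError):
    """A row or object violates a recall-data invariant."""


def parse_clock(value) -> int:
    """Parse a clock time given as ``"HH:MM"`` or as minutes since midnight.

    Returns integer minutes in [0, 1439].
    """
    if isinstance(value, str) and ":" in value:
        hh, _, mm = value.partition(":")
        try:
            minutes = int(hh) * 60 + int(mm)
        except ValueError as exc:
            raise RecallValidationError(f"unparseable clock time {value!r}") from exc
    else:
        try:
            minutes = int(value)
        except (TypeError, ValueError) as exc:
            raise RecallValidationError(f"unparseable clock time {value!r}") from exc
    if not 0 <= minutes <= 1439:
        raise RecallValidationError(f"clock time {value!r} outside 00:00-23:59")
    return minutes


def format_clock(minutes: int) -> str:
    """Render minutes since midnight as ``"HH:MM"``."""
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass(frozen=True)
class EatingOccasion:
    """One timed eating event with its energy and nutrient content."""

    label: str
    start_time: int  # minutes since midnight
    energy: float = 0.0  # kcal
    carbohydrate: float = 0.0  # g
    protein: float = 0.0  # g
    fat: float = 0.0  # g
    saturated_fat: float = 0.0  # g
    sugar: float = 0.0  # g
    fiber: float = 0.0  # g
    sodium: float = 0.0  # g
    fruit: float = 0.0  # g
    vegetables: float = 0.0  # g
    water: float = 0.0  # ml
    food_mass: float = 0.0  # g, excluding drinking water and beverages
    alcohol: float = 0.0  # g

    def __post_init__(self):
        if self.label not in OCCASION_LABELS:
            raise RecallValidationError(
                f"unknown occasion label {self.label!r}; expected one of {OCCASION_LABELS}"
            )
        if not 0 <= int(self.start_time) <= 1439:
            raise RecallValidationError(
                f"start_time {self.start_time} outside [0, 1439] for {self.label}"
            )
        for name in NUTRIENT_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise RecallValidationError(
                    f"negative {name} ({v}) in occasion {self.label}"
                )


@dataclass(frozen=True)
class RecallDay:
    """One 24-h recall: an ordered list of occasions for one subject-day."""

    subject_id: str
    day_index: int  # 1 or 2
    occasions: tuple[EatingOccasion, ...]

    def __post_init__(self):
        if self.day_index not in (1, 2):
            raise RecallValidationError(
                f"day_index must be 1 or 2, got {self.day_index}"
            )
        occ = tuple(sorted(self.occasions, key=lambda o: o.start_time))
        object.__setattr__(self, "occasions", occ)
        if not 1 <= len(occ) <= 8:
            raise RecallValidationError(
                f"day must contain 1-8 occasions, got {len(occ)} "
                f"(subject {self.subject_id}, day {self.day_index})"
            )
        labels = [o.label for o in occ]
        if len(set(labels)) != len(labels):
            dupes = {l for l in labels if labels.count(l) > 1}
            raise RecallValidationError(
                f"duplicate occasion label(s) {sorted(dupes)} "
                f"(subject {self.subject_id}, day {self.day_index})"
            )

    def occasion(self, label: str) -> EatingOccasion | None:
        for o in self.occasions:
            if o.label == label:
                return o
        return None

    @property
    def total_energy(self) -> float:
        return sum(o.energy for o in self.occasions)


@dataclass(frozen=True)
class Subject:
    """Demographics for one survey participant."""

    subject_id: str
    age: float  # years, 10-74
    gender: str  # "female" | "male"
    weight: float | None = None  # kg
    height: float | None = None  # cm
    bmi_measured: bool = False
    employed_outside_home: bool | None = None
    smoker: bool | None = None
    region: str | None = None
    urban: bool | None = None
    activity_hours_per_week: float | None = None  # opaque attribute

    def __post_init__(self):
        if not 10 <= self.age <= 74:
            raise RecallValidationError(
                f"age {self.age} outside supported range [10, 74] "
                f"(subject {self.subject_id})"
            )
        if self.gender not in ("female", "male"):
            raise RecallValidationError(
                f"gender must be 'female' or 'male', got {self.gender!r}"
            )
        for name in ("weight", "height"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise RecallValidationError(f"non-positive {name} ({v})")

    @property
    def is_child(self) -> bool:
        return self.age < 18

    @property
    def bmi(self) -> float | None:
        """kg/m^2, or None when weight or height is missing."""
        if self.weight is None or self.height is None:
            return None
        return self.weight / (self.height / 100.0) ** 2


def assign_age_category(age: float, categories=AGE_CATEGORIES) -> str:
    """Map an age in years to its category label (e.g. ``"30-47"``).

    Categories are half-open on integer year labels: ``[lo, hi + 1)``, so
    age 17.9 is still "10-17" and age 18 starts "18-29".
    """
    for lo, hi in categories:
        if lo <= age < hi + 1:
            return f"{lo}-{hi}"
    lo = categories[0][0]
    hi = categories[-1][1]
    raise RecallValidationError(f"age {age} outside supported range [{lo}, {hi}]")


@dataclass
class Dataset:
    """A full survey dataset: subjects plus their recall days."""

    subjects: dict[str, Subject] = field(default_factory=dict)
    days: dict[tuple[str, int], RecallDay] = field(default_factory=dict)

    def add_subject(self, subject: Subject) -> None:
        self.subjects[subject.subject_id] = subject

    def add_day(self, day: RecallDay) -> None:
        key = (day.subject_id, day.day_index)
        if key in self.days:
            raise RecallValidationError(f"duplicate recall day {key}")
        self.days[key] = day

    def days_for(self, subject_id: str) -> tuple[RecallDay, ...]:
        return tuple(
            self.days[(subject_id, d)]
            for d in (1, 2)
            if (subject_id, d) in self.days
        )

    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    def adults(self) -> list[Subject]:
        return [s for s in self.subjects.values() if not s.is_child]

    def children(self) -> list[Subject]:
        return [s for s in self.subjects.values() if s.is_child]

    def validate(self) -> list[str]:
        """Return a list of human-readable problems (empty when clean)."""
        problems = []
        for (sid, _d), day in self.days.items():
            if sid not in self.subjects:
                problems.append(f"recall day for unknown subject {sid!r}")
        for sid in self.subjects:
            n = len(self.days_for(sid))
            if n != 2:
                problems.append(f"subject {sid!r} has {n} recall day(s), expected 2")
        return problems


# ---------------------------------------------------------------------------
# Tabular I/O.  One CSV row per (subject, day, occasion); see docs/schema.md.
# ---------------------------------------------------------------------------

RECALL_COLUMNS = ("subject_id", "day", "label", "time") + NUTRIENT_FIELDS

SUBJECT_COLUMNS = (
    "subject_id",
    "age",
    "gender",
    "weight",
    "height",
    "bmi_measured",
    "employed_outside_home",
    "smoker",
    "region",
    "urban",
    "activity_hours_per_week",
)

_SUBJECT_OPTIONAL = set(SUBJECT_COLUMNS) - {"subject_id", "age", "gender"}


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        df = df.rename(columns=dict(schema))
    return df


def read_recall_table(path, schema: Mapping[str, str] | None = None) -> list[RecallDay]:
    """Read a recall CSV (one row per subject/day/occasion) into RecallDays.

    ``schema`` optionally maps file column names to canonical ones.  Times may
    be "HH:MM" strings or integer minutes.  Raises :class:`SchemaError` for a
    missing column and :class:`RecallValidationError` (with the offending row
    index) for invalid values.
    """
    df = _apply_schema(pd.read_csv(path), schema)
    missing = [c for c in RECALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"recall table missing required column(s): {missing}")

    days: list[RecallDay] = []
    for (sid, d), group in df.groupby(["subject_id", "day"], sort=True):
        occasions = []
        for idx, row in group.iterrows():
            try:
                occasions.append(
                    EatingOccasion(
                        label=str(row["label"]),
                        start_time=parse_clock(row["time"]),
                        **{n: float(row[n]) for n in NUTRIENT_FIELDS},
                    )
                )
            except RecallValidationError as exc:
                raise RecallValidationError(f"row {idx}: {exc}") from exc
        days.append(RecallDay(subject_id=str(sid), day_index=int(d), occasions=tuple(occasions)))
    return days


def write_recall_table(days: Iterable[RecallDay], path) -> None:
    """Write RecallDays to CSV; inverse of :func:`read_recall_table`."""
    rows = []
    for day in days:
        for o in day.occasions:
            row = {
                "subject_id": day.subject_id,
                "day": day.day_index,
                "label": o.label,
                "time": format_clock(o.start_time),
            }
            row.update({n: getattr(o, n) for n in NUTRIENT_FIELDS})
            rows.append(row)
    pd.DataFrame(rows, columns=list(RECALL_COLUMNS)).to_csv(path, index=False)


def _opt(row, name, cast):
    v = row.get(name)
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return cast(v)


def _as_bool(v):
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def read_subject_table(path, schema: Mapping[str, str] | None = None) -> list[Subject]:
    """Read a subject demographics CSV into Subject objects."""
    df = _apply_schema(pd.read_csv(path), schema)
    missing = [c for c in ("subject_id", "age", "gender") if c not in df.columns]
    if missing:
        raise SchemaError(f"subject table missing required column(s): {missing}")
    subjects = []
    for idx, row in df.iterrows():
        try:
            subjects.append(
                Subject(
                    subject_id=str(row["subject_id"]),
                    age=float(row["age"]),
                    gender=str(row["gender"]),
                    weight=_opt(row, "weight", float),
                    height=_opt(row, "height", float),
                    bmi_measured=bool(_opt(row, "bmi_measured", _as_bool) or False),
                    employed_outside_home=_opt(row, "employed_outside_home", _as_bool),
                    smoker=_opt(row, "smoker", _as_bool),
                    region=_opt(row, "region", str),
                    urban=_opt(row, "urban", _as_bool),
                    activity_hours_per_week=_opt(row, "activity_hours_per_week", float),
                )
            )
        except RecallValidationError as exc:
            raise RecallValidationError(f"row {idx}: {exc}") from exc
    return subjects


def write_subject_table(subjects: Iterable[Subject], path) -> None:
    rows = [asdict(s) for s in subjects]
    pd.DataFrame(rows, columns=list(SUBJECT_COLUMNS)).to_csv(path, index=False)


def read_dataset(recall_path, subject_path) -> Dataset:
    ds = Dataset()
    for s in read_subject_table(subject_path):
        ds.add_subject(s)
    for d in read_recall_table(recall_path):
        ds.add_day(d)
    return ds


def write_dataset(ds: Dataset, recall_path, subject_path) -> None:
    write_subject_table(ds.subjects.values(), subject_path)
    write_recall_table(
        [ds.days[k] for k in sorted(ds.days)], recall_path
    )


def dataset_to_json(ds: Dataset) -> str:
    """JSON serialization of the full dataset (for small fixtures)."""
    payload = {
        "subjects": [asdict(s) for s in ds.subjects.values()],
        "days": [
            {
                "subject_id": d.subject_id,
                "day_index": d.day_index,
                "occasions": [asdict(o) for o in d.occasions],
            }
            for d in (ds.days[k] for k in sorted(ds.days))
        ],
    }
    return json.dumps(payload, indent=1)


def dataset_from_json(text: str) -> Dataset:
    payload = json.loads(text)
    ds = Dataset()
    for s in payload["subjects"]:
        ds.add_subject(Subject(**s))
    for d in payload["days"]:
        ds.add_day(
            RecallDay(
                subject_id=d["subject_id"],
                day_index=d["day_index"],
                occasions=tuple(EatingOccasion(**o) for o in d["occasions"]),
            )
        )
    return ds
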