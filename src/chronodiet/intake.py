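"""Daily and two-day-averaged intake summaries.

Per-day totals are plain sums over a day's eating occasions.  Subject-level
intakes are the arithmetic mean of the two recall days, with derived metrics
(percent of energy, fiber density, energy density, protein per kg body
weight) computed from the *averaged* numerators and denominators — a ratio of
means, not a mean of ratios.

Percent-of-energy uses the conventional Atwater factors (4/4/9/7 kcal per g
of carbohydrate/protein/fat/alcohol); saturated fat uses the fat factor and
sugar the carbohydrate factor.  The energy in the denominator is the reported
(database-derived) occasion energy, never recomputed from macronutrients, so
on real-style data the macronutrient shares need not sum to 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .recall_data import NUTRIENT_FIELDS, Dataset, RecallDay, Subject

__all__ = [
    "ATWATER",
    "DailyIntake",
    "SubjectIntake",
    "UndefinedMetricError",
    "compute_daily_intake",
    "average_subject_intake",
    "percent_energy_from",
    "subject_intake_table",
]

#: kcal per gram.
ATWATER = {"carbohydrate": 4.0, "protein": 4.0, "fat": 9.0, "alcohol": 7.0,
           "saturated_fat": 9.0, "sugar": 4.0}


class UndefinedMetricError(ValueError):
    """A derived metric is undefined (e.g. percent of zero energy)."""


@dataclass(frozen=True)
class DailyIntake:
    """Nutrient totals for one recall day."""

    subject_id: str
    day_index: int
    energy: float
    carbohydrate: float
    protein: float
    fat: float
    saturated_fat: float
    sugar: float
    fiber: float
    sodium: float
    fruit: float
    vegetables: float
    water: float
    food_mass: float
    alcohol: float
    occasion_count: int


@dataclass(frozen=True)
class SubjectIntake:
    """Two-day-averaged intake with derived diet-quality inputs.

    Units: energy kcal/day; *_pct percent of energy; fiber_density g/1000
    kcal; fruit/vegetables/fruit_veg g/day; sodium g/day; water ml/day;
    protein_per_kg g/kg body weight (None when weight is missing);
    energy_density kcal per g of food excluding beverages.
    """

    subject_id: str
    energy: float
    carbohydrate: float
    protein: float
    fat: float
    saturated_fat: float
    sugar: float
    fiber: float
    sodium: float
    fruit: float
    vegetables: float
    water: float
    food_mass: float
    alcohol: float
    carbohydrate_pct: float
    protein_pct: float
    fat_pct: float
    saturated_fat_pct: float
    sugar_pct: float
    alcohol_pct: float
    fiber_density: float
    fruit_veg: float
    protein_per_kg: float | None
    energy_density: float
    occasions_per_day: float


def percent_energy_from(nutrient_grams: float, kcal_per_gram: float, energy: float) -> float:
    """Percent of daily energy contributed by ``nutrient_grams`` of a nutrient."""
    if energy <= 0:
        raise UndefinedMetricError("percent of energy undefined for energy <= 0")
    return 100.0 * nutrient_grams * kcal_per_gram / energy


def compute_daily_intake(day: RecallDay) -> DailyIntake:
    """Sum a day's occasions into nutrient totals."""
    totals = {n: sum(getattr(o, n) for o in day.occasions) for n in NUTRIENT_FIELDS}
    return DailyIntake(
        subject_id=day.subject_id,
        day_index=day.day_index,
        occasion_count=len(day.occasions),
        **totals,
    )


def average_subject_intake(
    day1: DailyIntake, day2: DailyIntake, subject: Subject
) -> SubjectIntake:
    """Average two recall days and derive the subject-level metrics."""
    if day1.subject_id != day2.subject_id or day1.subject_id != subject.subject_id:
        raise ValueError(
            f"subject mismatch: {day1.subject_id}, {day2.subject_id}, {subject.subject_id}"
        )
    mean = {
        n: 0.5 * (getattr(day1, n) + getattr(day2, n)) for n in NUTRIENT_FIELDS
    }
    energy = mean["energy"]
    if energy <= 0:
        raise UndefinedMetricError(
            f"subject {subject.subject_id}: zero mean energy, metrics undefined"
        )
    protein_per_kg = (
        mean["protein"] / subject.weight if subject.weight is not None else None
    )
    return SubjectIntake(
        subject_id=subject.subject_id,
        **mean,
        carbohydrate_pct=percent_energy_from(mean["carbohydrate"], ATWATER["carbohydrate"], energy),
        protein_pct=percent_energy_from(mean["protein"], ATWATER["protein"], energy),
        fat_pct=percent_energy_from(mean["fat"], ATWATER["fat"], energy),
        saturated_fat_pct=percent_energy_from(mean["saturated_fat"], ATWATER["saturated_fat"], energy),
        sugar_pct=percent_energy_from(mean["sugar"], ATWATER["sugar"], energy),
        alcohol_pct=percent_energy_from(mean["alcohol"], ATWATER["alcohol"], energy),
        fiber_density=1000.0 * mean["fiber"] / energy,
        fruit_veg=mean["fruit"] + mean["vegetables"],
        protein_per_kg=protein_per_kg,
        energy_density=(energy / mean["food_mass"]) if mean["food_mass"] > 0 else math.nan,
        occasions_per_day=0.5 * (day1.occasion_count + day2.occasion_count),
    )


def subject_intake_table(ds: Dataset) -> pd.DataFrame:
    """Per-subject intake summary for every subject with two recall days.

    Returns a DataFrame indexed by subject_id with one column per
    :class:`SubjectIntake` field plus ``age``, ``gender`` and ``is_child``.
    """
    rows = []
    for sid, subject in ds.subjects.items():
        days = ds.days_for(sid)
        if len(days) != 2:
            continue
        d1, d2 = (compute_daily_intake(d) for d in days)
        si = average_subject_intake(d1, d2, subject)
        row = si.__dict__.copy()
        row["age"] = subject.age
        row["gender"] = subject.gender
        row["is_child"] = subject.is_child
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("subject_id")
    return df
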