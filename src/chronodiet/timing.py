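"""Meal-timing metrics for two-day recall data.

The survey records only the *start* time of each eating occasion, so "energy
before 16:00" means energy of occasions that start strictly before the
cutoff, and "eating after 20:00" means any occasion starting strictly after
20:00 on either day.  The early-eater flag is inclusive at the threshold
("at least 60%" of daily energy before the cutoff).

The default percent-before is pooled over both days (ratio of sums), which
equals average kcal-before-cutoff divided by average daily energy; a
per-day-averaged variant is available via ``method="per_day_mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intake import UndefinedMetricError
from .recall_data import RecallDay

__all__ = [
    "TimingThresholds",
    "TimingProfile",
    "pct_energy_before",
    "classify_early_eater",
    "classify_after_2000",
    "largest_meal",
    "mean_occasion_times",
    "lunch_consistency",
    "timing_profile",
]


@dataclass(frozen=True)
class TimingThresholds:
    """Cutoffs for the eater classifications, in minutes since midnight."""

    cutoff_time: int = 960  # 16:00
    early_pct: float = 60.0  # "at least 60% of daily energy by 16:00"
    late_meal_time: int = 1200  # 20:00

    def __post_init__(self):
        if not 0 < self.cutoff_time < 1440:
            raise ValueError(f"cutoff_time {self.cutoff_time} outside (0, 1440)")
        if not 0 < self.early_pct <= 100:
            raise ValueError(f"early_pct {self.early_pct} outside (0, 100]")


@dataclass(frozen=True)
class TimingProfile:
    """Per-subject meal-timing summary across the two recall days."""

    subject_id: str
    pct_energy_before_cutoff: float
    mean_occasion_times: dict[str, float] = field(compare=False)
    largest_meal_label_by_day: tuple[str, str] = ("", "")
    largest_meal_time: float = 0.0
    early_eater: bool = False
    eats_after_2000: bool = False
    lunch_day_gap: float | None = None
    lunch_within_1h: bool | None = None
    occasions_per_day: float = 0.0


def pct_energy_before(
    day1: RecallDay, day2: RecallDay, cutoff: int = 960, method: str = "pooled"
) -> float:
    """Percent of energy from occasions starting strictly before ``cutoff``.

    ``method="pooled"`` (default) pools energy over both days; the
    alternative ``"per_day_mean"`` averages the two daily percentages.
    """
    def before(day):
        return sum(o.energy for o in day.occasions if o.start_time < cutoff)

    if method == "pooled":
        total = day1.total_energy + day2.total_energy
        if total <= 0:
            raise UndefinedMetricError("zero total energy over both days")
        return 100.0 * (before(day1) + before(day2)) / total
    if method == "per_day_mean":
        pcts = []
        for day in (day1, day2):
            if day.total_energy <= 0:
                raise UndefinedMetricError(f"zero energy on day {day.day_index}")
            pcts.append(100.0 * before(day) / day.total_energy)
        return 0.5 * (pcts[0] + pcts[1])
    raise ValueError(f"unknown method {method!r}")


def classify_early_eater(pct_before: float, thresholds: TimingThresholds) -> bool:
    """True when at least ``early_pct`` percent of energy comes before the cutoff."""
    return pct_before >= thresholds.early_pct


def classify_after_2000(
    day1: RecallDay, day2: RecallDay, thresholds: TimingThresholds
) -> bool:
    """True when any occasion on either day starts strictly after 20:00."""
    return any(
        o.start_time > thresholds.late_meal_time
        for day in (day1, day2)
        for o in day.occasions
    )


def largest_meal(day1: RecallDay, day2: RecallDay) -> tuple[tuple[str, str], float]:
    """The highest-energy occasion per day (any slot counts, snacks included).

    Ties are broken by earliest start time.  Returns the per-day labels and
    the mean of the two per-day largest-meal start times (minutes).
    """
    labels, times = [], []
    for day in (day1, day2):
        # occasions are sorted by start_time, so max() keeps the earliest on ties
        best = max(day.occasions, key=lambda o: o.energy)
        labels.append(best.label)
        times.append(best.start_time)
    return (labels[0], labels[1]), 0.5 * (times[0] + times[1])


def mean_occasion_times(day1: RecallDay, day2: RecallDay) -> dict[str, float]:
    """Mean start time per occasion label over the day(s) it occurs on."""
    sums: dict[str, list[float]] = {}
    for day in (day1, day2):
        for o in day.occasions:
            sums.setdefault(o.label, []).append(o.start_time)
    return {label: sum(ts) / len(ts) for label, ts in sums.items()}


def lunch_consistency(day1: RecallDay, day2: RecallDay) -> tuple[float | None, bool | None]:
    """Absolute between-day difference in lunch start, and the within-1-h flag.

    Returns ``(None, None)`` when lunch is missing on either day (flagged
    missing rather than an error).
    """
    l1, l2 = day1.occasion("lunch"), day2.occasion("lunch")
    if l1 is None or l2 is None:
        return None, None
    gap = abs(l1.start_time - l2.start_time)
    return float(gap), gap <= 60


def timing_profile(
    day1: RecallDay,
    day2: RecallDay,
    thresholds: TimingThresholds | None = None,
    method: str = "pooled",
) -> TimingProfile:
    """Assemble the full timing summary for one subject."""
    thresholds = thresholds or TimingThresholds()
    pct = pct_energy_before(day1, day2, thresholds.cutoff_time, method=method)
    labels, mean_time = largest_meal(day1, day2)
    gap, within = lunch_consistency(day1, day2)
    return TimingProfile(
        subject_id=day1.subject_id,
        pct_energy_before_cutoff=pct,
        mean_occasion_times=mean_occasion_times(day1, day2),
        largest_meal_label_by_day=labels,
        largest_meal_time=mean_time,
        early_eater=classify_early_eater(pct, thresholds),
        eats_after_2000=classify_after_2000(day1, day2, thresholds),
        lunch_day_gap=gap,
        lunch_within_1h=within,
        occasions_per_day=0.5 * (len(day1.occasions) + len(day2.occasions)),
    )
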