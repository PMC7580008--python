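"""Diet Quality Score (DQS) and Diet Quality z-Score.

The DQS counts how many of five EU Science Hub healthy-eating
recommendations a subject meets (0-5): fruit+vegetables >= 400 g/day, fiber
>= 14 g/1000 kcal, sugar < 10% of energy, saturated fat < 10% of energy,
sodium < 2.3 g/day.  "Meeting" recommendations for fruit/veg and fiber is
inclusive (>=); the three limits are strict (<).

The continuous companion, the Diet Quality z-Score, standardizes each
component against the *cohort* standard deviation: for component i of
subject j,

    z_ij = s_i * (x_ij - r_i) / SD_i

with sign s_i = +1 for fruit+veg and fiber (more is better) and s_i = -1 for
saturated fat, sodium and sugar (exceeding the limit is worse); SD_i is the
sample SD (n-1) of the component over the supplied cohort.  The z total is
the sum of the five components.  The cohort is always an explicit argument —
typically the adult analysis sample — never global state.

Note the sugar component scores *total* sugar as percent of energy, the
variable the survey produces, although the cited recommendation concerns
added sugar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .intake import SubjectIntake

__all__ = [
    "DQS_COMPONENTS",
    "COMPONENT_SIGNS",
    "Recommendations",
    "DQSResult",
    "DegenerateCohortError",
    "score_dqs",
    "dqs_category",
    "zscore_components",
    "score_cohort",
]

#: Component name -> SubjectIntake field holding the scored intake.
DQS_COMPONENTS = {
    "fv": "fruit_veg",           # g/day
    "fiber": "fiber_density",    # g/1000 kcal
    "sugar": "sugar_pct",        # % of energy
    "satfat": "saturated_fat_pct",  # % of energy
    "sodium": "sodium",          # g/day
}

#: +1 where exceeding the recommendation is good, -1 where it is bad.
COMPONENT_SIGNS = {"fv": 1.0, "fiber": 1.0, "sugar": -1.0, "satfat": -1.0, "sodium": -1.0}

DQS_CATEGORIES = ("0-1", "2-3", "4-5")


class DegenerateCohortError(ValueError):
    """A component has zero variance in the cohort; z-scores are undefined."""


@dataclass(frozen=True)
class Recommendations:
    """Scoring thresholds (EU Science Hub reference values), each overridable."""

    fv_min: float = 400.0       # g/day fruit + vegetables
    fiber_min: float = 14.0     # g per 1000 kcal
    sugar_max: float = 10.0     # % of energy
    satfat_max: float = 10.0    # % of energy
    sodium_max: float = 2.3     # g/day

    def __post_init__(self):
        for f in ("fv_min", "fiber_min", "sugar_max", "satfat_max", "sodium_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    def threshold(self, component: str) -> float:
        return {
            "fv": self.fv_min,
            "fiber": self.fiber_min,
            "sugar": self.sugar_max,
            "satfat": self.satfat_max,
            "sodium": self.sodium_max,
        }[component]


@dataclass(frozen=True)
class DQSResult:
    """Five component verdicts, the 0-5 score, and the signed z components."""

    subject_id: str
    component_met: dict[str, bool]
    dqs: int
    dqs_category: str
    z_components: dict[str, float]
    z_total: float


def _component_value(intake: SubjectIntake, component: str) -> float:
    v = getattr(intake, DQS_COMPONENTS[component])
    if v is None or (isinstance(v, float) and math.isnan(v)):
        raise ValueError(
            f"subject {intake.subject_id}: missing value for DQS component "
            f"{component!r}; score is undefined"
        )
    return float(v)


def score_dqs(intake: SubjectIntake, rec: Recommendations | None = None) -> tuple[dict[str, bool], int]:
    """Component flags and the 0-5 Diet Quality Score for one subject."""
    rec = rec or Recommendations()
    flags = {
        "fv": _component_value(intake, "fv") >= rec.fv_min,
        "fiber": _component_value(intake, "fiber") >= rec.fiber_min,
        "sugar": _component_value(intake, "sugar") < rec.sugar_max,
        "satfat": _component_value(intake, "satfat") < rec.satfat_max,
        "sodium": _component_value(intake, "sodium") < rec.sodium_max,
    }
    return flags, sum(flags.values())


def dqs_category(dqs: int) -> str:
    """Bin a 0-5 score into the ordinal categories 0-1, 2-3, 4-5."""
    if dqs not in (0, 1, 2, 3, 4, 5):
        raise ValueError(f"DQS must be an integer 0-5, got {dqs!r}")
    return DQS_CATEGORIES[int(dqs) // 2]


def zscore_components(
    intakes: list[SubjectIntake], rec: Recommendations | None = None
) -> pd.DataFrame:
    """Signed standardized components and z total for a cohort.

    Requires at least two subjects (the SD must be estimable).  Returns a
    DataFrame indexed by subject_id with columns ``z_<component>`` and
    ``z_total``.
    """
    rec = rec or Recommendations()
    if len(intakes) < 2:
        raise ValueError("z-scores need a cohort of at least 2 subjects")
    values = pd.DataFrame(
        {
            comp: [_component_value(si, comp) for si in intakes]
            for comp in DQS_COMPONENTS
        },
        index=pd.Index([si.subject_id for si in intakes], name="subject_id"),
    )
    out = pd.DataFrame(index=values.index)
    for comp in DQS_COMPONENTS:
        sd = values[comp].std(ddof=1)
        if sd == 0 or math.isnan(sd):
            raise DegenerateCohortError(
                f"component {comp!r} has zero variance in the cohort"
            )
        out[f"z_{comp}"] = COMPONENT_SIGNS[comp] * (values[comp] - rec.threshold(comp)) / sd
    out["z_total"] = out.sum(axis=1)
    return out


def score_cohort(
    intakes: list[SubjectIntake], rec: Recommendations | None = None
) -> list[DQSResult]:
    """Score a cohort: per-subject DQS plus cohort-standardized z-scores."""
    rec = rec or Recommendations()
    zs = zscore_components(intakes, rec)
    results = []
    for si in intakes:
        flags, dqs = score_dqs(si, rec)
        row = zs.loc[si.subject_id]
        results.append(
            DQSResult(
                subject_id=si.subject_id,
                component_met=flags,
                dqs=dqs,
                dqs_category=dqs_category(dqs),
                z_components={c: float(row[f"z_{c}"]) for c in DQS_COMPONENTS},
                z_total=float(row["z_total"]),
            )
        )
    return results
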