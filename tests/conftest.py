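import warnings

import pytest

from chronodiet.recall_data import EatingOccasion, RecallDay, parse_clock
from chronodiet.synthetic import SyntheticConfig, generate_cohort

# MixedLM emits benign convergence chatter on near-singular random effects
warnings.filterwarnings("ignore", message=".*Random effects covariance is singular.*")
warnings.filterwarnings("ignore", message=".*converge.*")


def make_day(sid, day_index, occasions, **nutrients_by_label):
    """Build a RecallDay from (label, 'HH:MM', kcal) triples.

    Extra per-label nutrient dicts may be passed as keyword arguments,
    e.g. ``lunch={"fat": 20}``.
    """
    occ = []
    for label, clock, kcal in occasions:
        extra = nutrients_by_label.get(label, {})
        occ.append(
            EatingOccasion(label=label, start_time=parse_clock(clock),
                           energy=kcal, **extra)
        )
    return RecallDay(subject_id=sid, day_index=day_index, occasions=tuple(occ))


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-adult / 20-child synthetic survey, fixed seed."""
    return generate_cohort(SyntheticConfig(n_children=20, n_adults=80), seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default synthetic survey (74 children, 260 adults)."""
    return generate_cohort(SyntheticConfig(), seed=1)
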