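"""Synthetic two-day recall cohorts with realistic survey structure.

The generator emulates a national dietary survey of 74 children and 260
adults, two 24-h recalls each: up to eight labelled eating occasions per day
(breakfast around 9:00, lunch around 15:15 as the largest meal, dinner
around 20:00, snacks in between), occasion energies with a right-skewed
spread, and nutrient profiles whose subject-level two-day averages follow
configured marginal means and SDs.

A single latent "traditionalism" factor T ~ N(0,1) per subject induces the
joint pattern the analysis is built to detect: higher T shifts lunch
earlier, lowers total energy, and raises age.  On top of that, the five
diet-quality components are coupled *linearly in conditional mean* to the
subject's realized percent of energy consumed before the cutoff, with
multiplicative lognormal noise:

    x = (mean + c * (pct - 60) + g * (female - p_female)) * exp(s*eps - s^2/2)

so E[x | pct, gender] is exactly linear with slope ``c`` (the "level
coupling") and the marginal mean is exactly ``mean``.  The level couplings
default to values whose implied slope of the diet-quality z-score on pct,
sum_i sign_i * c_i / SD_i, equals the configured generative slope (0.03 per
percentage point), and the fruit+veg coupling is sized to give the
configured early-vs-late gap (96 g/day) for the expected early/late split.
The noise scale solves for the configured marginal SD given the expected
variance of pct.

Because nutrient grams are derived from drawn percent-of-energy targets,
recomputing energy from the Atwater factors reproduces the drawn energy
exactly, and the four macronutrient energy shares sum to 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intake import subject_intake_table
from .quality import COMPONENT_SIGNS, DQS_COMPONENTS, Recommendations, zscore_components
from .recall_data import Dataset, EatingOccasion, RecallDay, Subject
from .stats import ols, random_intercept_meals, two_sample_t
from .timing import TimingThresholds, timing_profile

__all__ = [
    "OccasionSpec",
    "NutrientMarginal",
    "SyntheticConfig",
    "default_config",
    "implied_z_slope",
    "generate_cohort",
    "recovery_report",
]


@dataclass(frozen=True)
class OccasionSpec:
    """Occurrence and timing/energy parameters for one occasion slot."""

    prob: float                 # per-day occurrence probability (meals: 1.0)
    mean_time: float            # minutes since midnight
    subject_time_sd: float      # between-subject SD of habitual time, min
    day_jitter_sd: float        # within-subject day-to-day SD, min
    mean_kcal_adult: float
    mean_kcal_child: float

    def __post_init__(self):
        if not 0 <= self.prob <= 1:
            raise ValueError(f"prob {self.prob} outside [0, 1]")
        for f in ("subject_time_sd", "day_jitter_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass(frozen=True)
class NutrientMarginal:
    """Target marginal mean/SD of a subject-level two-day-averaged metric."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("marginal mean and sd must be positive")


# Day-to-day lunch jitter SD of 21 min makes the expected absolute
# between-day lunch gap 2*21/sqrt(pi) ~ 24 min.
_DEFAULT_OCCASIONS = {
    "pre_breakfast":      OccasionSpec(0.45,  480, 45, 25, 100, 134),
    "breakfast":          OccasionSpec(1.00,  540, 50, 25, 537, 560),
    "morning_snack":      OccasionSpec(0.85,  660, 50, 25, 180, 196),
    "lunch":              OccasionSpec(1.00,  915, 42, 21, 761, 665),
    "afternoon_snack_1":  OccasionSpec(0.90, 1020, 60, 25, 137, 184),
    "afternoon_snack_2":  OccasionSpec(0.50, 1110, 50, 25, 110, 147),
    "dinner":             OccasionSpec(1.00, 1200, 60, 15, 568, 520),
    "after_dinner_snack": OccasionSpec(0.75, 1320, 45, 25,  62, 160),
}

#: Occasion slots whose energy rises with the subject's morningness tilt;
#: the remaining slots fall by the same log factor.
_MORNING_SLOTS = ("pre_breakfast", "breakfast", "morning_snack", "lunch")

# Adult marginals: energy kcal/day; fv g/day; fiber g/1000 kcal; sugar and
# satfat % of energy; sodium g/day; water ml/day; energy density kcal/g.
_ADULT_MARGINALS = {
    "energy": NutrientMarginal(2265, 987),
    "fv": NutrientMarginal(473, 295),
    "fiber": NutrientMarginal(10.9, 6.4),
    "sugar": NutrientMarginal(13.2, 7.4),
    "satfat": NutrientMarginal(13.0, 4.0),
    "sodium": NutrientMarginal(3.99, 3.00),
    "water": NutrientMarginal(2246, 1333),
    "energy_density": NutrientMarginal(0.89, 0.32),
    "protein_pct": NutrientMarginal(16.0, 4.0),
    "fat_pct": NutrientMarginal(40.0, 9.0),
}

_CHILD_MARGINALS = {
    "energy": NutrientMarginal(2280, 951),
    "fv": NutrientMarginal(424, 259),
    "fiber": NutrientMarginal(8.1, 3.4),
    "sugar": NutrientMarginal(13.6, 6.4),
    "satfat": NutrientMarginal(12.0, 4.0),
    "sodium": NutrientMarginal(3.66, 2.69),
    "water": NutrientMarginal(1996, 1327),
    "energy_density": NutrientMarginal(1.01, 0.34),
    "protein_pct": NutrientMarginal(15.0, 4.0),
    "fat_pct": NutrientMarginal(39.0, 8.0),
}

#: Adult age-category weights (18-29, 30-47, 48-64, 65-74).
_AGE_WEIGHTS = ((18, 30, 75), (30, 48, 73), (48, 65, 73), (65, 75, 39))

#: Employment probability by adult age category.
_EMPLOYED_BY_AGE = {(18, 30): 0.51, (30, 48): 0.87, (48, 65): 0.69, (65, 75): 0.08}


@dataclass(frozen=True)
class SyntheticConfig:
    """All generative parameters for one synthetic cohort."""

    n_children: int = 74
    n_adults: int = 260
    female_frac: float = 0.54
    occasions: dict = field(default_factory=lambda: dict(_DEFAULT_OCCASIONS))
    adult_marginals: dict = field(default_factory=lambda: dict(_ADULT_MARGINALS))
    child_marginals: dict = field(default_factory=lambda: dict(_CHILD_MARGINALS))
    age_weights: tuple = _AGE_WEIGHTS

    # latent-traditionalism couplings
    lunch_minutes_per_t: float = 25.0   # lunch earlier per SD of T
    energy_log_per_t: float = 0.22      # total energy lower per SD of T
    age_t_rho: float = 0.45             # Gaussian-copula corr of T with age
    morningness_log_sd: float = 0.22    # subject tilt of energy toward morning
    morningness_per_t: float = 0.12     # tilt increases with T

    # diet-quality couplings (level slope of conditional mean per pct point)
    z_slope_target: float = 0.03        # generative slope of z-DQS on pct
    fv_gap_target: float = 96.0         # early-vs-late fruit+veg gap, g/day
    pct_split_diff: float = 29.5        # expected early-minus-late mean pct
    fiber_coupling: float = 0.065       # g/1000 kcal per pct point
    satfat_coupling: float = -0.012     # % energy per pct point
    sugar_coupling: float = -0.015      # % energy per pct point
    pct_mean: float = 60.0              # anchoring point of the couplings
    pct_var: float = 324.0              # assumed Var(pct) when solving noise SDs

    # gender effects on the components (level shift, female minus male scale)
    gender_effects: dict = field(
        default_factory=lambda: {"fv": 60.0, "fiber": 0.0, "sugar": -1.0,
                                 "satfat": -1.0, "sodium": -0.6}
    )

    # energy dispersion (log scale)
    subject_energy_log_sd: float = 0.31
    occasion_energy_log_sd: float = 0.38
    snackiness_prob_shift: float = 0.18
    after_dinner_habit_prob: float = 0.48  # subjects with a late-snack habit

    # anthropometry and other demographics
    bmi_age_copula_rho: float = 0.418   # Spearman 0.401 on the normal copula
    adult_bmi: NutrientMarginal = NutrientMarginal(25.2, 4.1)
    child_bmi: NutrientMarginal = NutrientMarginal(20.5, 3.0)
    anthropometry_missing_prob: float = 0.018
    measured_bmi_prob: float = 0.65
    smoker_prob_adult: float = 0.33
    smoker_prob_child: float = 0.06
    employed_t_shift: float = -0.10     # employment less likely for high T
    zero_fruit_prob_adult: float = 0.20
    zero_fruit_prob_child: float = 0.23
    drinker_prob_adult: float = 0.35

    cutoff_time: int = 960

    def __post_init__(self):
        if self.n_adults < 2:
            raise ValueError("n_adults must be >= 2")
        if self.n_children < 0:
            raise ValueError("n_children must be >= 0")
        for p in ("female_frac", "anthropometry_missing_prob", "measured_bmi_prob",
                  "zero_fruit_prob_adult", "zero_fruit_prob_child",
                  "drinker_prob_adult", "smoker_prob_adult", "smoker_prob_child"):
            if not 0 <= getattr(self, p) <= 1:
                raise ValueError(f"{p} outside [0, 1]")
        if self.pct_split_diff <= 0:
            raise ValueError("pct_split_diff must be positive")

    # ------------------------------------------------------------------
    def level_couplings(self) -> dict[str, float]:
        """Level slopes of the five component means per pct point.

        Fruit+veg is sized from the gap target; sodium absorbs the residual
        so that the implied z-slope equals ``z_slope_target`` exactly.
        """
        m = self.adult_marginals
        c = {
            "fv": self.fv_gap_target / self.pct_split_diff,
            "fiber": self.fiber_coupling,
            "satfat": self.satfat_coupling,
            "sugar": self.sugar_coupling,
        }
        partial = sum(COMPONENT_SIGNS[k] * c[k] / m[k].sd for k in c)
        c["sodium"] = -(self.z_slope_target - partial) * m["sodium"].sd
        return c


def default_config(**overrides) -> SyntheticConfig:
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


def implied_z_slope(config: SyntheticConfig) -> float:
    """The z-DQS-on-pct slope implied by the level couplings and marginal SDs."""
    c = config.level_couplings()
    return sum(
        COMPONENT_SIGNS[k] * c[k] / config.adult_marginals[k].sd for k in c
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_age(rng, config, z_age: float) -> float:
    """Adult age from the category-weight histogram via a Gaussian copula."""
    from scipy.stats import norm

    u = norm.cdf(z_age)
    weights = np.array([w for (_lo, _hi, w) in config.age_weights], dtype=float)
    cum = np.cumsum(weights) / weights.sum()
    k = int(np.searchsorted(cum, u, side="left"))
    k = min(k, len(config.age_weights) - 1)
    lo, hi, _ = config.age_weights[k]
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (u - prev) / (cum[k] - prev)
    return lo + frac * (hi - lo)


def _lognormal_factor(rng, log_sd: float) -> float:
    """exp(N(-s^2/2, s^2)); mean exactly 1."""
    return math.exp(rng.normal(-0.5 * log_sd**2, log_sd))


def _marginal_draw(rng, marg: NutrientMarginal) -> float:
    """Plain lognormal draw matching a marginal mean/SD."""
    var_log = math.log(1.0 + (marg.sd / marg.mean) ** 2)
    mu = math.log(marg.mean) - 0.5 * var_log
    return math.exp(rng.normal(mu, math.sqrt(var_log)))


def _coupled_draw(rng, marg, c_level, pct, g_level, female_c, config) -> float:
    """Linear-conditional-mean draw with multiplicative lognormal noise.

    E[x | pct, female] = mean + c*(pct - pct_mean) + g*female_c exactly; the
    noise log-SD solves for the configured marginal SD under the assumed
    Var(pct) and Var(female_c).
    """
    m = marg.mean + c_level * (pct - config.pct_mean) + g_level * female_c
    m = max(m, 0.05 * marg.mean)
    k = (
        marg.mean**2
        + c_level**2 * config.pct_var
        + g_level**2 * config.female_frac * (1 - config.female_frac)
    )
    e_sq = (marg.sd**2 + marg.mean**2) / k
    log_var = math.log(max(e_sq, 1.0))
    return m * _lognormal_factor(rng, math.sqrt(log_var))


def _subject_days(rng, config, sid, is_child, t_latent):
    """Draw the two recall days' occasion times and energies (no nutrients yet)."""
    snack_shift = config.snackiness_prob_shift * rng.normal()
    late_snacker = rng.random() < config.after_dinner_habit_prob
    habit_time = {}
    present_prob = {}
    for label, spec in config.occasions.items():
        mean_t = spec.mean_time
        if label == "lunch":
            mean_t -= config.lunch_minutes_per_t * t_latent
        habit_time[label] = mean_t + spec.subject_time_sd * rng.normal()
        if label == "after_dinner_snack":
            # a subject-level habit: non-snackers almost never report one
            p = spec.prob if late_snacker else 0.02
        else:
            p = spec.prob if spec.prob >= 1.0 else spec.prob + snack_shift
        present_prob[label] = min(max(p, 0.02), 1.0)

    e_subject = math.exp(
        -0.5 * (config.subject_energy_log_sd**2 + config.energy_log_per_t**2)
        - config.energy_log_per_t * t_latent
        + config.subject_energy_log_sd * rng.normal()
    )
    # subject-level tilt of energy toward the morning slots; the e^{m} /
    # e^{-m} factors are mean-corrected so marginal occasion means hold
    m_var = config.morningness_log_sd**2 + config.morningness_per_t**2
    morningness = (
        config.morningness_per_t * t_latent
        + config.morningness_log_sd * rng.normal()
    )
    days = []
    for day_index in (1, 2):
        occ = {}
        for label, spec in config.occasions.items():
            if rng.random() >= present_prob[label]:
                continue
            t = habit_time[label] + spec.day_jitter_sd * rng.normal()
            t = int(round(min(max(t, 0), 1439)))
            mean_kcal = spec.mean_kcal_child if is_child else spec.mean_kcal_adult
            sign = 1.0 if label in _MORNING_SLOTS else -1.0
            # the cross term cancels Cov(tilt, energy scale) through T so the
            # marginal occasion mean stays exactly mean_kcal
            cross = sign * config.morningness_per_t * config.energy_log_per_t
            kcal = (
                mean_kcal
                * e_subject
                * math.exp(sign * morningness - 0.5 * m_var + cross)
                * _lognormal_factor(rng, config.occasion_energy_log_sd)
            )
            occ[label] = (t, kcal)
        days.append(occ)
    return days


def _subject_nutrient_targets(rng, config, is_child, pct_before, female):
    """Subject-level two-day-average nutrient targets."""
    marg = config.child_marginals if is_child else config.adult_marginals
    female_c = float(female) - config.female_frac
    targets = {}
    if is_child:
        for comp in DQS_COMPONENTS:
            targets[comp] = _marginal_draw(rng, marg[comp])
    else:
        couplings = config.level_couplings()
        for comp in DQS_COMPONENTS:
            targets[comp] = _coupled_draw(
                rng, marg[comp], couplings[comp], pct_before,
                config.gender_effects.get(comp, 0.0), female_c, config,
            )
    targets["water"] = _marginal_draw(rng, marg["water"])
    targets["energy_density"] = _marginal_draw(rng, marg["energy_density"])
    targets["protein_pct"] = min(max(rng.normal(marg["protein_pct"].mean,
                                                marg["protein_pct"].sd), 8.0), 30.0)
    targets["fat_pct"] = min(max(rng.normal(marg["fat_pct"].mean,
                                            marg["fat_pct"].sd), 20.0), 70.0)
    if not is_child and rng.random() < config.drinker_prob_adult:
        targets["alcohol_g"] = _marginal_draw(rng, NutrientMarginal(12.0, 12.0))
    else:
        targets["alcohol_g"] = 0.0
    zero_fruit_p = (
        config.zero_fruit_prob_child if is_child else config.zero_fruit_prob_adult
    )
    targets["fruit_frac"] = 0.0 if rng.random() < zero_fruit_p else rng.beta(2.0, 2.1)
    return targets


def _build_days(sid, raw_days, targets, config):
    """Allocate subject nutrient targets across days and occasions."""
    e_day = [sum(k for (_t, k) in d.values()) for d in raw_days]
    e_total = e_day[0] + e_day[1]
    e_mean = 0.5 * e_total

    alcohol_pct = min(700.0 * targets["alcohol_g"] / e_mean, 12.0)
    fat_pct = targets["fat_pct"]
    protein_pct = targets["protein_pct"]
    carb_pct = 100.0 - protein_pct - fat_pct - alcohol_pct
    if carb_pct < 5.0:  # keep shares physical for extreme draws
        scale = (100.0 - 5.0 - alcohol_pct) / (protein_pct + fat_pct)
        protein_pct *= scale
        fat_pct *= scale
        carb_pct = 5.0
    sugar_pct = min(targets["sugar"], carb_pct - 1.0)
    satfat_pct = min(targets["satfat"], fat_pct - 1.0)

    days = []
    for d_idx, raw in enumerate(raw_days):
        e_d = e_day[d_idx]
        u_d = 2.0 * e_d / e_total  # day weight: two-day mean equals the target
        day_totals = {
            "carbohydrate": carb_pct * e_d / 400.0,
            "protein": protein_pct * e_d / 400.0,
            "fat": fat_pct * e_d / 900.0,
            "saturated_fat": satfat_pct * e_d / 900.0,
            "sugar": sugar_pct * e_d / 400.0,
            "alcohol": alcohol_pct * e_d / 700.0,
            "fiber": targets["fiber"] * e_d / 1000.0,
            "sodium": targets["sodium"] * u_d,
            "water": targets["water"] * u_d,
            "food_mass": e_d / targets["energy_density"],
            "fruit": targets["fv"] * targets["fruit_frac"] * u_d,
            "vegetables": targets["fv"] * (1.0 - targets["fruit_frac"]) * u_d,
        }
        occasions = []
        for label, (t, kcal) in raw.items():
            share = kcal / e_d
            occasions.append(
                EatingOccasion(
                    label=label,
                    start_time=t,
                    energy=kcal,
                    **{n: v * share for n, v in day_totals.items()},
                )
            )
        days.append(RecallDay(subject_id=sid, day_index=d_idx + 1,
                              occasions=tuple(occasions)))
    return days


def generate_cohort(config: SyntheticConfig | None = None, seed: int = 0) -> Dataset:
    """Generate a full synthetic survey dataset, deterministic given the seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    ds = Dataset()

    specs = [("C", True, i) for i in range(config.n_children)] + [
        ("A", False, i) for i in range(config.n_adults)
    ]
    for prefix, is_child, i in specs:
        sid = f"{prefix}{i + 1:04d}"
        t_latent = rng.normal()
        female = rng.random() < config.female_frac

        if is_child:
            age = float(rng.integers(10, 18))
            bmi_marg = config.child_bmi
            z_age = rng.normal()
        else:
            rho = config.age_t_rho
            z_age = rho * t_latent + math.sqrt(1 - rho**2) * rng.normal()
            age = _draw_age(rng, config, z_age)
            age = min(age, 74.0)
            bmi_marg = config.adult_bmi

        r = config.bmi_age_copula_rho
        z_bmi = r * z_age + math.sqrt(1 - r**2) * rng.normal()
        var_log = math.log(1.0 + (bmi_marg.sd / bmi_marg.mean) ** 2)
        bmi = math.exp(math.log(bmi_marg.mean) - 0.5 * var_log
                       + math.sqrt(var_log) * z_bmi)
        if rng.random() < config.anthropometry_missing_prob:
            weight = height = None
        else:
            height = rng.normal(165.0 if female else 178.0, 6.5)
            if is_child:
                height -= 10.0
            weight = bmi * (height / 100.0) ** 2

        if is_child:
            employed = False
            smoker = rng.random() < config.smoker_prob_child
        else:
            p_emp = 0.5
            for (lo, hi), p in _EMPLOYED_BY_AGE.items():
                if lo <= age < hi:
                    p_emp = p
                    break
            employed = rng.random() < min(max(
                p_emp + config.employed_t_shift * t_latent, 0.0), 1.0)
            smoker = rng.random() < config.smoker_prob_adult

        subject = Subject(
            subject_id=sid,
            age=age,
            gender="female" if female else "male",
            weight=weight,
            height=height,
            bmi_measured=rng.random() < config.measured_bmi_prob,
            employed_outside_home=employed,
            smoker=smoker,
        )

        raw_days = _subject_days(rng, config, sid, is_child, t_latent)
        e_before = sum(
            k for d in raw_days for (t, k) in d.values() if t < config.cutoff_time
        )
        e_total = sum(k for d in raw_days for (_t, k) in d.values())
        pct_before = 100.0 * e_before / e_total

        targets = _subject_nutrient_targets(rng, config, is_child, pct_before, female)
        days = _build_days(sid, raw_days, targets, config)

        ds.add_subject(subject)
        for day in days:
            ds.add_day(day)
    return ds


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


def _adult_analysis(ds: Dataset, config: SyntheticConfig):
    """Run the analysis stages on the adults of one cohort."""
    intakes = subject_intake_table(ds)
    adults = intakes[~intakes["is_child"]]
    thresholds = TimingThresholds(cutoff_time=config.cutoff_time)

    profiles = {}
    for sid in adults.index:
        d1, d2 = ds.days_for(sid)
        profiles[sid] = timing_profile(d1, d2, thresholds)
    pct = pd.Series({s: p.pct_energy_before_cutoff for s, p in profiles.items()})
    early = pd.Series({s: p.early_eater for s, p in profiles.items()})

    # z-DQS on the adult cohort
    from .intake import average_subject_intake, compute_daily_intake

    subject_intakes = []
    for sid in adults.index:
        d1, d2 = ds.days_for(sid)
        subject_intakes.append(
            average_subject_intake(
                compute_daily_intake(d1), compute_daily_intake(d2), ds.subjects[sid]
            )
        )
    z = zscore_components(subject_intakes, Recommendations())

    X = pd.DataFrame(
        {
            "pct_before": pct,
            "age": adults["age"],
            "female": (adults["gender"] == "female").astype(float),
        }
    )
    reg = ols(z["z_total"].loc[X.index], X)

    fv = adults["fruit_veg"]
    gap = float(fv[early].mean() - fv[~early].mean())

    long_rows = []
    for sid in adults.index:
        for day in ds.days_for(sid):
            for o in day.occasions:
                if o.label in ("breakfast", "lunch", "dinner"):
                    long_rows.append({"subject": sid, "meal": o.label, "kcal": o.energy})
    return reg, gap, pd.DataFrame(long_rows)


def recovery_report(
    config: SyntheticConfig | None = None,
    n_replicates: int = 20,
    seed: int = 0,
    include_meal_model: bool = True,
) -> dict:
    """Simulate replicates, rerun the pipeline, and compare against truth.

    For each replicate: generate a cohort, compute per-subject intakes,
    timing profiles and diet-quality z-scores, and record (a) the
    age/gender-adjusted OLS slope of the z-score on percent of energy
    before the cutoff, (b) the early-vs-late fruit+veg gap, and (c),
    optionally, the mixed-model per-meal marginal means.  Returns per-
    replicate values and a summary of bias against the generating values.
    """
    config = config or SyntheticConfig()
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        ds = generate_cohort(config, seed=rep_seed)
        reg, gap, long_df = _adult_analysis(ds, config)
        row = {
            "seed": rep_seed,
            "slope": reg.coef("pct_before"),
            "slope_se": reg.se("pct_before"),
            "fv_gap": gap,
        }
        if include_meal_model:
            mm = random_intercept_meals(long_df)
            for meal in ("breakfast", "lunch", "dinner"):
                row[f"mean_{meal}"] = mm.marginal_means[meal]
        rows.append(row)
    reps = pd.DataFrame(rows)

    def mc(col):
        return {
            "mean": float(reps[col].mean()),
            "mc_se": float(reps[col].std(ddof=1) / math.sqrt(len(reps)))
            if len(reps) > 1
            else float("nan"),
        }

    summary = {
        "replicates": reps,
        "slope": {**mc("slope"), "generative": implied_z_slope(config)},
        "fv_gap": {**mc("fv_gap"), "generative": config.fv_gap_target},
    }
    if include_meal_model:
        for meal in ("breakfast", "lunch", "dinner"):
            spec = config.occasions[meal]
            summary[f"mean_{meal}"] = {
                **mc(f"mean_{meal}"),
                "generative": spec.mean_kcal_adult,
            }
    return summary
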