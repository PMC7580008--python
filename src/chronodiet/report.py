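"""End-to-end pipeline driver and survey-style report tables.

Builds the standard deliverables of a two-recall dietary survey analysis:
a nutrient-intake summary by age group (children / adults / all, with
child-vs-adult t-tests and BH-FDR adjustment), early-vs-late eater and
eats-after-20:00 comparisons, per-occasion time/energy summaries, and
histogram data of largest-meal timing and percent-before-cutoff by
diet-quality category, plus the DQS-category ANOVAs.

Formatting follows survey conventions: "mean (SD)" cells, "n (%)" cells
with percentages rounded half-away-from-zero to integers, and percentages
computed over subjects with valid data for the variable in question.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intake import average_subject_intake, compute_daily_intake, subject_intake_table
from .quality import Recommendations, dqs_category, score_dqs, zscore_components
from .recall_data import Dataset, OCCASION_LABELS
from .stats import (
    anova_tukey,
    benjamini_hochberg,
    chi_square,
    ols,
    random_intercept_meals,
    two_sample_t,
)
from .timing import TimingThresholds, timing_profile

__all__ = [
    "ReportTable",
    "PipelineResult",
    "format_percent",
    "grams_to_servings",
    "run_pipeline",
]

log = logging.getLogger(__name__)


def format_percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero.

    Uses exact integer arithmetic so printed-table cells reproduce exactly.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return (200 * numerator + denominator) // (2 * denominator)


def grams_to_servings(grams_per_day: float, grams_per_serving: float = 85.0) -> tuple[float, int]:
    """Convert g/day to servings/day (default 85 g per half-cup serving).

    Returns the raw value and its nearest-integer rounding, e.g. 400 g/day
    is 4.71, about 5 servings.
    """
    if grams_per_serving <= 0:
        raise ValueError("grams_per_serving must be positive")
    raw = grams_per_day / grams_per_serving
    return raw, int(math.floor(raw + 0.5))


@dataclass
class ReportTable:
    """A formatted table: mean (SD) or n (%) cells plus footnotes."""

    title: str
    columns: list[str]
    rows: dict[str, list[str]] = field(default_factory=dict)
    footnotes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.rows, orient="index", columns=self.columns)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    intakes: pd.DataFrame          # per-subject intake metrics
    timing: pd.DataFrame           # per-subject timing profile
    quality: pd.DataFrame          # per-adult DQS and z-scores
    nutrient_table: ReportTable    # children/adults/all summary
    early_late_table: ReportTable  # early vs late eaters
    after_2000_table: ReportTable  # eats after 20:00 vs not
    occasion_summary: pd.DataFrame  # per-occasion mean time/kcal/consumers
    meal_model: object             # MixedModelResult for the three main meals
    largest_meal_hist: pd.DataFrame  # largest-meal time counts by DQS category
    pct_before_hist: pd.DataFrame    # pct-before counts by DQS category
    dqs_anova: dict                # ANOVA + Tukey for pct-before and ln(energy)
    statistics: dict               # flat bundle of headline numbers


def _fmt_mean_sd(values, decimals=0) -> str:
    a = np.asarray(values, dtype=float)
    a = a[~np.isnan(a)]
    if a.size == 0:
        return "-"
    m, s = a.mean(), a.std(ddof=1) if a.size > 1 else float("nan")
    return f"{m:.{decimals}f} ({s:.{decimals}f})"


def _fmt_n_pct(n: int, denom: int) -> str:
    return f"{n} ({format_percent(n, denom)}%)" if denom else "-"


# variable -> (pretty label, decimals) for mean (SD) formatting; kcal and
# percent-of-energy as integers, sodium and densities with two decimals.
_NUTRIENT_ROWS = [
    ("energy", "Energy (kcal/day)", 0),
    ("carbohydrate_pct", "Carbohydrate (% of energy)", 0),
    ("protein_pct", "Protein (% of energy)", 0),
    ("fat_pct", "Fat (% of energy)", 0),
    ("saturated_fat_pct", "Saturated fat (% of energy)", 0),
    ("fiber_density", "Fiber (g/1000 kcal)", 1),
    ("fruit", "Fruit (g/day)", 0),
    ("vegetables", "Vegetables (g/day)", 0),
    ("fruit_veg", "Fruit and vegetables (g/day)", 0),
    ("sodium", "Sodium (g/day)", 2),
    ("sugar_pct", "Sugar (% of energy)", 1),
    ("water", "Water (ml/day)", 0),
    ("protein_per_kg", "Protein (g/kg body weight)", 2),
    ("energy_density", "Energy density (kcal/g food)", 2),
    ("pct_energy_before_cutoff", "% of energy before cutoff", 0),
    ("occasions_per_day", "Eating occasions per day", 1),
]


def _nutrient_table(df: pd.DataFrame, alpha: float) -> ReportTable:
    """Children / adults / all nutrient summary with FDR-adjusted t-tests."""
    child = df[df["is_child"]]
    adult = df[~df["is_child"]]
    table = ReportTable(
        title="Nutrient intakes by age group",
        columns=[
            f"Children (n={len(child)})",
            f"Adults (n={len(adult)})",
            f"All (n={len(df)})",
            "p (child vs adult)",
        ],
    )
    pvals, keys = [], []
    for key, label, dec in _NUTRIENT_ROWS:
        if key not in df.columns:
            continue
        cv = child[key].dropna()
        av = adult[key].dropna()
        p_cell = "-"
        if len(cv) >= 2 and len(av) >= 2:
            p = two_sample_t(cv, av).p_value
            pvals.append(p)
            keys.append(label)
            p_cell = f"{p:.3g}"
        table.rows[label] = [
            _fmt_mean_sd(cv, dec),
            _fmt_mean_sd(av, dec),
            _fmt_mean_sd(df[key].dropna(), dec),
            p_cell,
        ]
    if pvals:
        fdr = benjamini_hochberg(pvals, alpha=alpha)
        flagged = [k for k, s in zip(keys, fdr.significant) if s]
        table.footnotes.append(
            "Two-sample t-tests (Welch), Benjamini-Hochberg FDR at "
            f"alpha={alpha}; significant after adjustment: {flagged or 'none'}"
        )
    return table


_COMPARISON_CONTINUOUS = [
    ("pct_energy_before_cutoff", "% of calories before cutoff", 0),
    ("energy", "Total calorie intake (kcal/day)", 0),
    ("age", "Age (years)", 1),
    ("bmi", "BMI (kg/m^2)", 1),
    ("occasions_per_day", "Eating occasions per day", 1),
    ("energy_density", "Energy density (kcal/g food)", 2),
    ("fruit_veg", "Fruits and vegetables (g/day)", 0),
    ("fiber_density", "Fiber (g/1000 kcal)", 1),
    ("saturated_fat_pct", "Saturated fat (% of energy)", 1),
    ("sugar_pct", "Sugar (% of energy)", 1),
    ("sodium", "Sodium (g/day)", 1),
    ("z_total", "Diet quality z-score", 2),
]

_COMPARISON_CATEGORICAL = [
    ("female", "Female"),
    ("employed", "Employed outside the home"),
    ("smoker", "Current smoker"),
    ("overweight_or_obese", "Overweight or obese"),
    ("dqs_high", "Diet quality score 4-5"),
]


def _group_comparison_table(adf: pd.DataFrame, flag: str, title: str,
                            group_labels: tuple[str, str], alpha: float) -> ReportTable:
    """Two-group comparison: mean (SD) + t-test or n (%) + chi-square, BH-FDR."""
    g1 = adf[adf[flag]]
    g0 = adf[~adf[flag]]
    if len(g1) < 2 or len(g0) < 2:
        log.warning("%s: degenerate group sizes (%d vs %d)", title, len(g1), len(g0))
    table = ReportTable(
        title=title,
        columns=[f"{group_labels[0]} (n={len(g1)})",
                 f"{group_labels[1]} (n={len(g0)})", "p-value"],
    )
    pvals, labels = [], []
    for key, label, dec in _COMPARISON_CONTINUOUS:
        if key not in adf.columns:
            continue
        v1, v0 = g1[key].dropna(), g0[key].dropna()
        p_cell = "-"
        if len(v1) >= 2 and len(v0) >= 2:
            p = two_sample_t(v1, v0).p_value
            pvals.append(p)
            labels.append(label)
            p_cell = f"{p:.3g}"
        table.rows[label] = [_fmt_mean_sd(v1, dec), _fmt_mean_sd(v0, dec), p_cell]
    for key, label in _COMPARISON_CATEGORICAL:
        if key not in adf.columns:
            continue
        c1, c0 = g1[key].dropna().astype(bool), g0[key].dropna().astype(bool)
        p_cell = "-"
        counts = np.array(
            [[c1.sum(), len(c1) - c1.sum()], [c0.sum(), len(c0) - c0.sum()]]
        )
        if counts.sum(axis=1).min() > 0 and counts.sum(axis=0).min() > 0:
            p = chi_square(counts).p_value
            pvals.append(p)
            labels.append(label)
            p_cell = f"{p:.3g}"
        table.rows[label] = [
            _fmt_n_pct(int(c1.sum()), len(c1)),
            _fmt_n_pct(int(c0.sum()), len(c0)),
            p_cell,
        ]
    if pvals:
        fdr = benjamini_hochberg(pvals, alpha=alpha)
        sig = [l for l, s in zip(labels, fdr.significant) if s]
        cut = fdr.largest_significant_raw_p
        table.footnotes.append(
            "t-tests for continuous and Pearson chi-square for categorical "
            f"variables; BH-FDR at alpha={alpha}: largest significant raw "
            f"p = {cut}; significant: {sig or 'none'}"
        )
    return table


def run_pipeline(
    ds: Dataset,
    thresholds: TimingThresholds | None = None,
    recommendations: Recommendations | None = None,
    alpha: float = 0.05,
) -> PipelineResult:
    """Run the full analysis on a validated dataset."""
    thresholds = thresholds or TimingThresholds()
    recommendations = recommendations or Recommendations()

    problems = ds.validate()
    if problems:
        raise ValueError("dataset failed validation: " + "; ".join(problems[:5]))

    intakes = subject_intake_table(ds)
    if intakes.empty:
        raise ValueError("pipeline stage 'intake': no subjects with two recall days")

    # --- timing stage ----------------------------------------------------
    timing_rows = []
    for sid in intakes.index:
        d1, d2 = ds.days_for(sid)
        p = timing_profile(d1, d2, thresholds)
        if p.lunch_day_gap is None:
            log.info("subject %s: lunch missing on a day, excluded from "
                     "lunch-consistency summary", sid)
        timing_rows.append(
            {
                "subject_id": sid,
                "pct_energy_before_cutoff": p.pct_energy_before_cutoff,
                "largest_meal_time": p.largest_meal_time,
                "largest_meal_day1": p.largest_meal_label_by_day[0],
                "largest_meal_day2": p.largest_meal_label_by_day[1],
                "early_eater": p.early_eater,
                "eats_after_2000": p.eats_after_2000,
                "lunch_day_gap": p.lunch_day_gap,
                "lunch_within_1h": p.lunch_within_1h,
                "occasions_per_day": p.occasions_per_day,
            }
        )
    timing_df = pd.DataFrame(timing_rows).set_index("subject_id")

    merged = intakes.join(timing_df.drop(columns=["occasions_per_day"]))
    merged["bmi"] = pd.Series(
        {sid: ds.subjects[sid].bmi for sid in merged.index}, dtype=float
    )
    for sid in merged.index[merged["bmi"].isna()]:
        log.info("subject %s: missing BMI, excluded from BMI summaries", sid)
    merged["female"] = merged["gender"] == "female"
    merged["employed"] = pd.Series(
        {sid: ds.subjects[sid].employed_outside_home for sid in merged.index}
    )
    merged["smoker"] = pd.Series(
        {sid: ds.subjects[sid].smoker for sid in merged.index}
    )
    merged["overweight_or_obese"] = (merged["bmi"] > 25.0).astype("object")
    merged.loc[merged["bmi"].isna(), "overweight_or_obese"] = np.nan

    # --- diet-quality stage (adults only) --------------------------------
    adult_ids = merged.index[~merged["is_child"]]
    subject_intakes = []
    for sid in adult_ids:
        d1, d2 = ds.days_for(sid)
        subject_intakes.append(
            average_subject_intake(
                compute_daily_intake(d1), compute_daily_intake(d2), ds.subjects[sid]
            )
        )
    try:
        z = zscore_components(subject_intakes, recommendations)
    except ValueError as exc:
        raise ValueError(f"pipeline stage 'diet-quality': {exc}") from exc
    qrows = []
    for si in subject_intakes:
        flags, dqs = score_dqs(si, recommendations)
        qrows.append(
            {
                "subject_id": si.subject_id,
                **{f"met_{k}": v for k, v in flags.items()},
                "dqs": dqs,
                "dqs_category": dqs_category(dqs),
            }
        )
    quality_df = pd.DataFrame(qrows).set_index("subject_id").join(z)

    adf = merged.loc[adult_ids].join(quality_df[["dqs", "dqs_category", "z_total"]])
    adf["dqs_high"] = adf["dqs"] >= 4

    # --- report tables ---------------------------------------------------
    nutrient_table = _nutrient_table(merged, alpha)
    early_late = _group_comparison_table(
        adf, "early_eater",
        "Adults who did or did not consume at least "
        f"{thresholds.early_pct:g}% of daily energy before the cutoff",
        ("Early eaters", "Late eaters"), alpha,
    )
    after_2000 = _group_comparison_table(
        adf, "eats_after_2000",
        "Adults who do or do not report eating after 20:00",
        ("Eat after 20:00", "Do not eat after 20:00"), alpha,
    )

    # --- per-occasion summary (figure data) -------------------------------
    occ_rows = []
    for label in OCCASION_LABELS:
        times, kcals, consumers = [], [], 0
        for sid in merged.index:
            ts, ks = [], []
            for day in ds.days_for(sid):
                o = day.occasion(label)
                if o is not None:
                    ts.append(o.start_time)
                    ks.append(o.energy)
            if ts:
                consumers += 1
                times.append(np.mean(ts))
                kcals.append(np.mean(ks))
        occ_rows.append(
            {
                "label": label,
                "n_consumers": consumers,
                "mean_time_min": float(np.mean(times)) if times else np.nan,
                "mean_kcal": float(np.mean(kcals)) if kcals else np.nan,
                "sd_kcal": float(np.std(kcals, ddof=1)) if len(kcals) > 1 else np.nan,
            }
        )
    occasion_summary = pd.DataFrame(occ_rows).set_index("label")

    # --- mixed model on the three main meals ------------------------------
    long_rows = [
        {"subject": sid, "meal": o.label, "kcal": o.energy}
        for sid in adult_ids
        for day in ds.days_for(sid)
        for o in day.occasions
        if o.label in ("breakfast", "lunch", "dinner")
    ]
    meal_model = random_intercept_meals(pd.DataFrame(long_rows))

    # --- histogram data by DQS category ----------------------------------
    hour_bins = np.arange(0, 25, 1)
    pct_bins = np.arange(0, 101, 10)
    lm_hist, pb_hist = {}, {}
    for cat, sub in adf.groupby("dqs_category", observed=False):
        lm_hist[cat] = np.histogram(sub["largest_meal_time"] / 60.0, bins=hour_bins)[0]
        pb_hist[cat] = np.histogram(
            sub["pct_energy_before_cutoff"].clip(0, 100), bins=pct_bins
        )[0]
    largest_meal_hist = pd.DataFrame(
        lm_hist, index=pd.Index(hour_bins[:-1], name="hour")
    )
    pct_before_hist = pd.DataFrame(
        pb_hist, index=pd.Index(pct_bins[:-1], name="pct_bin")
    )

    # --- DQS-category ANOVAs ----------------------------------------------
    cats = sorted(adf["dqs_category"].unique())
    dqs_anova = {}
    if len(cats) >= 2 and all((adf["dqs_category"] == c).sum() >= 2 for c in cats):
        groups_pct = [
            adf.loc[adf["dqs_category"] == c, "pct_energy_before_cutoff"] for c in cats
        ]
        groups_kcal = [adf.loc[adf["dqs_category"] == c, "energy"] for c in cats]
        dqs_anova = {
            "categories": cats,
            "pct_before": anova_tukey(groups_pct),
            "ln_energy": anova_tukey(groups_kcal, log_transform=True),
        }
    else:
        log.warning("DQS-category ANOVA skipped: a category has < 2 adults")

    # --- trend regression and headline statistics -------------------------
    X = pd.DataFrame(
        {
            "pct_before": adf["pct_energy_before_cutoff"],
            "age": adf["age"],
            "female": adf["female"].astype(float),
        }
    )
    trend = ols(adf["z_total"], X)

    lunch_gaps = timing_df.loc[adult_ids, "lunch_day_gap"].dropna()
    within = timing_df.loc[adult_ids, "lunch_within_1h"].dropna()
    n_adults = len(adult_ids)
    statistics = {
        "n_children": int(merged["is_child"].sum()),
        "n_adults": n_adults,
        "n_early": int(adf["early_eater"].sum()),
        "n_late": int((~adf["early_eater"]).sum()),
        "n_after_2000": int(adf["eats_after_2000"].sum()),
        "mean_pct_before_adults": float(adf["pct_energy_before_cutoff"].mean()),
        "mean_lunch_time_min": float(
            occasion_summary.loc["lunch", "mean_time_min"]
        ),
        "lunch_gap_mean_min": float(lunch_gaps.mean()) if len(lunch_gaps) else np.nan,
        "lunch_within_1h_pct": (
            format_percent(int(within.sum()), len(within)) if len(within) else np.nan
        ),
        "largest_meal_lunch_pct": format_percent(
            int(
                (
                    (adf["largest_meal_day1"] == "lunch")
                    & (adf["largest_meal_day2"] == "lunch")
                ).sum()
            ),
            n_adults,
        )
        if n_adults
        else np.nan,
        "zscore_slope_adjusted": trend.coef("pct_before"),
        "zscore_slope_se": trend.se("pct_before"),
        "zscore_slope_p": trend.p("pct_before"),
        "meal_marginal_means": meal_model.marginal_means,
        "meal_pairwise_p": {f"{a}_vs_{b}": p for (a, b), p in meal_model.pairwise_p.items()},
    }

    return PipelineResult(
        intakes=merged,
        timing=timing_df,
        quality=quality_df,
        nutrient_table=nutrient_table,
        early_late_table=early_late,
        after_2000_table=after_2000,
        occasion_summary=occasion_summary,
        meal_model=meal_model,
        largest_meal_hist=largest_meal_hist,
        pct_before_hist=pct_before_hist,
        dqs_anova=dqs_anova,
        statistics=statistics,
    )
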