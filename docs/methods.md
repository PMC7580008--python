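# Methods

## Scope

`chronodiet` analyses two-day 24-h dietary recall surveys in which each
subject reports up to eight labelled, timed eating occasions per day, each
already resolved to energy and nutrients by an upstream food-composition
step. The package computes per-subject intake summaries, meal-timing
metrics, a five-component Diet Quality Score with a continuous z-score
companion, group comparisons with FDR control, and ships a synthetic-cohort
generator so that the complete pipeline is testable without survey
microdata.

## Intake summaries

Daily totals are sums over a day's occasions; subject-level intake is the
arithmetic mean of the two recall days. Derived ratios are computed from
the averaged numerator and denominator (ratio of means):

- percent of energy for a macronutrient with Atwater factor `k` (4/4/9/7
  kcal/g for carbohydrate/protein/fat/alcohol; saturated fat uses 9, sugar
  uses 4): `100 * k * grams / energy`;
- fiber density `1000 * fiber / energy` (g/1000 kcal);
- energy density `energy / food_mass` (kcal/g), with `food_mass` excluding
  drinking water and beverages — including ~2–3 L/day of fluids would make
  typical energy densities (~0.9 kcal/g) arithmetically impossible;
- protein per kg body weight, reported missing when weight is missing.

Energy in the percent denominators is the reported (database-derived)
occasion energy, never recomputed from macronutrient grams, so on real data
the four macronutrient shares need not total 100%.

## Meal timing

Only occasion *start* times exist, so every convention is defined on them:

- **Percent of energy before the cutoff** (default 16:00): energy of
  occasions starting strictly before the cutoff, pooled over both days,
  divided by total energy over both days. This equals mean-kcal-before /
  mean daily energy. A per-day-averaged variant is available
  (`method="per_day_mean"`); pooled is the default.
- **Early eater**: at least 60% of energy before the cutoff (inclusive).
- **Eats after 20:00**: any occasion on either day starting strictly after
  20:00 — the strictest observable version of "habitually eats late" on two
  days of data.
- **Largest meal**: the highest-energy occasion of a day, snacks included;
  ties break to the earliest start. When the largest meal differs between
  days, the reported time is still the mean of the two per-day times.
- **Lunch consistency**: the absolute between-day difference in lunch start;
  "within one hour" is inclusive at 60 min.

## Diet quality

The Diet Quality Score (DQS) counts met recommendations (0–5), using the
EU Science Hub reference values: fruit+vegetables ≥ 400 g/day, fiber ≥ 14
g/1000 kcal, sugar < 10% of energy, saturated fat < 10% of energy, sodium
< 2.3 g/day. "Meeting" thresholds (fruit/veg, fiber) are inclusive; limits
are strict. The sugar component scores *total* sugar percent of energy —
the variable a recall survey produces — although the underlying
recommendation concerns added sugar; this is a documented divergence, and
all thresholds and comparison directions are overridable via
`Recommendations`.

The continuous Diet Quality z-Score standardizes each component against the
cohort:

    z_ij = s_i * (x_ij - r_i) / SD_i,    z_total,j = sum_i z_ij

with sign `s_i = +1` for fruit+veg and fiber and `-1` for sugar, saturated
fat and sodium, and `SD_i` the sample SD (n−1) of component `i` over the
cohort passed in. The cohort is an explicit argument (typically the adult
analysis sample — scoring is adult-only because child recommendations
differ); it is never global state. A zero-variance component raises a
degenerate-cohort error rather than returning infinities.

Scores are binned 0–1 / 2–3 / 4–5 for the ordinal analyses.

## Statistical procedures

All procedures are thin validated wrappers over scipy/statsmodels with
uniform result objects: Welch t-tests (pooled available for exact
ANOVA equivalence, F = t²), Pearson chi-square without continuity
correction, Spearman correlation with averaged ranks, one-way ANOVA with
Tukey HSD post-hoc (Tukey–Kramer SE under unequal n; studentized-range
tail probabilities from scipy), OLS with intercept and collinearity
diagnosis, and Benjamini–Hochberg step-up FDR (adjusted
`p_(i) = min_{j>=i} m p_(j)/j`, capped at 1, returned in input order).

Per-meal energy is compared with a linear mixed model
`kcal_ij = mu + meal_j + u_i + e_ij` with a subject random intercept,
fitted by REML (statsmodels MixedLM) in cell-means coding so the fixed
effects are the per-meal marginal means. Pairwise meal contrasts use Wald
z tests; a Satterthwaite degrees-of-freedom convention would give slightly
wider intervals at small n, which is immaterial at survey sizes. Variance
components are bounded below at zero; the balanced-case closed form (cell
means, paired-t contrasts) is used as a test oracle, not as the
implementation path.

For reproducing published footnotes, "< 0.001" p-values entering an FDR
recomputation are encoded as 0.0005.

## The synthetic cohort generator

The generator emulates a two-recall national dietary survey of 74 children
and 260 adults (54% female; adult ages drawn from the category histogram
75/73/73/39 over 18–29/30–47/48–64/65–74). Its defaults are the study
conditions the analysis targets:

- **Occasions.** Breakfast, lunch and dinner always present; snack slots
  occur with per-day probabilities shifted by a subject-level "snackiness",
  giving ~6 occasions/day (SD ~1). The after-dinner snack is a subject-level
  habit (48% of subjects), which makes roughly a quarter of adults never eat
  after 20:00 across two days. Occasion times are subject habitual means
  (breakfast ~9:00, lunch ~15:15, dinner ~20:00) plus day-to-day jitter;
  lunch jitter SD is 21 min so the expected absolute between-day lunch gap
  is 2·21/√π ≈ 24 min.
- **Energies.** Occasion energy is lognormal around configured means
  (adults 537/761/568 kcal for breakfast/lunch/dinner; children
  560/665/520; snack means solved so expected total energy is 2265
  kcal/day for adults and 2280 for children), multiplied by a subject
  energy scale and a "morningness" tilt that moves energy between morning
  and evening slots. All multiplicative factors are mean-corrected
  (including the cross-covariance of factors that share the latent trait)
  so marginal occasion means are exact.
- **Latent traditionalism T ~ N(0,1)** couples the joint pattern: higher T
  shifts lunch earlier (25 min/SD), tilts energy toward the morning, lowers
  total energy, and raises age (Gaussian copula, ρ = 0.45). This is the
  simplest structure that reproduces the observed correlated group
  differences (earlier, larger lunch; higher diet quality; older age)
  without asserting a causal model.
- **Diet-quality components.** After the days are drawn, the subject's
  realized percent of energy before 16:00 (`p`) is computed, and each of
  the five DQS components is drawn with a *linear conditional mean* and
  multiplicative lognormal noise:

      x = (mean + c (p - 60) + g (female - 0.54)) * exp(s·eps - s²/2)

  so `E[x | p, gender]` is exactly linear with level slope `c` and the
  marginal mean is exact; the noise scale `s` solves for the configured
  marginal SD given Var(p). By Stein's identity the implied slope of the
  diet-quality z-score on `p` is `sum_i s_i c_i / SD_i`; the defaults size
  the fruit+veg coupling as `gap_target / 29.5` (96 g/day early-vs-late
  gap over the expected early/late split difference of 29.5 percentage
  points, a constant measured once from the generator at design time) and
  solve the sodium coupling residually so the implied z-slope equals the
  configured 0.03 per percentage point exactly. Children use the same
  machinery with child marginals and no couplings (they are not scored).
- **Nutrient bookkeeping.** Macronutrient grams are derived from drawn
  percent-of-energy shares (carbohydrate takes the remainder), so Atwater
  arithmetic reconstructs energy exactly and the four shares sum to 100;
  fiber follows the drawn density times day energy; day-level amounts are
  weighted by day energy so two-day-averaged metrics equal the drawn
  subject targets exactly; occasion amounts are allocated proportional to
  occasion energy. BMI is lognormal (adults mean 25.2, SD 4.1) with a
  Gaussian-copula correlation of 0.418 to age (Spearman ≈ 0.40);
  anthropometry is missing for ~2% of subjects.

`recovery_report` reruns the full pipeline (generate → intake → timing →
z-scores → adjusted OLS, optionally the meal mixed model) over replicates
and summarizes recovered slope, early-vs-late fruit+veg gap and meal means
against the generating values with Monte-Carlo SEs.

### What the generator does and does not emulate

It reproduces marginal means/SDs of the key intake metrics, the meal-time
structure, the lunch-gap distribution's center, and the coupling between
early eating and diet quality. It does **not** emulate: correlations among
diet-quality components beyond their common coupling to timing (real
fruit/veg and fiber intakes are more strongly correlated, so the synthetic
DQS distribution has thinner 4–5 tails than a real survey); seasonality,
region, weekday/weekend structure; measurement error or under-reporting;
heavy-tailed lunch-time irregularity (the day-to-day lunch gap is
near-normal, so ~96% of synthetic subjects keep lunch within an hour versus
~84% in field data). Passing pipeline tests on synthetic data therefore
demonstrates correctness of the computations and recoverability of effects
of realistic size — not that any particular real population matches the
defaults.

## Numerical choices

- Times are integer minutes in [0, 1439]; no post-midnight wrap (the
  occasion vocabulary ends at the after-dinner snack).
- Age categories are half-open `[lo, hi+1)` on integer-year labels; adult
  tertile boundaries are configurable.
- Percentage cells round half away from zero using exact integer
  arithmetic (`(200n + d) // 2d`), matching every checkable printed survey
  cell (18.65 → 19, 12.5 → 13).
- Extreme share draws are kept physical: carbohydrate share floors at 5%,
  sugar/satfat are capped just below their parent macronutrient share, and
  coupled component means floor at 5% of the marginal mean.
- Mean (SD) report cells use survey precision: integers for kcal and
  percent-of-energy, one decimal for fiber density, two for sodium and
  energy density.

## Problem sizes

The test suite exercises the pipeline at the default survey size (334
subjects), uses 10,000-subject cohorts for law-of-large-numbers checks,
1000 replicates for null-calibration (type-I error) checks, and 200
replicates of the 260-adult cohort for parameter recovery; these sizes give
Monte-Carlo SEs comfortably below the effect sizes being verified.

## Known limitations

- The FDR family for each report table is simply "all rows of that table";
  real analyses may group tests differently, and families are caller-defined
  in `benjamini_hochberg`.
- The mixed-model p-values use Wald z contrasts; no Kenward–Roger or
  Satterthwaite correction.
- Sodium is scored in grams/day against a 2.3 g limit; data in mg must be
  converted upstream.
- The generator's couplings are calibrated for the default cutoff (16:00)
  and early-eater threshold (60%); moving those thresholds changes the
  realized early/late split and hence the gap implied by a given coupling.
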