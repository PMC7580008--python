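# chronodiet

Diet-quality scoring and meal-timing analysis for two-day 24-h dietary
recall surveys.

Nutrition surveys built on repeated 24-h recalls record, for each subject,
a day's worth of timed eating occasions (up to eight labelled slots from a
pre-breakfast bite to an after-dinner snack), each resolved to energy and
nutrients by food-composition software. `chronodiet` is for epidemiologists
and nutrition researchers who want to go from those records to the standard
chrononutrition deliverables: per-subject intake summaries, meal-timing
metrics, a diet-quality index, and the group comparisons that relate the
two — plus a synthetic-cohort generator so the whole pipeline can be
developed, tested and power-checked without access to survey microdata.

## The score and the timing metrics

The **Diet Quality Score (DQS)** counts how many of five EU Science Hub
recommendations a subject meets (0–5):

| component | recommendation | direction |
|---|---|---|
| fruit + vegetables | ≥ 400 g/day | inclusive |
| fiber | ≥ 14 g/1000 kcal | inclusive |
| sugar | < 10% of energy | strict |
| saturated fat | < 10% of energy | strict |
| sodium | < 2.3 g/day | strict |

Its continuous companion, the **Diet Quality z-Score**, standardizes each
component against the analysis cohort and sums with signs reflecting the
healthy direction:

```
z_ij = s_i (x_ij − r_i) / SD_i,   z_j = Σ_i z_ij
```

with `s_i = +1` for fruit/veg and fiber, `−1` for sugar, saturated fat and
sodium; `r_i` the recommended value and `SD_i` the cohort sample SD.

Meal-timing metrics are defined on occasion *start* times: the percent of
energy consumed before a cutoff (default 16:00, pooled over both recall
days), the early-eater flag (≥ 60% before the cutoff), eating after 20:00
(any occasion starting strictly later, either day), the largest meal of
each day (highest energy, ties to the earliest), and the between-day
consistency of lunch. Group contrasts use t-tests / chi-square with
Benjamini–Hochberg FDR, OLS trends adjusted for age and gender, ANOVA +
Tukey HSD across DQS categories, and a subject-random-intercept mixed model
for per-meal energy.

## Worked example

Simulate a survey-sized cohort (74 children, 260 adults, two recall days
each) and run the full analysis:

```python
from chronodiet import SyntheticConfig, generate_cohort, run_pipeline

ds = generate_cohort(SyntheticConfig(), seed=42)
res = run_pipeline(ds)
st = res.statistics

print(st["n_early"], st["n_late"])              # 157 103
print(round(st["mean_lunch_time_min"] / 60, 2))  # 15.22  (~15:13)
print({m: round(v) for m, v in st["meal_marginal_means"].items()})
# {'breakfast': 525, 'dinner': 559, 'lunch': 761}
print(round(st["zscore_slope_adjusted"], 4), round(st["zscore_slope_se"], 4))
# 0.0273 0.0081
```

Reading the output: 157 of 260 adults are "early eaters" (≥ 60% of energy
before 16:00); lunch, eaten mid-afternoon, is clearly the largest meal
(mixed-model marginal mean 761 kcal vs 525/559 for breakfast/dinner,
pairwise p < 1e-20); and each additional percentage point of energy eaten
before 16:00 predicts a 0.027 ± 0.008 increase in the diet-quality z-score
after adjusting for age and gender — the early-eating/diet-quality coupling
the generator plants (slope 0.03) and the pipeline recovers.

The same steps are available from a shell:

```
chronodiet simulate --seed 42 --out-recalls recalls.csv --out-subjects subjects.csv
chronodiet validate recalls.csv subjects.csv
chronodiet report recalls.csv subjects.csv --outdir report/
```

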