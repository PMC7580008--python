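# Input file schemas

`chronodiet` reads two delimited text (CSV) files: a **recall table** with
one row per (subject, day, eating occasion) and a **subject table** with one
row per subject.

## Recall table

| column | required | type / units | notes |
|---|---|---|---|
| `subject_id` | yes | string | must match a row in the subject table |
| `day` | yes | integer, 1 or 2 | recall day index |
| `label` | yes | enumerated | one of `pre_breakfast`, `breakfast`, `morning_snack`, `lunch`, `afternoon_snack_1`, `afternoon_snack_2`, `dinner`, `after_dinner_snack`; unique within a subject-day |
| `time` | yes | `"HH:MM"` or integer minutes | start of the eating occasion, 00:00–23:59 |
| `energy` | yes | kcal | occasion energy as resolved by the food-composition step |
| `carbohydrate` | yes | g | |
| `protein` | yes | g | |
| `fat` | yes | g | |
| `saturated_fat` | yes | g | |
| `sugar` | yes | g | total sugar |
| `fiber` | yes | g | dietary fiber |
| `sodium` | yes | g | note: grams, not mg |
| `fruit` | yes | g | |
| `vegetables` | yes | g | |
| `water` | yes | ml | drinking water |
| `food_mass` | yes | g | mass of foods excluding drinking water and beverages (energy-density denominator) |
| `alcohol` | yes | g | |

All quantities must be non-negative. A subject-day must contain 1–8
occasions. A column-name mapping can be supplied programmatically via the
`schema` argument of `read_recall_table`.

## Subject table

| column | required | type / units | notes |
|---|---|---|---|
| `subject_id` | yes | string | |
| `age` | yes | years, 10–74 | fractional ages accepted |
| `gender` | yes | `female` / `male` | |
| `weight` | no | kg | missing anthropometry is allowed; BMI-dependent outputs exclude the subject |
| `height` | no | cm | |
| `bmi_measured` | no | boolean | measured vs self-reported anthropometry |
| `employed_outside_home` | no | boolean | |
| `smoker` | no | boolean | |
| `region` | no | string | descriptive only |
| `urban` | no | boolean | descriptive only |
| `activity_hours_per_week` | no | hours | carried as an opaque attribute |

Boolean columns accept `1/0`, `true/false`, `yes/no`.
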