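# mealcount

Precise estimates of how much a hospitalized patient actually ate are hard
to obtain: the traditional calorie count has a dietitian hand-list every
item on a tray, look each one up in a nutrient database, and rescale for
portion and plate waste. `mealcount` implements the bookkeeping and the
statistics for a multi-component alternative in which a trained employee
works from a pre-generated per-tray checklist (the Nutritional Intake
Assessment Form, NIAF), records the percentage of each item consumed on an
integer 0–100 scale, and lets the software do the nutrient arithmetic —
plus photo-based quality control and the full evaluation machinery needed
to show such a system is accurate, reliable and fast.

The package is aimed at clinical-nutrition researchers and biostatisticians
who need either the accounting engine (menu cycle → NIAF → percent consumed
→ served/consumed nutrient totals) or the method-evaluation statistics:

* **Bland–Altman agreement** between rater and weighed-food energy
  estimates, with limits of agreement defined as the mean difference
  ± 2 SD of the paired differences `d_i = estimate_i − reference_i`.
* **Accuracy mixed model** `estimate = α + β·truth + u_tray + ε`, with a
  random tray intercept for the clustering of raters within tray and Wald
  tests of α = 0 and β = 1 (likelihood-ratio alternative behind a flag).
* **Inter-rater reliability** as the intraclass correlation
  `ICC = σ²_tray / (σ²_tray + σ²_resid)` from a REML mixed model with
  day/meal fixed covariates; works for complete and incomplete
  rater-by-tray designs; CI by seeded parametric bootstrap.
* **Time efficiency**: a REML mixed model on log total task time with fixed
  method/day/session/meal effects and a random rater intercept;
  `100 × exp(β_MCM − β_TM)` estimates the percent of traditional-method
  time the new method requires (a ratio of median times). Contrast
  inference uses Satterthwaite degrees of freedom.

A simulator reproduces the evaluation study designs (complete 3 × 30
laboratory grid, incomplete 6-rater ward design, 4 × 3 × 2 alternating
time-comparison grid), so every statistic is testable without external
data. The 24-row timing table of the time-comparison exercise is bundled
verbatim, including its internally inconsistent printed method labels;
`resolve_method_labels` repairs them against the stated design as an
explicit, logged step.

## Worked example

Generate a breakfast NIAF from the bundled demo menu, record bedside
percent-consumed estimates, and print the calorie-count report:

```python
from mealcount import (load_demo_food_db, load_demo_menu_cycle,
                       generate_niaf, record_consumption, meal_report)

db, cycle = load_demo_food_db(), load_demo_menu_cycle()
form = generate_niaf(db, cycle, "regular1800", 1, "breakfast",
                     tray_id="tray-12", patient_id="patient-7")
form = record_consumption(form, {"oatmeal": 75, "scrambled_eggs": 100,
                                 "toast_wheat": 50, "orange_juice": 100,
                                 "coffee": 100})
print(meal_report(form, db).text_table())
```

```
nutrient                    served    consumed
energy_kcal                  677.0       512.0
protein_g                     25.0        20.5
fat_sat_g                      7.1         6.0
fat_unsat_g                   13.2        10.2
carb_g                        89.0        62.5
vitamin_c_mg                  48.0        48.0
calcium_mg                   256.0       196.0
```

The patient was served 677 kcal and consumed 512 kcal (the oatmeal at 75%,
half the toast, everything else finished). Totals are exact rational sums
of per-line contributions, so linearity and consumed ≤ served hold exactly.

The headline efficiency analysis, from the shell:

```sh
mealcount evaluate efficiency --fixture table2 --correct-labels
```

reports `ratio_pct: 32.65` with 95% CI 30.91–34.50: a calorie count with
the multi-component method takes about a third of the traditional-method
time — a time saving of 67%. The same run lists the five method labels that
had to be flipped to satisfy the half-and-half, alternating assignment
design.

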