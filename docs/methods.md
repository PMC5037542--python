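# Methods

## The accounting model

A calorie count is a linear accounting identity. Each NIAF line carries an
item with a per-serving nutrient profile `p` (energy in kcal; protein,
fats, carbohydrate in g; micronutrients as a named map), a serving count
`s > 0`, and a recorded percent consumed `c ∈ {0, 1, …, 100}`. The
consumed amount of every nutrient on that line is `p · s · c/100`; served
amounts set `c = 100`. Meal totals are sums over lines, day totals sums
over meals. All totals are accumulated as exact rationals
(`fractions.Fraction`), so additivity, linearity in `s` and `c`, and
`consumed ≤ served` hold bit-exactly rather than to float tolerance;
reports render to one decimal.

Percent consumed is stored as an integer 0–100. Fractional inputs are
rejected rather than rounded: the form is an auditable clinical record, and
silent rounding would hide data-entry errors of exactly the kind the photo
review is meant to catch. Outside (non-institutional) foods must carry a
complete nutrient profile when first entered and are persisted into the
food database for reuse. Lines added mid-meal count as served — they
reached the patient. Photo references are opaque paths; no image handling.

The weighed-food reference path uses
`pct = (original − leftover)/original × 100`, computed as an exact
rational. Nutrient densities are per serving as served; weighed work
additionally requires `serving_weight_g` in the food database so energy
has a gram basis. The menu cycle is keyed by integer cycle day; mapping
calendar dates to cycle days is site configuration (cycle length is a
hospital choice, not a property of the method).

## Quality-control rules

Photo review compares a second rater's percent estimates against the
bedside entries. An item is flagged when the absolute difference is
*strictly greater than* the item threshold (default 15 percentage points);
retraining is indicated when the flag rate *reaches* the rate threshold
(default 5%, inclusive). The two readings are deliberately asymmetric —
"greater than" vs "reaches" — and both thresholds are parameters.
Disagreements default to the direct-observation value unless the review
exposes an obvious error (typo or omission). Error rates are computed
per reviewer set; pooling across raters is the caller's choice of input.

The trainee proficiency criterion ("estimates generally within 15% of
weighed values") is vague in the "generally"; it is operationalized as a
quantile parameter with conservative default 1.0 (every tray must be
within tolerance), configurable downward. Trays with a zero weighed value
have no defined relative error and are excluded with a warning.

## Statistical models

All four analyses reduce to one family: the random-intercept linear mixed
model `y = Xβ + Zb + ε`, `b ~ N(0, σ²_g I)`, `ε ~ N(0, σ²_e I)`, fitted by
REML in `mealcount.varcomp`. The REML criterion is profiled down to the
variance ratio λ = σ²_g/σ²_e and minimized in one dimension (bounded
search on log λ to tolerance 1e−12), which makes fits deterministic and
lets the balanced one-way case agree with the closed-form ANOVA
method-of-moments estimator to better than 1e−6. Negative variance
estimates are truncated at zero; at that boundary the model collapses to
OLS and residual degrees of freedom are used. REML rather than ML
throughout, since the fixed-effect designs are small relative to n and ML
variance components would be noticeably biased low; ML is used only inside
the optional likelihood-ratio tests, where REML likelihoods would not be
comparable across fixed-effect structures.

Fixed-effect contrasts use t statistics with Satterthwaite degrees of
freedom: `df = 2f²/(gᵀAg)` where `f(θ) = Var(cᵀβ̂)` as a function of
θ = (σ²_g, σ²_e), g its finite-difference gradient, and A the inverse of
the numerically differentiated REML information. df is clipped to
[1, n − p]. On unbalanced test data this reproduces an independent
Satterthwaite implementation to ~4 significant figures.

**Bland–Altman.** Differences are estimate − reference; SD uses the n−1
denominator; the CI of the mean difference uses the t distribution; limits
of agreement are the literal mean ± 2·SD (not 1.96·SD — the evaluation
convention this package follows states the multiple as 2). Pearson
correlation of differences against pair means (scipy) checks whether
agreement depends on meal size. Clustering of raters within trays is
ignored by design in this analysis.

**Accuracy.** `estimate ~ 1 + truth` with a random tray intercept; Wald
tests of intercept 0 and slope 1 with Satterthwaite df. With perfectly
accurate raters the fit degenerates (zero residual variance); the
degenerate case reports p = 1 for true nulls rather than failing.

**ICC.** `estimate ~ day + meal` (treatment-coded, configurable) with a
random tray intercept; `ICC = σ²_tray/(σ²_tray + σ²_resid)`. The identical
code path serves complete and incomplete rater-by-tray designs, since the
likelihood never requires the incidence to be full. The CI is a seeded
parametric bootstrap (default 1000 replicates): simulate from the fitted
Gaussian model, refit, take percentile quantiles. A bootstrap was chosen
because the closed-form CI depends on design balance and the original
analysis software's interval method is not documented; the bootstrap is
exactly reproducible given its seed and is configurable (`n_boot`, `seed`,
or `ci_method=None`).

**Time efficiency.** `log(total time) ~ method + day + session + meal`
with a random rater intercept and no interactions. Because the outcome is
logged, `100·exp(β_MCM − β_TM)` is the percent of traditional-method time
required — a median (geometric-mean) ratio, invariant to rescaling all
times and exactly equal to the raw geometric-mean ratio in a fully
balanced design. CI endpoints are the anti-logged Satterthwaite t limits
of the contrast.

## Method-label repair

The printed assignment matrix for the time comparison conflicts with its
own stated design: day 1 session 2 shows three of four raters on the new
method (the design says half per session), and on day 3 every rater is
shown using the same method in both sessions (the design says each rater
alternates within a day). `resolve_method_labels` enumerates, per day, all
assignments satisfying both constraints, keeps those requiring the fewest
label flips, and breaks remaining ties by minimizing the pooled
within-method variance of log total time over the whole corrected dataset.
On the bundled table this flips rater 4's day-1 session-2 label to the
traditional method and swaps all four day-3 session-1 labels (all six
day-3 candidates tie at four flips; the variance criterion selects the
orientation under which the short counts are the new-method counts). The
repair is never applied silently: it is a separate operation returning the
flip list, and analyses accept either printed or corrected records.

On the corrected data the fitted ratio is 32.65% (95% CI 30.91–34.50,
df = 17; the rater variance component is estimated at the zero boundary)
and the fitted meal effects order breakfast < lunch < dinner, computed by
the test suite and `scripts/acceptance.py` at run time.

## Simulator

The generators mirror the three evaluation designs at their actual sizes
(30 trays × 3 raters; 6 raters × 15 assessments with three raters per
tray; 4 raters × 3 days × 2 sessions). One master seed spawns named
`SeedSequence` substreams (trays, consumption, raters, timing), so adding
a downstream stage never perturbs earlier draws and identical configs give
byte-identical output.

Choices where no external value existed, with defaults:

* Tray energy ~ Normal(550, 120) kcal, truncated at 50, split over 3–8
  items by a uniform Dirichlet; serving weights uniform on 60–300 g.
  Typical institutional meals run 500–800 kcal over a handful of items.
* True percent consumed: Beta(1.2, 0.8) scaled to [0, 100] with point
  masses 0.05 at 0 and 0.15 at 100 — plates are often untouched or
  cleaned. Weighed records are built in exact rational arithmetic so the
  weighed-percent formula inverts the draw exactly.
* Rater estimates: `round(clip(true + bias + N(0, σ), 0, 100))` with
  default σ = 13 percentage points, calibrated so the SD of simulated
  (estimate − weighed) energy differences at the laboratory design size is
  ≈ 40 kcal, the scale of the reference evaluation; the 0/100 clipping
  makes simulated raters slightly conservative near full consumption,
  which is realistic but means the strategy-B generator is not exactly
  unbiased (the accuracy coverage checks therefore simulate unbiased
  raters directly at the record level).
* Task times: total time lognormal around a traditional-method median of
  1450 s, method ratio 0.327, residual log-SD 0.065 and rater log-SD 0.05
  (matching the corrected timing table), meal effects −0.10/0/+0.10 on the
  log scale; totals are split into the three recorded tasks by per-method
  proportions. Meal schedules are redrawn if the meal factor would be
  collinear with day and session.

What passing simulation tests show — and what they do not: parameter
recovery under the generator's Gaussian/lognormal assumptions demonstrates
the estimators are implemented correctly at the study's sample sizes; it
does not validate the behaviour of real raters (whose errors are
item-type- and size-dependent), real menus, or real plate-waste
distributions.

## Numerical and degenerate-input conventions

Exact rational arithmetic in the engine; REML optimizer tolerance 1e−12 on
log λ with an explicit boundary comparison at λ → 0; finite-difference
steps of 1e−4·θ (Hessian) and 1e−5·θ (gradient) for Satterthwaite;
singular fixed-effect designs raise immediately rather than pseudo-invert;
zero-variance Bland–Altman input reports an undefined correlation instead
of NaN; empty review sets, unpaired proficiency lists, single-rated trays
and one-method timing data all raise with specific messages.

## Known limitations

The label repair on day 3 rests on a variance-minimization inference, not
on documentation; both orientations are internally consistent with the
stated constraints. The ICC is the plain two-component variance ratio —
no absolute-vs-consistency distinction beyond it. The engine computes
protein, fat, carbohydrate and micronutrient totals by the same linear
rules as energy, but the evaluation machinery here quantifies agreement
for energy only; no accuracy claims attach to the other nutrients.
Condiment packets and similar part-use items are treated as ordinary
lines. The CLI covers the common workflows; bulk/batch orchestration is
left to scripts against the library API.
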