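# Methods

## Scope and data model

The pipeline analyses *group-level annual aggregates* of household food
purchases, the form in which household-budget-survey results are published:
per-person quantities per calendar year and food group (kg/person/year;
eggs in units/person/year). It does not model expenditure in currency,
prices, within-year seasonality, or person-level intake. All tabular
artifacts are plain CSV (UTF-8, `.` decimal, one header row) with closed
schemas: consumption `year,item,quantity,unit`, emission factors
`food,gco2e_per_g`, basket mappings `item,food,weight`, footprints
`year,group,gco2e_per_day`. Units are a closed enumeration; unknown units
are errors, never guesses.

The food-group taxonomy has 14 groups and three reporting super-groups that
partition them exactly: RM_FS_D_F (red meat, fish, seafood, dairy, fats),
Pou_Eggs (poultry, eggs) and Others (vegetables, fruits, legumes, potatoes,
grains, sugar, alcohol). The partition is validated at construction.

## Unit conversions and basket disaggregation

A 365-day year is used everywhere (single constant; leap days ignored) —
the simplest convention consistent with published per-day figures, and
configurable where it matters. Eggs convert at a configurable 60 g/unit;
alcohol volume at a configurable 1.0 g/mL density. Items bundling several
foods are split by per-item component weights (non-negative, summing to 1
within 1e-9); within-basket proportions default to equal weights when a
national consumption breakdown is not supplied. Disaggregation is linear
and conserves total mass exactly; both properties are tested, the latter
property-based on random baskets.

## Footprint accounting

Per food: emission = daily intake (g/person/day) × life-cycle coefficient
(g CO₂-eq per g). Emission factors operate at food level and are a
*configurable input*: published per-group intensities implied by
consumption and emission tables drift over time as the composition of each
group shifts, so the engine never hard-codes a constant per-group factor.
Group, super-group and global values are sums; percent changes
100·(end−start)/start are computed on unrounded values and displayed at one
decimal. When a published per-group emission table is supplied directly,
super-group and global rows are always recomputed from the group rows.

The packaged Spanish 2006–2023 reference tables are transcribed at the
published one-decimal precision. Their internal additivity holds to 0.1
in 17 of 18 years; the 2011 column sums to 3731.2 against a published
global of 3731.4 (a 0.2 rounding artifact of the printed cells), and the
published "Fats" consumption row (10.8→7.8 kg/year) disagrees with the
narrative figure (16.8→13.3) in its source; both discrepancies are encoded
as published and documented rather than resolved.

## Dietary Score (0–55)

Eleven components: six favourable (vegetables, potatoes, legumes, fruit,
whole grains, fish) banded 0/1–4/5–8/9–12/13–18/>18 servings per month →
0–5 points; three unfavourable (red meat, poultry, whole-fat dairy) on the
reversed banding; olive-oil use by frequency category (never → 0 … daily
→ 5); alcohol by mL/day (<300 → 5 … ≥700 → 0, using half-open hundreds
bands so every value maps to exactly one band). Servings/month = g/day ×
(365/12) ÷ serving size.

Design choices where the rubric is silent:

* **Fractional servings.** The integer band labels leave (0,1) and
  boundaries ambiguous. Policy: exactly 0 scores the zero band; otherwise
  the band of ⌈servings⌉. Tested exhaustively at the boundaries.
* **Serving sizes** (g): defaults vegetables 150, potatoes 150, legumes 60,
  fruit 120, grains 60, fish 125, red meat 125, poultry 125, dairy 200 —
  declared assumptions, all configurable. Under these defaults the Spanish
  series scores ≈38–41.
* **Reference calibration.** `SPAIN_REFERENCE_CONFIG` (legumes 70, fish
  170, poultry 80, whole-grain fraction 0.15, others default) was derived
  once by desk arithmetic on the published consumption levels so that
  annual totals track the published 34–35 range; it lands every year at
  35–36 (within ±1). The whole-grain fraction treats 15% of the
  bread-and-cereals group as whole grain, since the survey group does not
  separate them. `serving_size_sensitivity` reports totals under joint
  ±20% serving-size scaling (range 34–39), showing the "stable mid-30s
  adherence" reading is robust to the assumption while exact totals are not
  identifiable from purchase data alone.
* **Olive-oil frequency** is derived from fats-group purchases:
  > 0.25 L/person/month → "daily", anything positive → "1–3 per week",
  else "never" (thresholds configurable).
* **Tertiles** use fixed thirds of the 0–55 range (≤18 low, 19–36 medium,
  ≥37 high): a single national series provides no population distribution
  for empirical tertiles.

## Joinpoint regression

Model: ln y_t = β₀ + β₁(t−t₀) + Σ_j δ_j(t−τ_j)₊ + ε, ε homoscedastic
normal on the log scale, no autocorrelation correction. Segment slopes are
cumulative sums β₁+δ₁+…+δ_j; APC_j = 100(e^{β_j}−1); slope standard errors
come from the hinge-design covariance via contrast vectors, with t-based
two-sided p-values on n−(2+k) degrees of freedom.

* **Placement grid.** Joinpoints are restricted to observed interior years
  with ≥ `min_segment` (default 2) observations strictly between
  consecutive boundaries, series ends included. This keeps the grid exact
  at the data's resolution; grid search is exhaustive, minimum SSE, ties
  to the lexicographically earliest placement. Equivalence with an
  independent hat-basis enumeration oracle is tested for every series used
  in tests.
* **Selection.** Sequential permutation tests of k vs k+1 joinpoints:
  statistic (SSE_k−SSE_{k+1})/SSE_{k+1} with each SSE minimised over its
  grid; null draws permute the residuals of the k-joinpoint fit around its
  fitted values and re-run both grid searches (vectorised over
  permutations via cached QR factors); p = (1+#{T*≥T})/(n_perm+1),
  compared against α/k_max (Bonferroni across the at-most-k_max tests). A
  seed is mandatory; identical seeds reproduce selections exactly. BIC
  selection (n·ln(SSE/n) + (2k+2)·ln n, one coefficient plus one location
  per joinpoint) is available as a cheaper alternative.
* **Calibration** (tested on 100 simulated 18-year series each, n_perm =
  999, α = 0.05): on pure log-linear series with σ = 0.01 the procedure
  keeps 0 joinpoints in ≈98% of replicates; with a 0.06 slope change and
  σ = 0.005 it detects ≥1 joinpoint in ≈100%.
* On the Spanish global series the selection chooses 2 joinpoints at
  {2014, 2017}; the fixed-{2014, 2017} fit gives APCs −1.42 / −4.40 /
  +0.61 %/yr, the first two significant at 5%. A ±0.3 percentage-point
  tolerance is used when comparing against published APCs because the
  original analysis ran external software whose variance-model and grid
  options are not published.

## Synthetic survey generator

Emulates the published design scale — households keeping 14-day diaries
(defaults: configurable household size 2.5 persons, n configurable;
the real survey samples ≈24,000 dwellings/year) — with group-level mean
trends that are piecewise log-linear by construction: base level
(g/person/day) at the first year and one APC per segment. Household noise
is multiplicative lognormal parameterised mean-1 (σ² = ln(1+CV²), μ =
−σ²/2), so aggregates are unbiased for the trend trajectory; purchase
quantities are positive and right-skewed, which a normal model would not
respect. Aggregation is person-weighted: per-group kg/person/year = (Σ
fortnight kg ÷ Σ persons) × 365/14 — the within-year weighting actual
statistical offices apply is not published, so the 365/14 scaling is this
module's own convention. An optional regime switch reassigns a fraction of
a source group's purchases to a target group from a stated year onward
(persistently), conserving mass — the shape of the discontinuity a
classification revision (e.g. the 2016 COICOP→ECOICOP change visible in
the grains series) introduces.

What the generator does *not* emulate: seasonality and diary placement
within the year, household-size heterogeneity, price/income effects,
item-level heterogeneity within groups, and non-sampling error. Passing
recovery tests therefore show the estimators are correct under the stated
sampling model, not that real survey series satisfy that model.

## Problem sizes and numerical choices

Tests and the acceptance script run on the 18-year published series, on
synthetic surveys of 200–1000 households, and on 100-replicate calibration
batches with 999 permutations — sizes at which the permutation machinery
(vectorised SSE via QR projections) completes in seconds while leaving
Monte-Carlo margins wide relative to the 90% calibration thresholds.
Percent changes and APCs are computed on unrounded values and rounded only
for display (consumption and GHG at 1 decimal, shares at 4, APCs at 2).
Grid-search ties require a strictly smaller SSE (1e-12) to displace the
incumbent, making tie-breaks deterministic. Degenerate inputs (empty
tables, zero quantities, perfect fits with zero SSE) are handled
explicitly and tested.

## Known limitations

* Emission coefficients are inputs; the package validates internal
  consistency of published tables and pipeline correctness, not the
  coefficients themselves. With constant per-food factors, footprint
  trends are exactly consumption trends; composition change within groups
  needs food-level input data.
* The Dietary Score depends on serving-size and olive-oil assumptions that
  purchase data cannot pin down; only banded totals, not exact scores, are
  meaningful.
* The trend model assumes uncorrelated homoscedastic log-scale errors;
  autocorrelated-error and average-APC (AAPC) variants are out of scope.
* Out-of-home consumption, age/income stratification and real microdata
  parsing are outside the package's scope.
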