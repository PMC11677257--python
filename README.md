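# dietfootprint

Dietary greenhouse-gas accounting, Mediterranean-Diet adherence scoring and
joinpoint trend analysis for household food-consumption series.

National household budget surveys record food purchases (kg per person per
year, by item code) but say nothing directly about the climate impact of the
diet they describe. This package turns such series into an environmental and
nutritional time-series analysis, for epidemiologists and public-health
analysts working with survey aggregates rather than individual intake data:

1. **Footprint accounting.** Item quantities are converted to g/person/day,
   split onto emission-table foods by basket mappings (weights summing to 1),
   and multiplied by life-cycle emission coefficients *e_f* (g CO₂-eq per g
   of food): `GHG_y = Σ_f q_{f,y} · e_f`, reported per food group, per
   reporting super-group (RM_FS_D_F = red meat + fish/seafood + dairy + fats;
   Pou_Eggs; Others) and in total (g CO₂-eq/person/day).
2. **Mediterranean-Diet adherence.** The 11-component Dietary Score (0–55):
   monthly servings of vegetables, potatoes, legumes, fruit, whole grains and
   fish score 0–5 increasing; red meat, poultry and whole-fat dairy score
   5–0; olive-oil use scores by frequency and alcohol by mL/day. Serving
   sizes are explicit configuration, since purchase surveys record mass.
3. **Joinpoint trends.** For a positive annual series *y_t*, `ln y_t` is
   modelled as a continuous piecewise-linear function of year with kinks at
   joinpoints τ₁ < … < τ_k; each segment slope β is reported as an annual
   percent change, APC = 100·(e^β − 1). Joinpoint locations are found by
   exhaustive grid search and the number of joinpoints is chosen by seeded
   permutation tests (Bonferroni-adjusted across the sequence), with BIC as
   an alternative.
4. **Synthetic surveys.** A generator simulates households keeping 14-day
   diaries under known piecewise log-linear group trends with lognormal
   household noise and optional classification-regime switches, so every
   stage — including trend parameter recovery — is testable without survey
   microdata.

The package ships the published Spanish 2006–2023 series (per-group
consumption and dietary GHG emissions) as reference data and reproduces the
published headline results from them.

## Worked example

```python
from dietfootprint import (
    AnnualSeries, fit_fixed_joinpoints, load_spain_footprint,
    percent_change, total_footprint,
)

totals = total_footprint(load_spain_footprint(include_global=False))
print(percent_change(totals, "global", 2006, 2023).percent_change)

block = totals[totals["group"] == "global"].sort_values("year")
series = AnnualSeries(block["year"].to_numpy(), block["gco2e_per_day"].to_numpy())
fit = fit_fixed_joinpoints(series, [2014, 2017])
for (a, b), apc, p in zip(fit.segments, fit.apcs, fit.slope_p):
    print(f"{a}-{b}: APC {apc:+.2f}%/yr (p={p:.4f})")
```

prints

```
-17.51316457505845
2006-2014: APC -1.42%/yr (p=0.0000)
2014-2017: APC -4.40%/yr (p=0.0000)
2017-2023: APC +0.61%/yr (p=0.0607)
```

i.e. the Spanish dietary footprint fell 17.5% over 2006–2023, declining
1.4%/yr to 2014 and 4.4%/yr to 2017 (both significant at 5%), then drifting
up 0.6%/yr (not significant). `examples/` contains one short script per
capability (footprint accounting, diet scoring, trend fitting, synthetic
parameter recovery, the one-config pipeline); each prints the numbers it
computes and what they mean. A thin CLI wraps the same stages:
`dietfootprint run --config config.yaml` (also `simulate`, `footprint`,
`score`, `trends`).

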