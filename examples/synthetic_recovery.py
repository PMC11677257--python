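"""Parameter recovery on a synthetic household budget survey.

Simulates 1000 households keeping 14-day diaries under a known two-segment
trend (+2%/yr then -3%/yr, kink 2014), pushes the aggregates through the
footprint stage with a constant emission factor, and re-estimates the
segment APCs with the joinpoint model.
"""

import pandas as pd

from dietfootprint import (
    AnnualSeries,
    TrendSpec,
    aggregate_to_consumption,
    compute_footprint,
    generate_survey,
    grid_search_joinpoints,
)
from dietfootprint.units import consumption_to_daily_intake

spec = TrendSpec(
    "red_meat", base_level=120.0, segment_apcs=(2.0, -3.0),
    change_points=(2014,), noise_cv=0.05,
)
survey = generate_survey([spec], n_households=1000, years=range(2006, 2024), seed=7)
consumption = aggregate_to_consumption(survey, {"IT_red_meat": "red_meat"})

intake = consumption_to_daily_intake(consumption).rename(columns={"item": "food"})
factors = pd.DataFrame({"food": ["red_meat"], "gco2e_per_g": [18.0]})
footprint = compute_footprint(intake, factors)

block = footprint.sort_values("year")
fit = grid_search_joinpoints(
    AnnualSeries(block["year"].to_numpy(), block["gco2e_per_day"].to_numpy()), k=1
)
print(f"true change point: 2014   estimated: {fit.joinpoints[0]}")
print(f"true APCs: (+2.00, -3.00)  estimated: "
      f"({fit.apcs[0]:+.2f}, {fit.apcs[1]:+.2f})")
print(
    "\nWith 1000 diaries/year and 5% household noise the generating trend is\n"
    "recovered to within a fraction of a percentage point per segment."
)
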