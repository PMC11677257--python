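"""Built-in reference series: Spanish household diet, 2006–2023.

Two small published series ship with the package, transcribed from a
national Household Budget Survey analysis of Spanish food consumption:

* ``load_spain_consumption`` — annual per-person consumption by food group
  (kg/person/year; eggs in units/person/year), 13 groups × 18 years;
* ``load_spain_footprint`` — the corresponding dietary greenhouse-gas
  emissions (g CO₂-eq/person/day) per group plus the published global total.

They serve as regression fixtures and as ready-made inputs for the worked
examples.  Values are as printed at one decimal; per-year group sums can
therefore differ from the printed global row by up to 0.2 (cell rounding).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tables import validate_consumption

__all__ = ["load_spain_consumption", "load_spain_footprint"]

_CONSUMPTION = "spain_hbs_consumption_2006_2023.csv"
_FOOTPRINT = "spain_diet_ghg_2006_2023.csv"


def _read(name: str) -> pd.DataFrame:
    with resources.files("dietfootprint.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_spain_consumption() -> pd.DataFrame:
    """Per-person annual consumption by food group, Spain 2006–2023.

    Returns a validated consumption table (``year,item,quantity,unit``)
    with 234 rows: 13 food groups over 18 years.  Eggs are recorded in
    units/person/year, everything else in kg/person/year.
    """
    return validate_consumption(_read(_CONSUMPTION))


def load_spain_footprint(include_global: bool = True) -> pd.DataFrame:
    """Dietary GHG emissions by food group, Spain 2006–2023.

    Returns a footprint table (``year,group,gco2e_per_day``).  When
    ``include_global`` is False the published global-total rows are
    dropped, leaving only the 13 per-group series.
    """
    df = _read(_FOOTPRINT)
    if not include_global:
        df = df[df["group"] != "global"].reset_index(drop=True)
    return df
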