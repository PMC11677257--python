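"""Unit conversions and basket disaggregation.

Survey quantities arrive as kg/person/year (eggs as units/person/year) and
the footprint and diet-score computations want g/person/day (alcohol also
as mL/day).  The conversions here use a 365-day year throughout — a single
constant, ``DAYS_PER_YEAR`` — and leave leap days out.

Survey items that bundle several foods (a "citrus fruits" item, a processed
meat item that is half beef and half pork) are split onto emission-table
foods by a basket mapping: per item, a list of (food, weight) components
with non-negative weights summing to one.  Disaggregation conserves mass
exactly and is linear in the input quantities.
"""

from __future__ import annotations

import numbers

import pandas as pd

from .errors import ConfigurationError, MappingError, ValidationError
from .tables import validate_mapping

__all__ = [
    "DAYS_PER_YEAR",
    "DEFAULT_EGG_MASS_G",
    "DEFAULT_ALCOHOL_DENSITY",
    "kg_year_to_g_day",
    "eggs_units_to_g_day",
    "alcohol_to_ml_day",
    "consumption_to_daily_intake",
    "disaggregate",
]

DAYS_PER_YEAR = 365.0
#: Mass of one egg, g/unit.  The survey registers eggs in units/year.
DEFAULT_EGG_MASS_G = 60.0
#: Density used to turn alcohol mass into volume, g/mL.
DEFAULT_ALCOHOL_DENSITY = 1.0


def _check_nonneg(value: float, what: str) -> None:
    if isinstance(value, numbers.Real) and value < 0:
        raise ValidationError(f"{what} must be non-negative, got {value}")


def kg_year_to_g_day(quantity: float, days_per_year: float = DAYS_PER_YEAR) -> float:
    """Convert kg/person/year to g/person/day: ×1000 ÷ days."""
    _check_nonneg(quantity, "quantity (kg/person/year)")
    return quantity * 1000.0 / days_per_year


def eggs_units_to_g_day(
    units_per_year: float,
    egg_mass_g: float = DEFAULT_EGG_MASS_G,
    days_per_year: float = DAYS_PER_YEAR,
) -> float:
    """Convert egg units/person/year to g/person/day at a given egg mass."""
    if egg_mass_g <= 0:
        raise ConfigurationError(f"egg_mass_g must be positive, got {egg_mass_g}")
    _check_nonneg(units_per_year, "units_per_year")
    return units_per_year * egg_mass_g / days_per_year


def alcohol_to_ml_day(
    quantity_kg_year: float,
    density_g_ml: float = DEFAULT_ALCOHOL_DENSITY,
    days_per_year: float = DAYS_PER_YEAR,
) -> float:
    """Convert alcoholic-beverage kg/person/year to mL/person/day."""
    if density_g_ml <= 0:
        raise ConfigurationError(f"density_g_ml must be positive, got {density_g_ml}")
    _check_nonneg(quantity_kg_year, "quantity (kg/person/year)")
    return quantity_kg_year * 1000.0 / days_per_year / density_g_ml


def consumption_to_daily_intake(
    consumption: pd.DataFrame,
    egg_mass_g: float = DEFAULT_EGG_MASS_G,
    days_per_year: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Convert a validated consumption table to g/person/day per (year, item).

    Rows already in g/person/day pass through; mL/person/day rows are
    treated as grams at unit density (the table records beverages by
    volume only when mass and volume are interchangeable).

    Returns a ``year,item,grams_per_person_day`` table.
    """
    grams = pd.Series(index=consumption.index, dtype=float)
    unit = consumption["unit"]
    q = consumption["quantity"].astype(float)
    grams[unit == "kg/person/year"] = q * 1000.0 / days_per_year
    grams[unit == "units/person/year"] = eggs_units_to_g_day(1.0, egg_mass_g, days_per_year) * q
    grams[unit == "g/person/day"] = q
    grams[unit == "mL/person/day"] = q
    out = consumption[["year", "item"]].copy()
    out["grams_per_person_day"] = grams
    return out


def disaggregate(intake: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Split item-level daily intake onto emission-table foods.

    ``intake`` has columns ``year,item,grams_per_person_day``; ``mapping``
    has ``item,food,weight`` with weights summing to 1 per item.  Output
    has columns ``year,food,grams_per_person_day``; total grams per year
    are conserved exactly.
    """
    mapping = validate_mapping(mapping)
    unmapped = sorted(set(intake["item"]) - set(mapping["item"]))
    if unmapped:
        raise MappingError(f"no basket mapping for item(s): {unmapped}")
    merged = intake.merge(mapping, on="item", how="left")
    merged["grams_per_person_day"] = (
        merged["grams_per_person_day"] * merged["weight"]
    )
    out = (
        merged.groupby(["year", "food"], as_index=False)["grams_per_person_day"]
        .sum()
        .sort_values(["year", "food"])
        .reset_index(drop=True)
    )
    return out
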