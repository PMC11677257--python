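import numpy as np
import pandas as pd
import pytest

from dietfootprint import (
    AnnualSeries,
    load_spain_consumption,
    load_spain_footprint,
    total_footprint,
)


@pytest.fixture(scope="session")
def spain_consumption() -> pd.DataFrame:
    return load_spain_consumption()


@pytest.fixture(scope="session")
def spain_footprint_groups() -> pd.DataFrame:
    """The 13 published per-group GHG series (no global rows)."""
    return load_spain_footprint(include_global=False)


@pytest.fixture(scope="session")
def spain_footprint_published() -> pd.DataFrame:
    """Published table including the printed global row."""
    return load_spain_footprint(include_global=True)


@pytest.fixture(scope="session")
def spain_totals(spain_footprint_groups) -> pd.DataFrame:
    """Per-group table with recomputed super-group and global rows."""
    return total_footprint(spain_footprint_groups)


@pytest.fixture(scope="session")
def global_series(spain_totals) -> AnnualSeries:
    block = spain_totals[spain_totals["group"] == "global"].sort_values("year")
    return AnnualSeries(
        block["year"].to_numpy(), block["gco2e_per_day"].to_numpy(), "global"
    )


@pytest.fixture()
def small_consumption() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [2006, 2006, 2007],
            "item": ["red_meat", "eggs", "red_meat"],
            "quantity": [39.9, 117.8, 40.8],
            "unit": ["kg/person/year", "units/person/year", "kg/person/year"],
        }
    )


def make_series(years, values, label="") -> AnnualSeries:
    return AnnualSeries(np.asarray(years), np.asarray(values), label)
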