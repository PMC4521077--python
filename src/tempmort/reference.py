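"""Published country-level descriptives of the 13-country mortality dataset.

These are the country summaries (number of locations, study period, total
deaths, mean location temperature in degC) of the multi-country registry
dataset underlying this kind of two-stage analysis.  The raw daily series are
not publicly deposited; the table is shipped so that report layouts and
dataset-level arithmetic (e.g. the grand total of deaths) can be checked.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["country_table", "total_deaths"]

_ROWS = [
    # country, locations, period, total_deaths, mean_temp
    ("Australia", 3, "1988-2009", 1_177_950, 18.1),
    ("Brazil", 18, "1997-2011", 3_401_136, 24.2),
    ("Canada", 21, "1986-2009", 2_521_586, 6.5),
    ("China", 15, "1996-2008", 950_130, 15.1),
    ("Italy", 11, "1987-2010", 820_390, 15.4),
    ("Japan", 47, "1985-2012", 26_893_197, 15.3),
    ("South Korea", 7, "1992-2010", 1_726_938, 13.7),
    ("Spain", 51, "1990-2010", 3_479_910, 15.5),
    ("Sweden", 1, "1990-2002", 190_092, 7.5),
    ("Taiwan", 3, "1994-2007", 765_893, 24.0),
    ("Thailand", 62, "1999-2008", 1_827_853, 27.6),
    ("UK", 10, "1993-2006", 7_573_716, 10.4),
    ("USA", 135, "1985-2006", 22_896_409, 14.9),
]


def country_table() -> pd.DataFrame:
    """Descriptive statistics by country (one row per country)."""
    return pd.DataFrame(
        _ROWS, columns=["country", "locations", "period", "total_deaths", "mean_temp"]
    )


def total_deaths() -> int:
    """Grand total of deaths across the 13 countries, computed from the table."""
    return int(country_table()["total_deaths"].sum())
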