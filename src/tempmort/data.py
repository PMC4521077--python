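"""Core data container for one location's daily mortality series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LocationSeries"]


@dataclass
class LocationSeries:
    """Daily dates, all-cause death counts, and mean temperature (degC) for one
    location."""

    location: str
    dates: pd.DatetimeIndex
    deaths: np.ndarray
    tmean: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.deaths = np.asarray(self.deaths)
        self.tmean = np.asarray(self.tmean, dtype=float)
        if not (len(self.dates) == self.deaths.size == self.tmean.size):
            raise ValueError(f"{self.location}: dates/deaths/tmean lengths differ")
        if not self.dates.is_monotonic_increasing:
            raise ValueError(f"{self.location}: dates are not sorted")
        if np.any(self.deaths < 0):
            bad = int(np.flatnonzero(self.deaths < 0)[0])
            raise ValueError(f"{self.location}: negative death count at row {bad}")
        if np.any(~np.isfinite(self.tmean)):
            raise ValueError(f"{self.location}: non-finite temperatures")

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates.strftime("%Y-%m-%d"), "deaths": self.deaths,
             "tmean": self.tmean}
        )
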