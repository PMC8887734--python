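"""Half-month ("fortnight") calendar utilities.

The analysis bins admissions into half-months, two per calendar month and 24
per year, so that temporal units line up exactly across years.  The boundary
convention is fixed: days 1-15 fall in the first half of a month, day 16
through month end in the second half.
"""

from __future__ import annotations

import calendar
import datetime as dt

import numpy as np
import pandas as pd

FORTNIGHTS_PER_YEAR = 24


def fortnight_of_date(date: dt.date) -> tuple[int, int]:
    """Return (year, fortnight 1-24) of a calendar date."""
    f = 2 * date.month - 1 if date.day <= 15 else 2 * date.month
    return date.year, f


def fortnight_bounds(year: int, fortnight: int) -> tuple[dt.date, dt.date]:
    """Inclusive first/last day of a (year, fortnight) bin."""
    if not 1 <= fortnight <= FORTNIGHTS_PER_YEAR:
        raise ValueError(f"fortnight must be in 1..24, got {fortnight}")
    month = (fortnight + 1) // 2
    if fortnight % 2 == 1:
        return dt.date(year, month, 1), dt.date(year, month, 15)
    last = calendar.monthrange(year, month)[1]
    return dt.date(year, month, 16), dt.date(year, month, last)


def month_of_fortnight(fortnight: int) -> int:
    return (fortnight + 1) // 2


def quarter_of_fortnight(fortnight: int) -> int:
    """Calendar quarter (0: Jan-Mar, 1: Apr-Jun, 2: Jul-Sep, 3: Oct-Dec)."""
    return (month_of_fortnight(fortnight) - 1) // 3


def fortnight_index(year: int, fortnight: int, start_year: int) -> int:
    """Absolute 0-based position of (year, fortnight) on a grid starting Jan of start_year."""
    return (year - start_year) * FORTNIGHTS_PER_YEAR + (fortnight - 1)


def fortnight_grid(start_year: int, n_fortnights: int, start_fortnight: int = 1) -> pd.MultiIndex:
    """Regular (year, fortnight) MultiIndex of given length."""
    offset = fortnight_index(start_year, start_fortnight, start_year)
    t = np.arange(offset, offset + n_fortnights)
    years = start_year + t // FORTNIGHTS_PER_YEAR
    fns = t % FORTNIGHTS_PER_YEAR + 1
    return pd.MultiIndex.from_arrays([years, fns], names=["year", "fortnight"])


class FortnightSeries:
    """A regular series on the fortnight grid (no gaps, strictly increasing).

    ``values`` may hold nonnegative integer counts or a real-valued derived
    series (e.g. a seasonally adjusted series).
    """

    def __init__(self, values, start_year: int, start_fortnight: int = 1):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FortnightSeries values must be 1-d")
        self.start_year = int(start_year)
        self.start_fortnight = int(start_fortnight)
        if not 1 <= self.start_fortnight <= FORTNIGHTS_PER_YEAR:
            raise ValueError("start_fortnight must be in 1..24")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def index(self) -> pd.MultiIndex:
        return fortnight_grid(self.start_year, len(self), self.start_fortnight)

    @property
    def fortnights(self) -> np.ndarray:
        """Fortnight-of-year (1-24) for every position."""
        return np.asarray(self.index.get_level_values("fortnight"))

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.index.get_level_values("year"))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name="value")

    def with_values(self, values) -> "FortnightSeries":
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must match length")
        return FortnightSeries(values, self.start_year, self.start_fortnight)

    def slice(self, start: int, stop: int | None = None) -> "FortnightSeries":
        """Positional slice that keeps the grid alignment."""
        stop = len(self) if stop is None else stop
        if not 0 <= start <= stop <= len(self):
            raise ValueError("slice out of bounds")
        offset = fortnight_index(self.start_year, self.start_fortnight, self.start_year) + start
        year = self.start_year + offset // FORTNIGHTS_PER_YEAR
        fn = offset % FORTNIGHTS_PER_YEAR + 1
        return FortnightSeries(self.values[start:stop], year, fn)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FortnightSeries(n={len(self)}, start={self.start_year}-f{self.start_fortnight})"
        )
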