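"""Annual time-series container and CSV I/O.

The whole package works on gap-free annual series: an epidemiological
incidence rate, a climate index, a sunshine duration, or a domain-mean of a
gridded field.  Missing values are rejected at construction / read time
rather than carried through the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InvalidParameterError


@dataclass
class AnnualSeries:
    """A gap-free annual time series with optional units metadata.

    Parameters
    ----------
    years
        Strictly consecutive integer calendar years.
    values
        Finite real values, one per year.
    units
        Free-text units label (e.g. ``"incidences/100,000"``), carried
        through windowing and I/O.
    """

    years: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or self.values.ndim != 1:
            raise InvalidParameterError("years and values must be 1-D")
        if self.years.size != self.values.size:
            raise InvalidParameterError(
                f"length mismatch: {self.years.size} years vs {self.values.size} values"
            )
        if self.years.size == 0:
            raise InvalidParameterError("series must contain at least one year")
        if self.years.size > 1 and not np.all(np.diff(self.years) == 1):
            raise InvalidParameterError("years must be strictly consecutive (gap-free)")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("series contains missing or non-finite values")

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return int(self.years.size)

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def window(self, start_year: int, end_year: int) -> "AnnualSeries":
        """Inclusive sub-series over ``[start_year, end_year]``."""
        if start_year > end_year:
            raise InvalidParameterError("start_year must be <= end_year")
        if start_year < self.start_year or end_year > self.end_year:
            raise InvalidParameterError(
                f"window [{start_year}, {end_year}] outside series span "
                f"[{self.start_year}, {self.end_year}]"
            )
        i0 = start_year - self.start_year
        i1 = end_year - self.start_year + 1
        return AnnualSeries(self.years[i0:i1].copy(), self.values[i0:i1].copy(), self.units)

    def standardized(self) -> np.ndarray:
        """Values as z-scores (population standard deviation)."""
        sd = float(np.std(self.values))
        if sd == 0.0:
            raise InvalidParameterError("cannot standardize a constant series")
        return (self.values - self.values.mean()) / sd

    def with_values(self, values: np.ndarray) -> "AnnualSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "") -> "AnnualSeries":
        """Read a ``year,value`` CSV (UTF-8, '.' decimal separator)."""
        df = pd.read_csv(path)
        cols = {c.strip().lower() for c in df.columns}
        if not {"year", "value"} <= cols:
            raise InvalidParameterError(f"{path}: expected columns 'year,value'")
        df.columns = [c.strip().lower() for c in df.columns]
        if df["value"].isna().any() or df["year"].isna().any():
            raise InvalidParameterError(f"{path}: missing values are not allowed")
        return cls(df["year"].to_numpy(), df["value"].to_numpy(), units=units)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"year": self.years, "value": self.values}).to_csv(path, index=False)


def require_same_years(a: AnnualSeries, b: AnnualSeries) -> None:
    """Raise :class:`AlignmentError` unless both series cover identical years."""
    if not np.array_equal(a.years, b.years):
        raise AlignmentError(
            f"series years differ: [{a.start_year}, {a.end_year}] vs "
            f"[{b.start_year}, {b.end_year}]"
        )
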