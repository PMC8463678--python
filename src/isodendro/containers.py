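"""Shared data containers.

Annual series are plain :class:`pandas.Series` objects indexed by integer
calendar year CE — the universal currency of the pipeline.  The classes here
wrap the structured inputs: one tree's dated isotope measurements
(:class:`TreeSeries`), a monthly climate-station table (:class:`ClimateTable`)
and an annual atmospheric δ13C record (:class:`AtmosphericRecord`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError
from .periods import Period, period_years

#: month numbers 1..12
MONTHS = tuple(range(1, 13))

#: climate variables carried by a ClimateTable
CLIMATE_VARIABLES = ("temperature", "precipitation", "ao")


def as_annual_series(obj, name: str = "value") -> pd.Series:
    """Coerce to a float Series indexed by integer year, sorted ascending."""
    s = pd.Series(obj) if not isinstance(obj, pd.Series) else obj.copy()
    s.index = s.index.astype(int)
    s = s.astype(float).sort_index()
    s.name = name
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate years in annual series: {dups[:5]}")
    return s


@dataclass(frozen=True)
class TreeSeries:
    """One tree's dated isotope measurements.

    Parameters
    ----------
    tree_id
        Opaque label.
    first_year
        Calendar year CE of the first ring in ``values``.
    values
        One measurement per consecutive year (no missing rings), in ‰.
    pith_year
        Calendar year of ring age 0, if known.  Used to compute ring age for
        juvenile trimming; when ``None`` the series start stands in for it.
    scale
        Isotope scale tag, e.g. ``"d13C_VPDB"`` or ``"d18O_VSMOW"``.
    """

    tree_id: str
    first_year: int
    values: np.ndarray
    pith_year: int | None = None
    scale: str = "d13C_VPDB"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValidationError(f"tree {self.tree_id}: values must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"tree {self.tree_id}: non-finite values")
        if self.pith_year is not None and self.pith_year > self.first_year:
            raise ValidationError(
                f"tree {self.tree_id}: pith_year {self.pith_year} after first_year {self.first_year}"
            )

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.values)

    def ring_age(self, year: int) -> int:
        """Ring age of ``year``: distance from the pith (or series start)."""
        origin = self.pith_year if self.pith_year is not None else self.first_year
        return int(year) - origin

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name=self.tree_id)


@dataclass(frozen=True)
class ClimateTable:
    """Monthly climate-station table: temperature (°C), precipitation (mm)
    and an Arctic Oscillation index, 12 values per year each.

    Each attribute is a DataFrame indexed by year with columns 1..12.
    """

    temperature: pd.DataFrame
    precipitation: pd.DataFrame
    ao: pd.DataFrame

    def __post_init__(self):
        years = None
        for name in CLIMATE_VARIABLES:
            df = getattr(self, name)
            if tuple(df.columns) != MONTHS:
                df = df.copy()
                df.columns = [int(c) for c in df.columns]
                df = df[list(MONTHS)]
                object.__setattr__(self, name, df)
            if years is None:
                years = df.index.to_numpy()
            elif not np.array_equal(df.index.to_numpy(), years):
                raise ValidationError("climate variables cover different years")
            if df.isna().any().any():
                raise ValidationError(f"{name}: missing monthly values")
        if len(years) == 0:
            raise ValidationError("climate table is empty")
        if not np.array_equal(np.diff(years), np.ones(len(years) - 1)):
            raise ValidationError("climate years must be strictly increasing and contiguous")
        if (self.precipitation.to_numpy() < 0).any():
            raise ValidationError("negative precipitation")

    @property
    def years(self) -> np.ndarray:
        return self.temperature.index.to_numpy()

    @property
    def span(self) -> Period:
        y = self.years
        return int(y[0]), int(y[-1])

    def monthly(self, variable: str) -> pd.DataFrame:
        if variable not in CLIMATE_VARIABLES:
            raise ValidationError(f"unknown climate variable {variable!r}")
        return getattr(self, variable)

    def aggregate(self, variable: str, months, stat: str = "mean") -> pd.Series:
        """Annual series aggregated over ``months`` (e.g. July = [7])."""
        months = [int(m) for m in np.atleast_1d(months)]
        if not set(months) <= set(MONTHS):
            raise ValidationError(f"months out of range: {months}")
        df = self.monthly(variable)[months]
        if stat == "mean":
            out = df.mean(axis=1)
        elif stat == "sum":
            out = df.sum(axis=1)
        else:
            raise ValidationError(f"unknown aggregate stat {stat!r}")
        out.name = f"{variable}_{'-'.join(map(str, months))}_{stat}"
        return out

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table with columns year, month, variable columns."""
        frames = []
        for name in CLIMATE_VARIABLES:
            df = self.monthly(name).stack()
            df.name = name
            frames.append(df)
        out = pd.concat(frames, axis=1).reset_index()
        out.columns = ["year", "month", *CLIMATE_VARIABLES]
        return out

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "ClimateTable":
        wide = {}
        for name in CLIMATE_VARIABLES:
            w = df.pivot(index="year", columns="month", values=name)
            w.columns = [int(c) for c in w.columns]
            w.index = w.index.astype(int)
            wide[name] = w.sort_index()
        return cls(wide["temperature"], wide["precipitation"], wide["ao"])


@dataclass(frozen=True)
class AtmosphericRecord:
    """Annual atmospheric δ13C of CO2 (‰, VPDB), e.g. from ice cores."""

    values: pd.Series = field(repr=False)

    def __post_init__(self):
        s = as_annual_series(self.values, "d13c_atm")
        object.__setattr__(self, "values", s)
        years = s.index.to_numpy()
        if len(years) > 1 and not np.array_equal(np.diff(years), np.ones(len(years) - 1)):
            raise ValidationError("atmospheric record years must be contiguous")
        if ((s < -10) | (s > -5)).any():
            raise ValidationError("atmospheric δ13C outside plausible range [-10, -5] ‰")

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def at(self, year: int) -> float:
        try:
            return float(self.values.loc[int(year)])
        except KeyError:
            raise CoverageError(f"atmospheric record does not cover year {year}") from None

    def covers(self, period: Period) -> bool:
        idx = set(self.values.index)
        return all(int(y) in idx for y in period_years(period))
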