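"""Mean isotope chronologies from per-tree series.

A chronology is the equal-weight arithmetic mean across all trees covering a
year, kept only where enough trees overlap (the replication gate).  The first
rings of each tree are excluded beforehand because the juvenile period can
carry a non-climatic isotope trend.

Conventions: sample standard deviation (n−1 denominator) throughout; years
failing the replication gate are dropped, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TreeSeries
from .errors import CoverageError, EmptyChronologyError, EmptySeriesError, ValidationError
from .periods import Period, period_years, validate_period

DEFAULT_JUVENILE_EXCLUDE = 50
DEFAULT_MIN_REPLICATION = 4


def trim_juvenile(tree: TreeSeries, n_exclude: int = DEFAULT_JUVENILE_EXCLUDE) -> TreeSeries:
    """Drop a tree's first ``n_exclude`` rings (the possible juvenile period).

    Ring age counts from ``pith_year`` when known, else from the series
    start.  Raises :class:`EmptySeriesError` when nothing would remain.
    """
    if n_exclude < 0:
        raise ValidationError("n_exclude must be non-negative")
    if n_exclude == 0:
        return tree
    origin = tree.pith_year if tree.pith_year is not None else tree.first_year
    cut_year = origin + n_exclude  # first ring age kept is n_exclude
    start = max(cut_year, tree.first_year)
    if start > tree.last_year:
        raise EmptySeriesError(
            f"tree {tree.tree_id}: no rings left after excluding the first {n_exclude}"
        )
    offset = start - tree.first_year
    return TreeSeries(
        tree_id=tree.tree_id,
        first_year=start,
        values=tree.values[offset:],
        pith_year=tree.pith_year,
        scale=tree.scale,
    )


@dataclass(frozen=True)
class Chronology:
    """Replication-gated mean series with per-year sample depth.

    ``mean`` holds only years that pass the gate; ``sample_depth`` covers the
    whole union of tree coverage so that gaps are auditable.
    """

    mean: pd.Series = field(repr=False)
    sample_depth: pd.Series = field(repr=False)
    min_replication: int = DEFAULT_MIN_REPLICATION
    scale: str = "d13C_VPDB"

    @property
    def years(self) -> np.ndarray:
        return self.mean.index.to_numpy()

    @property
    def span(self) -> Period:
        y = self.years
        return int(y[0]), int(y[-1])

    def __len__(self) -> int:
        return len(self.mean)


def build_chronology(
    trees: list[TreeSeries],
    min_replication: int = DEFAULT_MIN_REPLICATION,
) -> Chronology:
    """Average trees year by year, keeping years with enough replication.

    Every tree contributes with equal weight.  Years covered by fewer than
    ``min_replication`` trees are excluded from the mean (but still appear in
    ``sample_depth``).  Raises :class:`EmptyChronologyError` if no year
    passes the gate.
    """
    if not trees:
        raise ValidationError("no trees supplied")
    if min_replication < 1:
        raise ValidationError("min_replication must be ≥ 1")
    scales = {t.scale for t in trees}
    if len(scales) > 1:
        raise ValidationError(f"trees on mixed isotope scales: {sorted(scales)}")
    # sort by tree_id so the result is exactly permutation-invariant
    table = pd.concat([t.to_series() for t in sorted(trees, key=lambda t: t.tree_id)],
                      axis=1)
    if table.columns.has_duplicates:
        raise ValidationError("duplicate tree_id among input trees")
    table = table.sort_index()
    depth = table.notna().sum(axis=1).astype(int)
    depth.name = "sample_depth"
    gated = table.loc[depth >= min_replication]
    if gated.empty:
        raise EmptyChronologyError(
            f"no year is covered by ≥ {min_replication} trees"
        )
    mean = gated.mean(axis=1)
    mean.name = "mean"
    return Chronology(mean=mean, sample_depth=depth,
                      min_replication=min_replication, scale=scales.pop())


def _reference_stats(series: pd.Series, reference_period: Period) -> tuple[float, float]:
    first, last = validate_period(reference_period, "reference_period")
    ref = series.loc[(series.index >= first) & (series.index <= last)]
    if ref.empty:
        raise CoverageError(f"reference period {reference_period} has no coverage")
    sd = float(ref.std(ddof=1)) if len(ref) > 1 else 0.0
    return float(ref.mean()), sd


def zscore(chronology, value_or_year, reference_period: Period) -> float:
    """Standard score (x − mean) / SD relative to a reference period.

    ``chronology`` may be a :class:`Chronology` or any annual Series.  If
    ``value_or_year`` is an integer year inside the coverage, that year's
    value is scored; an integer year outside coverage raises
    :class:`CoverageError`.  Any float is scored as a raw value in the
    series' units.
    """
    series = chronology.mean if isinstance(chronology, Chronology) else pd.Series(chronology)
    mean, sd = _reference_stats(series, reference_period)
    if sd == 0:
        raise ValidationError("reference-period SD is zero; z-score undefined")
    if isinstance(value_or_year, (int, np.integer)) and not isinstance(value_or_year, bool):
        year = int(value_or_year)
        if year not in series.index:
            raise CoverageError(f"year {year} not in chronology coverage")
        x = float(series.loc[year])
    else:
        x = float(value_or_year)
    return (x - mean) / sd


def summary_stats(chronology, period: Period | None = None) -> dict:
    """Mean, sample SD, SE = SD/√n and n over ``period`` (default: all)."""
    series = chronology.mean if isinstance(chronology, Chronology) else pd.Series(chronology)
    if period is None:
        y = series.index
        period = (int(y[0]), int(y[-1]))
    first, last = validate_period(period)
    sel = series.loc[(series.index >= first) & (series.index <= last)]
    if sel.empty:
        raise CoverageError(f"period {period} does not overlap chronology coverage")
    n = len(sel)
    sd = float(sel.std(ddof=1)) if n > 1 else 0.0
    return {
        "mean": float(sel.mean()),
        "sd": sd,
        "se": sd / np.sqrt(n),
        "n": n,
    }
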