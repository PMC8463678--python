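"""CSV interchange: tidy year-value tables with commented metadata headers.

All pipeline inputs and outputs are plain CSV.  Files written by the
package carry ``#``-prefixed header lines recording the package version,
the seed and the configuration hash, so every artifact is traceable to the
run that produced it.  Readers skip such comment lines, validate the
schema, reject duplicate keys, and name the offending line on malformed
rows.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import AtmosphericRecord, ClimateTable, TreeSeries, as_annual_series
from .errors import IntegrityError, ParseError
from .chronology import Chronology


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _read_raw(path) -> tuple[pd.DataFrame, int]:
    """Read a commented CSV; return the frame and the number of header lines
    preceding the column row (comments + 1), for line-number reporting."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    text = path.read_text()
    n_comment = 0
    for line in text.splitlines():
        if line.startswith("#"):
            n_comment += 1
        else:
            break
    try:
        df = pd.read_csv(_io.StringIO(text), comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no header row") from None
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    return df, n_comment + 1


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}; have {list(df.columns)}")


def _numeric(df: pd.DataFrame, column: str, path, header_lines: int,
             integer: bool = False) -> pd.Series:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = coerced.isna() & df[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"{path}, line {header_lines + row + 1}: "
            f"non-numeric value {df[column].iloc[row]!r} in column {column!r}"
        )
    if coerced.isna().any():
        row = int(np.flatnonzero(coerced.isna())[0])
        raise ParseError(
            f"{path}, line {header_lines + row + 1}: missing value in column {column!r}"
        )
    return coerced.astype(int) if integer else coerced.astype(float)


def _metadata_header(meta: dict | None) -> str:
    lines = [f"# isodendro {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return "\n".join(lines) + "\n"


def write_csv(df: pd.DataFrame, path, meta: dict | None = None,
              index: bool = False) -> None:
    """Write a DataFrame as CSV with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_header(meta))
        df.to_csv(fh, index=index)


# ---------------------------------------------------------------------------
# typed readers / writers
# ---------------------------------------------------------------------------

def read_annual_csv(path, value_column: str = "value") -> pd.Series:
    """Read a two-column (year, value) annual series; duplicates rejected."""
    df, header_lines = _read_raw(path)
    _require_columns(df, ["year", value_column], path)
    if df.empty:
        return pd.Series(dtype=float, name=value_column)
    years = _numeric(df, "year", path, header_lines, integer=True)
    values = _numeric(df, value_column, path, header_lines)
    if years.duplicated().any():
        dup = int(years[years.duplicated()].iloc[0])
        raise IntegrityError(f"{path}: duplicated year {dup}")
    return as_annual_series(pd.Series(values.to_numpy(), index=years.to_numpy()),
                            name=value_column)


def write_annual_csv(series: pd.Series, path, meta: dict | None = None,
                     value_column: str = "value") -> None:
    s = as_annual_series(series, value_column)
    df = pd.DataFrame({"year": s.index.to_numpy(), value_column: s.to_numpy()})
    write_csv(df, path, meta)


def read_tree_csv(path) -> list[TreeSeries]:
    """Read per-tree series from tidy long CSV (year, tree_id, value[, pith_year, scale])."""
    df, header_lines = _read_raw(path)
    _require_columns(df, ["year", "tree_id", "value"], path)
    if df.empty:
        return []
    years = _numeric(df, "year", path, header_lines, integer=True)
    values = _numeric(df, "value", path, header_lines)
    work = pd.DataFrame({"year": years, "tree_id": df["tree_id"].astype(str),
                         "value": values})
    if "pith_year" in df.columns:
        work["pith_year"] = df["pith_year"]
    if "scale" in df.columns:
        work["scale"] = df["scale"]
    dup = work.duplicated(subset=["year", "tree_id"])
    if dup.any():
        row = work.loc[dup].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate (year={int(row['year'])}, tree_id={row['tree_id']}) rows"
        )
    trees = []
    for tree_id, grp in work.groupby("tree_id", sort=True):
        grp = grp.sort_values("year")
        yrs = grp["year"].to_numpy()
        if len(yrs) > 1 and not np.array_equal(np.diff(yrs), np.ones(len(yrs) - 1)):
            raise IntegrityError(f"{path}: tree {tree_id} has missing rings (gap in years)")
        pith = grp["pith_year"].iloc[0] if "pith_year" in grp.columns else None
        pith = None if pith is None or pd.isna(pith) else int(pith)
        scale = str(grp["scale"].iloc[0]) if "scale" in grp.columns else "d13C_VPDB"
        trees.append(TreeSeries(
            tree_id=str(tree_id), first_year=int(yrs[0]),
            values=grp["value"].to_numpy(), pith_year=pith, scale=scale,
        ))
    return trees


def write_tree_csv(trees: list[TreeSeries], path, meta: dict | None = None) -> None:
    rows = []
    for tree in trees:
        for year, value in zip(tree.years, tree.values):
            rows.append({
                "year": int(year), "tree_id": tree.tree_id, "value": value,
                "pith_year": tree.pith_year if tree.pith_year is not None else "",
                "scale": tree.scale,
            })
    write_csv(pd.DataFrame(rows), path, meta)


def read_climate_csv(path) -> ClimateTable:
    """Read a tidy monthly climate table (year, month, temperature, precipitation, ao)."""
    df, header_lines = _read_raw(path)
    _require_columns(df, ["year", "month", "temperature", "precipitation", "ao"], path)
    df = df.assign(
        year=_numeric(df, "year", path, header_lines, integer=True),
        month=_numeric(df, "month", path, header_lines, integer=True),
    )
    if df.duplicated(subset=["year", "month"]).any():
        raise IntegrityError(f"{path}: duplicate (year, month) rows")
    return ClimateTable.from_tidy(df)


def write_climate_csv(climate: ClimateTable, path, meta: dict | None = None) -> None:
    write_csv(climate.to_tidy(), path, meta)


def read_atm_csv(path) -> AtmosphericRecord:
    return AtmosphericRecord(read_annual_csv(path, value_column="d13c_atm"))


def write_atm_csv(atm: AtmosphericRecord, path, meta: dict | None = None) -> None:
    write_annual_csv(atm.values, path, meta, value_column="d13c_atm")


def read_eruption_csv(path) -> pd.DataFrame:
    df, header_lines = _read_raw(path)
    _require_columns(df, ["year", "vei"], path)
    if df.empty:
        return pd.DataFrame(columns=["year", "name", "vei"])
    out = pd.DataFrame({
        "year": _numeric(df, "year", path, header_lines, integer=True),
        "name": df["name"].astype(str) if "name" in df.columns else "",
        "vei": _numeric(df, "vei", path, header_lines, integer=True),
    })
    if out["year"].duplicated().any():
        raise IntegrityError(f"{path}: duplicated eruption year")
    return out


def write_chronology_csv(chronology: Chronology, path, meta: dict | None = None) -> None:
    """Chronology CSV over the union of coverage: year, mean, sample_depth.

    Years failing the replication gate appear with an empty mean so the
    sample-depth panel stays complete.
    """
    depth = chronology.sample_depth
    df = pd.DataFrame({
        "year": depth.index.to_numpy(),
        "mean": chronology.mean.reindex(depth.index).to_numpy(),
        "sample_depth": depth.to_numpy(),
    })
    write_csv(df, path, meta)
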