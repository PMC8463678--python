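"""Smoothing, σ-threshold extreme years, period contrasts, volcanic matching.

Reconstructions are smoothed with normalized Hamming windows for display and
low-frequency interpretation; extreme years are flagged where the annual
value departs from a reference-period mean by at least 2 (or 3) standard
deviations; and negative (cold/wet) extremes are cross-referenced against a
catalog of explosive volcanic eruptions (VEI ≥ 4) that plausibly forced them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .containers import as_annual_series
from .errors import CoverageError, ValidationError
from .periods import Period, validate_period


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def hamming_weights(window_length: int) -> np.ndarray:
    """Normalized Hamming weights w_k ∝ 0.54 − 0.46·cos(2πk/(M−1))."""
    if window_length < 3 or window_length % 2 == 0:
        raise ValidationError("window_length must be an odd integer ≥ 3")
    w = np.hamming(window_length)
    return w / w.sum()


def hamming_smooth(series, window_length: int) -> pd.Series:
    """Centered Hamming-weighted moving average of an annual series.

    Edges are handled by truncating the window to the available years and
    renormalizing the remaining weights — no values are fabricated beyond
    the series ends.  The window must be odd, ≥ 3 and no longer than the
    series.
    """
    s = as_annual_series(series, "smoothed")
    w = hamming_weights(window_length)  # validates oddness and minimum size
    if window_length > len(s):
        raise ValidationError(
            f"window_length {window_length} exceeds series length {len(s)}"
        )
    x = s.to_numpy()
    num = np.convolve(x, w, mode="same")
    den = np.convolve(np.ones_like(x), w, mode="same")
    return pd.Series(num / den, index=s.index, name="smoothed")


# ---------------------------------------------------------------------------
# extremes
# ---------------------------------------------------------------------------

def detect_extremes(
    series,
    reference_period: Period | None = None,
    thresholds: tuple[float, ...] = (2.0, 3.0),
) -> pd.DataFrame:
    """Flag years departing ≥ 2σ (and ≥ 3σ) from a reference mean.

    The z-score reference defaults to the full series.  The sign column
    refers to the series' own units (e.g. for a precipitation reconstruction
    positive = wet, negative = dry), so callers reconstruct first and detect
    extremes on the climate scale rather than on the raw isotope sign.

    Returns a DataFrame with columns ``year, value, z, sign, level`` where
    ``level`` is the highest threshold attained.
    """
    s = as_annual_series(series, "value")
    thresholds = tuple(sorted(float(t) for t in thresholds))
    if not thresholds or thresholds[0] <= 0:
        raise ValidationError("thresholds must be positive")
    if reference_period is None:
        reference_period = (int(s.index[0]), int(s.index[-1]))
    first, last = validate_period(reference_period, "reference_period")
    ref = s.loc[(s.index >= first) & (s.index <= last)]
    if ref.empty:
        raise CoverageError(f"reference period {reference_period} has no coverage")
    mean = ref.mean()
    sd = ref.std(ddof=1)
    if not sd > 0:
        raise ValidationError("reference-period SD is zero; extremes undefined")
    z = (s - mean) / sd
    flagged = z[np.abs(z) >= thresholds[0]]
    levels = [
        max((t for t in thresholds if abs(zz) >= t))
        for zz in flagged
    ]
    return pd.DataFrame({
        "year": flagged.index.to_numpy(),
        "value": s.loc[flagged.index].to_numpy(),
        "z": flagged.to_numpy(),
        "sign": np.where(flagged.to_numpy() >= 0, "positive", "negative"),
        "level": levels,
    })


def period_contrast(series, period_a: Period, period_b: Period) -> dict:
    """Compare two sub-periods: means and per-period linear trends.

    For each period the mean, the OLS trend of value on year, its r² and the
    two-sided p-value of the slope are reported, plus the mean difference
    (b − a).
    """
    s = as_annual_series(series, "value")
    out: dict = {}
    for label, period in (("a", period_a), ("b", period_b)):
        first, last = validate_period(period)
        sel = s.loc[(s.index >= first) & (s.index <= last)]
        if len(sel) < 3:
            raise CoverageError(f"period {period} has {len(sel)} years; need ≥ 3")
        years = sel.index.to_numpy(dtype=float)
        vals = sel.to_numpy()
        if np.ptp(vals) == 0:
            slope, r2, p = 0.0, 0.0, 1.0
        else:
            fit = scipy.stats.linregress(years, vals)
            slope, r2, p = fit.slope, fit.rvalue ** 2, fit.pvalue
        out[f"mean_{label}"] = float(sel.mean())
        out[f"trend_slope_{label}"] = float(slope)
        out[f"trend_r2_{label}"] = float(r2)
        out[f"trend_p_{label}"] = float(p)
        out[f"n_{label}"] = len(sel)
    out["mean_difference"] = out["mean_b"] - out["mean_a"]
    return out


# ---------------------------------------------------------------------------
# volcanic matching
# ---------------------------------------------------------------------------

def match_volcanic(
    cold_extremes: pd.DataFrame,
    catalog: pd.DataFrame,
    min_vei: int = 4,
    lag_window: tuple[int, int] = (0, 3),
) -> dict:
    """Match negative extremes to explosive eruptions within a lag window.

    ``cold_extremes`` is a :func:`detect_extremes` frame (its ``year``
    column is used); ``catalog`` needs columns ``year, name, vei``.  For
    each eruption with VEI ≥ ``min_vei``, extreme years falling in
    ``[eruption_year + lag_window[0], eruption_year + lag_window[1]]`` are
    listed.

    Returns a dict with a per-eruption ``matches`` DataFrame and summary
    counts of matched/unmatched eruptions and extremes.
    """
    if catalog is None or len(catalog) == 0:
        raise ValidationError("eruption catalog is empty")
    lo, hi = int(lag_window[0]), int(lag_window[1])
    if hi < lo:
        raise ValidationError(f"lag window {lag_window} is not well ordered")
    vei = catalog["vei"].astype(int)
    if (vei < 0).any() or (vei > 8).any():
        raise ValidationError("VEI must be in [0, 8]")
    big = catalog.loc[vei >= min_vei]
    extreme_years = (
        np.sort(cold_extremes["year"].to_numpy(dtype=int))
        if len(cold_extremes) else np.array([], dtype=int)
    )
    rows = []
    matched_extremes: set[int] = set()
    for _, erup in big.iterrows():
        ey = int(erup["year"])
        hits = extreme_years[(extreme_years >= ey + lo) & (extreme_years <= ey + hi)]
        matched_extremes.update(int(y) for y in hits)
        rows.append({
            "eruption_year": ey,
            "name": erup.get("name", ""),
            "vei": int(erup["vei"]),
            "matched_years": list(int(y) for y in hits),
            "n_matched": len(hits),
        })
    matches = pd.DataFrame(rows)
    n_eruptions_matched = int((matches["n_matched"] > 0).sum()) if len(matches) else 0
    return {
        "matches": matches,
        "n_eruptions": len(big),
        "n_eruptions_matched": n_eruptions_matched,
        "n_extremes": len(extreme_years),
        "n_extremes_matched": len(matched_extremes),
    }
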