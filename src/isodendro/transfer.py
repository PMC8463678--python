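"""Linear transfer functions: screening, calibration, verification, reconstruction.

The transfer function is an inverse-calibration regression: the climate
variable is the dependent variable and the isotope proxy the predictor,

    Rec_t = a · I_t + b + ε_t,

fitted by ordinary least squares over a calibration window.  Split-period
verification scores the model on withheld years with the standard
dendroclimatological skill statistics:

* r   — Pearson correlation between observed and reconstructed values;
* RE  — reduction of error, ``1 − Σ(obs−rec)² / Σ(obs−mean_cal)²``, skill
  against the calibration-period observed mean as a no-skill forecast;
* CE  — coefficient of efficiency, same form but with the verification-period
  mean in the denominator (always ≤ RE);
* DW  — Durbin–Watson statistic of the verification residuals,
  ``Σ(e_t − e_{t−1})² / Σ e_t²``, near 2 when residuals are uncorrelated;
* Ks  — Gleichläufigkeit / coefficient of synchronicity, the fraction of
  adjacent year-pairs where observation and reconstruction move in the same
  direction (ties count one half).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import yaml

from .containers import ClimateTable, as_annual_series
from .errors import (
    CoverageError,
    DegenerateFitError,
    ValidationError,
)
from .periods import Period, check_disjoint, validate_period

#: named month aggregates screened alongside single months
DEFAULT_AGGREGATES: dict[str, tuple[int, ...]] = {
    "JJ": (6, 7),
    "JA": (7, 8),
    "JJA": (6, 7, 8),
    "annual": tuple(range(1, 13)),
}


# ---------------------------------------------------------------------------
# model and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransferModel:
    """Fitted linear mapping climate = slope·proxy + intercept + extra_offset.

    ``extra_offset`` is an additive constant kept separate from the fitted
    intercept; freshly fitted models always have 0, and it is non-zero only
    for bundled reference models whose published coefficients carry such a
    term.  ``residual_rmse`` is the calibration residual RMS and drives the
    constant ±1.96·RMSE band used as the 95 % confidence interval of the
    reconstruction.
    """

    slope: float
    intercept: float
    extra_offset: float = 0.0
    calibration_period: Period | None = None
    residual_rmse: float = np.nan
    r: float = np.nan
    r2: float = np.nan
    n: int = 0
    slope_se: float = np.nan
    intercept_se: float = np.nan
    calibration_obs_mean: float = np.nan
    proxy_name: str = "proxy"
    target_name: str = "climate"

    def __post_init__(self):
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValidationError("transfer coefficients must be finite")

    def predict(self, proxy) -> pd.Series:
        proxy = as_annual_series(proxy, "proxy")
        out = self.slope * proxy + self.intercept + self.extra_offset
        out.name = "reconstruction"
        return out

    def slope_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1−alpha) confidence interval of the slope (t-based)."""
        if self.n < 3 or not np.isfinite(self.slope_se):
            raise ValidationError("slope CI requires a fitted model with n ≥ 3")
        tcrit = scipy.stats.t.ppf(1 - alpha / 2, self.n - 2)
        return self.slope - tcrit * self.slope_se, self.slope + tcrit * self.slope_se


@dataclass(frozen=True)
class VerificationStats:
    """Split-period verification skill scores over ``n`` withheld years."""

    r: float
    re: float
    ce: float
    dw: float
    ks: float
    n: int

    def as_dict(self) -> dict:
        return {"r": self.r, "RE": self.re, "CE": self.ce,
                "DW": self.dw, "Ks": self.ks, "n": self.n}


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

def _common_years(a: pd.Series, b: pd.Series, period: Period | None = None) -> pd.Index:
    years = a.dropna().index.intersection(b.dropna().index)
    if period is not None:
        first, last = validate_period(period)
        years = years[(years >= first) & (years <= last)]
    return years


def correlate_monthly(
    proxy,
    climate: ClimateTable,
    aggregates: dict[str, tuple[int, ...]] | None = None,
    period: Period | None = None,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Screen proxy–climate Pearson correlations month by month.

    For every climate variable, every single month 1–12 and every named
    aggregate, the Pearson r, two-sided p (t-transform) and sample size are
    computed over the common years.  Precipitation aggregates use monthly
    sums, temperature and index aggregates monthly means.

    Returns a tidy DataFrame with columns
    ``variable, predictor, months, r, p, n, significant_05``.
    """
    proxy = as_annual_series(proxy, "proxy")
    if aggregates is None:
        aggregates = DEFAULT_AGGREGATES
    rows = []
    for variable in ("temperature", "precipitation", "ao"):
        stat = "sum" if variable == "precipitation" else "mean"
        predictors: list[tuple[str, tuple[int, ...]]] = [
            (str(m), (m,)) for m in range(1, 13)
        ] + [(name, tuple(months)) for name, months in aggregates.items()]
        for name, months in predictors:
            target = climate.aggregate(variable, list(months), stat=stat)
            years = _common_years(proxy, target, period)
            if len(years) < min_overlap:
                raise CoverageError(
                    f"only {len(years)} overlapping years for {variable} {name}; "
                    f"need ≥ {min_overlap}"
                )
            x = proxy.loc[years].to_numpy()
            y = target.loc[years].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = scipy.stats.pearsonr(x, y)
            rows.append({
                "variable": variable,
                "predictor": name,
                "months": "-".join(map(str, months)),
                "r": float(r),
                "p": float(p),
                "n": len(years),
                "significant_05": bool(p < 0.05) if np.isfinite(p) else False,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def fit_transfer(
    proxy,
    climate_target,
    calibration_period: Period | None = None,
    proxy_name: str = "proxy",
    target_name: str = "climate",
) -> TransferModel:
    """OLS fit of climate on proxy over the calibration window.

    Raises :class:`DegenerateFitError` when the proxy has zero variance and
    :class:`CoverageError` with fewer than 3 overlapping calibration years.
    """
    proxy = as_annual_series(proxy, "proxy")
    target = as_annual_series(climate_target, "target")
    years = _common_years(proxy, target, calibration_period)
    if len(years) < 3:
        raise CoverageError(
            f"need ≥ 3 overlapping calibration years, have {len(years)}"
        )
    x = proxy.loc[years].to_numpy()
    y = target.loc[years].to_numpy()
    if np.ptp(x) == 0:
        raise DegenerateFitError("proxy has zero variance over the calibration window")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    resid = res.resid
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    r = float(np.corrcoef(x, y)[0, 1])
    if calibration_period is None:
        calibration_period = (int(years.min()), int(years.max()))
    return TransferModel(
        slope=float(slope),
        intercept=float(intercept),
        extra_offset=0.0,
        calibration_period=validate_period(calibration_period),
        residual_rmse=rmse,
        r=r,
        r2=float(res.rsquared),
        n=len(years),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        calibration_obs_mean=float(np.mean(y)),
        proxy_name=proxy_name,
        target_name=target_name,
    )


def apply_transfer(model: TransferModel, proxy) -> pd.DataFrame:
    """Reconstruct the climate variable from a proxy series.

    Returns a year-indexed DataFrame with the reconstruction and its 95 %
    confidence band, a constant ±1.96 · calibration residual RMSE.  Models
    without a fitted RMSE (e.g. bundled reference coefficients) get a NaN
    band.
    """
    proxy = as_annual_series(proxy, "proxy")
    if proxy.empty:
        raise ValidationError("proxy series is empty")
    rec = model.predict(proxy)
    half = 1.96 * model.residual_rmse if np.isfinite(model.residual_rmse) else np.nan
    return pd.DataFrame({
        "reconstruction": rec,
        "ci_lower": rec - half,
        "ci_upper": rec + half,
    })


# ---------------------------------------------------------------------------
# verification statistics
# ---------------------------------------------------------------------------

def reduction_of_error(obs: np.ndarray, rec: np.ndarray, calibration_mean: float) -> float:
    obs = np.asarray(obs, float)
    rec = np.asarray(rec, float)
    denom = np.sum((obs - calibration_mean) ** 2)
    if denom == 0:
        raise DegenerateFitError("RE undefined: observations equal the calibration mean")
    return 1.0 - np.sum((obs - rec) ** 2) / denom


def coefficient_of_efficiency(obs: np.ndarray, rec: np.ndarray) -> float:
    obs = np.asarray(obs, float)
    rec = np.asarray(rec, float)
    denom = np.sum((obs - obs.mean()) ** 2)
    if denom == 0:
        raise DegenerateFitError("CE undefined: constant observations")
    return 1.0 - np.sum((obs - rec) ** 2) / denom


def durbin_watson(residuals: np.ndarray) -> float:
    e = np.asarray(residuals, float)
    if len(e) < 2:
        raise ValidationError("DW needs ≥ 2 residuals")
    denom = np.sum(e ** 2)
    if denom == 0:
        return 2.0  # perfect fit: no autocorrelation information, report neutral
    return float(np.sum(np.diff(e) ** 2) / denom)


def gleichlaufigkeit(obs: np.ndarray, rec: np.ndarray) -> float:
    """Sign-agreement fraction of adjacent-year changes; ties score ½."""
    d_obs = np.sign(np.diff(np.asarray(obs, float)))
    d_rec = np.sign(np.diff(np.asarray(rec, float)))
    if len(d_obs) == 0:
        raise ValidationError("Ks needs ≥ 2 years")
    prod = d_obs * d_rec
    score = np.where(prod > 0, 1.0, np.where(prod < 0, 0.0, 0.5))
    return float(score.mean())


def verify(
    model: TransferModel,
    proxy,
    climate_target,
    verification_period: Period,
) -> VerificationStats:
    """Score a fitted model on a withheld verification window.

    The verification window must be disjoint from the model's calibration
    window.  Residuals are observed − reconstructed in chronological order.
    """
    if model.calibration_period is not None:
        check_disjoint(model.calibration_period, verification_period)
    if not np.isfinite(model.calibration_obs_mean):
        raise ValidationError(
            "model lacks a calibration-period observed mean; RE undefined"
        )
    proxy = as_annual_series(proxy, "proxy")
    target = as_annual_series(climate_target, "target")
    years = _common_years(proxy, target, verification_period)
    if len(years) < 3:
        raise CoverageError(
            f"need ≥ 3 verification years, have {len(years)}"
        )
    obs = target.loc[years].to_numpy()
    rec = model.predict(proxy.loc[years]).to_numpy()
    resid = obs - rec
    r = float(np.corrcoef(obs, rec)[0, 1]) if np.std(rec) > 0 else np.nan
    return VerificationStats(
        r=r,
        re=float(reduction_of_error(obs, rec, model.calibration_obs_mean)),
        ce=float(coefficient_of_efficiency(obs, rec)),
        dw=durbin_watson(resid),
        ks=gleichlaufigkeit(obs, rec),
        n=len(years),
    )


# ---------------------------------------------------------------------------
# full split-period calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationReport:
    """Both split directions, coefficient percentiles, and the final model."""

    forward_model: TransferModel
    forward_stats: VerificationStats
    reverse_model: TransferModel
    reverse_stats: VerificationStats
    final_model: TransferModel
    coefficient_percentiles: dict = field(default_factory=dict)
    n_bootstrap: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for direction, m, s in (
            ("forward", self.forward_model, self.forward_stats),
            ("reverse", self.reverse_model, self.reverse_stats),
        ):
            rows.append({
                "direction": direction,
                "cal_start": m.calibration_period[0],
                "cal_end": m.calibration_period[1],
                "slope": m.slope, "intercept": m.intercept,
                "cal_r": m.r, "cal_r2": m.r2, "rmse": m.residual_rmse,
                **s.as_dict(),
            })
        return pd.DataFrame(rows)


def _residual_bootstrap(
    proxy: np.ndarray, fitted: np.ndarray, resid: np.ndarray,
    n_boot: int, rng: np.random.Generator,
) -> np.ndarray:
    """Coefficient draws by resampling calibration residuals with replacement."""
    n = len(proxy)
    X = np.column_stack([np.ones(n), proxy])
    # pseudoinverse reused across resamples
    pinv = np.linalg.pinv(X)
    idx = rng.integers(0, n, size=(n_boot, n))
    ystar = fitted[None, :] + resid[idx]
    return (pinv @ ystar.T).T  # (n_boot, 2): intercept, slope


def calibrate_full(
    proxy,
    climate_target,
    cal_period: Period,
    ver_period: Period,
    n_bootstrap: int = 1000,
    seed: int | None = 0,
    proxy_name: str = "proxy",
    target_name: str = "climate",
) -> CalibrationReport:
    """Split-period calibration/verification in both directions.

    Fits on ``cal_period`` and verifies on ``ver_period``, then swaps the
    windows, and finally fits the production model on the union of both.
    Coefficient uncertainty is summarised by 2.5 / 97.5 percentiles from a
    seeded residual bootstrap of the union fit.
    """
    check_disjoint(cal_period, ver_period)
    kw = dict(proxy_name=proxy_name, target_name=target_name)
    fwd = fit_transfer(proxy, climate_target, cal_period, **kw)
    fwd_stats = verify(fwd, proxy, climate_target, ver_period)
    rev = fit_transfer(proxy, climate_target, ver_period, **kw)
    rev_stats = verify(rev, proxy, climate_target, cal_period)

    union = (min(cal_period[0], ver_period[0]), max(cal_period[1], ver_period[1]))
    final = fit_transfer(proxy, climate_target, union, **kw)

    percentiles: dict = {}
    if n_bootstrap > 0:
        p = as_annual_series(proxy)
        t = as_annual_series(climate_target)
        years = _common_years(p, t, union)
        x = p.loc[years].to_numpy()
        y = t.loc[years].to_numpy()
        fitted = final.slope * x + final.intercept
        resid = y - fitted
        rng = np.random.default_rng(seed)
        coefs = _residual_bootstrap(x, fitted, resid, n_bootstrap, rng)
        lo, hi = np.percentile(coefs, [2.5, 97.5], axis=0)
        percentiles = {
            "intercept": (float(lo[0]), float(hi[0])),
            "slope": (float(lo[1]), float(hi[1])),
        }
    return CalibrationReport(
        forward_model=fwd, forward_stats=fwd_stats,
        reverse_model=rev, reverse_stats=rev_stats,
        final_model=final, coefficient_percentiles=percentiles,
        n_bootstrap=n_bootstrap,
    )


# ---------------------------------------------------------------------------
# bundled reference models
# ---------------------------------------------------------------------------

def load_reference_model(name: str) -> TransferModel:
    """Load a bundled reference transfer model by name.

    Available: ``"july_precipitation"`` (July precipitation, mm, from a
    δ13C cellulose chronology) and ``"ao_may"`` (May Arctic Oscillation
    index from a δ18O cellulose chronology).  These carry published regional
    coefficients, including their small constant offset, and no residual
    statistics; they are for applying, not for verification.
    """
    ref = resources.files("isodendro.data").joinpath("reference_models.yaml")
    models = yaml.safe_load(ref.read_text())
    if name not in models:
        raise ValidationError(
            f"unknown reference model {name!r}; available: {sorted(models)}"
        )
    m = models[name]
    period = m.get("calibration_period")
    return TransferModel(
        slope=float(m["slope"]),
        intercept=float(m["intercept"]),
        extra_offset=float(m.get("extra_offset", 0.0)),
        calibration_period=tuple(period) if period else None,
        proxy_name=m.get("proxy", "proxy"),
        target_name=m.get("target", "climate"),
    )
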