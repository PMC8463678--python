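"""Transfer functions: OLS fits, skill statistics, reconstructions.

Brute-force direct-summation oracles for the OLS coefficients and for RE,
CE, DW and Ks are defined here, independent of the library code paths they
check.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.stats.stattools

import isodendro as iso
from isodendro.errors import (
    CoverageError,
    DegenerateFitError,
    InvalidSplitError,
    ValidationError,
)
from isodendro.transfer import TransferModel


# ---------------------------------------------------------------------------
# independent oracles (direct summation, no vectorised shortcuts)
# ---------------------------------------------------------------------------

def ols_oracle(x, y):
    """Normal-equation solution from explicit centered sums."""
    xb = sum(x) / len(x)
    yb = sum(y) / len(y)
    slope = sum((a - xb) * (b - yb) for a, b in zip(x, y)) / \
        sum((a - xb) ** 2 for a in x)
    return slope, yb - slope * xb


def re_oracle(obs, rec, cal_mean):
    num = sum((o - r) ** 2 for o, r in zip(obs, rec))
    den = sum((o - cal_mean) ** 2 for o in obs)
    return 1 - num / den


def ce_oracle(obs, rec):
    m = sum(obs) / len(obs)
    num = sum((o - r) ** 2 for o, r in zip(obs, rec))
    den = sum((o - m) ** 2 for o in obs)
    return 1 - num / den


def dw_oracle(e):
    num = sum((e[t] - e[t - 1]) ** 2 for t in range(1, len(e)))
    den = sum(v ** 2 for v in e)
    return num / den


def ks_oracle(obs, rec):
    total = 0.0
    for t in range(1, len(obs)):
        do = np.sign(obs[t] - obs[t - 1])
        dr = np.sign(rec[t] - rec[t - 1])
        total += 1.0 if do * dr > 0 else (0.5 if do * dr == 0 else 0.0)
    return total / (len(obs) - 1)


def annual(values, start=1900):
    return pd.Series(np.asarray(values, float),
                     index=np.arange(start, start + len(values)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TestFitTransfer:
    def test_exact_line(self):
        x = annual([1.0, 2.0, 3.0, 4.0, 5.0])
        model = iso.fit_transfer(x, 2 * x + 1)
        assert model.slope == pytest.approx(2.0, abs=1e-12)
        assert model.intercept == pytest.approx(1.0, abs=1e-12)
        assert model.residual_rmse == pytest.approx(0.0, abs=1e-10)
        assert model.r2 == pytest.approx(1.0)

    def test_five_point_toy_matches_normal_equations(self):
        x = annual([-25.1, -24.2, -24.9, -23.8, -24.4])
        y = annual([51.0, 38.0, 47.5, 30.0, 41.0])
        model = iso.fit_transfer(x, y)
        slope, intercept = ols_oracle(x.to_numpy(), y.to_numpy())
        assert model.slope == pytest.approx(slope, rel=1e-12)
        assert model.intercept == pytest.approx(intercept, rel=1e-12)
        assert model.calibration_obs_mean == pytest.approx(y.mean())

    def test_zero_variance_proxy(self):
        x = annual([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(DegenerateFitError):
            iso.fit_transfer(x, annual([1.0, 2.0, 3.0, 4.0]))

    def test_too_few_years(self):
        with pytest.raises(CoverageError):
            iso.fit_transfer(annual([1.0, 2.0]), annual([1.0, 2.0]))

    def test_fitted_values_reproduce_ols(self):
        rng = np.random.default_rng(0)
        x = annual(rng.normal(-25, 0.8, 40))
        y = annual(-16 * x.to_numpy() + rng.normal(0, 5, 40))
        model = iso.fit_transfer(x, y, (1900, 1939))
        rec = iso.apply_transfer(model, x)["reconstruction"]
        expected = model.slope * x + model.intercept
        assert np.allclose(rec, expected, atol=1e-12)


class TestApplyTransfer:
    def test_reference_july_precipitation_coefficients(self):
        """Published coefficients at δ13C = −24.0 ‰ give 43.711 mm."""
        model = iso.load_reference_model("july_precipitation")
        rec = iso.apply_transfer(model, annual([-24.0]))
        assert rec["reconstruction"].iloc[0] == pytest.approx(43.711, abs=1e-9)

    def test_reference_ao_root(self):
        """The May AO model crosses zero at δ18O = 21.640625 ‰."""
        model = iso.load_reference_model("ao_may")
        rec = iso.apply_transfer(model, annual([21.640625]))
        assert rec["reconstruction"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_slope_constant_reconstruction(self):
        model = TransferModel(slope=0.0, intercept=5.0, extra_offset=0.25)
        rec = iso.apply_transfer(model, annual([1.0, 2.0, 3.0]))
        assert (rec["reconstruction"] == 5.25).all()

    def test_ci_band_is_const_1p96_rmse(self):
        x = annual(np.arange(10.0))
        rng = np.random.default_rng(1)
        y = annual(3 * np.arange(10.0) + rng.normal(0, 1, 10))
        model = iso.fit_transfer(x, y)
        rec = iso.apply_transfer(model, x)
        half = (rec["ci_upper"] - rec["reconstruction"]).to_numpy()
        assert np.allclose(half, 1.96 * model.residual_rmse)

    def test_unknown_reference_model(self):
        with pytest.raises(ValidationError):
            iso.load_reference_model("nope")


# ---------------------------------------------------------------------------
# verification statistics
# ---------------------------------------------------------------------------

class TestVerificationStats:
    def test_perfect_reconstruction(self):
        rng = np.random.default_rng(2)
        proxy = annual(rng.normal(-25, 1, 40))
        target = 2.0 * proxy + 3.0
        model = iso.fit_transfer(proxy, target, (1900, 1919))
        stats = iso.verify(model, proxy, target, (1920, 1939))
        assert stats.r == pytest.approx(1.0)
        assert stats.re == pytest.approx(1.0)
        assert stats.ce == pytest.approx(1.0)
        assert stats.ks == pytest.approx(1.0)

    def test_calibration_mean_forecast_has_zero_re(self):
        rng = np.random.default_rng(3)
        obs = rng.normal(50, 5, 25)
        cal_mean = 48.0
        model = TransferModel(slope=0.0, intercept=cal_mean,
                              calibration_period=(1900, 1919),
                              calibration_obs_mean=cal_mean)
        proxy = annual(rng.normal(-25, 1, 25), start=1920)
        stats = iso.verify(model, proxy, annual(obs, start=1920), (1920, 1944))
        assert stats.re == pytest.approx(0.0, abs=1e-12)
        assert stats.ce < 0  # verification mean beats a wrong constant

    def test_alternating_residuals_push_dw_to_four(self):
        e = np.resize([1.0, -1.0], 1000)
        assert iso.durbin_watson(e) == pytest.approx(4.0, abs=0.01)
        assert iso.durbin_watson(e) == pytest.approx(dw_oracle(list(e)), rel=1e-12)

    def test_dw_matches_statsmodels(self):
        rng = np.random.default_rng(4)
        e = rng.normal(0, 1, 50)
        assert iso.durbin_watson(e) == pytest.approx(
            float(statsmodels.stats.stattools.durbin_watson(e)), rel=1e-12)

    def test_gleichlaufigkeit_tie_counts_half(self):
        obs = [0.0, 1.0, 1.0, 0.0]
        rec = [0.0, 1.0, 2.0, 1.0]
        # pairs: (+,+)=1, (0,+)=0.5, (−,−)=1 → 2.5/3
        assert iso.gleichlaufigkeit(obs, rec) == pytest.approx(2.5 / 3)
        assert iso.gleichlaufigkeit(obs, rec) == pytest.approx(ks_oracle(obs, rec))

    def test_overlapping_split_rejected(self):
        rng = np.random.default_rng(5)
        proxy = annual(rng.normal(0, 1, 40))
        target = annual(rng.normal(0, 1, 40))
        model = iso.fit_transfer(proxy, target, (1900, 1920))
        with pytest.raises(InvalidSplitError):
            iso.verify(model, proxy, target, (1920, 1939))

    def test_oracle_equivalence_random_series(self):
        """RE, CE, DW, Ks and OLS agree with direct summation to ≤ 1e-10."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(5, 51))
            obs = rng.normal(50, 10, n)
            rec = obs + rng.normal(0, 5, n)
            cal_mean = float(rng.normal(50, 5))
            assert iso.reduction_of_error(obs, rec, cal_mean) == pytest.approx(
                re_oracle(list(obs), list(rec), cal_mean), rel=1e-10)
            assert iso.coefficient_of_efficiency(obs, rec) == pytest.approx(
                ce_oracle(list(obs), list(rec)), rel=1e-10)
            assert iso.durbin_watson(obs - rec) == pytest.approx(
                dw_oracle(list(obs - rec)), rel=1e-10)
            assert iso.gleichlaufigkeit(obs, rec) == pytest.approx(
                ks_oracle(list(obs), list(rec)), rel=1e-10)

    def test_ce_never_exceeds_re(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            obs = rng.normal(0, 1, n)
            rec = rng.normal(0, 1, n)
            cal_mean = float(rng.normal(0, 2))
            re = iso.reduction_of_error(obs, rec, cal_mean)
            ce = iso.coefficient_of_efficiency(obs, rec)
            assert ce <= re + 1e-12

    def test_re_ce_shift_invariant(self):
        rng = np.random.default_rng(8)
        obs = rng.normal(0, 1, 30)
        rec = rng.normal(0, 1, 30)
        c = 17.3
        assert iso.reduction_of_error(obs + c, rec + c, 1.0 + c) == pytest.approx(
            iso.reduction_of_error(obs, rec, 1.0), rel=1e-9)
        assert iso.coefficient_of_efficiency(obs + c, rec + c) == pytest.approx(
            iso.coefficient_of_efficiency(obs, rec), rel=1e-9)


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

class TestCorrelateMonthly:
    def test_identical_and_negated_columns(self):
        climate = iso.gen_climate((1969, 2009), seed=10)
        july_p = climate.aggregate("precipitation", [7], stat="sum")
        table = iso.correlate_monthly(july_p, climate)
        row = table[(table.variable == "precipitation") & (table.predictor == "7")]
        assert row["r"].iloc[0] == pytest.approx(1.0)
        table_neg = iso.correlate_monthly(-july_p, climate)
        row = table_neg[(table_neg.variable == "precipitation") & (table_neg.predictor == "7")]
        assert row["r"].iloc[0] == pytest.approx(-1.0)

    def test_insufficient_overlap(self):
        climate = iso.gen_climate((2000, 2005), seed=0)
        proxy = annual(np.arange(6.0), start=2000)
        with pytest.raises(CoverageError):
            iso.correlate_monthly(proxy, climate)

    def test_july_signal_wins_screening(self):
        """A proxy built from July precipitation is screened back to July in
        ≥ 90 % of seeded replicates."""
        wins = 0
        for rep in range(100):
            climate = iso.gen_climate((1969, 2009), seed=20_000 + rep)
            july_p = climate.aggregate("precipitation", [7], stat="sum")
            rng = np.random.default_rng(30_000 + rep)
            proxy = july_p / -16.7 + rng.normal(0, 0.2, len(july_p))
            table = iso.correlate_monthly(proxy, climate)
            months = table[(table.variable == "precipitation")
                           & table.predictor.str.fullmatch(r"\d+")]
            best = months.loc[months["r"].abs().idxmax(), "predictor"]
            wins += best == "7"
        assert wins >= 90


# ---------------------------------------------------------------------------
# full calibration
# ---------------------------------------------------------------------------

class TestCalibrateFull:
    def test_noise_free_split_directions_agree(self):
        x = annual(np.sin(np.arange(40.0)) - 25)
        y = -16.7 * x + 42.0
        report = iso.calibrate_full(x, y, (1920, 1939), (1900, 1919),
                                    n_bootstrap=200, seed=0)
        assert report.forward_model.slope == pytest.approx(report.reverse_model.slope)
        assert report.forward_model.intercept == pytest.approx(
            report.reverse_model.intercept)
        lo, hi = report.coefficient_percentiles["slope"]
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_skill_under_correct_model(self):
        """Correctly specified noisy scenarios verify with RE, CE > 0."""
        good = 0
        for rep in range(100):
            rng = np.random.default_rng(40_000 + rep)
            x = annual(rng.normal(-25, 0.8, 41), start=1969)
            y = -16.7 * x + 42.0 + annual(rng.normal(0, 5, 41), start=1969)
            report = iso.calibrate_full(x, y, (1990, 2009), (1969, 1989),
                                        n_bootstrap=0)
            good += (report.forward_stats.re > 0) and (report.forward_stats.ce > 0)
        assert good >= 90

    def test_shuffled_null_has_no_skill(self):
        """Year-shuffled proxies produce median verification RE ≤ 0."""
        res = []
        for rep in range(100):
            rng = np.random.default_rng(50_000 + rep)
            x = rng.normal(-25, 0.8, 41)
            y = -16.7 * x + 42.0 + rng.normal(0, 5, 41)
            x_null = annual(rng.permutation(x), start=1969)
            report = iso.calibrate_full(x_null, annual(y, start=1969),
                                        (1990, 2009), (1969, 1989), n_bootstrap=0)
            res.append(report.forward_stats.re)
        assert np.median(res) <= 0

    def test_final_model_fits_union(self):
        rng = np.random.default_rng(9)
        x = annual(rng.normal(-25, 0.8, 41), start=1969)
        y = -16.7 * x + annual(rng.normal(0, 5, 41), start=1969)
        report = iso.calibrate_full(x, y, (1990, 2009), (1969, 1989), n_bootstrap=0)
        direct = iso.fit_transfer(x, y, (1969, 2009))
        assert report.final_model.slope == pytest.approx(direct.slope)
        assert report.final_model.n == 41

    def test_bootstrap_percentiles_bracket_estimate(self):
        rng = np.random.default_rng(10)
        x = annual(rng.normal(-25, 0.8, 41), start=1969)
        y = -16.7 * x + annual(rng.normal(0, 5, 41), start=1969)
        report = iso.calibrate_full(x, y, (1990, 2009), (1969, 1989),
                                    n_bootstrap=500, seed=1)
        lo, hi = report.coefficient_percentiles["slope"]
        assert lo < report.final_model.slope < hi
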