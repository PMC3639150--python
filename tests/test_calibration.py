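"""OLS calibration, inverse prediction and detection limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import zerocross as zc
from zerocross.calibration import MeasurementSetting
from zerocross.errors import FitError, QuantificationError

SETTING = MeasurementSetting("clindamycin", 1, 20.0, 251.0)

# printed regression coefficients of the reference system: first/second
# order, four delta-lambda settings, for the short- and long-wavelength
# analyte respectively
CLINDAMYCIN_EQUATIONS = [
    (1, 16.0, 252.0, 0.000120, -9.761e-5),
    (1, 20.0, 251.0, 0.000185, -0.00098),
    (2, 10.5, 234.0, 0.00024, -3.912e-5),
    (2, 14.0, 239.0, 0.0004282, -0.038),
]
TRETINOIN_EQUATIONS = [
    (1, 16.0, 364.0, 0.05086, -0.00035),
    (1, 20.0, 364.0, 0.06260, -0.0024),
    (2, 10.5, 386.0, 0.010585, 0.00035),
    (2, 14.0, 387.0, 0.018587, 0.00437),
]
CLINDAMYCIN_X = np.array([60, 120, 240, 360, 480, 720, 960, 1200], dtype=float)
TRETINOIN_X = np.array([1.25, 2.5, 5, 7.5, 10, 15, 20, 25], dtype=float)


def _ols_oracle(x, y):
    """Normal-equations OLS with classical n-2 standard errors."""
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta[1], beta[0], np.sqrt(cov[1, 1]), np.sqrt(cov[0, 0])


class TestFitCalibration:
    def test_perfect_line(self):
        m = zc.fit_calibration([(0, 0), (1, 1), (2, 2)], SETTING)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-15)
        assert m.r == pytest.approx(1.0)
        assert m.rsd_slope_pct == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # Sxy = 3, Sxx = 2, Syy = 14/3 by direct summation
        m = zc.fit_calibration([(1, 2), (2, 3), (3, 5)], SETTING)
        assert m.slope == pytest.approx(1.5)
        assert m.intercept == pytest.approx(1.0 / 3.0)
        assert m.r == pytest.approx(3.0 / np.sqrt(2.0 * 14.0 / 3.0), abs=1e-12)
        assert round(m.r, 4) == 0.9820

    @pytest.mark.parametrize("order,dl,lam,slope,intercept", CLINDAMYCIN_EQUATIONS)
    def test_recovers_printed_coefficients_from_noiseless_points(
        self, order, dl, lam, slope, intercept
    ):
        y = slope * CLINDAMYCIN_X + intercept
        m = zc.fit_calibration(
            (CLINDAMYCIN_X, y), MeasurementSetting("clindamycin", order, dl, lam)
        )
        assert m.slope == pytest.approx(slope, rel=1e-12)
        assert m.intercept == pytest.approx(intercept, rel=1e-9)
        assert m.r == pytest.approx(1.0)

    def test_matches_normal_equations_oracle_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(4, 12)
            x = np.sort(rng.uniform(1, 100, n))
            y = rng.normal(0.02 * x + 0.5, 0.3)
            m = zc.fit_calibration((x, y), SETTING)
            slope, intercept, sd_s, sd_i = _ols_oracle(x, y)
            assert m.slope == pytest.approx(slope, rel=1e-10)
            assert m.intercept == pytest.approx(intercept, rel=1e-10)
            assert m.sd_slope == pytest.approx(sd_s, rel=1e-10)
            assert m.sd_intercept == pytest.approx(sd_i, rel=1e-10)

    def test_r_squared_equals_coefficient_of_determination(self):
        rng = np.random.default_rng(11)
        x = np.arange(1.0, 11.0)
        y = 2 * x + rng.normal(0, 1, 10)
        m = zc.fit_calibration((x, y), SETTING)
        pred = m.slope * x + m.intercept
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert m.r**2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)

    def test_constant_shift_moves_intercept_only(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        y = np.array([0.1, 0.25, 0.4, 0.9])
        m0 = zc.fit_calibration((x, y), SETTING)
        m1 = zc.fit_calibration((x, y + 0.5), SETTING)
        assert m1.slope == pytest.approx(m0.slope, rel=1e-12)
        assert m1.sd_slope == pytest.approx(m0.sd_slope, rel=1e-12)
        assert m1.intercept == pytest.approx(m0.intercept + 0.5, rel=1e-12)

    def test_weighted_mode_agrees_on_homoscedastic_perfect_line(self):
        x = np.array([1.0, 2.0, 5.0, 10.0])
        y = 0.3 * x + 0.1
        m = zc.fit_calibration((x, y), SETTING, weighting="1/x")
        assert m.slope == pytest.approx(0.3, rel=1e-9)
        assert m.intercept == pytest.approx(0.1, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            zc.fit_calibration([(1, 1), (1, 2), (1, 3)], SETTING)
        with pytest.raises(FitError):
            zc.fit_calibration([(1, 1), (2, 2)], SETTING)

    def test_json_roundtrip(self):
        m = zc.fit_calibration([(1, 2), (2, 3), (3, 5)], SETTING)
        back = zc.CalibrationModel.from_json(m.to_json())
        assert back == m


class TestPrediction:
    def test_predict_at_zero_is_intercept(self):
        m = zc.fit_calibration([(1, 2), (2, 3), (3, 5)], SETTING)
        assert zc.predict_signal(m, 0.0) == m.intercept

    @pytest.mark.parametrize(
        "order,dl,lam,slope,intercept,x,expected",
        [
            (1, 16.0, 364.0, 0.05086, -0.00035, 12.5, 0.63540),
            (1, 20.0, 251.0, 0.000185, -0.00098, 600.0, 0.11002),
        ],
    )
    def test_printed_equation_arithmetic(self, order, dl, lam, slope, intercept,
                                         x, expected):
        m = _model(slope, intercept, order, dl, lam)
        assert zc.predict_signal(m, x) == pytest.approx(expected, abs=5e-6)
        assert zc.quantify(m, expected) == pytest.approx(x, rel=1e-4)

    def test_quantify_at_intercept_is_zero(self):
        m = _model(0.05, 0.002)
        assert zc.quantify(m, 0.002) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(-1e3, 1e3, allow_nan=False))
    def test_quantify_inverts_predict(self, x):
        m = _model(0.000185, -0.00098)
        assert zc.quantify(m, zc.predict_signal(m, x)) == pytest.approx(
            x, rel=1e-9, abs=1e-9
        )

    def test_zero_slope_rejected(self):
        m = _model(0.0, 0.1)
        with pytest.raises(QuantificationError):
            zc.quantify(m, 0.5)


def _model(slope, intercept, order=1, dl=20.0, lam=251.0):
    return zc.CalibrationModel(
        analyte="clindamycin", order=order, delta_lambda_nm=dl, wavelength_nm=lam,
        slope=slope, intercept=intercept, r=0.999, sd_slope=0.0, sd_intercept=0.0,
        rsd_slope_pct=0.0, n_points=8, range_ug_ml=(60.0, 1200.0),
    )


class TestLodLoq:
    def test_zero_sigma_gives_zero_limits(self):
        assert zc.lod_loq(0.0, 0.1) == (0.0, 0.0)

    def test_arithmetic(self):
        lod, loq = zc.lod_loq(0.00024, 0.000185)
        assert lod == pytest.approx(4.281, abs=5e-4)
        assert loq == pytest.approx(12.97, abs=5e-3)

    def test_ratio_is_fixed(self):
        lod, loq = zc.lod_loq(0.037, 0.42)
        assert loq / lod == pytest.approx(10.0 / 3.3, rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(QuantificationError):
            zc.lod_loq(0.1, 0.0)
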