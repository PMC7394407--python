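"""Exponential adaptation model: identifiability, indices, steady state."""

import numpy as np
import pytest
from sklearn.base import clone

from posturadapt import (
    ExponentialAdaptationModel,
    average_trials,
    derive_indices,
    fit_exponential,
    goodness_of_fit,
    steady_state,
)
from posturadapt.cycles import CycleSeries


def exp_series(A, B, C, n_cycles=27):
    n = np.arange(1, n_cycles + 1)
    return n, A + B * np.exp(-C * (n - 1))


class TestNoiselessIdentifiability:
    @pytest.mark.parametrize(
        "A,B,C",
        [
            (4.0, 6.0, 0.5),
            (10.0, -2.0, 1.0 / 1.84),
            (8.0, 4.0, 0.05),
            (0.9, -0.45, 1.0 / 4),
            (12.0, -6.0, 3.0),
            (5.0, 2.5, 2.0),
        ],
    )
    def test_exact_recovery(self, A, B, C):
        """Any noiseless series with C in [0.05, 3] is recovered to 1e-6."""
        n, y = exp_series(A, B, C)
        fit = fit_exponential(y, n)
        assert fit.A == pytest.approx(A, rel=1e-6)
        assert fit.B == pytest.approx(B, rel=1e-6)
        assert fit.C == pytest.approx(C, rel=1e-6)
        assert fit.R == pytest.approx(1.0, abs=1e-9)
        assert not fit.degenerate

    def test_ten_cycle_series_suffices(self):
        n, y = exp_series(3.0, 1.5, 0.3, n_cycles=10)
        fit = fit_exponential(y, n)
        assert fit.tau_cycles == pytest.approx(1 / 0.3, rel=1e-6)

    def test_constant_series_degenerate(self):
        fit = fit_exponential(np.full(27, 7.0), np.arange(1, 28))
        assert fit.A == pytest.approx(7.0, abs=1e-9)
        assert fit.degenerate
        assert np.isnan(fit.R)  # zero-variance fitted curve: R undefined

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_exponential(np.array([1.0, 2.0, 3.0]), np.array([1, 2, 3]))

    def test_intercept_identity(self):
        """I = A + B exactly: the model is evaluated with cycle 1 at t = 0."""
        n, y = exp_series(4.0, 6.0, 0.5)
        fit = fit_exponential(y, n)
        assert fit.I == fit.A + fit.B
        assert y[0] == pytest.approx(fit.I, rel=1e-9)


class TestSklearnProtocol:
    def test_estimator_fit_predict(self):
        n, y = exp_series(4.0, 6.0, 0.5)
        model = ExponentialAdaptationModel(frequency=0.18)
        model.fit(n.reshape(-1, 1), y)
        np.testing.assert_allclose(model.predict(n), y, atol=1e-8)
        assert model.score(n, y) == pytest.approx(1.0)
        assert model.tau_seconds_ == pytest.approx(model.tau_cycles_ / 0.18)

    def test_get_set_params_clone(self):
        model = ExponentialAdaptationModel(frequency=0.56, tol_b=0.05)
        params = model.get_params()
        assert params["frequency"] == 0.56
        cloned = clone(model)
        assert cloned.get_params() == params


class TestDeriveIndices:
    def test_ai_half_asymptote(self):
        """A = half of I gives AI = -1/3, i.e. about -0.3."""
        n, y = exp_series(0.5, 0.5, 0.5)
        fit = derive_indices(fit_exponential(y, n), 0.18)
        assert fit.AI == pytest.approx(-1.0 / 3.0)
        assert round(fit.AI, 1) == -0.3

    def test_ai_zero_when_no_adaptation(self):
        fit = fit_exponential(np.full(27, 5.0), np.arange(1, 28))
        fit = derive_indices(fit, 0.18)
        assert fit.AI == pytest.approx(0.0, abs=1e-9)

    def test_tau_conversion_to_seconds(self):
        """C = 1/3 at 0.18 Hz: tau = 3 cycles = 3/0.18 = 16.7 s."""
        n, y = exp_series(4.0, 2.0, 1.0 / 3.0)
        fit = derive_indices(fit_exponential(y, n), 0.18)
        assert fit.tau_cycles == pytest.approx(3.0, rel=1e-6)
        assert fit.tau_seconds == pytest.approx(16.7, abs=0.05)

    def test_tau_always_positive_for_decay_and_rise(self):
        for B in (+4.0, -4.0):
            n, y = exp_series(8.0, B, 0.4)
            fit = fit_exponential(y, n)
            assert fit.tau_cycles > 0
            assert np.sign(fit.AI) == np.sign(-B)

    def test_ai_bounds_and_monotonicity(self):
        """AI in (-1, 1) for positive A, I; monotone increasing in A."""
        I = 6.0
        ais = []
        for A in np.linspace(0.5, 20.0, 25):
            ai = (A - I) / (A + I)
            assert -1 < ai < 1
            ais.append(ai)
        assert np.all(np.diff(ais) > 0)


class TestGoodnessOfFit:
    def test_noiseless_r_is_one(self):
        n, y = exp_series(4.0, 6.0, 0.5)
        fit = fit_exponential(y, n)
        r, p = goodness_of_fit(y, fit, n)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_six_point_worked_series_matches_covariance_formula(self):
        """R equals the direct covariance-formula computation."""
        n = np.arange(1, 7)
        y = np.array([9.8, 7.1, 6.0, 5.2, 4.9, 4.75])
        fit = fit_exponential(y, n)
        fitted = fit.predict(n)
        num = np.sum((y - y.mean()) * (fitted - fitted.mean()))
        den = np.sqrt(np.sum((y - y.mean()) ** 2) * np.sum((fitted - fitted.mean()) ** 2))
        r, _ = goodness_of_fit(y, fit, n)
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_p_r_is_anticonservative_under_noise_null(self, rng):
        """Fitting noise then correlating with the fit inflates rejections.

        p_R is descriptive: the curve is fitted to the same data it is
        correlated with, so under a white-noise null the nominal-5% rate
        is exceeded (simulation-established behaviour).
        """
        hits = 0
        reps = 150
        for _ in range(reps):
            y = rng.normal(10.0, 1.0, 27)
            fit = fit_exponential(y, np.arange(1, 28))
            if np.isfinite(fit.p_R) and fit.p_R < 0.05:
                hits += 1
        assert hits / reps > 0.065  # clearly above nominal alpha


class TestRecoveryUnderNoise:
    def test_residual_never_exceeds_constant_model(self, rng):
        """The constant model is nested, so the fit RSS cannot be worse."""
        for _ in range(20):
            y = rng.normal(5.0, 1.0, 27)
            fit = fit_exponential(y, np.arange(1, 28))
            rss_const = float(np.sum((y - y.mean()) ** 2))
            assert fit.rss <= rss_const + 1e-9

    @pytest.mark.parametrize("tau", [1.47, 3.16])
    def test_tau_recovery_on_reported_grid(self, tau, rng):
        """Median relative error of tau below 15% at 5% noise, 27 cycles."""
        n = np.arange(1, 28)
        A, I = 10.0, 8.0
        taus = []
        for _ in range(150):
            y = A + (I - A) * np.exp(-(n - 1) / tau) + rng.normal(0, 0.05 * A, 27)
            taus.append(fit_exponential(y, n).tau_cycles)
        assert abs(np.median(taus) - tau) / tau <= 0.15

    def test_ai_recovery_on_reported_grid(self, rng):
        n = np.arange(1, 28)
        for ai_true in (-0.16, 0.09):
            I = 8.0
            A = I * (1 + ai_true) / (1 - ai_true)
            ais = []
            for _ in range(150):
                y = A + (I - A) * np.exp(-(n - 1) / 2.0) + rng.normal(0, 0.05 * A, 27)
                ais.append(fit_exponential(y, n).AI)
            assert abs(np.median(ais) - ai_true) <= 0.05


class TestSteadyState:
    @staticmethod
    def series(pp, mean_ap=None):
        pp = np.asarray(pp, dtype=float)
        if mean_ap is None:
            mean_ap = np.zeros_like(pp)
        return CycleSeries("head", pp, mean_ap - mean_ap[0], pp.size)

    def test_constant_pp(self):
        ss = steady_state(self.series(np.full(27, 10.0)))
        assert ss.mean_pp == pytest.approx(10.0)
        assert ss.n_cycles_averaged == 13  # cycles 15..27 inclusive

    def test_closed_form_envelope_mean(self):
        """Envelope (A=12, I=8, tau=2): mean PP over 15-27 within 0.1% of A."""
        n = np.arange(1, 28)
        pp = 12.0 + (8.0 - 12.0) * np.exp(-(n - 1) / 2.0)
        expected = np.mean(pp[14:27])  # closed-form window mean
        ss = steady_state(self.series(pp))
        assert ss.mean_pp == pytest.approx(expected, rel=1e-12)
        assert abs(ss.mean_pp - 12.0) / 12.0 < 0.001

    def test_window_outside_series_errors(self):
        with pytest.raises(ValueError, match="outside"):
            steady_state(self.series(np.ones(10)), window=(15, 27))


class TestAverageTrials:
    def test_identical_series_unchanged(self):
        s = TestSteadyState.series(np.linspace(8, 12, 27))
        avg = average_trials([s, s])
        np.testing.assert_allclose(avg.pp, s.pp)

    def test_elementwise_mean(self):
        a = TestSteadyState.series(np.full(10, 2.0))
        b = TestSteadyState.series(np.full(10, 4.0))
        np.testing.assert_allclose(average_trials([a, b]).pp, 3.0)

    def test_mismatched_lengths_rejected(self):
        a = TestSteadyState.series(np.ones(10))
        b = TestSteadyState.series(np.ones(12))
        with pytest.raises(ValueError, match="mismatched"):
            average_trials([a, b])

    def test_averaging_reduces_noise_sqrt2(self, rng):
        """SD of the two-trial average shrinks by ~sqrt(2) (Monte-Carlo)."""
        sds_single, sds_avg = [], []
        for _ in range(200):
            a = rng.normal(10, 1.0, 27)
            b = rng.normal(10, 1.0, 27)
            sds_single.append(np.std(a))
            sds_avg.append(np.std((a + b) / 2))
        ratio = np.mean(sds_single) / np.mean(sds_avg)
        assert ratio == pytest.approx(np.sqrt(2), rel=0.05)
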