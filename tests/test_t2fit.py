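"""T2 estimation: log-linear baseline and Rician maximum likelihood."""

import numpy as np
import pytest
from scipy.special import i0

from cardiomad.phantom import default_echo_times, simulate_rician_signal
from cardiomad.t2fit import (EchoSeries, MonoExpDecayModel, fit_loglinear,
                             fit_map, fit_rician_mle, rician_loglik)

TE = default_echo_times()


class TestLogLinear:
    def test_two_point_closed_form(self):
        # T2 = delta TE / ln(M1/M2) for two echoes
        t2, a = fit_loglinear(np.array([100.0, 36.788]), np.array([15.0, 76.6]))
        assert t2 == pytest.approx(61.6, abs=0.05)
        assert a == pytest.approx(100.0 * np.exp(15.0 / t2), rel=1e-9)

    def test_noiseless_nine_echo_recovery(self):
        t2, a = fit_loglinear(500.0 * np.exp(-TE / 60.0), TE)
        assert t2 == pytest.approx(60.0, rel=1e-12)
        assert a == pytest.approx(500.0, rel=1e-12)

    def test_constant_magnitudes_flagged(self):
        t2, a = fit_loglinear(np.full(9, 50.0), TE)
        assert np.isnan(t2) and np.isnan(a)

    def test_nonpositive_magnitude_flagged(self):
        m = 500.0 * np.exp(-TE / 60.0)
        m[3] = 0.0
        t2, _ = fit_loglinear(m, TE)
        assert np.isnan(t2)

    def test_non_increasing_echoes_rejected(self):
        with pytest.raises(ValueError):
            fit_loglinear(np.ones(3), np.array([15.0, 10.0, 20.0]))


class TestRicianLoglik:
    def test_rayleigh_limit(self):
        # nu -> 0: density reduces termwise to Rayleigh log(M/sigma^2) - M^2/(2 sigma^2)
        m = np.full(9, 5.0)
        ll = rician_loglik((1e-12, 60.0, 10.0), m, TE)
        expected = np.sum(np.log(m / 100.0) - m**2 / 200.0)
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_no_overflow_at_huge_bessel_argument(self):
        nu = 1e6 * np.exp(-TE / 60.0)
        ll = rician_loglik((1e6, 60.0, 1.0), nu, TE)  # M*nu/sigma^2 ~ 1e12
        assert np.isfinite(ll)

    def test_matches_naive_formula_at_small_argument(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, t2, sig = rng.uniform(1, 5), rng.uniform(40, 90), rng.uniform(2, 9)
            m = rng.uniform(0.5, 6.0, TE.size)
            naive = np.sum(np.log(m) - 2 * np.log(sig)
                           - (m**2 + (a * np.exp(-TE / t2))**2) / (2 * sig**2)
                           + np.log(i0(m * a * np.exp(-TE / t2) / sig**2)))
            assert rician_loglik((a, t2, sig), m, TE) == pytest.approx(naive, rel=1e-10)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(ValueError):
            rician_loglik((0.0, 60.0, 1.0), np.ones(9), TE)


class TestRicianMLE:
    def test_noiseless_recovery(self):
        fit = fit_rician_mle(500.0 * np.exp(-TE / 60.0), TE)
        assert fit.T2_ms == pytest.approx(60.0, rel=1e-3)
        assert fit.converged

    def test_loglik_not_below_initialiser(self):
        m = simulate_rician_signal(np.tile(500.0 * np.exp(-TE / 60.0), (500, 1)),
                                   25.0, seed=3)
        fit = fit_rician_mle(m, TE)
        t2_ll, a_ll = fit_loglinear(m, TE)
        for i in range(0, 500, 25):
            if not np.isfinite(t2_ll[i]):
                continue
            sig0 = np.sqrt(np.mean((m[i] - a_ll[i] * np.exp(-TE / t2_ll[i]))**2))
            ll0 = rician_loglik((a_ll[i], np.clip(t2_ll[i], 1.01, 495.0),
                                 max(sig0, 1e-3 * a_ll[i])), m[i], TE)
            assert fit.loglik[i] >= ll0 - 1e-6

    def test_scale_equivariance(self):
        m = simulate_rician_signal(500.0 * np.exp(-TE / 55.0), 20.0, seed=5)
        f1 = fit_rician_mle(m, TE)
        f2 = fit_rician_mle(7.5 * m, TE)
        assert f2.T2_ms == pytest.approx(f1.T2_ms, rel=1e-5)
        assert f2.A / f1.A == pytest.approx(7.5, rel=1e-5)
        assert f2.sigma / f1.sigma == pytest.approx(7.5, rel=1e-4)

    @pytest.mark.parametrize("t2", [45.0, 60.0, 80.0, 110.0])
    @pytest.mark.parametrize("snr", [20.0, 40.0])
    def test_median_bias_small_at_moderate_snr(self, t2, snr):
        nu = 500.0 * np.exp(-TE / t2)
        m = simulate_rician_signal(np.tile(nu, (2000, 1)), 500.0 / snr, seed=17)
        fit = fit_rician_mle(m, TE)
        assert abs(np.median(fit.T2_ms) - t2) / t2 < 0.03

    def test_loglinear_bias_positive_and_larger_at_low_snr(self):
        # near the noise floor the Rayleigh offset inflates log-linear T2
        nu = 500.0 * np.exp(-TE / 60.0)
        m = simulate_rician_signal(np.tile(nu, (10_000, 1)), 100.0, seed=21)
        fit = fit_rician_mle(m, TE)
        t2_ll, _ = fit_loglinear(m, TE)
        bias_ll = np.nanmean(np.clip(t2_ll, None, 500.0)) - 60.0
        bias_mle = fit.T2_ms.mean() - 60.0
        assert bias_ll > 0
        assert abs(bias_mle) < bias_ll

    def test_all_zero_magnitudes_rejected(self):
        with pytest.raises(ValueError):
            fit_rician_mle(np.zeros(9), TE)


class TestFitMap:
    def test_roundtrip_mean_within_one_percent(self, highsnr_fit):
        spec, _, truth, t2map, _ = highsnr_fit
        vals = t2map.T2_ms[t2map.mask & t2map.converged]
        assert vals.mean() == pytest.approx(spec.baseline_T2_ms, rel=0.01)

    def test_single_pixel_mask(self, noiseless_subject):
        _, series, truth = noiseless_subject
        mask = np.zeros(series.grid_shape, dtype=bool)
        idx = tuple(np.argwhere(truth.myocardium_mask)[0])
        mask[idx] = True
        t2map = fit_map(series, mask=mask)
        assert np.isfinite(t2map.T2_ms).sum() == 1

    def test_methods_agree_on_noiseless_data(self, noiseless_subject):
        _, series, _ = noiseless_subject
        m_ll = fit_map(series, method="loglinear")
        m_ml = fit_map(series, method="rician_mle")
        sel = m_ll.mask
        assert np.allclose(m_ll.T2_ms[sel], m_ml.T2_ms[sel], rtol=1e-3)

    def test_empty_mask_rejected(self, noiseless_subject):
        _, series, _ = noiseless_subject
        with pytest.raises(ValueError):
            fit_map(series, mask=np.zeros(series.grid_shape, dtype=bool))


class TestEchoSeriesAndModel:
    def test_series_validation(self):
        with pytest.raises(ValueError):
            EchoSeries(magnitudes=np.ones((4, 8)), echo_times_ms=TE)
        with pytest.raises(ValueError):
            EchoSeries(magnitudes=-np.ones((4, 9)), echo_times_ms=TE)

    def test_model_results_summary(self):
        m = simulate_rician_signal(400.0 * np.exp(-TE / 70.0), 10.0, seed=2)
        res = MonoExpDecayModel(m, TE).fit()
        assert res.T2_ms == pytest.approx(70.0, rel=0.15)
        assert "T2 [ms]" in res.summary()
        assert res.predict().shape == TE.shape
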