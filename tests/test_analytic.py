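import numpy as np
import pytest

from ricepop import (
    GaussianCorrelation,
    NeuronConfig,
    RCFilteredOUCorrelation,
    Sinusoid,
    Step,
    StimulusSpec,
    conditional_rate,
    correlation_peak,
    linear_response_mean,
    linear_response_variance,
    network_input_moments,
    nonlinear_rate_mean,
    nonlinear_rate_variance,
    spike_triggered_average,
    spike_triggered_covariance,
    stationary_rate,
    step_response_mean,
    step_response_variance,
)
from ricepop.analytic import _upcross_rate_perms, _upcross_rate_perms_quad


class TestStationaryRate:
    def test_hand_value(self, ga_cfg):
        # 1000/(2 pi tau_V) exp(-psi^2/(2 sigma_V^2)) with tau_V=10, ratio 1
        expected = 1000.0 / (2 * np.pi * 10.0) * np.exp(-0.5)
        assert stationary_rate(ga_cfg) == pytest.approx(expected, rel=1e-12)

    def test_quadrature_agreement(self):
        for psi, a, b, c, d in [(1.0, 1.0, 0.01, 0.0, 0.0),
                                (2.0, 0.5, 0.02, 0.003, 0.001),
                                (0.5, 2.0, 0.05, -0.01, -0.02)]:
            assert _upcross_rate_perms(psi, a, b, c, d) == pytest.approx(
                _upcross_rate_perms_quad(psi, a, b, c, d), rel=1e-9)

    def test_decreasing_in_threshold(self, ga_model):
        rates = [stationary_rate(NeuronConfig(psi, 10.0, ga_model))
                 for psi in np.linspace(0.0, 3.0, 7)]
        assert np.all(np.diff(rates) < 0)
        assert rates[0] == pytest.approx(1000.0 / (2 * np.pi * 10.0))

    def test_mean_offset_lowers_effective_threshold(self, ga_cfg):
        assert stationary_rate(ga_cfg, mean_offset=0.3) > stationary_rate(ga_cfg)
        shifted = NeuronConfig(0.7, 10.0, ga_cfg.voltage_model)
        assert stationary_rate(ga_cfg, mean_offset=0.3) == pytest.approx(
            stationary_rate(shifted))


class TestLinearResponses:
    def test_mean_channel_limits(self, ga_cfg):
        nu1_0 = linear_response_mean(1e-9, ga_cfg)
        model = ga_cfg.voltage_model
        nu0 = stationary_rate(ga_cfg)
        assert abs(nu1_0) == pytest.approx(nu0 * 1.0 / model.variance, rel=1e-6)
        # finite, real-amplitude high-frequency limit
        hf = abs(linear_response_mean(1e6, ga_cfg))
        assert np.isfinite(hf) and hf > 0

    def test_mean_dc_matches_rate_derivative(self, ga_cfg):
        eps = 1e-6
        fd = (stationary_rate(ga_cfg, eps) - stationary_rate(ga_cfg, -eps)) / (2 * eps)
        assert abs(linear_response_mean(1e-9, ga_cfg)) == pytest.approx(fd, rel=1e-6)

    def test_variance_dc_matches_sigma_derivative(self, ou_cfg, ou_model):
        s = np.sqrt(ou_model.sigma2_current)
        eps = 1e-5
        def rate_at(ds):
            m = RCFilteredOUCorrelation((s + ds) ** 2, ou_model.tau_i,
                                        ou_model.tau_m)
            return stationary_rate(NeuronConfig(ou_cfg.threshold, ou_cfg.tau_m, m))
        fd = (rate_at(eps) - rate_at(-eps)) / (2 * eps)
        dc = linear_response_variance(1e-9, ou_cfg, ou_model.tau_i)
        assert np.real(dc) == pytest.approx(fd, rel=1e-5)
        assert abs(np.imag(dc)) < 1e-6 * abs(dc)

    def test_shape_independence_of_mean_channel(self, ou_cfg, ou_model):
        ga = GaussianCorrelation(ou_model.variance, ou_model.effective_width)
        ga_cfg = NeuronConfig(ou_cfg.threshold, ou_cfg.tau_m, ga)
        freqs = np.logspace(-1, 3, 30)
        np.testing.assert_allclose(linear_response_mean(freqs, ou_cfg),
                                   linear_response_mean(freqs, ga_cfg),
                                   rtol=1e-12)

    def test_variance_channel_requires_ou_voltage(self, ga_cfg):
        with pytest.raises(ValueError, match="rc_filtered_ou"):
            linear_response_variance(10.0, ga_cfg, 5.0)


class TestNonlinear:
    def test_zero_amplitude_is_stationary(self, ga_cfg):
        t = np.linspace(0, 50, 11)
        stim = StimulusSpec("mean", Sinusoid(20.0, 1e-14))
        np.testing.assert_allclose(nonlinear_rate_mean(t, stim, ga_cfg),
                                   stationary_rate(ga_cfg), rtol=1e-6)

    def test_linearizes_for_small_amplitude(self, ga_cfg):
        f, a = 20.0, 0.01
        t = np.linspace(0, 50, 101)
        stim = StimulusSpec("mean", Sinusoid(f, a))
        nl = nonlinear_rate_mean(t, stim, ga_cfg)
        nu1 = linear_response_mean(f, ga_cfg)
        lin = stationary_rate(ga_cfg) + a * np.imag(
            nu1 * np.exp(1j * 2 * np.pi * f / 1000.0 * t))
        assert np.max(np.abs(nl - lin)) < 1e-3 * a * abs(nu1) * 50

    def test_variance_modulation_fundamental_matches_linear(self, ou_cfg,
                                                            ou_model):
        f, a = 10.0, 0.02
        period = 1000.0 / f
        t = np.arange(0.0, period, period / 256)
        stim = StimulusSpec("variance", Sinusoid(f, a))
        nl = nonlinear_rate_variance(t, stim, ou_cfg, ou_model.tau_i)
        coef = 2 * np.mean(nl * np.exp(-1j * 2 * np.pi * f / 1000.0 * t))
        pred = linear_response_variance(f, ou_cfg, ou_model.tau_i) * a
        # stimulus a sin(wt) -> fundamental coefficient -i * a * nu1
        assert coef == pytest.approx(-1j * pred, rel=2e-2)


class TestSteps:
    def test_mean_step_jump_and_plateau(self, ga_cfg):
        a = 0.05
        t = np.array([-5.0, 1e-9, 1e5])
        r = step_response_mean(t, a, ga_cfg)
        assert r[0] == 0.0
        assert r[1] == pytest.approx(a * abs(linear_response_mean(1e9, ga_cfg)),
                                     rel=1e-5)
        assert r[2] == pytest.approx(
            a * abs(linear_response_mean(1e-9, ga_cfg)), rel=1e-5)

    def test_mean_step_single_exponential(self, ga_cfg):
        a = 0.05
        t = np.linspace(0.5, 60, 120)
        r = step_response_mean(t, a, ga_cfg)
        plateau = step_response_mean(np.array([1e6]), a, ga_cfg)[0]
        resid = np.log(np.abs(plateau - r[:60]))
        slopes = np.diff(resid) / np.diff(t[:60])
        np.testing.assert_allclose(-1.0 / slopes, ga_cfg.tau_m, rtol=1e-6)

    def test_variance_step_jump_and_plateau(self, ou_cfg, ou_model):
        ds = 0.1
        t = np.array([1e-9, 1e5])
        r = step_response_variance(t, ds, ou_cfg, ou_model.tau_i)
        hf = abs(linear_response_variance(1e7, ou_cfg, ou_model.tau_i))
        dc = np.real(linear_response_variance(1e-9, ou_cfg, ou_model.tau_i))
        assert r[0] == pytest.approx(ds * hf, rel=1e-4)
        assert r[1] == pytest.approx(ds * dc, rel=1e-4)

    def test_variance_step_degenerate_time_constants(self):
        m = RCFilteredOUCorrelation(2.0, 10.0, 10.0)
        cfg = NeuronConfig(1.0, 10.0, m)
        r = step_response_variance(np.linspace(0, 50, 6), 0.1, cfg, 10.0)
        assert np.all(np.isfinite(r))


class TestPairsAndSpikeTriggered:
    def test_conditional_rate_peak_matches_closed_form(self, ga_cfg):
        c = 0.05
        curve = conditional_rate(np.array([0.0]), c, ga_cfg)
        excess = curve.values[0] - stationary_rate(ga_cfg)
        assert excess == pytest.approx(correlation_peak(c, ga_cfg), rel=1e-9)

    def test_peak_linear_in_c(self, ga_cfg):
        p1 = correlation_peak(0.02, ga_cfg)
        p2 = correlation_peak(0.04, ga_cfg)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_conditional_rate_decays_to_baseline(self, ga_cfg):
        curve = conditional_rate(np.array([200.0]), 0.1, ga_cfg)
        assert curve.values[0] == pytest.approx(stationary_rate(ga_cfg),
                                                rel=1e-6)

    def test_sta_at_zero_lag_is_threshold(self, ga_cfg):
        sta = spike_triggered_average(np.array([0.0]), ga_cfg)
        assert sta.values[0] == pytest.approx(ga_cfg.threshold, rel=1e-12)

    def test_sta_vanishes_at_large_lag(self, ga_cfg):
        sta = spike_triggered_average(np.array([150.0]), ga_cfg)
        assert abs(sta.values[0]) < 1e-8

    def test_sta_undershoot_before_spike(self, ga_cfg):
        lags = np.linspace(0, 60, 301)
        sta = spike_triggered_average(lags, ga_cfg)
        assert sta.values.min() < 0

    def test_stc_zero_on_diagonal_at_spike(self, ga_cfg):
        assert spike_triggered_covariance(0.0, 0.0, ga_cfg) == pytest.approx(
            0.0, abs=1e-12)

    def test_stc_symmetric_and_asymptotic(self, ga_cfg):
        l1 = np.array([3.0, 10.0, 200.0])
        l2 = np.array([7.0, 4.0, 205.0])
        a = spike_triggered_covariance(l1, l2, ga_cfg)
        b = spike_triggered_covariance(l2, l1, ga_cfg)
        np.testing.assert_allclose(a, b, rtol=1e-12)
        model = ga_cfg.voltage_model
        assert a[2] == pytest.approx(model.evaluate(5.0), rel=1e-6)


class TestNetworkMoments:
    def test_hand_values(self):
        mu, var = network_input_moments(rate_exc=10.0, rate_inh=8.0, K=1000,
                                        J=0.2)
        # mean sqrt(K) J (nu_E - nu_I), variance J^2 (nu_E + nu_I)
        assert mu == pytest.approx(np.sqrt(1000) * 0.2 * 2.0)
        assert var == pytest.approx(0.04 * 18.0)

    def test_antisymmetric_modulation_moves_mean_only(self):
        mu0, var0 = network_input_moments(10.0, 10.0, 900, 0.1)
        mu1, var1 = network_input_moments(10.0, 10.0, 900, 0.1, delta=1.0,
                                          channel="mean")
        assert mu1 > mu0 and var1 == pytest.approx(var0)

    def test_symmetric_modulation_moves_variance_only(self):
        mu0, var0 = network_input_moments(10.0, 10.0, 900, 0.1)
        mu1, var1 = network_input_moments(10.0, 10.0, 900, 0.1, delta=1.0,
                                          channel="variance")
        assert var1 > var0 and mu1 == pytest.approx(mu0)
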