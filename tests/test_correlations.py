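import numpy as np
import pytest

from ricepop import (
    GaussianCorrelation,
    NonEmbeddableError,
    NonRealizableCorrelationError,
    NonSmoothModelError,
    OUCurrentCorrelation,
    RCFilteredOUCorrelation,
    TabulatedCorrelation,
    make_correlation_model,
    membrane_filter_signal,
    rc_filter_correlation,
    synthesize_ensemble,
    synthesize_path,
)


class TestModels:
    def test_zero_lag_is_variance(self, ga_model, ou_model):
        assert ga_model.evaluate(0.0) == pytest.approx(ga_model.variance)
        assert ou_model.evaluate(0.0) == pytest.approx(ou_model.variance)

    def test_even_in_lag(self, ga_model, ou_model):
        taus = np.linspace(0.1, 40, 17)
        for m in (ga_model, ou_model):
            np.testing.assert_allclose(m.evaluate(taus), m.evaluate(-taus))

    def test_gaussian_effective_width_is_width_parameter(self):
        m = GaussianCorrelation(2.5, 7.0)
        assert m.effective_width == pytest.approx(7.0)

    def test_rc_filtered_ou_closed_forms(self):
        m = RCFilteredOUCorrelation(2.0, 5.0, 10.0)
        # variance sigma^2 tau_i / (tau_i + tau_m)
        assert m.variance == pytest.approx(2.0 * 5.0 / 15.0)
        # effective width sqrt(tau_i tau_m)
        assert m.effective_width == pytest.approx(np.sqrt(50.0))

    def test_rc_filtered_matches_numeric_filter_route(self):
        current = OUCurrentCorrelation(2.0, 5.0)
        closed = RCFilteredOUCorrelation(2.0, 5.0, 10.0)
        numeric = rc_filter_correlation(current, 10.0)
        taus = np.linspace(0, 60, 31)
        np.testing.assert_allclose(
            numeric.evaluate(taus), closed.evaluate(taus), rtol=1e-6,
            atol=1e-9,
        )

    def test_degenerate_equal_time_constants_continuous(self):
        taus = np.linspace(0, 40, 41)
        exact = RCFilteredOUCorrelation(1.0, 8.0, 8.0).evaluate(taus)
        near = RCFilteredOUCorrelation(1.0, 8.0 + 1e-7, 8.0).evaluate(taus)
        np.testing.assert_allclose(near, exact, rtol=1e-5)

    def test_ou_current_curvature_raises(self):
        with pytest.raises(NonSmoothModelError):
            OUCurrentCorrelation(1.0, 5.0).curvature0

    def test_spectrum_nonnegative_and_integrates_to_variance(self, ga_model,
                                                            ou_model):
        omega = np.linspace(-40, 40, 200_001)
        for m in (ga_model, ou_model):
            s = m.spectrum(omega)
            assert np.all(s >= 0)
            var = np.trapezoid(s, omega) / (2 * np.pi)
            assert var == pytest.approx(m.variance, rel=1e-3)

    def test_factory(self):
        m = make_correlation_model("gaussian", variance=1.0, corr_time=5.0)
        assert isinstance(m, GaussianCorrelation)
        with pytest.raises(ValueError):
            make_correlation_model("nope", variance=1.0, corr_time=5.0)

    def test_scaled_variance(self, ga_model):
        m2 = ga_model.scaled(4.0)
        assert m2.variance == pytest.approx(4.0 * ga_model.variance)
        assert m2.effective_width == pytest.approx(ga_model.effective_width)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            GaussianCorrelation(-1.0, 5.0)
        with pytest.raises(ValueError):
            RCFilteredOUCorrelation(1.0, 0.0, 5.0)


class TestTabulated:
    def test_round_trip_gaussian(self, ga_model):
        lags = np.arange(0.0, 80.0, 0.25)
        tab = TabulatedCorrelation(lags, ga_model.evaluate(lags))
        taus = np.linspace(0, 50, 101)
        np.testing.assert_allclose(tab.evaluate(taus), ga_model.evaluate(taus),
                                   atol=1e-6)
        assert tab.effective_width == pytest.approx(10.0, rel=1e-3)

    def test_non_realizable_rejected(self):
        lags = np.arange(0.0, 50.0, 0.5)
        # a top-hat-like correlation has strongly negative spectral lobes
        values = np.where(lags < 10.0, 1.0, 0.0)
        with pytest.raises(NonRealizableCorrelationError):
            TabulatedCorrelation(lags, values)

    def test_from_csv(self, tmp_path, ga_model):
        lags = np.arange(0.0, 80.0, 0.25)
        p = tmp_path / "corr.csv"
        with open(p, "w") as fh:
            fh.write("lag_ms,correlation\n")
            for l, v in zip(lags, ga_model.evaluate(lags)):
                fh.write(f"{l},{v}\n")
        tab = TabulatedCorrelation.from_csv(p)
        assert tab.evaluate(5.0) == pytest.approx(ga_model.evaluate(5.0),
                                                  abs=1e-6)


class TestSynthesis:
    def test_sample_covariance_matches_model(self, ga_model):
        paths = synthesize_ensemble(ga_model, duration=400.0, dt=2.0,
                                    master_seed=5, n_trials=4000)
        x = paths - paths.mean()
        for k_lag, tau in ((0, 0.0), (5, 10.0), (10, 20.0)):
            if k_lag:
                emp = np.mean(x[:, :-k_lag] * x[:, k_lag:])
            else:
                emp = np.mean(x * x)
            assert emp == pytest.approx(ga_model.evaluate(tau), abs=0.03)

    def test_deterministic_and_trial_addressable(self, ga_model):
        a = synthesize_ensemble(ga_model, 200.0, 1.0, master_seed=9, n_trials=3)
        b = synthesize_ensemble(ga_model, 200.0, 1.0, master_seed=9, n_trials=5)
        np.testing.assert_array_equal(a, b[:3])
        c = synthesize_ensemble(ga_model, 200.0, 1.0, master_seed=10, n_trials=3)
        assert not np.array_equal(a, c)

    def test_too_coarse_dt_rejected(self, ga_model):
        with pytest.raises(ValueError, match="dt"):
            synthesize_path(ga_model, duration=100.0, dt=5.0, seed=0)

    def test_path_metadata_and_csv(self, tmp_path, ga_model):
        p = synthesize_path(ga_model, duration=100.0, dt=0.5, seed=3)
        assert p.values.size == 200
        assert p.duration == 100.0
        out = tmp_path / "path.csv"
        p.to_csv(out)
        assert out.read_text().count("\n") >= 200

    def test_non_embeddable_raises(self):
        lags = np.arange(0.0, 30.0, 0.5)
        # realizable on the tabulated grid but embedding a short slice of a
        # long-memory-looking table can fail; construct one that does
        values = np.exp(-lags / 8.0) * np.cos(lags)
        try:
            tab = TabulatedCorrelation(lags, values)
        except NonRealizableCorrelationError:
            pytest.skip("table rejected earlier than embedding")
        with pytest.raises((NonEmbeddableError, ValueError)):
            synthesize_path(tab, duration=10.0, dt=0.25, seed=0)


class TestMembraneFilter:
    def test_step_response_exact(self):
        dt, tau = 0.37, 9.0
        t = np.arange(400) * dt
        z = membrane_filter_signal(np.ones(400), dt, tau, initial=0.0)
        np.testing.assert_allclose(z, 1 - np.exp(-t / tau), rtol=1e-10,
                                   atol=1e-12)

    def test_dc_gain_one(self):
        z = membrane_filter_signal(3.5 * np.ones(5000), 0.1, 7.0, initial=3.5)
        np.testing.assert_allclose(z, 3.5, rtol=1e-9)

    def test_sinusoid_gain_and_phase(self):
        dt, tau, f = 0.02, 10.0, 20.0
        omega = 2 * np.pi * f / 1000.0
        t = np.arange(200_000) * dt
        z = membrane_filter_signal(np.sin(omega * t), dt, tau)
        tail = z[100_000:]
        expected = (np.exp(1j * omega * t[100_000:]) / (1 + 1j * omega * tau)).imag
        np.testing.assert_allclose(tail, expected, atol=1e-5)
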