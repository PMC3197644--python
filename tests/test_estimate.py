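import numpy as np
import pytest

from ricepop import (
    Sinusoid,
    StimulusSpec,
    conditional_rate_estimate,
    population_rate,
    simulate_population,
    sta_estimate,
    stationary_rate,
    stc_estimate,
    vector_strength,
)
from ricepop.simulate import SpikeEnsemble


def _toy_ensemble(trials, duration=100.0, dt=0.1, cfg=None):
    return SpikeEnsemble(trials=[np.asarray(t, dtype=float) for t in trials],
                         dt=dt, duration=duration, master_seed=0,
                         stimulus=None, cfg=cfg)


class TestPopulationRate:
    def test_known_counts(self, ga_cfg):
        ens = _toy_ensemble([[5.0, 15.0, 25.0], [5.0, 15.0, 25.0]],
                            duration=30.0, cfg=ga_cfg)
        psth = population_rate(ens, bin_width=10.0)
        np.testing.assert_allclose(psth.rate, [100.0, 100.0, 100.0])
        np.testing.assert_allclose(psth.stderr, 0.0)

    def test_across_trial_stderr(self, ga_cfg):
        ens = _toy_ensemble([[5.0], []], duration=10.0, cfg=ga_cfg)
        psth = population_rate(ens, bin_width=10.0)
        assert psth.rate[0] == pytest.approx(50.0)
        assert psth.stderr[0] == pytest.approx(50.0)

    def test_bin_width_validation(self, ga_cfg):
        ens = _toy_ensemble([[1.0]], duration=10.0, dt=0.5, cfg=ga_cfg)
        with pytest.raises(ValueError):
            population_rate(ens, bin_width=0.1)


class TestVectorStrength:
    def test_perfectly_locked(self, ga_cfg):
        f = 10.0  # period 100 ms
        times = 25.0 + 100.0 * np.arange(30)  # always at phase pi/2
        ens = _toy_ensemble([times], duration=3000.0, cfg=ga_cfg)
        vs = vector_strength(ens, f)
        assert vs.r == pytest.approx(1.0)
        assert vs.mean_phase == pytest.approx(np.pi / 2)

    def test_uniform_phases_near_zero(self, ga_cfg):
        n = 4000
        times = np.linspace(0.01, 999.99, n)
        ens = _toy_ensemble([times], duration=1000.0, cfg=ga_cfg)
        vs = vector_strength(ens, 10.0)
        assert vs.r < 4 * vs.stderr + vs.bias

    def test_min_spikes_enforced(self, ga_cfg):
        ens = _toy_ensemble([[1.0, 2.0]], duration=10.0, cfg=ga_cfg)
        with pytest.raises(ValueError, match="at least"):
            vector_strength(ens, 10.0)

    def test_amplitude_reconstruction(self, ou_cfg):
        f, a = 10.0, 0.15
        stim = StimulusSpec("mean", Sinusoid(f, a))
        ens = simulate_population(stim, ou_cfg, 150, 2000.0, master_seed=21)
        vs = vector_strength(ens, f, amplitude=a)
        from ricepop import linear_response_mean
        pred = abs(linear_response_mean(f, ou_cfg))
        assert abs(vs.response_amplitude - pred) < 4 * vs.response_stderr


class TestConditionalRate:
    def test_independent_trains_flat_at_rate(self, rng):
        duration = 200_000.0
        rate = 0.02  # per ms
        a = np.sort(rng.uniform(0, duration, int(rate * duration)))
        b = np.sort(rng.uniform(0, duration, int(rate * duration)))
        curve = conditional_rate_estimate(a, b, duration, lag_max=20.0,
                                          bin_width=5.0)
        z = (curve.values - 20.0) / curve.stderr
        assert np.max(np.abs(z)) < 4.0

    def test_edge_triggers_excluded(self):
        a = np.array([1.0, 50.0, 99.0])
        b = np.array([50.0])
        curve = conditional_rate_estimate(a, b, 100.0, lag_max=10.0,
                                          bin_width=5.0)
        assert curve.meta["n_triggers"] == 1

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            conditional_rate_estimate(np.array([]), np.array([1.0]), 10.0,
                                      2.0, 1.0)


class TestSpikeTriggered:
    def test_requires_voltage(self, ga_cfg):
        ens = simulate_population(None, ga_cfg, 2, 200.0, master_seed=0)
        with pytest.raises(ValueError, match="keep_voltage"):
            sta_estimate(ens, np.array([0.0, 5.0]))

    def test_sta_at_zero_lag_near_threshold(self, ga_cfg):
        ens = simulate_population(None, ga_cfg, 30, 2000.0, master_seed=13,
                                  keep_voltage=True)
        sta = sta_estimate(ens, np.array([0.0]))
        assert abs(sta.values[0] - ga_cfg.threshold) < max(
            4 * sta.stderr[0], 0.01)

    def test_shuffled_triggers_give_null_sta(self, ga_cfg, rng):
        ens = simulate_population(None, ga_cfg, 30, 2000.0, master_seed=13,
                                  keep_voltage=True)
        shuffled = [np.sort(rng.uniform(30.0, 1970.0, len(t)))
                    for t in ens.trials]
        sta = sta_estimate(ens, np.array([0.0, 10.0, 25.0]),
                           trigger_times=shuffled)
        z = sta.values / sta.stderr
        assert np.max(np.abs(z)) < 4.0

    def test_shuffled_stc_recovers_unconditioned_covariance(self, ga_cfg, rng):
        ens = simulate_population(None, ga_cfg, 40, 2000.0, master_seed=14,
                                  keep_voltage=True)
        shuffled = [np.sort(rng.uniform(30.0, 1970.0, len(t)))
                    for t in ens.trials]
        lags = np.array([0.0, 8.0])
        stc, err = stc_estimate(ens, lags, trigger_times=shuffled)
        model = ga_cfg.voltage_model
        expected = model.evaluate(lags[None, :] - lags[:, None])
        z = (stc - expected) / err
        assert np.max(np.abs(z)) < 4.0
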