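"""Monte-Carlo ground truth: ensembles of independent threshold neurons.

Spikes are detected as upward crossings of the threshold by synthesized
Gaussian voltage paths.  Wherever possible the voltage is synthesized
*directly* from its correlation model (exact stationarity, no filter
transient): the mean-channel signal is added as the analytically
membrane-filtered waveform.  Only the variance channel, where the modulation
multiplies the current before the membrane, integrates the RC equation
numerically (with a burn-in discarded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .analytic import NeuronConfig, Sampled, Sinusoid, Step, StimulusSpec, \
    _filtered_mean_signal
from .correlations import (
    OUCurrentCorrelation,
    RCFilteredOUCorrelation,
    _draw_paths,
    _embedding_eigenvalues,
    membrane_filter_signal,
)


@dataclass
class SpikeEnsemble:
    """Spike times of N independent trials plus simulation metadata."""

    trials: list[NDArray[np.float64]]
    dt: float
    duration: float
    master_seed: int
    stimulus: StimulusSpec | None
    cfg: NeuronConfig = field(repr=False)
    voltages: NDArray[np.float64] | None = field(default=None, repr=False)

    def __post_init__(self):
        for times in self.trials:
            if len(times) and (np.any(np.diff(times) <= 0)
                               or times[0] < 0 or times[-1] >= self.duration):
                raise ValueError("spike times must be strictly increasing in "
                                 "[0, duration)")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trials))

    def pooled_times(self) -> NDArray[np.float64]:
        if not self.trials:
            return np.empty(0)
        return np.concatenate(self.trials)

    def mean_rate_hz(self) -> float:
        return self.n_spikes / (self.n_trials * self.duration) * 1000.0

    def to_frame(self) -> pd.DataFrame:
        trial_idx = np.repeat(
            np.arange(self.n_trials), [len(t) for t in self.trials]
        )
        return pd.DataFrame({"trial": trial_idx, "time_ms": self.pooled_times()})

    def export(self, csv_path, json_path=None) -> None:
        """One-row-per-spike CSV plus a JSON parameter sidecar."""
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            meta = {
                "dt": self.dt,
                "duration": self.duration,
                "n_trials": self.n_trials,
                "master_seed": self.master_seed,
                "threshold": self.cfg.threshold,
                "tau_m": self.cfg.tau_m,
                "voltage_family": self.cfg.voltage_model.family,
                "voltage_variance": self.cfg.voltage_model.variance,
            }
            with open(json_path, "w") as fh:
                json.dump(meta, fh, indent=1, sort_keys=True)


def detect_spikes(values: NDArray[np.float64], dt: float, threshold: float,
                  t0: float = 0.0) -> NDArray[np.float64]:
    """Upward-crossing times of ``threshold``, linearly interpolated.

    A spike sits between samples i, i+1 whenever ``v[i] < psi <= v[i+1]``;
    downward crossings are ignored and a path exactly at threshold never
    fires.  Interpolated times (rather than bin labels) keep phase estimates
    unbiased at high stimulus frequencies.
    """
    v = np.asarray(values, dtype=float)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return t0 + (idx + frac) * dt


def _trial_rngs(master_seed: int, start: int, count: int,
                stream: int = 0) -> list[np.random.Generator]:
    return [
        np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(stream, start + i))
        )
        for i in range(count)
    ]


def simulate_population(
    stim: StimulusSpec | None,
    cfg: NeuronConfig,
    n_trials: int,
    duration: float,
    master_seed: int,
    dt: float | None = None,
    keep_voltage: bool = False,
    chunk_size: int = 256,
) -> SpikeEnsemble:
    """Ensemble of independent neurons driven by a shared stimulus.

    Mean channel: each trial is an exact stationary voltage path plus the
    analytically membrane-filtered signal (the filter's steady state for
    sinusoids, the exact exponential for steps).  Variance channel: each
    trial synthesizes the OU current exactly, multiplies it by the
    deterministic envelope ``1 + (a/sigma) s(t)`` and integrates the RC
    membrane, discarding a burn-in of ``10 max(tau_V, tau_m)``.  Trial ``i``
    is reproducible from ``(master_seed, i)`` alone.
    """
    model = cfg.voltage_model
    if stim is not None and stim.channel == "variance":
        return _simulate_variance_channel(
            stim, cfg, n_trials, duration, master_seed, dt, keep_voltage,
            chunk_size,
        )

    if dt is None:
        dt = model.effective_width / 25.0
    n = int(round(duration / dt))
    dt = duration / n
    t = np.arange(n) * dt
    if stim is None or stim.waveform is None:
        z = np.zeros(n)
    else:
        z, _ = _filtered_mean_signal(t, stim, cfg.tau_m)

    lam = _embedding_eigenvalues(model, n, dt)
    trials: list[NDArray] = []
    kept = [] if keep_voltage else None
    for start in range(0, n_trials, chunk_size):
        count = min(chunk_size, n_trials - start)
        paths = _draw_paths(lam, n, _trial_rngs(master_seed, start, count))
        paths += z
        for row in paths:
            trials.append(detect_spikes(row, dt, cfg.threshold))
        if kept is not None:
            kept.append(paths)
    voltages = np.concatenate(kept, axis=0) if kept is not None else None
    return SpikeEnsemble(trials=trials, dt=dt, duration=duration,
                         master_seed=master_seed, stimulus=stim, cfg=cfg,
                         voltages=voltages)


def _variance_envelope(stim: StimulusSpec, sigma: float, t_stim: NDArray) -> NDArray:
    w = stim.waveform
    if isinstance(w, Sinusoid):
        depth = w.amplitude / sigma
        if depth >= 1.0:
            raise ValueError("variance modulation drives sigma(t) to zero")
        return 1.0 + depth * np.sin(w.omega * t_stim + w.phase)
    if isinstance(w, Step):
        env = 1.0 + (w.amplitude / sigma) * (t_stim >= w.onset_ms)
        if np.any(env <= 0):
            raise ValueError("variance step drives sigma(t) negative")
        return env
    if isinstance(w, Sampled):
        series_t = np.arange(len(w.series)) * w.dt
        env = 1.0 + np.interp(t_stim, series_t, w.series) / sigma
        if np.any(env <= 0):
            raise ValueError("variance waveform drives sigma(t) negative")
        return env
    raise TypeError(f"unsupported waveform {type(w).__name__}")


def _simulate_variance_channel(stim, cfg, n_trials, duration, master_seed,
                               dt, keep_voltage, chunk_size) -> SpikeEnsemble:
    model = cfg.voltage_model
    if not isinstance(model, RCFilteredOUCorrelation):
        raise ValueError("variance-channel simulation needs an OU current "
                         "drive (rc_filtered_ou voltage model)")
    current = OUCurrentCorrelation(model.sigma2_current, model.tau_i)
    sigma = float(np.sqrt(model.sigma2_current))
    if dt is None:
        dt = min(model.tau_i, model.tau_m) / 40.0
    burn = 10.0 * max(model.effective_width, cfg.tau_m)
    burn_n = int(np.ceil(burn / dt))
    n_rec = int(round(duration / dt))
    dt = duration / n_rec
    n_tot = burn_n + n_rec
    t_stim = (np.arange(n_tot) - burn_n) * dt
    env = _variance_envelope(stim, sigma, t_stim)

    lam = _embedding_eigenvalues(current, n_tot, dt)
    trials: list[NDArray] = []
    kept = [] if keep_voltage else None
    for start in range(0, n_trials, chunk_size):
        count = min(chunk_size, n_trials - start)
        xi = _draw_paths(lam, n_tot, _trial_rngs(master_seed, start, count))
        xi *= env
        for row in xi:
            v = membrane_filter_signal(row, dt, cfg.tau_m)[burn_n:]
            trials.append(detect_spikes(v, dt, cfg.threshold))
            if kept is not None:
                kept.append(v)
    voltages = np.vstack(kept) if kept is not None else None
    return SpikeEnsemble(trials=trials, dt=dt, duration=duration,
                         master_seed=master_seed, stimulus=stim, cfg=cfg,
                         voltages=voltages)


def simulate_common_input_pair(
    c: float,
    cfg: NeuronConfig,
    duration: float,
    seed: int,
    dt: float | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Spike trains of two neurons sharing a fraction ``c`` of their input.

    The shared and private components have identical statistics and are
    mixed as ``sqrt(c) * shared + sqrt(1 - c) * private`` so that each
    neuron's marginal voltage correlation is exactly the model's and the
    input correlation coefficient equals ``c`` at every lag.  Mixing voltage
    paths is equivalent to mixing currents because the membrane is linear.
    ``c = 0`` gives independent trains; ``c = 1`` identical ones.
    """
    if not 0 <= c <= 1:
        raise ValueError("c must lie in [0, 1]")
    model = cfg.voltage_model
    if dt is None:
        dt = model.effective_width / 25.0
    n = int(round(duration / dt))
    dt = duration / n
    lam = _embedding_eigenvalues(model, n, dt)
    shared, priv_a, priv_b = _draw_paths(lam, n, _trial_rngs(seed, 0, 3, stream=1))
    va = np.sqrt(c) * shared + np.sqrt(1 - c) * priv_a
    vb = np.sqrt(c) * shared + np.sqrt(1 - c) * priv_b
    return (
        detect_spikes(va, dt, cfg.threshold),
        detect_spikes(vb, dt, cfg.threshold),
    )
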