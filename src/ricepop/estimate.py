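"""Estimators turning spike ensembles into measured population quantities.

Every estimator reports a standard error alongside its point estimate so
that analytic curves can be compared to simulations on a z-score scale.
Standard errors come from the observed across-trial (or across-spike)
variability, not from a Poisson assumption.  Finite-sample bias notes:

* the vector strength of ``n`` unmodulated spikes has expectation
  ``~ sqrt(pi) / (2 sqrt(n))`` rather than zero (reported as ``bias``);
* spike-triggered standard errors treat triggers as independent, which
  slightly understates the error when windows overlap at high rates;
* the conditional-rate estimator restricts trigger spikes to windows fully
  inside the recording, so it carries no edge bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .analytic import ResponseCurve
from .simulate import SpikeEnsemble


@dataclass
class PSTH:
    """Peristimulus time histogram of an ensemble, in spikes/s per bin."""

    bin_edges: NDArray[np.float64]
    rate: NDArray[np.float64]
    stderr: NDArray[np.float64]
    n_trials: int

    @property
    def centers(self) -> NDArray[np.float64]:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def time_averaged_rate(self) -> float:
        return float(self.rate.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.centers, "rate_hz": self.rate,
            "stderr_hz": self.stderr,
        })


def population_rate(ens: SpikeEnsemble, bin_width: float) -> PSTH:
    """Across-trial PSTH: rate = counts / (n_trials bin_width), in spikes/s."""
    if ens.n_trials == 0:
        raise ValueError("empty ensemble")
    if bin_width < ens.dt:
        raise ValueError("bin_width must be at least the simulation dt")
    n_bins = int(np.floor(ens.duration / bin_width + 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.empty((ens.n_trials, n_bins))
    for i, times in enumerate(ens.trials):
        counts[i], _ = np.histogram(times, bins=edges)
    per_trial_rate = counts / bin_width * 1000.0
    rate = per_trial_rate.mean(axis=0)
    stderr = per_trial_rate.std(axis=0, ddof=1) / np.sqrt(ens.n_trials)
    return PSTH(bin_edges=edges, rate=rate, stderr=stderr,
                n_trials=ens.n_trials)


@dataclass
class VectorStrengthResult:
    """Phase locking of pooled spikes to a sinusoid of known frequency."""

    r: float
    mean_phase: float
    stderr: float
    bias: float
    n_spikes: int
    rate_hz: float
    response_amplitude: float | None = None
    response_stderr: float | None = None
    response_phase: float | None = None


def vector_strength(ens: SpikeEnsemble, freq_hz: float,
                    amplitude: float | None = None,
                    min_spikes: int = 20) -> VectorStrengthResult:
    """Resultant length of spike phases; optionally the implied |nu1|.

    Built directly from interpolated spike times (no PSTH binning, hence no
    bin-size bias).  For a rate modulated as ``nu0 (1 + M sin(omega t))``
    the expected resultant length is ``r = M / 2``, so with stimulus
    amplitude ``a`` the linear-response magnitude is reconstructed as
    ``|nu1| = 2 r nu0 / a`` and its phase as ``pi/2 - mean_phase``.
    """
    times = ens.pooled_times()
    n = times.size
    if n < min_spikes:
        raise ValueError(f"need at least {min_spikes} spikes, got {n}")
    omega = 2 * np.pi * freq_hz / 1000.0
    z = np.exp(1j * omega * times)
    resultant = z.mean()
    r = float(np.abs(resultant))
    mean_phase = float(np.angle(resultant))
    stderr = 1.0 / np.sqrt(2.0 * n)
    bias = float(np.sqrt(np.pi) / (2 * np.sqrt(n)))
    rate_hz = ens.mean_rate_hz()
    out = VectorStrengthResult(r=r, mean_phase=mean_phase, stderr=stderr,
                               bias=bias, n_spikes=n, rate_hz=rate_hz)
    if amplitude is not None:
        out.response_amplitude = 2 * r * rate_hz / amplitude
        out.response_stderr = 2 * stderr * rate_hz / amplitude
        out.response_phase = float(np.pi / 2 - mean_phase)
    return out


def conditional_rate_estimate(
    train_a: NDArray[np.float64],
    train_b: NDArray[np.float64],
    duration: float,
    lag_max: float,
    bin_width: float,
) -> ResponseCurve:
    """Cross-correlogram of B spikes around A spikes, in spikes/s.

    Counts are normalized by (number of trigger spikes x bin width), so the
    flat level for independent trains is the firing rate of B.  Trigger
    spikes closer than ``lag_max`` to either edge are excluded.  Positive
    lags mean B fires after A.
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty spike train")
    triggers = a[(a >= lag_max) & (a <= duration - lag_max)]
    if triggers.size == 0:
        raise ValueError("no trigger spikes with a full window inside the recording")
    n_bins = int(round(2 * lag_max / bin_width))
    edges = -lag_max + np.arange(n_bins + 1) * bin_width
    counts = np.zeros((triggers.size, n_bins))
    lo = np.searchsorted(b, triggers - lag_max)
    hi = np.searchsorted(b, triggers + lag_max)
    for i, (t, l, h) in enumerate(zip(triggers, lo, hi)):
        counts[i], _ = np.histogram(b[l:h] - t, bins=edges)
    per_trigger_rate = counts / bin_width * 1000.0
    rate = per_trigger_rate.mean(axis=0)
    if triggers.size > 1:
        stderr = per_trigger_rate.std(axis=0, ddof=1) / np.sqrt(triggers.size)
    else:
        stderr = np.full(n_bins, np.inf)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ResponseCurve(grid=centers, values=rate, stderr=stderr,
                         grid_name="lag_ms", value_name="conditional_rate_hz",
                         meta={"n_triggers": int(triggers.size)})


def _spike_snippets(voltages: NDArray, dt: float,
                    trials: list[NDArray], lag_grid: NDArray) -> NDArray:
    """Matrix of V(t_spike - lag) rows, linearly interpolated.

    Positive lag = before the spike.  Spikes whose full lag window falls
    outside the recording are dropped.
    """
    lag_grid = np.asarray(lag_grid, dtype=float)
    n = voltages.shape[1]
    t_max = (n - 1) * dt
    rows = []
    for trial_idx, times in enumerate(trials):
        if len(times) == 0:
            continue
        t = np.asarray(times)
        ok = (t - lag_grid.max() >= 0) & (t - lag_grid.min() <= t_max)
        t = t[ok]
        if t.size == 0:
            continue
        pos = (t[:, None] - lag_grid[None, :]) / dt
        i0 = np.floor(pos).astype(int)
        frac = pos - i0
        i0 = np.clip(i0, 0, n - 2)
        v = voltages[trial_idx]
        rows.append(v[i0] * (1 - frac) + v[i0 + 1] * frac)
    if not rows:
        raise ValueError("no usable spikes for spike-triggered statistics")
    return np.vstack(rows)


def sta_estimate(ens: SpikeEnsemble, lag_grid: NDArray,
                 trigger_times: list[NDArray] | None = None) -> ResponseCurve:
    """Spike-triggered average voltage with across-spike standard errors.

    ``ens`` must have been simulated with ``keep_voltage=True``.  Passing
    ``trigger_times`` (e.g. shuffled times) replaces the ensemble's spikes
    as triggers -- the shuffled average is a stationarity control that
    should vanish.
    """
    if ens.voltages is None:
        raise ValueError("ensemble was simulated without keep_voltage=True")
    triggers = trigger_times if trigger_times is not None else ens.trials
    snip = _spike_snippets(ens.voltages, ens.dt, triggers, np.asarray(lag_grid))
    mean = snip.mean(axis=0)
    stderr = snip.std(axis=0, ddof=1) / np.sqrt(snip.shape[0])
    return ResponseCurve(grid=np.asarray(lag_grid, dtype=float), values=mean,
                         stderr=stderr, grid_name="lag_ms",
                         value_name="sta_voltage",
                         meta={"n_spikes": int(snip.shape[0]),
                               "lag_sign": "positive=pre-spike"})


def stc_estimate(ens: SpikeEnsemble, lag_grid: NDArray,
                 trigger_times: list[NDArray] | None = None
                 ) -> tuple[NDArray, NDArray]:
    """Spike-triggered voltage covariance matrix over the lag grid.

    Returns ``(stc, stderr)``; symmetric by construction.  With shuffled
    triggers it estimates the unconditioned covariance ``C_V(lag_i - lag_j)``.
    """
    if ens.voltages is None:
        raise ValueError("ensemble was simulated without keep_voltage=True")
    triggers = trigger_times if trigger_times is not None else ens.trials
    snip = _spike_snippets(ens.voltages, ens.dt, triggers, np.asarray(lag_grid))
    n = snip.shape[0]
    dev = snip - snip.mean(axis=0)
    prods = dev[:, :, None] * dev[:, None, :]
    stc = prods.sum(axis=0) / (n - 1)
    stderr = prods.std(axis=0, ddof=1) / np.sqrt(n)
    return stc, stderr
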