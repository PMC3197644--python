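"""Closed-form population responses of threshold (level-crossing) neurons.

A neuron fires whenever its stationary Gaussian voltage ``V(t)`` crosses the
threshold ``psi`` from below.  For a smooth voltage correlation ``C_V`` with
variance ``sigma_V^2 = C_V(0)`` and derivative-process variance
``sigma_V'^2 = -C_V''(0)``, the stationary rate is the Rice formula ::

    nu0 = (1 / (2 pi tau_V)) * exp(-psi^2 / (2 sigma_V^2)),
    tau_V = sigma_V / sigma_V'

which depends on the noise only through the correlation width ``tau_V`` and
the threshold-to-sigma ratio -- not on the shape of ``C_V``.  This module
derives every population-level quantity from Gaussian conditioning on the
crossing event:

* the complete (non-linear) rate under mean or variance modulation,
* the linear frequency-response functions for both channels,
* step responses (instantaneous component + exponential transients),
* the pairwise conditional firing rate under weak common input,
* the spike-triggered average and covariance of the voltage,
* shot-noise input moments of a balanced excitatory/inhibitory network.

All times are milliseconds; rates are returned in spikes/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import integrate
from scipy.special import ndtr  # standard normal CDF

from .correlations import (
    CorrelationModel,
    NonSmoothModelError,
    RCFilteredOUCorrelation,
    membrane_filter_signal,
)

PER_MS_TO_HZ = 1000.0
_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _phi(x):
    return np.exp(-0.5 * np.asarray(x, dtype=float) ** 2) / _SQRT_2PI


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronConfig:
    """Threshold neuron: threshold ``psi``, membrane ``tau_m``, voltage noise.

    ``voltage_model`` is the correlation model of the *voltage* fluctuations
    (current noise already filtered by the membrane); it must be smooth at
    zero lag for any rate computation.  ``psi / sigma_V > 0`` is the
    fluctuation-driven regime the model is valid in.
    """

    threshold: float
    tau_m: float
    voltage_model: CorrelationModel = field(repr=False)

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")

    @property
    def sigma_v(self) -> float:
        return float(np.sqrt(self.voltage_model.variance))

    @property
    def tau_v(self) -> float:
        return self.voltage_model.effective_width

    @property
    def sigma_dv(self) -> float:
        """Standard deviation of dV/dt (units of voltage per ms)."""
        return float(np.sqrt(self.voltage_model.curvature0))


@dataclass(frozen=True)
class Sinusoid:
    freq_hz: float
    amplitude: float
    phase: float = 0.0

    def __post_init__(self):
        if self.freq_hz <= 0:
            raise ValueError("sinusoid frequency must be positive")

    @property
    def omega(self) -> float:
        """Angular frequency in rad/ms."""
        return 2 * np.pi * self.freq_hz / 1000.0

    def __call__(self, t_ms):
        return self.amplitude * np.sin(self.omega * np.asarray(t_ms) + self.phase)


@dataclass(frozen=True)
class Step:
    amplitude: float
    onset_ms: float = 0.0

    def __call__(self, t_ms):
        return self.amplitude * (np.asarray(t_ms, dtype=float) >= self.onset_ms)


@dataclass(frozen=True)
class Sampled:
    series: NDArray[np.float64]
    dt: float


Waveform = Union[Sinusoid, Step, Sampled]


@dataclass(frozen=True)
class StimulusSpec:
    """Which moment of the input current carries the signal, and its waveform.

    In the mean channel the amplitude is a current (same units as the
    voltage, since the membrane filter has unit DC gain); in the variance
    channel the amplitude is an increment of the current *standard
    deviation*.
    """

    channel: Literal["mean", "variance"]
    waveform: Waveform

    def __post_init__(self):
        if self.channel not in ("mean", "variance"):
            raise ValueError("channel must be 'mean' or 'variance'")


@dataclass
class ResponseCurve:
    """Values on a frequency (Hz) or lag (ms) grid, with optional errors."""

    grid: NDArray[np.float64]
    values: NDArray
    stderr: NDArray[np.float64] | None = None
    grid_name: str = "lag_ms"
    value_name: str = "value"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if np.any(self.stderr < 0):
                raise ValueError("stderr must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        d = {self.grid_name: self.grid}
        if np.iscomplexobj(self.values):
            d["value_real"] = self.values.real
            d["value_imag"] = self.values.imag
        else:
            d["value_real"] = self.values
            d["value_imag"] = np.full_like(self.grid, np.nan)
        d["stderr"] = (
            self.stderr if self.stderr is not None else np.full_like(self.grid, np.nan)
        )
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            if self.meta:
                items = " ".join(f"{k}={v}" for k, v in sorted(self.meta.items()))
                fh.write(f"# {items}\n")
            self.to_frame().to_csv(fh, index=False)


# --------------------------------------------------------------------------
# the generalized Rice rate
# --------------------------------------------------------------------------

def _upcross_rate_perms(psi_eff, var_v, var_dv, cov_vdv=0.0, drift=0.0):
    """Upward-crossing rate (per ms) of level ``psi_eff``.

    ``(V, dV/dt)`` are jointly Gaussian with zero mean, variances ``var_v``
    and ``var_dv`` and covariance ``cov_vdv`` (nonzero only when the variance
    is being modulated); ``drift`` is a deterministic velocity added to
    ``dV/dt`` (the time derivative of a mean signal).  Conditioning on
    ``V = psi_eff`` leaves a Gaussian velocity with mean
    ``m = drift + cov_vdv psi_eff / var_v`` and variance
    ``s^2 = var_dv - cov_vdv^2 / var_v``; the rate is the Rice integral
    ``p_V(psi_eff) * E[(velocity)^+]``.
    """
    psi_eff = np.asarray(psi_eff, dtype=float)
    var_v = np.asarray(var_v, dtype=float)
    var_dv = np.asarray(var_dv, dtype=float)
    cov_vdv = np.asarray(cov_vdv, dtype=float)
    drift = np.asarray(drift, dtype=float)
    s2 = var_dv - cov_vdv**2 / var_v
    if np.any(s2 <= 0):
        raise ValueError("degenerate velocity distribution (s^2 <= 0)")
    s = np.sqrt(s2)
    m = drift + cov_vdv * psi_eff / var_v
    density = np.exp(-0.5 * psi_eff**2 / var_v) / np.sqrt(2 * np.pi * var_v)
    u = m / s
    bracket = s * _phi(u) + m * ndtr(u)
    return density * bracket


def _upcross_rate_perms_quad(psi_eff, var_v, var_dv, cov_vdv=0.0, drift=0.0):
    """Adaptive-quadrature route for the same rate (transcription guard)."""
    s2 = var_dv - cov_vdv**2 / var_v
    s = np.sqrt(s2)
    m = drift + cov_vdv * psi_eff / var_v
    density = np.exp(-0.5 * psi_eff**2 / var_v) / np.sqrt(2 * np.pi * var_v)
    val, _ = integrate.quad(
        lambda w: w * np.exp(-0.5 * ((w - m) / s) ** 2) / (s * _SQRT_2PI),
        0.0, m + 12 * s, limit=200,
    )
    return density * val


def stationary_rate(cfg: NeuronConfig, mean_offset: float = 0.0) -> float:
    """Rice rate in spikes/s; ``mean_offset`` shifts the threshold down.

    Depends only on ``tau_V`` and ``(psi - offset) / sigma_V``; strictly
    decreasing in the threshold-to-sigma ratio and maximal (``1/(2 pi
    tau_V)`` per ms) at zero effective threshold.
    """
    model = cfg.voltage_model
    rate = _upcross_rate_perms(
        cfg.threshold - mean_offset, model.variance, model.curvature0
    )
    return float(rate) * PER_MS_TO_HZ


# --------------------------------------------------------------------------
# mean channel
# --------------------------------------------------------------------------

def linear_response_mean(freq_hz: ArrayLike, cfg: NeuronConfig) -> NDArray[np.complex128]:
    """Linear response to a mean-current modulation, (spikes/s) per unit current.

    For a stimulus ``a sin(omega t)`` the rate modulation is
    ``a * Im[nu1(omega) exp(i omega t)]``.  The closed form is ::

        nu1(omega) = nu0 [psi/sigma_V^2 + i omega sqrt(pi/2)/sigma_V']
                     / (1 + i omega tau_m)

    one threshold high-pass against one membrane low-pass, finite at every
    frequency, and independent of the correlation shape (only ``tau_V``,
    ``tau_m`` and ``psi/sigma_V`` enter).  At ``omega = 0`` it equals the
    static susceptibility ``d nu0 / d(mean offset)`` exactly.
    """
    model = cfg.voltage_model
    nu0 = _upcross_rate_perms(cfg.threshold, model.variance, model.curvature0)
    omega = 2 * np.pi * np.asarray(freq_hz, dtype=float) / 1000.0
    sigma_dv = np.sqrt(model.curvature0)
    num = cfg.threshold / model.variance + 1j * omega * np.sqrt(np.pi / 2) / sigma_dv
    return nu0 * num / (1 + 1j * omega * cfg.tau_m) * PER_MS_TO_HZ


def _filtered_mean_signal(t, stim: StimulusSpec, tau_m: float):
    """Membrane-filtered signal Z(t) and its derivative on the grid ``t``."""
    w = stim.waveform
    t = np.asarray(t, dtype=float)
    if isinstance(w, Sinusoid):
        zc = w.amplitude * np.exp(1j * (w.omega * t + w.phase)) / (1 + 1j * w.omega * tau_m)
        return zc.imag, (1j * w.omega * zc).imag
    if isinstance(w, Step):
        rel = t - w.onset_ms
        on = rel >= 0
        z = np.where(on, w.amplitude * (1 - np.exp(-np.clip(rel, 0, None) / tau_m)), 0.0)
        dz = np.where(on, w.amplitude * np.exp(-np.clip(rel, 0, None) / tau_m) / tau_m, 0.0)
        return z, dz
    if isinstance(w, Sampled):
        z_full = membrane_filter_signal(w.series, w.dt, tau_m)
        full_t = np.arange(len(w.series)) * w.dt
        z = np.interp(t, full_t, z_full)
        s = np.interp(t, full_t, w.series)
        return z, (s - z) / tau_m
    raise TypeError(f"unsupported waveform {type(w).__name__}")


def nonlinear_rate_mean(t_grid: ArrayLike, stim: StimulusSpec,
                        cfg: NeuronConfig) -> NDArray[np.float64]:
    """Complete (non-perturbative) rate trajectory for a mean stimulus, spikes/s.

    The membrane-filtered signal ``Z(t)`` offsets the threshold,
    ``psi -> psi - Z(t)``, and its derivative adds a deterministic velocity;
    the generalized Rice rate is then evaluated pointwise.  At zero amplitude
    this is the stationary rate; for small amplitudes it linearizes to
    :func:`linear_response_mean` with an O(amplitude^2) error.  Depolarizing
    and hyperpolarizing half-cycles respond asymmetrically because the rate
    is exponential in the effective threshold.
    """
    if stim.channel != "mean":
        raise ValueError("nonlinear_rate_mean needs a mean-channel stimulus")
    model = cfg.voltage_model
    z, dz = _filtered_mean_signal(t_grid, stim, cfg.tau_m)
    rate = _upcross_rate_perms(
        cfg.threshold - z, model.variance, model.curvature0, drift=dz
    )
    return rate * PER_MS_TO_HZ


# --------------------------------------------------------------------------
# variance channel (Ornstein-Uhlenbeck current drive)
# --------------------------------------------------------------------------

def _require_ou_voltage(cfg: NeuronConfig, tau_i: float) -> RCFilteredOUCorrelation:
    model = cfg.voltage_model
    if not isinstance(model, RCFilteredOUCorrelation):
        raise ValueError(
            "variance-channel closed forms are valid for an Ornstein-Uhlenbeck "
            "current drive only (voltage model must be rc_filtered_ou)"
        )
    if abs(model.tau_i - tau_i) > 1e-9 * tau_i:
        raise ValueError(
            f"tau_i={tau_i} does not match the voltage model's {model.tau_i}"
        )
    if abs(model.tau_m - cfg.tau_m) > 1e-9 * cfg.tau_m:
        raise ValueError("voltage model's tau_m does not match the neuron's")
    return model


def _vc_F(a, b, s2, tau_m, gamma):
    """Double filter integral F = s2/tau_m^2 * 1/(a+b) (1/(a+gamma)+1/(b+gamma)).

    Equals int_0^inf int_0^inf h(s)h(s') e^{-(a-1/tau_m)s -(b-1/tau_m)s'}
    C_I(s-s') ds ds' for the RC kernel h and the OU current correlation --
    the building block of every modulated second moment.
    """
    return s2 / tau_m**2 / (a + b) * (1.0 / (a + gamma) + 1.0 / (b + gamma))


def _vc_moments(t, x_omega, depth, s2, tau_i, tau_m):
    """Exact (A, B, c) = (Var V, Var dV/dt, Cov) under sinusoidal modulation.

    The current is ``q(t) xi(t)`` with ``q = 1 + depth sin(omega t)`` and
    ``xi`` the stationary OU process; the voltage stays exactly Gaussian with
    these time-dependent second moments (all integrals are elementary for
    exponential kernels, including the second-harmonic depth^2 terms).
    ``x_omega = i omega``.
    """
    beta = 1.0 / tau_m
    gamma = 1.0 / tau_i
    e = np.exp(x_omega * np.asarray(t, dtype=float))
    omega = x_omega.imag
    q = 1.0 + depth * np.sin(omega * np.asarray(t, dtype=float))

    F00 = _vc_F(beta, beta, s2, tau_m, gamma)
    Fw0 = _vc_F(beta + x_omega, beta, s2, tau_m, gamma)
    Fww_conj = _vc_F(beta - x_omega, beta + x_omega, s2, tau_m, gamma)
    Fww = _vc_F(beta + x_omega, beta + x_omega, s2, tau_m, gamma)
    g0 = (1.0 / tau_m) / (beta + gamma)
    gw = (1.0 / tau_m) / (beta + gamma + x_omega)

    A = (
        F00
        + 2 * depth * (e * Fw0).imag
        + 0.5 * depth**2 * np.real(Fww_conj)
        - 0.5 * depth**2 * (e * e * Fww).real
    )
    xi_v = s2 * (g0 + depth * (e * gw).imag)
    c = (q * xi_v - A) / tau_m
    B = (q**2 * s2 - 2 * q * xi_v + A) / tau_m**2
    return A, B, c


def nonlinear_rate_variance(t_grid: ArrayLike, stim: StimulusSpec,
                            cfg: NeuronConfig, tau_i: float) -> NDArray[np.float64]:
    """Complete rate trajectory under sinusoidal variance modulation, spikes/s.

    The modulation multiplies the OU current's standard deviation by
    ``1 + (amplitude/sigma) sin(omega t)``; the voltage remains Gaussian with
    exactly computable time-dependent moments, and the generalized Rice rate
    (including the voltage/velocity covariance that a changing variance
    induces) gives the population rate with no further approximation.
    """
    if stim.channel != "variance":
        raise ValueError("nonlinear_rate_variance needs a variance-channel stimulus")
    if not isinstance(stim.waveform, Sinusoid):
        raise ValueError("closed-form variance trajectory supports sinusoids")
    model = _require_ou_voltage(cfg, tau_i)
    sigma = np.sqrt(model.sigma2_current)
    depth = stim.waveform.amplitude / sigma
    if depth >= 1.0:
        raise ValueError(
            "modulation depth drives the instantaneous variance to zero "
            f"(amplitude {stim.waveform.amplitude} >= sigma {sigma})"
        )
    A, B, c = _vc_moments(
        t_grid, 1j * stim.waveform.omega, depth,
        model.sigma2_current, tau_i, cfg.tau_m,
    )
    rate = _upcross_rate_perms(cfg.threshold, A, B, cov_vdv=c)
    return rate * PER_MS_TO_HZ


def _vc_linear_hat(x, s2, tau_i, tau_m):
    """Complex first-order amplitudes (A^, B^, c^) at x = i omega."""
    beta = 1.0 / tau_m
    gamma = 1.0 / tau_i
    A_hat = 2.0 * _vc_F(beta + x, beta, s2, tau_m, gamma)
    g0 = (1.0 / tau_m) / (beta + gamma)
    gw = (1.0 / tau_m) / (beta + gamma + x)
    c_hat = (s2 * (g0 + gw) - A_hat) / tau_m
    B_hat = (2 * s2 - 2 * s2 * (g0 + gw) + A_hat) / tau_m**2
    return A_hat, B_hat, c_hat


def _vc_partials(psi, A0, B0):
    """Partial derivatives of the Rice rate at the stationary moments."""
    f0 = _upcross_rate_perms(psi, A0, B0)
    p_v = np.exp(-0.5 * psi**2 / A0) / np.sqrt(2 * np.pi * A0)
    dA = f0 * (psi**2 / A0 - 1.0) / (2 * A0)
    dB = f0 / (2 * B0)
    dc = p_v * psi / (2 * A0)
    return f0, dA, dB, dc


def _nu1_var_of_x(x, cfg: NeuronConfig, model: RCFilteredOUCorrelation):
    """Per-unit-sigma-increment response as a function of x = i omega (per ms)."""
    s2, tau_i, tau_m = model.sigma2_current, model.tau_i, cfg.tau_m
    A_hat, B_hat, c_hat = _vc_linear_hat(x, s2, tau_i, tau_m)
    _, dA, dB, dc = _vc_partials(cfg.threshold, model.variance, model.curvature0)
    per_depth = dA * A_hat + dB * B_hat + dc * c_hat
    return per_depth / np.sqrt(s2)


def linear_response_variance(freq_hz: ArrayLike, cfg: NeuronConfig,
                             tau_i: float) -> NDArray[np.complex128]:
    """Linear response to a modulation of the current standard deviation.

    Units: (spikes/s) per unit sigma increment; convention as in
    :func:`linear_response_mean` (stimulus ``Delta_sigma sin(omega t)``).
    Derived for an OU current through the RC membrane by linearizing the
    generalized Rice rate in the exact modulated voltage moments.  The result
    combines two high-pass/low-pass pairs (time constants ``tau_m/2`` and the
    harmonic mix of ``tau_m`` and ``tau_I``), is finite and nonzero as
    ``freq -> inf`` regardless of firing rate, and equals ``d nu0 / d sigma``
    at zero frequency.
    """
    model = _require_ou_voltage(cfg, tau_i)
    omega = 2 * np.pi * np.asarray(freq_hz, dtype=float) / 1000.0
    out = _nu1_var_of_x(1j * omega, cfg, model)
    return out * PER_MS_TO_HZ


# --------------------------------------------------------------------------
# step responses
# --------------------------------------------------------------------------

def step_response_mean(t_grid: ArrayLike, amplitude: float,
                       cfg: NeuronConfig) -> NDArray[np.float64]:
    """Linear-regime rate change after a mean-current step at t = 0 (spikes/s).

    Inverse-transforming the mean-channel response against a step gives an
    instantaneous jump to ``a nu1(inf)`` followed by a single exponential
    with the membrane time constant relaxing to the plateau ``a nu1(0)``::

        dnu(t) = a [nu1(0) - (nu1(0) - nu1(inf)) exp(-t/tau_m)],  t >= 0
    """
    model = cfg.voltage_model
    nu0 = _upcross_rate_perms(cfg.threshold, model.variance, model.curvature0)
    sigma_dv = np.sqrt(model.curvature0)
    r0 = nu0 * cfg.threshold / model.variance
    rinf = nu0 * np.sqrt(np.pi / 2) / (sigma_dv * cfg.tau_m)
    t = np.asarray(t_grid, dtype=float)
    resp = r0 - (r0 - rinf) * np.exp(-np.clip(t, 0, None) / cfg.tau_m)
    return amplitude * np.where(t >= 0, resp, 0.0) * PER_MS_TO_HZ


def _simple_poles_variance(tau_i: float, tau_m: float) -> NDArray[np.float64]:
    return np.array([-2.0 / tau_m, -(1.0 / tau_m + 1.0 / tau_i)])


def _contour_residue(h, pole: complex, radius: float, n_nodes: int = 64) -> complex:
    theta = 2 * np.pi * (np.arange(n_nodes) + 0.5) / n_nodes
    z = pole + radius * np.exp(1j * theta)
    return radius * np.mean(h(z) * np.exp(1j * theta))


def step_response_variance(t_grid: ArrayLike, sigma_step: float,
                           cfg: NeuronConfig, tau_i: float) -> NDArray[np.float64]:
    """Linear-regime rate change after a step of the current std dev (spikes/s).

    The variance-channel transfer function is rational in ``i omega`` with
    simple poles at ``-2/tau_m`` and ``-(1/tau_m + 1/tau_I)``; exact partial
    fractions (residues extracted by small-circle contour integration) give
    an instantaneous component plus two exponentials.  The plateau equals
    ``sigma_step * d nu0 / d sigma``; the instantaneous jump grows with the
    stationary firing rate.
    """
    model = _require_ou_voltage(cfg, tau_i)
    tau_i_eff = tau_i
    if abs(1.0 / tau_i - 1.0 / cfg.tau_m) < 1e-7 / cfg.tau_m:
        # coincident poles: nudge tau_I to keep them simple (error O(1e-6))
        tau_i_eff = tau_i * (1 + 1e-6)
        model = RCFilteredOUCorrelation(model.sigma2_current, tau_i_eff, cfg.tau_m)
    poles = _simple_poles_variance(tau_i_eff, cfg.tau_m)

    def h(x):
        return _nu1_var_of_x(x, cfg, model)

    sep = abs(poles[0] - poles[1])
    # high-frequency limit: A^ -> 0, g_omega -> 0
    s2, tau_m = model.sigma2_current, cfg.tau_m
    g0 = (1.0 / tau_m) / (1.0 / tau_m + 1.0 / tau_i_eff)
    _, dA, dB, dc = _vc_partials(cfg.threshold, model.variance, model.curvature0)
    h_inf = (dB * (2 * s2 - 2 * s2 * g0) / tau_m**2 + dc * s2 * g0 / tau_m) / np.sqrt(s2)

    t = np.asarray(t_grid, dtype=float)
    resp = np.full_like(t, h_inf, dtype=float)
    for p in poles:
        radius = 0.25 * min(sep, abs(p))
        r = _contour_residue(h, p, radius)
        resp = resp + np.real(r / p) * (np.exp(p * np.clip(t, 0, None)) - 1.0)
    return sigma_step * np.where(t >= 0, resp, 0.0) * PER_MS_TO_HZ


# --------------------------------------------------------------------------
# pairwise spike correlations
# --------------------------------------------------------------------------

def conditional_rate(lag_grid: ArrayLike, c: float,
                     cfg: NeuronConfig) -> ResponseCurve:
    """Conditional firing rate nu_c(tau) of neuron B given a spike of A.

    Two statistically identical neurons share a fraction ``c`` of their input
    current.  To first order in ``c`` each neuron responds linearly to the
    shared component, and the excess conditional rate is the shared-signal
    power propagated through the mean-channel response ::

        nu_c(tau) - nu0 = c nu0 [ (psi^2/sigma_V^4) C_V(tau)
                                   - (pi/2) (tau_V^2/sigma_V^2) C_V''(tau) ]

    even in the lag, decaying to ``nu0`` at large lags, linear in ``c``.
    """
    if not 0 <= c <= 1:
        raise ValueError("correlation strength c must lie in [0, 1]")
    if c > 0.3:
        warnings.warn(
            f"c={c} is outside the weak-correlation regime; the linear-in-c "
            "result may be inaccurate", stacklevel=2,
        )
    model = cfg.voltage_model
    lag = np.asarray(lag_grid, dtype=float)
    nu0 = _upcross_rate_perms(cfg.threshold, model.variance, model.curvature0)
    sv2 = model.variance
    tau_v2 = sv2 / model.curvature0
    excess = c * nu0 * (
        cfg.threshold**2 / sv2**2 * model.evaluate(lag)
        - (np.pi / 2) * (tau_v2 / sv2) * model.second_derivative(lag)
    )
    values = (nu0 + excess) * PER_MS_TO_HZ
    return ResponseCurve(
        grid=lag, values=values, grid_name="lag_ms",
        value_name="conditional_rate_hz",
        meta={"c": c, "nu0_hz": nu0 * PER_MS_TO_HZ},
    )


def correlation_peak(c: float, cfg: NeuronConfig) -> float:
    """Peak excess conditional rate, nu_c(0) - nu0 = c nu0 (psi^2/sigma_V^2 + pi/2).

    In spikes/s.  Increases with the stationary rate (the exponential rate
    factor dominates the slowly shrinking threshold term) and, at fixed
    ``psi/sigma_V``, decreases with the correlation width ``tau_V``.
    """
    model = cfg.voltage_model
    nu0 = _upcross_rate_perms(cfg.threshold, model.variance, model.curvature0)
    return float(
        c * nu0 * (cfg.threshold**2 / model.variance + np.pi / 2) * PER_MS_TO_HZ
    )


# --------------------------------------------------------------------------
# spike-triggered statistics
# --------------------------------------------------------------------------

def spike_triggered_average(lag_grid: ArrayLike, cfg: NeuronConfig) -> ResponseCurve:
    """Average voltage a lag ``tau`` *before* a spike (positive lag = earlier).

    Conditioning the Gaussian triple ``(V(t - tau), V(t), dV/dt)`` on an
    upward crossing at ``t`` gives exactly ::

        STA(tau) = psi C_V(tau)/sigma_V^2 + sqrt(pi/2) (tau_V/sigma_V) C_V'(tau)

    The first term relaxes toward threshold like the correlation function
    itself (and dominates at low rates); the second, the high-pass
    contribution of the crossing velocity, is negative before the spike and
    produces the rate-dependent pre-spike hyperpolarizing undershoot.
    """
    model = cfg.voltage_model
    lag = np.asarray(lag_grid, dtype=float)
    sv2 = model.variance
    tau_v = model.effective_width
    values = (
        cfg.threshold * model.evaluate(lag) / sv2
        + np.sqrt(np.pi / 2) * (tau_v / np.sqrt(sv2)) * model.derivative(lag)
    )
    return ResponseCurve(
        grid=lag, values=values, grid_name="lag_ms", value_name="sta_voltage",
        meta={"threshold": cfg.threshold},
    )


def spike_triggered_covariance(lag1: ArrayLike, lag2: ArrayLike,
                               cfg: NeuronConfig) -> NDArray[np.float64]:
    """Covariance of the pre-spike voltage at lags (lag1, lag2), broadcasting.

    Exact Gaussian-conditioning result ::

        STC = C_V(lag2 - lag1) - C_V(lag1) C_V(lag2) / sigma_V^2
              + (1 - pi/2) C_V'(lag1) C_V'(lag2) / sigma_V'^2

    symmetric in its arguments, zero on the diagonal at lag 0 (the voltage is
    pinned to threshold at the spike) and approaching the unconditioned
    variance ``sigma_V^2`` at large equal lags.
    """
    model = cfg.voltage_model
    l1 = np.asarray(lag1, dtype=float)
    l2 = np.asarray(lag2, dtype=float)
    sv2 = model.variance
    b0 = model.curvature0
    return (
        model.evaluate(l2 - l1)
        - model.evaluate(l1) * model.evaluate(l2) / sv2
        + (1 - np.pi / 2) * model.derivative(l1) * model.derivative(l2) / b0
    )


# --------------------------------------------------------------------------
# network input moments
# --------------------------------------------------------------------------

def network_input_moments(
    rate_exc: float,
    rate_inh: float,
    K: int,
    J: float,
    delta: float = 0.0,
    channel: Literal["mean", "variance", None] = None,
    psc_shape_factor: float = 1.0,
) -> tuple[float, float]:
    """Shot-noise mean and variance of the net current in a balanced network.

    Each neuron receives K excitatory and K inhibitory inputs with synaptic
    weight ``J/sqrt(K)`` (balanced scaling) and a unit-normalized
    postsynaptic current kernel (``psc_shape_factor`` is the integral of the
    squared kernel).  Then ::

        mean     = sqrt(K) J (nu_E - nu_I)
        variance = J^2 (nu_E + nu_I) * psc_shape_factor

    ``channel='mean'`` perturbs the rates antisymmetrically
    (``nu_E + delta, nu_I - delta``): the mean shifts linearly in ``delta``
    at fixed variance.  ``channel='variance'`` perturbs them symmetrically:
    the variance shifts at fixed mean (exactly fixed in the balanced
    configuration ``nu_E == nu_I``).
    """
    if rate_exc < 0 or rate_inh < 0:
        raise ValueError("rates must be non-negative")
    if K < 1:
        raise ValueError("K must be at least 1")
    ne, ni = float(rate_exc), float(rate_inh)
    if channel == "mean":
        ne, ni = ne + delta, ni - delta
    elif channel == "variance":
        ne, ni = ne + delta, ni + delta
    elif channel is not None:
        raise ValueError("channel must be 'mean', 'variance' or None")
    if ne < 0 or ni < 0:
        raise ValueError("perturbed rates must remain non-negative")
    mean = np.sqrt(K) * J * (ne - ni)
    variance = J**2 * (ne + ni) * psc_shape_factor
    return float(mean), float(variance)
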