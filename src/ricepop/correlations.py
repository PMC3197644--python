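"""Stationary correlation models, membrane filtering, and Gaussian path synthesis.

The voltage of a threshold neuron is modelled as a stationary, zero-mean
Gaussian process.  Everything downstream (firing rates, response functions,
spike statistics) is a functional of the voltage correlation function
``C_V(tau)``, its variance ``C_V(0) = sigma_V**2`` and its curvature at zero
lag ``-C_V''(0)``.  This module provides a small catalogue of correlation
families, the RC membrane filter that maps current-side correlations to
voltage-side ones, and an exact circulant-embedding synthesiser for sample
paths.

Units: time in milliseconds throughout; ``variance`` carries the squared
signal units (mV^2-like for voltage, arbitrary current units squared for
current).  Angular frequencies passed to ``spectrum`` are in rad/ms.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import integrate, interpolate, signal


class NonSmoothModelError(ValueError):
    """Raised when an operation needs a finite curvature at zero lag.

    The Ornstein-Uhlenbeck current correlation has a kink at zero, so the
    effective width and the level-crossing rate are undefined for it until it
    has passed through the membrane filter.
    """


class NonRealizableCorrelationError(ValueError):
    """Raised when a tabulated correlation has a negative power spectrum."""


class NonEmbeddableError(ValueError):
    """Raised when circulant embedding fails (eigenvalues too negative)."""


# --------------------------------------------------------------------------
# model base class
# --------------------------------------------------------------------------

class CorrelationModel(abc.ABC):
    """A stationary correlation function C(tau) with its Fourier pair.

    Subclasses implement :meth:`evaluate` (even in the lag) and
    :meth:`spectrum` (the non-negative power spectral density, the continuous
    Fourier transform of ``evaluate``).  Smooth families also expose
    ``curvature0 = -C''(0) > 0`` and derivative methods used by the
    spike-triggered statistics.
    """

    family: str = "abstract"

    def __init__(self, variance: float, corr_time: float):
        if variance <= 0:
            raise ValueError(f"variance must be positive, got {variance}")
        if corr_time <= 0:
            raise ValueError(f"corr_time must be positive, got {corr_time}")
        self.variance = float(variance)
        self.corr_time = float(corr_time)

    @abc.abstractmethod
    def evaluate(self, lag: ArrayLike) -> NDArray[np.float64]:
        """C(tau) for lag(s) in ms.  Even in the lag; C(0) == variance."""

    @abc.abstractmethod
    def spectrum(self, omega: ArrayLike) -> NDArray[np.float64]:
        """Power spectral density at angular frequency omega (rad/ms)."""

    @property
    def curvature0(self) -> float:
        """-C''(0); positive and finite for smooth (voltage-side) families."""
        raise NonSmoothModelError(
            f"{self.family} correlation is not smooth at zero lag; "
            "curvature0 is undefined (filter it through the membrane first)"
        )

    @property
    def is_smooth(self) -> bool:
        try:
            self.curvature0
        except NonSmoothModelError:
            return False
        return True

    @property
    def effective_width(self) -> float:
        """tau_V = sqrt(C(0) / (-C''(0))) -- curvature-based correlation width.

        Fixed convention: the parabolic fit C(0) - C''(0) tau^2 / 2 ... crosses
        an e-fold-like scale at this tau; the Gaussian family's width parameter
        equals its effective width under this convention.
        """
        return float(np.sqrt(self.variance / self.curvature0))

    def derivative(self, lag: ArrayLike) -> NDArray[np.float64]:
        """dC/dtau (odd in the lag).  Numeric fallback; families override."""
        lag = np.asarray(lag, dtype=float)
        h = self.corr_time * 1e-4
        return (self.evaluate(lag + h) - self.evaluate(lag - h)) / (2 * h)

    def second_derivative(self, lag: ArrayLike) -> NDArray[np.float64]:
        """d^2C/dtau^2 (even in the lag).  Numeric fallback; families override."""
        lag = np.asarray(lag, dtype=float)
        h = self.corr_time * 1e-3
        return (
            self.evaluate(lag + h) - 2 * self.evaluate(lag) + self.evaluate(lag - h)
        ) / h**2

    # -- convenience -------------------------------------------------------
    def scaled(self, factor: float) -> "CorrelationModel":
        """Return a copy with the variance multiplied by ``factor``."""
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{type(self).__name__}(variance={self.variance:g}, "
            f"corr_time={self.corr_time:g})"
        )


class GaussianCorrelation(CorrelationModel):
    """C(tau) = sigma^2 exp(-tau^2 / (2 tau_c^2)).

    The canonical smooth family: infinitely differentiable at zero lag, with
    effective width exactly equal to the width parameter ``tau_c``.
    """

    family = "gaussian"

    def evaluate(self, lag):
        lag = np.asarray(lag, dtype=float)
        return self.variance * np.exp(-(lag**2) / (2 * self.corr_time**2))

    def spectrum(self, omega):
        omega = np.asarray(omega, dtype=float)
        tc = self.corr_time
        return self.variance * tc * np.sqrt(2 * np.pi) * np.exp(-(omega * tc) ** 2 / 2)

    @property
    def curvature0(self) -> float:
        return self.variance / self.corr_time**2

    def derivative(self, lag):
        lag = np.asarray(lag, dtype=float)
        return -lag / self.corr_time**2 * self.evaluate(lag)

    def second_derivative(self, lag):
        lag = np.asarray(lag, dtype=float)
        tc2 = self.corr_time**2
        return (lag**2 / tc2 - 1.0) / tc2 * self.evaluate(lag)

    def scaled(self, factor):
        return GaussianCorrelation(self.variance * factor, self.corr_time)


class OUCurrentCorrelation(CorrelationModel):
    """Ornstein-Uhlenbeck current: C(tau) = sigma^2 exp(-|tau| / tau_I).

    Kinked at zero lag, hence non-smooth: it models the *current* noise and
    must be passed through :func:`rc_filter_correlation` before it can drive
    a threshold neuron.
    """

    family = "ou_current"

    def evaluate(self, lag):
        lag = np.asarray(lag, dtype=float)
        return self.variance * np.exp(-np.abs(lag) / self.corr_time)

    def spectrum(self, omega):
        omega = np.asarray(omega, dtype=float)
        tc = self.corr_time
        return 2 * self.variance * tc / (1 + (omega * tc) ** 2)

    def scaled(self, factor):
        return OUCurrentCorrelation(self.variance * factor, self.corr_time)


class RCFilteredOUCorrelation(CorrelationModel):
    """Ornstein-Uhlenbeck current passed through an RC membrane.

    For current correlation ``sigma_I^2 exp(-|tau|/tau_I)`` and a first-order
    membrane with time constant ``tau_m`` (DC gain one), the voltage
    correlation has the two-exponential closed form ::

        C_V(tau) = sigma_I^2 tau_I / (tau_I^2 - tau_m^2)
                   * (tau_I e^{-|tau|/tau_I} - tau_m e^{-|tau|/tau_m})

    with variance ``sigma_I^2 tau_I / (tau_I + tau_m)``, curvature
    ``-C_V''(0) = sigma_I^2 / (tau_m (tau_I + tau_m))`` and hence effective
    width ``sqrt(tau_I tau_m)``.  The degenerate case ``tau_I == tau_m`` is
    handled by its analytic limit.
    """

    family = "rc_filtered_ou"

    def __init__(self, sigma2_current: float, tau_i: float, tau_m: float):
        if sigma2_current <= 0:
            raise ValueError("current variance must be positive")
        if tau_i <= 0 or tau_m <= 0:
            raise ValueError("tau_i and tau_m must be positive")
        self.sigma2_current = float(sigma2_current)
        self.tau_i = float(tau_i)
        self.tau_m = float(tau_m)
        variance = sigma2_current * tau_i / (tau_i + tau_m)
        super().__init__(variance=variance, corr_time=float(np.sqrt(tau_i * tau_m)))

    @property
    def _degenerate(self) -> bool:
        return abs(self.tau_i - self.tau_m) < 1e-9 * max(self.tau_i, self.tau_m)

    def evaluate(self, lag):
        t = np.abs(np.asarray(lag, dtype=float))
        a, b, s2 = self.tau_i, self.tau_m, self.sigma2_current
        if self._degenerate:
            return 0.5 * s2 * (1 + t / b) * np.exp(-t / b)
        pref = s2 * a / (a**2 - b**2)
        return pref * (a * np.exp(-t / a) - b * np.exp(-t / b))

    def derivative(self, lag):
        lag = np.asarray(lag, dtype=float)
        t = np.abs(lag)
        a, b, s2 = self.tau_i, self.tau_m, self.sigma2_current
        if self._degenerate:
            d = -0.5 * s2 * t / b**2 * np.exp(-t / b)
        else:
            pref = s2 * a / (a**2 - b**2)
            d = pref * (-np.exp(-t / a) + np.exp(-t / b))
        return np.sign(lag) * d

    def second_derivative(self, lag):
        t = np.abs(np.asarray(lag, dtype=float))
        a, b, s2 = self.tau_i, self.tau_m, self.sigma2_current
        if self._degenerate:
            return 0.5 * s2 * (t / b - 1.0) / b**2 * np.exp(-t / b)
        pref = s2 * a / (a**2 - b**2)
        return pref * (np.exp(-t / a) / a - np.exp(-t / b) / b)

    def spectrum(self, omega):
        omega = np.asarray(omega, dtype=float)
        a, b, s2 = self.tau_i, self.tau_m, self.sigma2_current
        return 2 * s2 * a / ((1 + (omega * a) ** 2) * (1 + (omega * b) ** 2))

    @property
    def curvature0(self) -> float:
        return self.sigma2_current / (self.tau_m * (self.tau_i + self.tau_m))

    def scaled(self, factor):
        return RCFilteredOUCorrelation(
            self.sigma2_current * factor, self.tau_i, self.tau_m
        )


class TabulatedCorrelation(CorrelationModel):
    """Correlation model built from sampled (lag, correlation) pairs.

    The table must include lag zero; it is extended evenly to negative lags.
    Evaluation uses a clamped cubic spline (zero slope at lag zero, zero
    beyond the last tabulated lag).  The spectrum is computed once by FFT of
    the even extension; a significantly negative spectrum marks the table as
    a non-realizable correlation function and is rejected.
    """

    family = "tabulated"

    def __init__(self, lags: ArrayLike, values: ArrayLike, *,
                 spectrum_tol: float = 1e-8):
        lags = np.asarray(lags, dtype=float)
        values = np.asarray(values, dtype=float)
        if lags.ndim != 1 or lags.shape != values.shape:
            raise ValueError("lags and values must be matching 1-d arrays")
        order = np.argsort(lags)
        lags, values = lags[order], values[order]
        if lags[0] < 0:
            # fold onto non-negative lags, checking even symmetry loosely
            mask = lags >= 0
            lags, values = lags[mask], values[mask]
        if lags[0] != 0.0:
            raise ValueError("tabulated correlation must include lag 0")
        if not np.all(np.diff(lags) > 0):
            raise ValueError("lags must be strictly increasing")
        self._lags = lags
        self._values = values
        variance = float(values[0])
        # effective width estimate from a parabolic fit near zero (used only
        # as the characteristic time scale for grids)
        corr_time = self._estimate_width(lags, values)
        super().__init__(variance=variance, corr_time=corr_time)
        self._spline = interpolate.CubicSpline(
            lags, values, bc_type=((1, 0.0), "not-a-knot")
        )
        self._validate_spectrum(spectrum_tol)

    @staticmethod
    def _estimate_width(lags, values) -> float:
        c0 = values[0]
        below = np.nonzero(values < c0 * np.exp(-0.5))[0]
        if below.size:
            return float(max(lags[below[0]], lags[1]))
        return float(lags[-1])

    def _validate_spectrum(self, tol: float) -> None:
        dt = float(np.min(np.diff(self._lags)))
        n = int(np.ceil(self._lags[-1] / dt)) + 1
        grid = np.arange(n) * dt
        c = self.evaluate(grid)
        emb = np.concatenate([c, c[-2:0:-1]])
        spec = np.fft.rfft(emb).real * dt
        smax = spec.max()
        if spec.min() < -tol * smax:
            raise NonRealizableCorrelationError(
                "tabulated correlation has a negative power spectrum "
                f"(min {spec.min():.3e} vs max {smax:.3e}); not a valid "
                "stationary process"
            )
        self._spec_grid_omega = 2 * np.pi * np.fft.rfftfreq(emb.size, d=dt)
        self._spec_grid_values = np.clip(spec, 0.0, None)

    def evaluate(self, lag):
        t = np.abs(np.asarray(lag, dtype=float))
        out = np.where(t <= self._lags[-1], self._spline(np.minimum(t, self._lags[-1])), 0.0)
        return out

    def derivative(self, lag):
        lag = np.asarray(lag, dtype=float)
        t = np.abs(lag)
        inside = t <= self._lags[-1]
        d = np.where(inside, self._spline(np.minimum(t, self._lags[-1]), 1), 0.0)
        return np.sign(lag) * d

    def second_derivative(self, lag):
        t = np.abs(np.asarray(lag, dtype=float))
        inside = t <= self._lags[-1]
        return np.where(inside, self._spline(np.minimum(t, self._lags[-1]), 2), 0.0)

    def spectrum(self, omega):
        omega = np.abs(np.asarray(omega, dtype=float))
        return np.interp(
            omega, self._spec_grid_omega, self._spec_grid_values, right=0.0
        )

    @property
    def curvature0(self) -> float:
        c2 = float(self._spline(0.0, 2))
        if not np.isfinite(c2) or c2 >= 0:
            raise NonSmoothModelError(
                "tabulated correlation has no negative curvature at zero lag"
            )
        return -c2

    def scaled(self, factor):
        return TabulatedCorrelation(self._lags, self._values * factor)

    @classmethod
    def from_csv(cls, path) -> "TabulatedCorrelation":
        """Read a two-column CSV with header columns ``lag_ms, correlation``."""
        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        if "lag_ms" not in cols or "correlation" not in cols:
            raise ValueError("CSV must have header columns 'lag_ms, correlation'")
        df.columns = cols
        return cls(df["lag_ms"].to_numpy(), df["correlation"].to_numpy())


class SpectralCorrelation(CorrelationModel):
    """Model defined by an analytic spectrum; C(tau) obtained numerically.

    Used for generic membrane-filtered models (e.g. a Gaussian current through
    the RC filter) where no closed form is carried around.  ``evaluate`` is a
    cubic interpolation of a dense inverse-FFT grid computed once.
    """

    family = "spectral"

    def __init__(self, spectrum_fn: Callable[[NDArray], NDArray],
                 time_scale: float, *, grid_points: int = 1 << 16,
                 span_factor: float = 60.0):
        self._spectrum_fn = spectrum_fn
        dt = time_scale / 200.0
        n = grid_points
        # ensure the lag span covers the decay of the correlation
        while n * dt < span_factor * time_scale:
            n *= 2
        omega = 2 * np.pi * np.fft.rfftfreq(n, d=dt)
        spec = np.asarray(spectrum_fn(omega), dtype=float)
        # inverse continuous FT approximated by the inverse DFT
        c = np.fft.irfft(spec, n=n) / dt
        lags = np.arange(n // 2) * dt
        self._grid_lags = lags
        self._grid_values = c[: n // 2]
        self._spline = interpolate.CubicSpline(lags, self._grid_values)
        variance = float(self._grid_values[0])
        curv = float(
            integrate.quad(
                lambda w: w**2 * float(spectrum_fn(np.array([w]))[0]) / np.pi,
                0, np.inf, limit=400,
            )[0]
        )
        self._curvature0 = curv
        width = float(np.sqrt(variance / curv)) if curv > 0 else time_scale
        super().__init__(variance=variance, corr_time=width)

    def evaluate(self, lag):
        t = np.abs(np.asarray(lag, dtype=float))
        tmax = self._grid_lags[-1]
        return np.where(t <= tmax, self._spline(np.minimum(t, tmax)), 0.0)

    def derivative(self, lag):
        lag = np.asarray(lag, dtype=float)
        t = np.abs(lag)
        tmax = self._grid_lags[-1]
        d = np.where(t <= tmax, self._spline(np.minimum(t, tmax), 1), 0.0)
        return np.sign(lag) * d

    def second_derivative(self, lag):
        t = np.abs(np.asarray(lag, dtype=float))
        tmax = self._grid_lags[-1]
        return np.where(t <= tmax, self._spline(np.minimum(t, tmax), 2), 0.0)

    def spectrum(self, omega):
        return np.asarray(self._spectrum_fn(np.abs(np.asarray(omega, dtype=float))))

    @property
    def curvature0(self) -> float:
        if self._curvature0 <= 0 or not np.isfinite(self._curvature0):
            raise NonSmoothModelError("spectral model has undefined curvature")
        return self._curvature0


# --------------------------------------------------------------------------
# factory / operations
# --------------------------------------------------------------------------

def make_correlation_model(
    family: str,
    variance: float | None = None,
    corr_time: float | None = None,
    table: ArrayLike | None = None,
) -> CorrelationModel:
    """Build a correlation model from the catalogue.

    Parameters
    ----------
    family : {"gaussian", "ou_current", "tabulated"}
        ``gaussian`` and ``ou_current`` need ``variance`` and ``corr_time``;
        ``tabulated`` needs ``table`` (an (n, 2) array of lag/value pairs
        covering lag zero).
    """
    if family == "gaussian":
        return GaussianCorrelation(variance, corr_time)
    if family == "ou_current":
        return OUCurrentCorrelation(variance, corr_time)
    if family == "tabulated":
        if table is None:
            raise ValueError("tabulated family needs a lag/value table")
        table = np.asarray(table, dtype=float)
        return TabulatedCorrelation(table[:, 0], table[:, 1])
    raise ValueError(f"unknown correlation family {family!r}")


def rc_filter_correlation(current_model: CorrelationModel, tau_m: float) -> CorrelationModel:
    """Voltage correlation of ``current_model`` after the RC membrane filter.

    The voltage spectrum is the current spectrum times the squared magnitude
    of the first-order filter ``1 / (1 + i omega tau_m)`` (DC gain one).  For
    an OU current the closed two-exponential form is returned; other families
    go through a numerically inverted spectrum.  The output is smooth at zero
    lag even when the input has a kink.
    """
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    if isinstance(current_model, OUCurrentCorrelation):
        return RCFilteredOUCorrelation(
            current_model.variance, current_model.corr_time, tau_m
        )

    def filtered_spectrum(omega):
        return current_model.spectrum(omega) / (1 + (np.asarray(omega) * tau_m) ** 2)

    scale = max(current_model.corr_time, tau_m)
    return SpectralCorrelation(filtered_spectrum, time_scale=scale)


def effective_width(model: CorrelationModel) -> float:
    """tau_V = sqrt(C(0) / (-C''(0))) for a smooth model (ms)."""
    return model.effective_width


# --------------------------------------------------------------------------
# sample paths
# --------------------------------------------------------------------------

@dataclass
class SamplePath:
    """A synthesized stationary Gaussian path with its provenance."""

    values: NDArray[np.float64]
    dt: float
    duration: float
    seed: int | tuple
    corr_model: CorrelationModel = field(repr=False)

    def __post_init__(self):
        n = int(round(self.duration / self.dt))
        if abs(self.duration / self.dt - n) > 1e-9 or n != len(self.values):
            raise ValueError(
                "path length must equal duration/dt "
                f"(duration={self.duration}, dt={self.dt}, len={len(self.values)})"
            )

    @property
    def times(self) -> NDArray[np.float64]:
        return np.arange(len(self.values)) * self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "value": self.values})

    def to_csv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(
                f"# family={self.corr_model.family} "
                f"variance={self.corr_model.variance:g} "
                f"corr_time={self.corr_model.corr_time:g} "
                f"dt={self.dt:g} seed={self.seed}\n"
            )
            df.to_csv(fh, index=False)


def _embedding_eigenvalues(model: CorrelationModel, n: int, dt: float,
                           tol: float = 1e-8) -> NDArray[np.float64]:
    c = model.evaluate(np.arange(n) * dt)
    emb = np.concatenate([c, c[-2:0:-1]])
    lam = np.fft.fft(emb).real
    lmax = lam.max()
    if lam.min() < -tol * lmax:
        raise NonEmbeddableError(
            f"{model.family} model is not embeddable on this grid "
            f"(min eigenvalue {lam.min():.3e} vs max {lmax:.3e}); "
            "refine dt or extend the duration"
        )
    return np.clip(lam, 0.0, None)


def _draw_paths(lam: NDArray, n: int, rngs: Sequence[np.random.Generator]) -> NDArray:
    """Davies-Harte draw: one row per rng, exact covariance on the grid."""
    m = lam.size
    scale = np.sqrt(lam / m)
    out = np.empty((len(rngs), n))
    block = np.empty((len(rngs), m), dtype=complex)
    for i, rng in enumerate(rngs):
        z = rng.standard_normal(2 * m)
        block[i] = scale * (z[:m] + 1j * z[m:])
    paths = np.fft.fft(block, axis=1)
    out[:] = paths.real[:, :n]
    return out


def synthesize_path(model: CorrelationModel, duration: float, dt: float,
                    seed: int) -> SamplePath:
    """Exact synthesis of a stationary zero-mean Gaussian path.

    Uses circulant embedding (Davies-Harte): the sampled covariance sequence
    is embedded in a circulant matrix whose eigenvalues, obtained by FFT, must
    be non-negative up to a small tolerance; the path then has *exactly* the
    model covariance on the grid.  Identical ``(model, duration, dt, seed)``
    give bit-identical paths.

    Grid rule: for smooth models ``dt <= effective_width / 20`` is enforced so
    that threshold-crossing detection downstream is unbiased; for the kinked
    OU current the rule uses ``corr_time`` instead.
    """
    width = model.effective_width if model.is_smooth else model.corr_time
    if dt > width / 20 * (1 + 1e-12):
        raise ValueError(
            f"dt={dt} too coarse: need dt <= {width / 20:g} "
            "(effective width / 20)"
        )
    n = int(round(duration / dt))
    if abs(duration / dt - n) > 1e-9:
        raise ValueError("duration must be an integer multiple of dt")
    lam = _embedding_eigenvalues(model, n, dt)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = _draw_paths(lam, n, [rng])[0]
    return SamplePath(values=values, dt=dt, duration=duration, seed=seed,
                      corr_model=model)


def synthesize_ensemble(model: CorrelationModel, duration: float, dt: float,
                        master_seed: int, n_trials: int,
                        trial_offset: int = 0) -> NDArray[np.float64]:
    """(n_trials, n) array of independent paths with counter-based seeding.

    Trial ``i`` is drawn from ``SeedSequence(master_seed, spawn_key=(i,))``,
    so any single trial can be regenerated independently of the ensemble
    size or chunking.
    """
    n = int(round(duration / dt))
    lam = _embedding_eigenvalues(model, n, dt)
    rngs = [
        np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(trial_offset + i,))
        )
        for i in range(n_trials)
    ]
    return _draw_paths(lam, n, rngs)


# --------------------------------------------------------------------------
# membrane filter
# --------------------------------------------------------------------------

def membrane_filter_signal(sig: ArrayLike, dt: float, tau_m: float,
                           initial: float = 0.0) -> NDArray[np.float64]:
    """Solve tau_m dz/dt = -z + s(t) on a uniform grid (DC gain one).

    Exact for piecewise-linear input: the update over one step integrates the
    first-order ODE analytically with the input interpolated linearly between
    samples, so a step input reproduces ``a (1 - exp(-t/tau_m))`` to machine
    precision at the sample points and a sinusoid acquires the exact
    steady-state gain ``1/sqrt(1 + (omega tau_m)^2)`` and phase lag
    ``arctan(omega tau_m)``.
    """
    x = np.asarray(sig, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    alpha = np.exp(-dt / tau_m)
    r = tau_m / dt
    b0 = 1.0 - r * (1.0 - alpha)          # weight of x[k+1]
    b1 = r * (1.0 - alpha) - alpha        # weight of x[k]
    z = np.empty_like(x)
    z[0] = initial
    # z[k+1] = alpha z[k] + b1 x[k] + b0 x[k+1]
    zi = signal.lfiltic([b0, b1], [1.0, -alpha], y=[initial], x=[x[0]])
    z[1:], _ = signal.lfilter([b0, b1], [1.0, -alpha], x[1:], zi=zi)
    return z
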