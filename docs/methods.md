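# Methods

Model, closed forms, numerical choices and limitations of `ricepop`.
All formulas below were derived from first principles (Gaussian
conditioning and elementary filter integrals) and are cross-checked against
Monte-Carlo oracles in the test suite.

## 1. Model

The membrane integrates an input current `I(t)` with a first-order RC
filter of unit DC gain and time constant `tau_m`:

    tau_m dV/dt = -V + I(t).

`I` is a stationary Gaussian process; hence `V` is stationary Gaussian with
correlation `C_V(tau)`.  A **spike** is an upward crossing of the threshold
`psi` by `V`; there is no reset.  The model is meaningful in the
fluctuation-driven regime `psi / sigma_V >~ 0.5`, where crossings are rare
compared to `1/tau_V` and the point process is far from its
refractoriness-free pathologies.

Two numbers summarize the noise wherever only first-order crossing
statistics matter:

- `sigma_V^2 = C_V(0)` — voltage variance,
- `tau_V = sqrt(C_V(0) / -C_V''(0))` — effective correlation width
  (equivalently `sigma_V / sigma_V'`, with `sigma_V'^2 = Var dV/dt`).

### Correlation families (`ricepop.correlations`)

| family | form | notes |
|---|---|---|
| `gaussian` | `s^2 exp(-tau^2 / 2 tau_c^2)` | smooth; `tau_V = tau_c` |
| `ou_current` | `s^2 exp(-abs(tau)/tau_I)` | kinked at 0: models the *current*, must pass through the membrane before crossing statistics exist |
| `rc_filtered_ou` | `s^2 tau_I/(tau_I^2 - tau_m^2) (tau_I e^{-abs(tau)/tau_I} - tau_m e^{-abs(tau)/tau_m})` | closed form incl. the degenerate `tau_I = tau_m` limit `(s^2/2)(1 + abs(tau)/tau_m) e^{-abs(tau)/tau_m}`; `sigma_V^2 = s^2 tau_I/(tau_I + tau_m)`, `tau_V = sqrt(tau_I tau_m)` |
| `TabulatedCorrelation` | sampled table | clamped cubic spline; rejected if the FFT spectrum of the even extension is significantly negative |
| `SpectralCorrelation` | analytic spectrum | generic filtered families; correlation via inverse FFT |

## 2. Closed forms (`ricepop.analytic`)

### Stationary rate

The Rice rate of upward crossings, generalized to a Gaussian pair
`(V, dV/dt)` with variances `A, B`, covariance `c` and deterministic
velocity `drift`:

    rate = p_V(psi) * [ s phi(m/s) + m Phi(m/s) ],
    m = drift + c psi / A,   s^2 = B - c^2 / A,

with `phi, Phi` the standard normal pdf/cdf.  For stationary noise
(`c = drift = 0`) this reduces to

    nu0 = 1/(2 pi tau_V) exp(-psi^2 / (2 sigma_V^2))      [per ms]

— dependent on the noise only through `(sigma_V, tau_V)`: the
**shape-independence** property.  A quadrature implementation of the same
expectation guards against transcription errors.

### Mean channel

A mean-current signal `s(t)` is filtered to `Z(t)` (the RC response) and
offsets the threshold, `psi -> psi - Z(t)`, while `dZ/dt` adds a drift.
Evaluating the generalized Rice rate pointwise gives the
**non-perturbative** trajectory (`nonlinear_rate_mean`); linearizing gives

    nu1(w) = nu0 [ psi/sigma_V^2 + i w sqrt(pi/2)/sigma_V' ] / (1 + i w tau_m)

— one high-pass zero (threshold advance) against one membrane low-pass,
finite and nonzero as `w -> inf`.  Step response: an instantaneous jump to
`a*abs(nu1(inf))` followed by a single exponential with time constant
`tau_m` to the plateau `a*nu1(0)`.

### Variance channel

Valid for an Ornstein-Uhlenbeck current through the RC membrane (the one
family where the time-dependent second moments are elementary).  Modulating
the current standard deviation by `1 + d sin(w t)` leaves the voltage
Gaussian with exactly computable `A(t), B(t), c(t)` built from

    F(a, b) = s^2/tau_m^2 * 1/(a+b) * (1/(a+gamma) + 1/(b+gamma)),

including the `d^2` second-harmonic terms (`nonlinear_rate_variance`).
Linearizing the generalized Rice rate in `(A, B, c)` with partials

    dnu/dA = nu0 (psi^2/A - 1)/(2A),  dnu/dB = nu0/(2B),
    dnu/dc = p_V(psi) psi/(2A)

gives `linear_response_variance` (per unit sigma increment).  The step
response is obtained by exact partial fractions of the rational transfer
function — simple poles at `-2/tau_m` and `-(1/tau_m + 1/tau_I)`, residues
extracted by small-circle contour integration (64 nodes, accurate to
machine precision for these pole separations) — yielding an instantaneous
jump plus two exponentials.

### Pairwise correlations

Two neurons share a fraction `c` of their input.  To first order in `c`
the conditional rate of B around an A spike is

    nu_c(tau) - nu0 = c nu0 [ psi^2/sigma_V^4 C_V(tau)
                              - (pi/2)(tau_V^2/sigma_V^2) C_V''(tau) ],

with peak excess `c nu0 (psi^2/sigma_V^2 + pi/2)`.  `conditional_rate`
warns above `c = 0.3` where the first-order treatment degrades.

### Spike-triggered statistics

Conditioning `(V(t - tau), V(t), dV/dt)` on an upward crossing at `t`:

    STA(tau) = psi C_V(tau)/sigma_V^2 + sqrt(pi/2) (tau_V/sigma_V) C_V'(tau)
    STC(l1, l2) = C_V(l2-l1) - C_V(l1) C_V(l2)/sigma_V^2
                  + (1 - pi/2) C_V'(l1) C_V'(l2)/sigma_V'^2

(positive lag = before the spike).  The velocity term uses the *first*
derivative of `C_V`; this was verified against Monte Carlo after an
independent derivation.  The STC vanishes at `l1 = l2 = 0` (voltage pinned
at threshold) — estimators comparing to it there divide noise by noise, so
validation grids exclude that point.

### Network input moments

Balanced network, `K` excitatory and `K` inhibitory inputs of weight
`J/sqrt(K)`:

    mean = sqrt(K) J (nu_E - nu_I),   variance = J^2 (nu_E + nu_I) * q,

with `q` the integral of the squared unit-normalized PSC kernel.
Antisymmetric rate modulations move only the mean; symmetric ones only the
variance.

## 3. Simulation (`ricepop.simulate`)

**Path synthesis** uses Davies-Harte circulant embedding: the covariance
sequence on the grid is embedded in a circulant matrix whose FFT
eigenvalues must be non-negative (tolerance `1e-8` of the largest,
else `NonEmbeddableError`); sampled paths then have *exactly* the target
covariance — no burn-in, no AR approximation.  Grid rule: `dt <=
tau_V / 20` enforced (default `tau_V / 25`) so that discrete crossing
detection misses a negligible fraction of crossings.

**Spike detection**: `v[i] < psi <= v[i+1]` with linear interpolation of
the crossing time (keeps phase estimates unbiased at high stimulus
frequencies).

**Mean channel**: trials are exact stationary paths plus the analytically
filtered signal (steady-state sinusoid / exact exponential step), so the
recording is stationary from `t = 0`.

**Variance channel**: the OU current is synthesized exactly, multiplied by
the deterministic envelope `1 + (a/sigma) s(t)`, and integrated through the
RC filter with an exact piecewise-linear update; a burn-in of
`10 max(tau_V, tau_m)` is discarded.  Default `dt = min(tau_I, tau_m)/40`.

**Pairs**: `sqrt(c) shared + sqrt(1-c) private` mixing of voltage paths
(equivalent to mixing currents, since the membrane is linear).

**Reproducibility**: trial `i` of stream `s` is seeded by
`SeedSequence(master_seed, spawn_key=(s, i))`, so any single trial can be
regenerated without the ensemble and enlarging an ensemble preserves the
existing trials.

## 4. Estimators (`ricepop.estimate`)

All estimators report standard errors from observed variability
(across trials, triggers or spikes), not Poisson assumptions:
PSTHs (across-trial SEM); vector strength from interpolated spike phases
(`stderr = 1/sqrt(2n)`, small-sample bias `sqrt(pi)/(2 sqrt(n))` reported,
`abs(nu1) = 2 r nu0 / a`); cross-correlograms with edge-complete trigger
windows; STA/STC from interpolated voltage snippets, with optional shuffled
triggers as a stationarity control.

## 5. Experiments and problem sizes

`ricepop.experiments` packages nine standard comparisons (rate curve, both
frequency responses, both steps, pairs, STA/STC, linearity sweep, shape
independence) behind a validated config; each writes CSVs, a max-|z|
comparison report, and a provenance file supporting bit-identical rerun.
Default problem sizes are package choices tuned for minutes-scale runs on
one CPU; all sizes (trial counts, durations, grids) are configurable, and
statistical gates are z-score-based so they scale automatically with the
chosen size.

## 6. Limitations

- No reset or refractoriness: at low `psi/sigma_V` the crossing process
  produces unphysically clustered spikes; closed forms remain exact for the
  crossing process itself but stop being a good neuron model.
- Variance-channel closed forms (and its simulator) require the OU-current
  family; other families would need new moment integrals.
- Pairwise formulas are first order in the shared fraction `c`.
- Spike-triggered standard errors treat triggers as independent; at high
  rates overlapping windows understate the error slightly.
- The linear-response convention assumes the stimulus is small enough that
  the rate stays positive; the non-perturbative evaluators are provided to
  check exactly when that fails.
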