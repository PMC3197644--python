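# ricepop

Population rate responses of threshold (level-crossing) neurons: closed-form
analytics, exact Monte-Carlo simulators, and estimators with standard errors.

## The model

A neuron's voltage is a stationary, correlated Gaussian process
`V(t)` (an input current filtered by an RC membrane), and a **spike** is an
upward crossing of a fixed threshold `psi` — no reset, no explicit
refractoriness.  In the fluctuation-driven regime this caricature admits
closed forms for essentially every population statistic:

- **Stationary rate** (the Rice level-crossing rate):
  `nu0 = 1/(2 pi tau_V) * exp(-psi^2 / (2 sigma_V^2))`,
  which depends on the noise *only* through its standard deviation
  `sigma_V` and effective correlation width `tau_V = sqrt(C(0) / -C''(0))` —
  not on the shape of the correlation function.
- **Linear response** of the population rate to signals encoded in the
  **mean** of the input current or in its **variance** (standard deviation).
  Both transfer functions stay finite at arbitrarily high frequency, so the
  population responds to a step **instantaneously**, then relaxes with the
  membrane time constant (mean channel) or faster (variance channel).
- **Pairwise spike correlations** of neurons sharing a fraction `c` of
  their input, to first order in `c`.
- **Spike-triggered average and covariance** of the voltage, by exact
  Gaussian conditioning on the crossing.
- **Network input moments**: how antisymmetric vs symmetric rate changes in
  a balanced excitatory/inhibitory network map onto the mean vs variance
  channel.

Every closed form ships with a matching Monte-Carlo simulator (exact
stationary path synthesis by circulant embedding) and estimators that report
standard errors, so analytics and simulation can always be compared on a
z-score scale.

## Quick start

```python
import numpy as np
from ricepop import (
    NeuronConfig, RCFilteredOUCorrelation, Sinusoid, StimulusSpec,
    linear_response_mean, simulate_population, stationary_rate,
    vector_strength,
)

# Ornstein-Uhlenbeck current (variance 2, correlation time 5 ms)
# through a 10-ms membrane; threshold at one voltage unit.
model = RCFilteredOUCorrelation(sigma2_current=2.0, tau_i=5.0, tau_m=10.0)
cfg = NeuronConfig(threshold=1.0, tau_m=10.0, voltage_model=model)

print(stationary_rate(cfg))            # 10.632... Hz
print(abs(linear_response_mean(50.0, cfg)))   # 16.955... Hz per unit current

# simulate 200 neurons driven by a 50-Hz mean-current wiggle
stim = StimulusSpec("mean", Sinusoid(freq_hz=50.0, amplitude=0.06))
ens = simulate_population(stim, cfg, n_trials=200, duration=2000.0,
                          master_seed=1)
vs = vector_strength(ens, 50.0, amplitude=0.06)
print(vs.response_amplitude, "+/-", vs.response_stderr)  # ~17 +/- 1.5
```

Units: times in milliseconds, rates in spikes/s; a stimulus
`a*sin(2 pi f t)` produces the rate modulation `a*Im[nu1(f) e^{i w t}]`.

## Worked examples

The `examples/` directory contains narrative scripts, one per capability:

| script | shows |
|---|---|
| `01_stationary_rate.py` | the rate law and noise-shape independence |
| `02_frequency_response.py` | mean/variance-channel transfer functions vs simulation |
| `03_step_response.py` | the instantaneous jump and relaxation after a step |
| `04_pair_correlations.py` | cross-correlograms under common input |
| `05_spike_triggered.py` | STA/STC vs the Gaussian-conditioning closed forms |
| `06_network_inputs.py` | balanced-network shot noise and the two channels |
| `07_custom_correlation.py` | driving everything from a tabulated correlation |

Each runs in seconds to about a minute: `python examples/01_stationary_rate.py`.

## Command line

A thin CLI wraps the config-driven experiment runner:

```bash
ricepop list                      # available experiments
ricepop rate --seed 1             # rate law vs Monte Carlo
ricepop respond --channel variance
ricepop run config.yaml           # any experiment from YAML
ricepop rerun results/provenance.json   # bit-identical reproduction
```

Every run writes tidy CSVs, a `comparison.json` with the maximum |z|
between analytic and simulated points, and a `provenance.json` from which
the run can be reproduced byte for byte.

## Tests and reproducing the results

```bash
pytest -q tests/                  # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` checks one criterion per test: the rate law over
a parameter grid, shape independence, both frequency responses, step
responses (including the single-exponential mean-channel relaxation),
susceptibility identities, the quadratic onset of nonlinearity, pairwise
correlations, spike-triggered statistics, and bit-identical determinism.
`scripts/acceptance.py` recomputes the same quantities from scratch for any
seed and writes them as JSON.

See `docs/methods.md` for derivation notes, numerical choices and
limitations.
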