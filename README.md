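# aoncb — subthreshold variability of neurons driven by synchronous synaptic inputs

Cortical neurons receive thousands of synaptic inputs, yet their membrane
voltage fluctuates far more than independent inputs could explain, with
variances of several mV², strong voltage correlations across neighboring
cells (ρ ≈ 0.4–0.8) and markedly right-skewed voltage distributions during
spontaneous activity.  `aoncb` implements an exactly solvable modeling
framework that quantifies how *weak but nonzero spiking synchrony* (pairwise
input correlations of only 0.01–0.04) produces all three signatures in
conductance-based neurons.

The model is the all-or-none-conductance-based (AONCB) neuron: the membrane
voltage obeys

    C dV/dt = G (V_L − V) + G_e (V_e − V) + G_i (V_i − V) + I,

with synapses that switch on to a fixed conductance for a duration τ_s.  In
the instantaneous-synapse limit (τ_s/τ → 0) the synaptic drive becomes a
compound Poisson process: synaptic *events* arrive at Poisson rate b and
carry random dimensionless jumps (W_e, W_i), the summed weights of all
inputs coactivating at that instant — synchrony lives entirely in the jump
distribution.  At an event the voltage updates by the Marcus rule

    V ← V + ( (W_e V_e + W_i V_i)/(W_e + W_i) − V ) (1 − e^{−(W_e+W_i)}),

and relaxes exponentially toward I/G in between.  Because Poisson arrivals
see time averages (PASTA), stationarity yields a closed, triangular system
for the shifted mixed moments μ_A = E[∏_a (V_a − I_a/G_a)] of any feedforward
neuron set, which the package solves exactly at any order.  On top of the
exact engine it provides the interpretable small-weight formulas: the
variance with its synchrony amplification factor 1 + (K−1)ρ, the
cross-neuron voltage correlation ρ_V = ρ′/((1−ρ)/κ + ρ), and the skewness
approximation S[V] ≃ s[V] · (1 − 2c_eτ)/(1 + c_eτ) · √(1 + ρ_e K_e).

## Contents

- `aoncb.synchrony` — jump models (discrete atoms, exchangeable
  beta-binomial, seeded samplers), spiking-correlation algebra of any order,
  collective/pair event rates, faulty-transmission transforms.
- `aoncb.generator` — correlated spike rasters via beta marginals mixed by a
  calibrated Gaussian copula; spike jitter; raster → event-train conversion.
- `aoncb.simulate` — exact event-driven Marcus simulator for neuron
  populations, a finite-τ_s Euler reference integrator, and an exact
  propagator for gap-junction-coupled pairs.
- `aoncb.moments` — the exact PASTA moment engine and every closed-form
  special case and small-weight approximation.
- `aoncb.tracestats` — closed-form empirical moment estimators with block
  bootstrap errors.
- `aoncb.experiments` / `aoncb.cli` — config-driven sweeps
  (`aoncb simulate|moments|estimate|experiment`).

## Worked example

```python
import numpy as np
from aoncb import (NeuronParams, BetaBinomialModel, DiscreteJumpModel,
                   events_from_jump_model, simulate_population,
                   empirical_summary, moment_table)

p = NeuronParams()                       # tau=15 ms, Ve=60 mV, Vi=-10 mV
bb = BetaBinomialModel(K=1000, rho=0.03, r=5.0)   # weak synchrony
jm = DiscreteJumpModel.from_beta_binomial(bb, w=1e-3, kind="e")

tab = moment_table(jm, p, order=3)       # exact stationary moments
print(f"mean     {tab.means[0]:.3f} mV")
print(f"variance {tab.variance(0):.3f} mV^2")
print(f"skewness {tab.skewness(0):.3f}")

ev = events_from_jump_model(jm, T=300.0, seed=42)  # exact Marcus simulation
tr = simulate_population(ev, p, V0=1.0, T=300.0)
est = empirical_summary(tr)
print(f"simulated mean {est.means[0][0]:.3f} ± {est.means[0][1]:.3f} mV")
```

Output:

```
mean     4.127 mV
variance 3.189 mV^2
skewness 1.030
simulated mean 4.123 ± 0.019 mV
```

A thousand weak inputs (w = 10⁻³) firing at 5 Hz with pairwise correlation
of only 0.03 drive mV-scale fluctuations (variance ≈ 3.2 mV², ~30× the
asynchronous value at these parameters) with a clearly right-skewed voltage
distribution, and the exact event-driven simulation reproduces the theory
within its standard error.

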