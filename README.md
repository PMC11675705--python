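# acuglm

Coupled point-process GLM analysis of stimulus-evoked multi-neuron spike
trains, with a wavelet spike-sorting front end and a synthetic-recording
generator.

## The problem

Low-frequency mechanical stimulation (e.g. acupuncture needle manipulation
at tens of events per minute) evokes dense clusters of spikes in sensory
neurons. Each evoked spike becomes *history*: it changes the firing
probability of the neuron that emitted it and of its neighbours. Telling
apart the three drives — the stimulus itself, a neuron's own spike history
(self-coupling), and the history of neighbouring neurons (cross-coupling) —
is a functional-connectivity question. `acuglm` answers it with a coupling
generalized linear model: for neuron *i* in time bin *t* (width Δt),

```
λ_i(t) = exp( k_i·x(t) + Σ_j h_ij·y_j(t) ),      n_t ~ Poisson(λ_i(t)·Δt)
```

where `x` is the kernel-filtered stimulus train, `y_j` the kernel-filtered
spike history of neuron *j*, and the scalar weights `k_i` (stimulus) and
`h_ij` (self-coupling on the diagonal, cross-coupling off it) are estimated
by maximum likelihood from the concave Poisson log-likelihood

```
log p(Y | X, θ) = c + Σ_t [ n_t·log(λ(t)Δt) − λ(t)Δt ].
```

The package is for computational neuroscientists who want to simulate from
this model, fit it to binned or timestamped spike trains, reproduce its
recovery/sweep studies, and run the preprocessing chain (spike detection,
Haar-wavelet features, k-means + Gaussian-mixture refinement, noise-unit
flagging) on raw extracellular traces.

## Worked example

Simulate three coupled neurons for 600 s from the bundled ground-truth
weights, refit all twelve parameters, and tabulate the recovery:

```python
import acuglm

rows, summary = acuglm.recovery_experiment(duration_s=600, seed=1)
print("max %.2f  min %.2f  median %.2f"
      % (summary["max_rel_error_pct"], summary["min_rel_error_pct"],
         summary["median_rel_error_pct"]))
for r in rows[:4]:
    print(f"{r.name:4s} true={r.true_value:5.2f} est={r.estimate:6.3f}"
          f" rel_err={r.rel_error_pct:5.2f}%")
```

```
max 1.66  min 0.14  median 0.65
k1   true= 0.85 est= 0.857 rel_err= 0.77%
h11  true= 1.00 est= 1.005 rel_err= 0.47%
h12  true= 1.40 est= 1.392 rel_err= 0.60%
h13  true= 0.80 est= 0.805 rel_err= 0.61%
```

Every relative error sits inside the reference 0.14–3.76% band: with
~9–13k spikes per neuron the ML estimator pins each coupling weight to
within about a percent. The same model object is available sklearn-style:

```python
import numpy as np
from acuglm import (CouplingGLM, SimulationConfig, default_kernels,
                    make_stimulus_train, reference_true_params, simulate)

ker  = default_kernels()                              # 1 ms bins
stim = make_stimulus_train(100, 600, 1e-3, ker)       # 100 events/min, 600 s
spk  = simulate(reference_true_params(), ker, stim, SimulationConfig(seed=1))
fit  = CouplingGLM(kernels=ker, family="bernoulli").fit(spk, stim)
print(np.round(fit.H_, 3))        # fitted history-coupling matrix
print(np.round(fit.se_H_, 4))     # Wald standard errors
```

Applying the comparison logic to the bundled per-manipulation coupling
estimates reproduces the headline orderings — stimulus weights are
orders of magnitude below every history weight, self-coupling decreases
from neuron 1 to neuron 3, and the dominant cross-couplings under twirling
are `h13`, `h21`, `h31` (the strongest being `h31 = 3.5635`):

```python
cmp = acuglm.compare_coupling_classes(acuglm.acupuncture_estimates("twirling"))
print([n["dominant_cross"] for n in cmp.per_neuron], cmp.self_order)
# ['h13', 'h21', 'h31'] [1, 2, 3]
```

A command line wraps the same operations:

```bash
acuglm recover --seed 1 --duration 600 --out recovery.csv
acuglm sweep --axis h12 --out sweep.csv
acuglm synth --manipulation twirling --seed 11 --out scenario/
acuglm sort --trace scenario/trace.csv --fs 24000 --k 4 --out sorted/
acuglm compare --manipulation twirling --out comparison.json
```

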