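# Methods

## Model

`acuglm` models the binned spiking of `N` simultaneously recorded neurons
responding to a periodic low-frequency mechanical stimulus as a coupled
discrete-time point-process GLM with an exponential link. The conditional
intensity (rate, events/s) of neuron `i` in bin `t` of width `Δt` is

```
λ_i(t) = exp( b_i + k_i · x(t) + Σ_j H[i,j] · y_j(t) )
```

where `x(t)` is the stimulus event train convolved with a fixed stimulus
kernel, `y_j(t)` is neuron `j`'s spike train convolved with a fixed,
strictly causal post-spike kernel (zero at lag 0), `k_i` is the scalar
stimulus-coupling weight, `H[i,j]` the history-coupling weight (diagonal =
self-coupling, off-diagonal = cross-coupling), and `b_i` an optional
intercept, off by default so the baseline rate is `exp(0) = 1` event/s.
Setting `H = 0` recovers the linear–nonlinear–Poisson cascade; zeroing the
off-diagonal recovers the soft-threshold integrate-and-fire (self-history)
model.

**Scalar-weight factorisation.** Each stimulus/history filter is a shared
temporal kernel times one scalar weight per neuron (pair). This is the only
parameterisation consistent with reporting a single number per coupling
(twelve parameters for three neurons), and it is what the estimator fits.
Nonparametric filter shapes (basis expansions) are out of scope.

## Kernels: defaults and why

Kernel shapes and scales are not identifiable from a table of scalar
weights, so they are fixed design choices (all config-overridable through
`make_kernels`). The defaults were calibrated, by pilot simulation, to
reproduce the qualitative regime the underlying experiments describe —
dense post-stimulus spike clusters at the order of 10²–10³ spikes per
neuron per minute, spike totals that rise with stimulus frequency from 30
to 120 events/min and do **not** rise further at 150 events/min, totals
that rise with every coupling weight — while remaining dynamically stable
and informative enough for maximum-likelihood recovery at the study's own
sample sizes. They were frozen before the acceptance suite was written.

**Stimulus kernel** (`stim_amp = 6.5`, decay `tau = 80 ms`, support 600 ms):
a fast excitatory exponential minus a *depletion window* of depth 0.7
log-units lasting `dep_recovery = 450 ms` (sigmoid edges, 15 ms). A unit
weight therefore multiplies the rate by ≈ `e^6.5·e^-0.7 ≈ 330` at stimulus
onset, producing a burst that relaxes over ~200 ms. The depletion window is
the package's concrete mechanism for transmitter/ion-channel depletion
with a finite recovery time: stimuli spaced more than 450 ms apart (up to
120/min) evoke full-sized bursts, so totals grow essentially linearly in
frequency, while at 150/min (400 ms period) each event lands inside its
predecessor's window and is damped — the evoked count saturates. The knee
sits between the 120/min and 150/min periods by construction.

**History kernel** (`hist_amp = 2.0`, facilitation `tau = 20 ms`,
refractory `tau = 2 ms`, support 120 ms, `hist_balance = 2.0`): a brief
deep refractory dip followed by a facilitation lobe peaking near 10 ms
(unit weight ≈ doubles the rate there). The refractory area is twice the
facilitation area. Net inhibition is load-bearing: because spike timing
correlates with the facilitation lobe, a merely *zero-sum* kernel still
admits a self-sustained "ignited" state in which the purely excitatory
coupling weights drive hundreds of hertz of stimulus-independent firing;
with `hist_balance = 2` all parameter sets exercised by the package (the
recovery truths and the full 0.1–1.0 sweep grids) remain
stimulus-locked. Single spikes still excite their targets on net: the
refractory dip is bounded below through the exponential link (a rate
cannot fall past zero) while the facilitation lobe is amplified by the
link's convexity, which is why spike totals increase in every history
weight.

## Simulation

Bins are processed in time order; at bin `t` the intensity uses only the
stimulus and already-generated history. Counts are drawn either as
`Poisson(λΔt)` or, by default, as `Bernoulli(1 − exp(−λΔt))` ("binary"
mode, at most one spike per bin — the discrete analogue of absolute
refractoriness, and the mode that keeps pathological parameter sets
bounded). One uniform variate per (bin, neuron) is pre-drawn from a single
NumPy generator, consumed neuron-major within each bin; Poisson counts use
the inverse CDF of the same uniform, so output is bit-reproducible across
modes given (parameters, config, seed). The log intensity is clipped at
±10 (λ ≤ e¹⁰ ≈ 22 kHz) during simulation only. The implementation is
event-driven (vectorised scans between spikes, incremental history
updates on spikes); the incrementally maintained covariates equal the
batch-built design matrix exactly, which is a tested invariant.

## Inference

Per-neuron likelihood: the Poisson bin model gives
`ll(θ) = Σ_t [n_t log(λ_t Δt) − λ_t Δt]` up to the constant `−Σ log n_t!`,
which is dropped (it does not depend on θ; rankings and the argmax are
unaffected). With the exponential link this is concave with gradient
`Xᵀ(n − λΔt)`, so a damped Newton ascent (Armijo line search, L-BFGS
fallback, gradient tolerance `1e-8`, zero initialisation) finds the global
optimum regardless of start. Standard errors come from the inverse
observed Fisher information at the optimum; 95% intervals are
`θ̂ ± 1.96·se`. The joint likelihood factorises over target neurons given
the recorded histories, so the three (k_i, h_i·) sets are fit
independently. `log Δt` is folded into the likelihood, not the design, so
the weights stay on their natural scale.

A second family, `"bernoulli"` (`p = 1 − exp(−λΔt)`, a complementary
log-log binomial GLM, also log-concave), is the *exact* likelihood of
binary-mode data. `recovery_experiment` matches the fit family to the
simulation mode; within bursts `λΔt` reaches ~0.1–0.3 and the Poisson
approximation would otherwise contribute an avoidable O(λΔt/2) bias.
The Poisson family remains the default elsewhere and is cross-checked
against statsmodels in the test suite.

## Experiments

* **Recovery** (`recovery_experiment`): simulate 600 s at 100 stimuli/min
  (1 ms bins, binary mode) from the bundled ground-truth weights
  (k = 0.85/0.9/0.7, H rows (1, 1.4, 0.8), (1, 1.25, 0.7), (0.9, 1.2, 1)),
  refit, and tabulate per-parameter percent relative errors. At the default
  duration each neuron emits ~9–13k spikes and the worst of the twelve
  errors lands well inside the reference 0.14–3.76% band (≈1.7% at seed 1);
  a warning is raised below 500 spikes per neuron, and `scripts/acceptance.py`
  uses 900 s for additional margin. Zero-valued truths are flagged rather
  than given an undefined relative error.
* **Sweeps** (`sweep_stimulus_coupling`, `sweep_history_coupling`): spike
  totals over a 0.1–1.0 weight grid at stimulus frequencies
  30/60/100/120/150 per minute (stimulus weight, history fixed) or at
  100/min (one history weight varied). One-minute records averaged over
  five seeds; monotonicity is asserted on seed means with one permitted
  inversion per curve, since single-minute totals are noisy.
* **Coupling-class comparison** (`compare_coupling_classes`): magnitudes
  are compared for stimulus-vs-history and for the dominant
  cross-coupling (the reported tables mix signs but discuss sizes); the
  self-coupling ordering across neurons uses signed values — the only
  reading under which the reported lifting–thrusting self-weights
  (0.1662 > −0.0352 > −0.0622) decrease from neuron 1 to neuron 3. Ties
  are reported explicitly, never broken silently. No significance test is
  attached: none is defined for these comparisons.

## Spike sorting

Detection thresholds the trace at `4.5 σ` with `σ = median(|v|)/0.6745`;
crossings closer than 1 ms merge. Each event is aligned on the *earliest*
local extremum within `3σ` of the group maximum: waveforms with two
near-equal extrema (a full sinusoidal cycle) would otherwise align at
random under noise and split into spurious classes. Snippets are 64
samples at 24 kHz. Features are 4-level Haar DWT coefficients ranked by a
Lilliefors-type KS distance from normality (multimodal coefficients
separate units; Gaussian ones carry only noise); the top 10 are kept and
the top 2 give the classic 2-D scatter. k-means (k = 4, k-means++, fixed
seed) provides initial labels; a full-covariance Gaussian-mixture EM
(reg. 1e-4, tol 1e-6, ≤200 iterations) initialised from those labels
refines them. The unit whose mean waveform has the smallest absolute
excursion from baseline (mean of the first 8 samples) is flagged — never
deleted — as the putative noise class.

## Synthetic recordings

Four templates: a high-amplitude biphasic pulse (peak 8, in noise-SD
units), a Hann-windowed sine cycle (6.5) and cosine cycle (6.0) — exactly
orthogonal by the window's symmetry — and a low pulse (5.5) riding an
elevated tapered baseline, the "ambient noise" class. White Gaussian noise
(SD 1) is added; overlapping events superpose additively; ground truth
records every placement and suffices to regenerate the trace
bit-identically.

`default_acupuncture_scenario` drives neurons 1–3 with the bundled
coupling estimates for one needle manipulation (100 stimuli/min for 60 s),
plus a 5 Hz baseline through the optional intercept, since the reported
stimulus weights (~1e-3) are inert on this covariate scale; per-unit
totals then land at roughly the reported few-hundred-per-minute scale.
The scenario's history kernel uses `hist_amp = 1`: the reported
lifting–thrusting mutual couplings (1.55/1.26) are supercritical at the
recovery-study scale and would ignite, and the recordings' true filter
scale is unknowable. Unit 4 fires as a stimulus-independent 2 Hz
homogeneous Poisson process — frequent enough that its cluster and count
are recoverable against threshold false positives.

## What the generator does and does not emulate

The synthetic data reproduce: stimulus-locked burst structure, coupled
cross-neuron firing, waveform classes of graded amplitude and shape,
additive waveform superposition, and a low-amplitude noise class. They do
not emulate electrode drift, 1/f or correlated noise, biophysical spike
shapes, bursting cell types beyond what the GLM produces, or the real
(unpublished) recordings' kernels and rates — so passing tests demonstrate
correctness of the pipeline under the model's own assumptions, not
fidelity to any particular animal dataset. The real-data tables bundled
with the package are used as *inputs* (fixtures for the comparison logic
and scenario weights), not as quantities the code claims to re-measure.

## Numerical choices and degenerate inputs

Relative error is undefined at a zero truth (rows flagged). A
rank-deficient design warns and falls back to a pseudo-inverse Fisher
matrix. Non-convergence is flagged on the result, never raised. A flat
trace yields an explicit empty sort result; an empty initial cluster is
dropped with a warning; `k = 1` clustering is the trivial labelling.
Spike timestamps bin by `floor(t/Δt)` (half-open bins); writers emit
bin-centre times so CSV round trips preserve count matrices exactly.

## Problem sizes

Default problem sizes (600–900 s recovery records, 60 s one-minute sweep
epochs over five seeds, 60 s sorting scenarios over ten seeds) are the
package's standing choices for its own studies: they match the
one-minute-epoch design of the underlying experiments and give
maximum-likelihood errors and sorting accuracies with comfortable margin
to their reference bands.

## Known limitations

* Kernel shapes are conventions; only the scalar weights are estimated.
* The saturation mechanism (depletion window) is a modelling choice — the
  underlying phenomenon is only described verbally in the source material.
* Binary mode caps rates at 1 kHz (1 ms bins); Poisson mode with strongly
  positive feedback is bounded only by the log-intensity clip.
* The comparison logic treats "significantly less" as a plain ordering of
  magnitudes; no inferential test is performed.
* Overlapping spikes are superposed but not decomposed by the sorter;
  heavily co-firing regimes therefore lose a few percent of events to
  detection merging.
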