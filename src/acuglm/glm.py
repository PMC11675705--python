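"""Core data types and the conditional intensity of the coupling GLM.

The model: neuron ``i`` fires as a discrete-time point process whose
conditional intensity (rate, events/second) in bin ``t`` is

    lambda_i(t) = exp( b_i + k_i * x(t) + sum_j H[i, j] * y_j(t) )

where ``x`` is the stimulus event train filtered by the stimulus kernel,
``y_j`` is neuron ``j``'s spike train filtered by the (strictly causal)
history kernel, ``k_i`` is the scalar stimulus coupling weight, ``H[i, j]``
the history coupling weight of source ``j`` onto target ``i`` (diagonal =
self-coupling, off-diagonal = cross-coupling), and ``b_i`` an optional
intercept that defaults to zero (baseline rate exp(0) = 1 event/s).

Setting all of ``H`` to zero recovers the linear–nonlinear–Poisson cascade;
zeroing only the off-diagonal recovers the soft-threshold
integrate-and-fire (self-history only) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSet, TimeGrid

__all__ = [
    "StimulusTrain",
    "CouplingParams",
    "SpikeTrainSet",
    "DesignMatrix",
    "make_stimulus_train",
    "filter_history",
    "build_design",
    "conditional_intensity",
    "history_effect_curves",
    "LOG_RATE_CLIP",
]

#: Symmetric clip on the log intensity used during simulation
#: (lambda <= e**10 ~ 22 kHz); keeps positive-feedback regimes bounded.
LOG_RATE_CLIP = 10.0


@dataclass(frozen=True)
class StimulusTrain:
    """Periodic stimulus events plus the kernel-filtered covariate ``x``."""

    grid: TimeGrid
    event_bins: np.ndarray
    freq_per_min: float
    x: np.ndarray

    def __post_init__(self) -> None:
        eb = np.asarray(self.event_bins, dtype=int)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "event_bins", eb)
        object.__setattr__(self, "x", x)
        if x.shape != (self.grid.n_bins,):
            raise ValueError("x must have one entry per grid bin")
        if eb.size and (eb.min() < 0 or eb.max() >= self.grid.n_bins):
            raise ValueError("event bins outside the grid")
        if eb.size > 1 and not (np.diff(eb) > 0).all():
            raise ValueError("event bins must be strictly increasing")


@dataclass(frozen=True)
class CouplingParams:
    """Scalar coupling weights: stimulus ``k`` (per neuron) and history matrix ``H``.

    ``H[i, j]`` weights the filtered spike history of source neuron ``j``
    in the log rate of target neuron ``i``.
    """

    k: np.ndarray
    H: np.ndarray
    intercept: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        k = np.atleast_1d(np.asarray(self.k, dtype=float))
        H = np.asarray(self.H, dtype=float)
        n = k.size
        b = np.broadcast_to(np.asarray(self.intercept, dtype=float), (n,)).copy()
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "intercept", b)
        if H.shape != (n, n):
            raise ValueError(f"H must be {n}x{n} to match k, got {H.shape}")
        if not (np.isfinite(k).all() and np.isfinite(H).all() and np.isfinite(b).all()):
            raise ValueError("coupling parameters must be finite")

    @property
    def n_neurons(self) -> int:
        return self.k.size


@dataclass(frozen=True)
class SpikeTrainSet:
    """Binned spike counts, one row per neuron, on a common grid."""

    grid: TimeGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != self.grid.n_bins:
            raise ValueError("counts must be n_neurons x n_bins")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c)

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class DesignMatrix:
    """Covariate matrix for one target neuron.

    Column 0 is the filtered stimulus; column ``j + 1`` the filtered history
    of neuron ``j``.  History columns at bin ``t`` depend only on counts at
    bins strictly before ``t``.  The matrix is identical for every target
    neuron — only the weight vector differs — but the target index is kept
    for bookkeeping.
    """

    grid: TimeGrid
    X: np.ndarray
    target: int
    columns: tuple = ()

    @property
    def n_neurons(self) -> int:
        return self.X.shape[1] - 1


def make_stimulus_train(
    freq_per_min: float, duration_s: float, dt: float, kernels: KernelSet
) -> StimulusTrain:
    """Periodic stimulus events starting at t = 0, filtered by the stimulus kernel.

    Raises ``ValueError`` for non-positive duration/dt or when the stimulus
    period is shorter than one bin (unresolvable aliasing).
    """
    if duration_s <= 0 or dt <= 0:
        raise ValueError("duration_s and dt must be positive")
    if freq_per_min < 0:
        raise ValueError("freq_per_min must be nonnegative")
    n_bins = int(round(duration_s / dt))
    grid = TimeGrid(dt=dt, n_bins=n_bins)
    if freq_per_min == 0:
        return StimulusTrain(grid, np.empty(0, int), 0.0, np.zeros(n_bins))
    period = 60.0 / freq_per_min
    if period < dt:
        raise ValueError("stimulus period shorter than one bin")
    n_events = int(np.floor((duration_s - 1e-12) / period)) + 1
    event_bins = np.round(np.arange(n_events) * period / dt).astype(int)
    event_bins = event_bins[event_bins < n_bins]
    indicator = np.zeros(n_bins)
    indicator[event_bins] = 1.0
    x = np.convolve(indicator, kernels.stim)[:n_bins]
    return StimulusTrain(grid, event_bins, float(freq_per_min), x)


def filter_history(counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Strictly causal convolution of a spike-count sequence with a history kernel.

    ``out[t] = sum_{tau >= 1} kernel[tau] * counts[t - tau]``; requires
    ``kernel[0] == 0`` so a spike never feeds back into its own bin.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel[0] != 0.0:
        raise ValueError("history kernel must have zero lag-0 entry (causality)")
    counts = np.asarray(counts, dtype=float)
    return np.convolve(counts, kernel)[: counts.size]


def build_design(
    stim: StimulusTrain, spikes: SpikeTrainSet, kernels: KernelSet, target_neuron: int = 0
) -> DesignMatrix:
    """Assemble the per-target design: [stimulus, history of neuron 0, 1, ...]."""
    if not stim.grid.compatible(spikes.grid):
        raise ValueError("stimulus and spike trains must share a time grid")
    n = spikes.n_neurons
    if not 0 <= target_neuron < n:
        raise ValueError("target_neuron out of range")
    cols = [stim.x]
    cols += [filter_history(spikes.counts[j], kernels.hist) for j in range(n)]
    X = np.column_stack(cols)
    names = ("stimulus",) + tuple(f"history_{j + 1}" for j in range(n))
    return DesignMatrix(grid=spikes.grid, X=X, target=target_neuron, columns=names)


def _theta(params: CouplingParams, target: int) -> np.ndarray:
    return np.concatenate([[params.k[target]], params.H[target]])


def conditional_intensity(
    params: CouplingParams,
    design: DesignMatrix,
    target_neuron: int | None = None,
    l_max: float = LOG_RATE_CLIP,
) -> np.ndarray:
    """Conditional intensity lambda(t) in events/second for one target neuron.

    The log intensity is clipped to ``+/- l_max`` (simulation-stability
    convention); the result is strictly positive for finite parameters.
    """
    i = design.target if target_neuron is None else target_neuron
    eta = design.X @ _theta(params, i) + params.intercept[i]
    return np.exp(np.clip(eta, -l_max, l_max))


def history_effect_curves(
    params: CouplingParams, kernels: KernelSet, target_neuron: int
) -> dict:
    """Per-source post-spike effect on the target's log rate, raw and exponentiated.

    Source ``j``'s raw curve is ``H[target, j] * hist_kernel``; the
    exponentiated curve is its pointwise multiplicative effect on the rate.
    """
    i = target_neuron
    raw = params.H[i][:, None] * kernels.hist[None, :]
    return {"raw": raw, "exp": np.exp(raw), "lags_s": np.arange(kernels.hist.size) * kernels.dt}
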