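"""Temporal kernels and the discrete time grid.

The coupling GLM factorises every stimulus and spike-history filter into a
*fixed temporal kernel* shared across neurons times a *scalar coupling
weight* estimated per neuron pair.  This module owns the grid and the
kernels; the weights live in :class:`acuglm.glm.CouplingParams`.

Kernel design
-------------
``stim``
    A fast excitatory exponential (time constant ``tau``) minus a
    fixed-duration depletion window (depth ``dep_depth`` lasting
    ``dep_recovery`` seconds, smooth edges).  The positive lobe turns each
    stimulus event into a burst of firing; the depletion window models
    transmitter/channel depletion with a finite recovery time, so stimuli
    spaced wider than the recovery window evoke full-sized bursts (totals
    grow linearly with stimulus frequency) while stimuli arriving inside the
    previous event's window are damped — the evoked spike count saturates
    once the stimulus period drops below the recovery time.

``hist``
    A post-spike filter with a strong brief refractory dip (``refract_tau``)
    followed by an excitatory facilitation lobe (``tau``).  The refractory
    area is ``balance`` times the facilitation area; with ``balance > 1``
    sustained firing generates net self-inhibition, so the purely excitatory
    coupling weights of the model cannot ignite run-away activity, while
    isolated spikes still facilitate their neighbours: the refractory dip is
    bounded below through the exponential link (a rate cannot drop below
    zero) whereas the facilitation lobe is amplified by its convexity, so
    the net effect of a single spike on downstream spike counts is positive.
    The lag-0 entry is identically zero: a spike may not influence its own
    bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeGrid", "KernelSet", "default_kernels", "make_kernels"]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform binning of time into half-open windows ``[t*dt, (t+1)*dt)``."""

    dt: float
    n_bins: int

    def __post_init__(self) -> None:
        if not (self.dt > 0 and np.isfinite(self.dt)):
            raise ValueError(f"dt must be positive and finite, got {self.dt}")
        if int(self.n_bins) != self.n_bins or self.n_bins < 1:
            raise ValueError(f"n_bins must be a positive integer, got {self.n_bins}")

    @property
    def duration(self) -> float:
        """Total grid duration in seconds."""
        return self.dt * self.n_bins

    @property
    def times(self) -> np.ndarray:
        """Left bin edges in seconds."""
        return np.arange(self.n_bins) * self.dt

    def compatible(self, other: "TimeGrid") -> bool:
        return self.n_bins == other.n_bins and np.isclose(self.dt, other.dt)


@dataclass(frozen=True)
class KernelSet:
    """Fixed stimulus and spike-history kernels sampled on a grid of width ``dt``.

    ``stim[tau]`` and ``hist[tau]`` give the log-rate contribution of an
    event ``tau`` bins in the past, per unit coupling weight.
    """

    dt: float
    stim: np.ndarray
    hist: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        stim = np.asarray(self.stim, dtype=float)
        hist = np.asarray(self.hist, dtype=float)
        object.__setattr__(self, "stim", stim)
        object.__setattr__(self, "hist", hist)
        if stim.ndim != 1 or hist.ndim != 1 or stim.size == 0 or hist.size == 0:
            raise ValueError("kernels must be non-empty 1-D arrays")
        if not (np.isfinite(stim).all() and np.isfinite(hist).all()):
            raise ValueError("kernels must be finite")
        if hist[0] != 0.0:
            raise ValueError(
                "history kernel must have a zero lag-0 entry "
                "(a spike cannot influence its own bin)"
            )

    @property
    def stim_support(self) -> float:
        return self.stim.size * self.dt

    @property
    def hist_support(self) -> float:
        return self.hist.size * self.dt


def make_kernels(
    dt: float = 1e-3,
    *,
    stim_amp: float = 6.5,
    stim_tau: float = 0.08,
    dep_depth: float = 0.7,
    dep_recovery: float = 0.45,
    dep_edge: float = 0.015,
    stim_support: float = 0.6,
    hist_amp: float = 2.0,
    hist_tau: float = 0.02,
    hist_refract_tau: float = 0.002,
    hist_support: float = 0.12,
    hist_balance: float = 2.0,
) -> KernelSet:
    """Build the parametric kernel pair described in the module docstring.

    Parameters are in seconds (time constants, supports) or dimensionless
    log-rate units (amplitudes).  The refractory weight of the history
    kernel is solved internally so its area is ``hist_balance`` times the
    facilitation area (net inhibition for values above one).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for name, val in [("stim_support", stim_support), ("hist_support", hist_support)]:
        if val < dt:
            raise ValueError(f"{name} must be at least one bin wide")

    u_s = np.arange(int(round(stim_support / dt))) * dt
    from scipy.special import expit

    recovery = expit((u_s - dep_recovery) / max(dep_edge, dt))  # 0 inside the window, 1 after
    stim = stim_amp * np.exp(-u_s / stim_tau) - dep_depth * (1.0 - recovery)

    u_h = np.arange(int(round(hist_support / dt))) * dt
    facil = np.exp(-u_h / hist_tau)
    refract = np.exp(-u_h / hist_refract_tau)
    facil[0] = 0.0
    refract[0] = 0.0
    beta = hist_balance * facil.sum() / refract.sum() if refract.sum() > 0 else 0.0
    hist = hist_amp * (facil - beta * refract)

    meta = {
        "dt": dt,
        "stim": {
            "amp": stim_amp,
            "tau": stim_tau,
            "dep_depth": dep_depth,
            "dep_recovery": dep_recovery,
            "dep_edge": dep_edge,
            "support": stim_support,
        },
        "hist": {
            "amp": hist_amp,
            "tau": hist_tau,
            "refract_tau": hist_refract_tau,
            "support": hist_support,
            "balance": hist_balance,
        },
    }
    return KernelSet(dt=dt, stim=stim, hist=hist, meta=meta)


def default_kernels(dt: float = 1e-3) -> KernelSet:
    """Default kernels at bin width ``dt`` (defaults chosen in docs/methods.md)."""
    return make_kernels(dt)


def kernels_from_meta(meta: dict) -> KernelSet:
    """Rebuild a :class:`KernelSet` from its ``meta`` dictionary (JSON round trip)."""
    s, h = meta["stim"], meta["hist"]
    return make_kernels(
        meta["dt"],
        stim_amp=s["amp"],
        stim_tau=s["tau"],
        dep_depth=s["dep_depth"],
        dep_recovery=s["dep_recovery"],
        dep_edge=s["dep_edge"],
        stim_support=s["support"],
        hist_amp=h["amp"],
        hist_tau=h["tau"],
        hist_refract_tau=h["refract_tau"],
        hist_support=h["support"],
        hist_balance=h.get("balance", 2.0),
    )
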