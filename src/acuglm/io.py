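"""Plain-text interchange: timestamped spike CSVs, stimulus CSVs, parameter JSON.

Conventions: times are seconds; spike timestamps are binned with the
half-open rule ``bin = floor(t / dt)`` (a time exactly on edge ``k * dt``
belongs to bin ``k``); writers emit bin-centre timestamps so a write/read
round trip reproduces the count matrix exactly.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .glm import CouplingParams, SpikeTrainSet
from .kernels import KernelSet, TimeGrid, default_kernels, kernels_from_meta

__all__ = [
    "ParseError",
    "SchemaError",
    "read_spikes_csv",
    "write_spikes_csv",
    "read_stimulus_csv",
    "write_stimulus_csv",
    "read_params_json",
    "write_params_json",
    "write_fit_json",
]


class ParseError(ValueError):
    """Malformed CSV content (message names the offending line)."""


class SchemaError(ValueError):
    """Parameter JSON missing or inconsistent fields."""


def read_spikes_csv(
    path, dt: float, duration_s: float | None = None, n_neurons: int | None = None
) -> SpikeTrainSet:
    """Read a timestamped spike CSV (header ``neuron_id,time_s``) into binned counts."""
    df = pd.read_csv(path)
    if list(df.columns) != ["neuron_id", "time_s"]:
        raise ParseError(f"{path}: expected header 'neuron_id,time_s', got {list(df.columns)}")
    if df["time_s"].size and (df["time_s"] < 0).any():
        line = int(np.flatnonzero(df["time_s"].to_numpy() < 0)[0]) + 2  # 1-based + header
        raise ParseError(f"{path}: negative time at line {line}")
    n = int(n_neurons or (df["neuron_id"].max() + 1 if len(df) else 1))
    t_max = float(df["time_s"].max()) if len(df) else 0.0
    duration = duration_s if duration_s is not None else t_max + dt
    grid = TimeGrid(dt=dt, n_bins=int(round(duration / dt)))
    counts = np.zeros((n, grid.n_bins), dtype=np.int64)
    if len(df):
        bins = np.floor(df["time_s"].to_numpy() / dt).astype(int)
        keep = bins < grid.n_bins
        np.add.at(counts, (df["neuron_id"].to_numpy(int)[keep], bins[keep]), 1)
    return SpikeTrainSet(grid=grid, counts=counts)


def write_spikes_csv(spikes: SpikeTrainSet, path) -> None:
    """Write binned counts as timestamped rows (bin-centre times, one row per spike)."""
    dt = spikes.grid.dt
    rows = []
    for i in range(spikes.n_neurons):
        bins = np.flatnonzero(spikes.counts[i])
        for b in bins:
            rows.extend([(i, (b + 0.5) * dt)] * int(spikes.counts[i, b]))
    pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(path, index=False)


def read_stimulus_csv(path) -> np.ndarray:
    """Stimulus event times (seconds) from a single-column CSV with header ``time_s``."""
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s"]:
        raise ParseError(f"{path}: expected header 'time_s', got {list(df.columns)}")
    return df["time_s"].to_numpy(float)


def write_stimulus_csv(event_times_s: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": np.asarray(event_times_s, float)}).to_csv(path, index=False)


def read_params_json(path) -> tuple[CouplingParams, KernelSet, float]:
    """Load coupling parameters, kernels and dt from the parameters JSON schema."""
    with open(path) as fh:
        doc = json.load(fh)
    missing = [f for f in ("dt", "neurons", "k", "H") if f not in doc]
    if missing:
        raise SchemaError(f"{path}: missing field(s) {missing}")
    dt = float(doc["dt"])
    n = int(doc["neurons"])
    k = np.asarray(doc["k"], dtype=float)
    H = np.asarray(doc["H"], dtype=float)
    if k.shape != (n,) or H.shape != (n, n):
        raise SchemaError(
            f"{path}: k must have length {n} and H shape ({n}, {n}); "
            f"got {k.shape} and {H.shape}"
        )
    params = CouplingParams(k=k, H=H, intercept=doc.get("intercept", 0.0))
    if "kernels" in doc:
        meta = dict(doc["kernels"])
        meta.setdefault("dt", dt)
        kernels = kernels_from_meta(meta)
    else:
        kernels = default_kernels(dt)
    return params, kernels, dt


def write_params_json(params: CouplingParams, kernels: KernelSet, dt: float, path) -> None:
    doc = {
        "dt": dt,
        "neurons": int(params.n_neurons),
        "k": params.k.tolist(),
        "H": params.H.tolist(),
        "intercept": params.intercept.tolist(),
        "kernels": kernels.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def write_fit_json(model, path, dt: float | None = None) -> None:
    """Serialise a fitted :class:`acuglm.inference.CouplingGLM` with uncertainty."""
    doc = {
        "dt": dt if dt is not None else model.design_.grid.dt,
        "neurons": int(model.k_.size),
        "k": model.k_.tolist(),
        "H": model.H_.tolist(),
        "intercept": model.intercept_.tolist(),
        "kernels": model.kernels_.meta,
        "se_k": model.se_k_.tolist(),
        "se_H": model.se_H_.tolist(),
        "loglik": model.loglik_,
        "converged": bool(model.converged_),
        "per_neuron": [
            {
                "names": list(r.names),
                "theta": r.theta.tolist(),
                "se": r.se.tolist(),
                "ci95": r.ci95.tolist(),
                "converged": bool(r.converged),
                "n_iter": int(r.n_iter),
            }
            for r in model.results_
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
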