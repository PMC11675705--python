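"""Spike sorting: detection, wavelet features, clustering, Bayesian refinement.

The preprocessing stage that turns a raw extracellular voltage trace into
per-unit spike trains: threshold detection against a robust noise estimate,
a Haar discrete-wavelet-transform feature space ranked by
deviation-from-Gaussianity (a Lilliefors-type Kolmogorov–Smirnov score —
multimodal coefficients separate units, Gaussian ones carry only noise),
k-means for initial labels, then Gaussian-mixture EM refinement seeded from
those labels.  The lowest-amplitude unit is flagged as a putative noise
class but never deleted, so downstream coupling analysis can exclude it
auditably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

__all__ = [
    "WaveformSet",
    "FeatureMatrix",
    "SortResult",
    "detect_spikes",
    "wavelet_features",
    "cluster_initial",
    "bayesian_refine",
    "summarize_units",
    "SpikeSorter",
    "match_accuracy",
]

_DWT_LEVELS = 4


@dataclass(frozen=True)
class WaveformSet:
    """Peak-aligned spike snippets cut from a raw trace."""

    fs: float
    snippets: np.ndarray  # n_snippets x length
    peak_times: np.ndarray  # seconds
    align_index: int

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.snippets, dtype=float))
        object.__setattr__(self, "snippets", s)
        object.__setattr__(self, "peak_times", np.asarray(self.peak_times, dtype=float))
        if s.shape[0] != self.peak_times.size:
            raise ValueError("one peak time per snippet required")
        if s.size and not 0 <= self.align_index < s.shape[1]:
            raise ValueError("alignment index outside the snippet")

    @property
    def n_snippets(self) -> int:
        return self.snippets.shape[0]


@dataclass(frozen=True)
class FeatureMatrix:
    values: np.ndarray  # n_snippets x n_features
    indices: np.ndarray  # selected wavelet-coefficient indices (unique)
    scores: np.ndarray  # selection score of every coefficient


@dataclass
class SortResult:
    labels: np.ndarray
    unit_ids: np.ndarray
    mean_waveforms: np.ndarray  # n_units x snippet length
    counts: np.ndarray
    amplitudes: np.ndarray  # peak-to-baseline of the unit means
    noise_unit: int | None


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    thresh_mult: float = 4.5,
    window: int = 64,
    align_index: int = 20,
    refractory_s: float = 1e-3,
    tie_margin: float = 3.0,
) -> WaveformSet:
    """Threshold detection with a median-based noise scale.

    The noise scale is ``sigma = median(|trace|) / 0.6745`` (the MAD-normal
    convention); events are groups of samples with ``|trace| >= thresh_mult
    * sigma``, merged when closer than the refractory window.  Each event is
    aligned on the earliest local extremum whose magnitude is within
    ``tie_margin * sigma`` of the group maximum — waveforms with two
    near-equal extrema (e.g. a full sinusoidal cycle) would otherwise align
    at random under noise and split into spurious classes.  A flat trace
    yields an explicit empty result.
    """
    trace = np.asarray(trace, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if trace.size <= window:
        raise ValueError("trace shorter than the snippet window")
    sigma = np.median(np.abs(trace)) / 0.6745
    empty = WaveformSet(fs, np.empty((0, window)), np.empty(0), align_index)
    if sigma == 0:
        return empty
    thr = thresh_mult * sigma
    above = np.flatnonzero(np.abs(trace) >= thr)
    if above.size == 0:
        return empty
    gap = max(1, int(round(refractory_s * fs)))
    splits = np.flatnonzero(np.diff(above) > gap) + 1
    groups = np.split(above, splits)
    peaks = []
    absval = np.abs(trace)
    for g in groups:
        lo, hi = g[0], g[-1] + 1
        seg = absval[lo:hi]
        # local-extremum filter: sample at least as large as both neighbours
        padded = np.pad(seg, 1, constant_values=-np.inf)
        is_peak = (seg >= padded[:-2]) & (seg >= padded[2:])
        cand = np.flatnonzero((seg >= seg.max() - tie_margin * sigma) & is_peak)
        p = lo + int(cand[0])
        if p - align_index >= 0 and p - align_index + window <= trace.size:
            if peaks and p - peaks[-1] <= gap:
                continue
            peaks.append(int(p))
    if not peaks:
        return empty
    peaks = np.asarray(peaks)
    snippets = np.stack([trace[p - align_index : p - align_index + window] for p in peaks])
    return WaveformSet(fs, snippets, peaks / fs, align_index)


def wavelet_features(waves: WaveformSet, n_keep: int = 10) -> FeatureMatrix:
    """Haar DWT coefficients ranked by a Lilliefors-type KS normality score.

    Each snippet is decomposed with a 4-level Haar transform; for every
    coefficient the Kolmogorov–Smirnov distance between its standardised
    distribution across snippets and the standard normal is the selection
    score, and the ``n_keep`` highest-scoring coefficients are retained
    (the top two make the classic 2-D feature scatter).
    """
    L = waves.snippets.shape[1]
    if L % (2**_DWT_LEVELS) != 0:
        raise ValueError(f"snippet length must be a multiple of {2 ** _DWT_LEVELS}")
    coeffs = pywt.wavedec(waves.snippets, "haar", level=_DWT_LEVELS, axis=1)
    C = np.concatenate(coeffs, axis=1)
    m, total = C.shape
    n_keep = int(n_keep)
    if not 1 <= n_keep <= total:
        raise ValueError("n_keep must be between 1 and the number of coefficients")
    scores = np.zeros(total)
    for idx in range(total):
        col = C[:, idx]
        sd = col.std()
        # a coefficient is informative only if it genuinely varies across
        # snippets (guard against representation dust on constant columns)
        varies = sd > 0 and np.ptp(col) > 1e-9 * (1.0 + np.abs(col).max())
        if varies and m > 3:
            z = (col - col.mean()) / sd
            scores[idx] = stats.kstest(z, "norm").statistic
    order = np.lexsort((np.arange(total), -scores))
    indices = np.sort(order[:n_keep])
    return FeatureMatrix(values=C[:, indices], indices=indices, scores=scores)


def cluster_initial(features: FeatureMatrix | np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means (k-means++ init, fixed seed) on the wavelet features."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > X.shape[0]:
        raise ValueError("more clusters requested than snippets")
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(X)


def bayesian_refine(
    features: FeatureMatrix | np.ndarray,
    init_labels: np.ndarray,
    reg_covar: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """Gaussian-mixture EM (full covariances) initialised from the given labels.

    Each snippet is reassigned to its maximum-posterior component.  Empty
    initial clusters are dropped with a warning.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    labels = np.asarray(init_labels, dtype=int)
    if labels.shape != (X.shape[0],):
        raise ValueError("one initial label per snippet required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < np.max(labels) + 1:
        warnings.warn("empty initial cluster(s) dropped before refinement", stacklevel=2)
    d = X.shape[1]
    means, weights, precisions = [], [], []
    for lbl, cnt in zip(uniq, counts):
        pts = X[labels == lbl]
        means.append(pts.mean(axis=0))
        weights.append(cnt / X.shape[0])
        cov = np.cov(pts, rowvar=False) if cnt > 1 else np.zeros((d, d))
        cov = np.atleast_2d(cov) + reg_covar * np.eye(d)
        precisions.append(np.linalg.inv(cov))
    if len(uniq) == 1:
        return np.zeros(X.shape[0], dtype=int)
    gm = GaussianMixture(
        n_components=len(uniq),
        covariance_type="full",
        reg_covar=reg_covar,
        tol=tol,
        max_iter=max_iter,
        weights_init=np.asarray(weights),
        means_init=np.asarray(means),
        precisions_init=np.asarray(precisions),
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # EM convergence chatter
        gm.fit(X)
        return gm.predict(X)


def summarize_units(
    waves: WaveformSet, labels: np.ndarray, flag_noise: bool = True, baseline_samples: int = 8
) -> SortResult:
    """Per-unit mean waveforms, counts, and the noise-unit flag.

    A unit's amplitude is the largest absolute excursion of its mean
    waveform from the baseline (mean of the first ``baseline_samples``
    samples); with more than one unit the lowest-amplitude unit is flagged —
    not deleted — as noise.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (waves.n_snippets,):
        raise ValueError("one label per snippet required")
    unit_ids = np.unique(labels)
    means = np.stack([waves.snippets[labels == u].mean(axis=0) for u in unit_ids])
    counts = np.array([(labels == u).sum() for u in unit_ids])
    base = means[:, :baseline_samples].mean(axis=1)
    amplitudes = np.abs(means - base[:, None]).max(axis=1)
    noise = int(unit_ids[np.argmin(amplitudes)]) if (flag_noise and unit_ids.size > 1) else None
    return SortResult(
        labels=labels,
        unit_ids=unit_ids,
        mean_waveforms=means,
        counts=counts,
        amplitudes=amplitudes,
        noise_unit=noise,
    )


class SpikeSorter(BaseEstimator):
    """End-to-end sorter: detect -> wavelet features -> k-means -> GMM -> summary.

    ``fit(trace)`` runs the pipeline; fitted attributes are ``waveforms_``,
    ``features_``, ``labels_``, ``result_`` (a :class:`SortResult`) and
    ``noise_unit_``.  Deterministic given (trace, parameters, seed).
    """

    def __init__(
        self,
        fs: float = 24000.0,
        thresh_mult: float = 4.5,
        window: int = 64,
        align_index: int = 20,
        n_keep: int = 10,
        k: int = 4,
        refine: bool = True,
        seed: int = 0,
    ):
        self.fs = fs
        self.thresh_mult = thresh_mult
        self.window = window
        self.align_index = align_index
        self.n_keep = n_keep
        self.k = k
        self.refine = refine
        self.seed = seed

    def fit(self, trace: np.ndarray, y=None) -> "SpikeSorter":
        self.waveforms_ = detect_spikes(
            trace, self.fs, self.thresh_mult, self.window, self.align_index
        )
        if self.waveforms_.n_snippets == 0:
            self.features_ = None
            self.labels_ = np.empty(0, dtype=int)
            self.result_ = None
            self.noise_unit_ = None
            return self
        self.features_ = wavelet_features(self.waveforms_, self.n_keep)
        init = cluster_initial(self.features_, self.k, seed=self.seed)
        self.labels_ = bayesian_refine(self.features_, init) if self.refine else init
        self.result_ = summarize_units(self.waveforms_, self.labels_)
        self.noise_unit_ = self.result_.noise_unit
        return self

    def fit_predict(self, trace: np.ndarray, y=None) -> np.ndarray:
        return self.fit(trace).labels_


def match_accuracy(
    pred_labels: np.ndarray, true_labels: np.ndarray
) -> tuple[float, dict]:
    """Hungarian-matched agreement between two labelings of the same snippets.

    Returns the fraction of snippets whose predicted cluster maps onto their
    true unit under the optimal one-to-one cluster/unit assignment, plus the
    mapping used.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label vectors must align")
    if pred.size == 0:
        return 0.0, {}
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(true, return_inverse=True)
    conf = np.zeros((pu.size, tu.size))
    np.add.at(conf, (pi, ti), 1)
    rows, cols = linear_sum_assignment(-conf)
    mapping = {int(pu[r]): int(tu[c]) for r, c in zip(rows, cols)}
    acc = conf[rows, cols].sum() / pred.size
    return float(acc), mapping
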