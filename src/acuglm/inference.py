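"""Maximum-likelihood fitting of the coupling weights.

The per-neuron log-likelihood under the Poisson bin model, up to the
parameter-free constant ``-sum_t log(n_t!)`` (excluded throughout; it
shifts the objective but not the optimiser), is

    ll(theta) = sum_t [ n_t * log(lambda_t * dt) - lambda_t * dt ],
    lambda_t = exp(x_t . theta),

with gradient ``X^T (n - lambda * dt)`` and Hessian
``-X^T diag(lambda * dt) X`` — concave in ``theta``, so Newton ascent from
any start finds the global optimum.

A second family, ``"bernoulli"``, is the exact likelihood of binary-mode
simulated data: ``n_t ~ Bernoulli(1 - exp(-lambda_t * dt))`` (a
complementary-log-log binomial GLM, also log-concave).  For
``lambda * dt -> 0`` the two coincide; on strongly bursting binary data the
Bernoulli family removes an O(lambda*dt/2) bias of the Poisson fit.

Standard errors come from the inverse observed Fisher information at the
optimum; Wald intervals are ``theta_hat +/- z(level) * se``.

The joint likelihood of the coupled model factorises over target neurons
given the recorded histories, so :class:`CouplingGLM` fits each neuron's
``(k_i, h_i1..h_iN)`` independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from .glm import DesignMatrix, CouplingParams, SpikeTrainSet, StimulusTrain, build_design
from .kernels import KernelSet, default_kernels

__all__ = [
    "FitResult",
    "log_likelihood",
    "loglik_gradient",
    "loglik_hessian",
    "fit_mle",
    "relative_error",
    "wald_ci",
    "CouplingGLM",
]


def _as_matrix(design) -> np.ndarray:
    return design.X if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)


def _check(X: np.ndarray, counts: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts, dtype=float)
    if X.ndim != 2 or counts.shape != (X.shape[0],):
        raise ValueError("design and counts lengths disagree")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return X, counts


def log_likelihood(theta, design, counts, dt: float, family: str = "poisson") -> float:
    """Log-likelihood (constant dropped) of ``counts`` under the exponential link."""
    X, n = _check(_as_matrix(design), counts, dt)
    eta = X @ np.asarray(theta, dtype=float)
    mu = np.exp(eta) * dt
    if family == "poisson":
        # n * log(mu) with the 0*log(0) := 0 convention (mu > 0 for finite theta)
        return float(n @ (eta + np.log(dt)) - mu.sum())
    if family == "bernoulli":
        log_p = np.log(-np.expm1(-mu))
        return float(np.where(n > 0, log_p, -mu).sum())
    raise ValueError(f"unknown family {family!r}")


def _bernoulli_weights(mu: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """d ll / d eta and d^2 ll / d eta^2, per bin, for the Bernoulli family."""
    p = -np.expm1(-mu)  # 1 - exp(-mu), accurate for small mu
    emu = np.exp(-mu)
    r = np.where(p > 0, mu * emu / np.where(p > 0, p, 1.0), 1.0)
    w1 = np.where(n > 0, r, -mu)
    curv_spike = np.where(
        p > 0, mu * emu * ((1.0 - mu) * p - mu * emu) / np.where(p > 0, p**2, 1.0), -0.5 * mu
    )
    w2 = np.where(n > 0, curv_spike, -mu)
    return w1, w2


def loglik_gradient(theta, design, counts, dt: float, family: str = "poisson") -> np.ndarray:
    """Analytic gradient; for Poisson it is ``X^T (n - lambda * dt)``."""
    X, n = _check(_as_matrix(design), counts, dt)
    mu = np.exp(X @ np.asarray(theta, dtype=float)) * dt
    if family == "poisson":
        return X.T @ (n - mu)
    if family == "bernoulli":
        w1, _ = _bernoulli_weights(mu, n)
        return X.T @ w1
    raise ValueError(f"unknown family {family!r}")


def loglik_hessian(theta, design, counts, dt: float, family: str = "poisson") -> np.ndarray:
    """Observed Hessian; negative semidefinite for both families."""
    X, n = _check(_as_matrix(design), counts, dt)
    mu = np.exp(X @ np.asarray(theta, dtype=float)) * dt
    if family == "poisson":
        w2 = -mu
    elif family == "bernoulli":
        _, w2 = _bernoulli_weights(mu, n)
    else:
        raise ValueError(f"unknown family {family!r}")
    return (X * w2[:, None]).T @ X


@dataclass
class FitResult:
    """Outcome of one per-neuron ML fit."""

    theta: np.ndarray
    loglik: float
    se: np.ndarray
    ci95: np.ndarray  # p x 2
    converged: bool
    n_iter: int
    grad_norm: float
    family: str = "poisson"
    names: tuple = field(default_factory=tuple)


def fit_mle(
    design,
    counts,
    dt: float,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    family: str = "poisson",
    names: tuple = (),
) -> FitResult:
    """Maximise the log-likelihood by damped Newton ascent (L-BFGS fallback).

    The likelihood is concave, so the optimum is global and independent of
    ``init`` (within tolerance).  Non-convergence after ``max_iter`` is
    flagged on the result, not raised.  A rank-deficient design triggers a
    warning and a pseudo-inverse Fisher matrix for the standard errors.
    """
    X, n = _check(_as_matrix(design), counts, dt)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        warnings.warn("design matrix is rank deficient; using pseudo-inverse Fisher", stacklevel=2)
    theta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()

    def f(th):
        with np.errstate(over="ignore"):
            return log_likelihood(th, X, n, dt, family)

    ll = f(theta)
    converged, n_iter, gnorm = False, 0, np.inf
    for it in range(1, max_iter + 1):
        n_iter = it
        g = loglik_gradient(theta, X, n, dt, family)
        gnorm = float(np.abs(g).max())
        if gnorm <= tol:
            converged = True
            break
        hess = loglik_hessian(theta, X, n, dt, family)
        try:
            step = linalg.solve(-hess, g, assume_a="pos")
        except linalg.LinAlgError:
            step = np.linalg.pinv(-hess) @ g
        alpha, ok = 1.0, False
        for _ in range(40):
            cand = theta + alpha * step
            ll_new = f(cand)
            if np.isfinite(ll_new) and ll_new >= ll + 1e-4 * alpha * float(g @ step):
                theta, ll, ok = cand, ll_new, True
                break
            alpha *= 0.5
        if not ok:  # Newton stalled; hand off to L-BFGS
            res = optimize.minimize(
                lambda th: -f(th),
                theta,
                jac=lambda th: -loglik_gradient(th, X, n, dt, family),
                method="L-BFGS-B",
                options={"maxiter": max_iter, "gtol": tol},
            )
            theta, ll = res.x, f(res.x)
            gnorm = float(np.abs(loglik_gradient(theta, X, n, dt, family)).max())
            converged = gnorm <= max(tol, 1e-6 * max(1.0, abs(ll)))
            break
    else:
        pass

    if not converged:
        g = loglik_gradient(theta, X, n, dt, family)
        gnorm = float(np.abs(g).max())
        converged = gnorm <= tol

    fisher = -loglik_hessian(theta, X, n, dt, family)
    try:
        cov = linalg.inv(fisher)
    except linalg.LinAlgError:
        cov = np.linalg.pinv(fisher)
    var = np.clip(np.diag(cov), 0.0, None)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    ci95 = np.column_stack([theta - z * se, theta + z * se])
    return FitResult(
        theta=theta,
        loglik=float(ll),
        se=se,
        ci95=ci95,
        converged=bool(converged),
        n_iter=n_iter,
        grad_norm=gnorm,
        family=family,
        names=tuple(names),
    )


def relative_error(true_value: float, estimate: float) -> float:
    """Percent relative error ``100 * |estimate - true| / |true|``."""
    if true_value == 0:
        raise ValueError("relative error undefined for a zero true value")
    return 100.0 * abs(estimate - true_value) / abs(true_value)


def wald_ci(fit: FitResult, level: float = 0.95) -> np.ndarray:
    """Wald intervals ``theta_hat +/- z(level) * se`` (p x 2 array)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return np.column_stack([fit.theta - z * fit.se, fit.theta + z * fit.se])


class CouplingGLM(BaseEstimator):
    """Scikit-learn style estimator for the coupled point-process GLM.

    Fits every neuron's stimulus weight and history-weight row by maximum
    likelihood on the shared design matrix.

    Parameters
    ----------
    kernels : KernelSet or None
        Fixed temporal kernels; ``None`` uses :func:`default_kernels` at the
        spike trains' bin width.
    family : {"poisson", "bernoulli"}
        Bin likelihood. ``"bernoulli"`` is the exact likelihood for
        binary-mode simulated data.
    fit_intercept : bool
        Include a per-neuron intercept column (defaults off: the model's
        baseline rate is exp(0) = 1 event/s).

    Attributes (after ``fit``)
    --------------------------
    k_ : (n,) stimulus weights; H_ : (n, n) history weights;
    intercept_ : (n,) intercepts; se_k_, se_H_ : standard errors;
    loglik_ : summed log-likelihood; converged_ : all-neuron flag;
    results_ : list of per-neuron :class:`FitResult`.
    """

    def __init__(
        self,
        kernels: KernelSet | None = None,
        family: str = "poisson",
        fit_intercept: bool = False,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.kernels = kernels
        self.family = family
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, spikes: SpikeTrainSet, stimulus: StimulusTrain) -> "CouplingGLM":
        kernels = self.kernels or default_kernels(spikes.grid.dt)
        design = build_design(stimulus, spikes, kernels)
        X = design.X
        if self.fit_intercept:
            X = np.column_stack([X, np.ones(X.shape[0])])
        n = spikes.n_neurons
        dt = spikes.grid.dt
        self.results_ = []
        for i in range(n):
            names = ("k",) + tuple(f"h{i + 1}{j + 1}" for j in range(n))
            if self.fit_intercept:
                names += ("intercept",)
            self.results_.append(
                fit_mle(
                    X,
                    spikes.counts[i],
                    dt,
                    tol=self.tol,
                    max_iter=self.max_iter,
                    family=self.family,
                    names=names,
                )
            )
        theta = np.array([r.theta for r in self.results_])
        se = np.array([r.se for r in self.results_])
        self.k_ = theta[:, 0]
        self.H_ = theta[:, 1 : 1 + n]
        self.intercept_ = theta[:, -1] if self.fit_intercept else np.zeros(n)
        self.se_k_ = se[:, 0]
        self.se_H_ = se[:, 1 : 1 + n]
        self.loglik_ = float(sum(r.loglik for r in self.results_))
        self.converged_ = all(r.converged for r in self.results_)
        self.design_ = design
        self.kernels_ = kernels
        return self

    def coupling_params_(self) -> CouplingParams:
        """Fitted weights packed as :class:`CouplingParams`."""
        return CouplingParams(k=self.k_, H=self.H_, intercept=self.intercept_)

    def predict_intensity(self, spikes: SpikeTrainSet, stimulus: StimulusTrain) -> np.ndarray:
        """Fitted conditional intensity (events/s) for each neuron, n x n_bins."""
        from .glm import conditional_intensity

        design = build_design(stimulus, spikes, self.kernels_)
        params = self.coupling_params_()
        return np.vstack(
            [conditional_intensity(params, design, i) for i in range(spikes.n_neurons)]
        )
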