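"""Relevance vector machine: sparse Bayesian kernel regression/classification.

The RVM places an independent zero-mean Gaussian prior with precision
``alpha_i`` on every weight of a kernel expansion

    f(x) = w_0 + sum_j w_j K(x, basis_j),

and maximises the marginal likelihood (evidence) over the ``alpha_i`` and,
for regression, the noise variance ``sigma^2``.  Most precisions diverge
during the iteration, pruning their basis functions; the surviving inputs
are the *relevance vectors*, so the fitted model is sparse and its outputs
are probabilistic.

Regression mode implements the Gaussian-likelihood updates literally:

    Sigma = (sigma^-2 Phi^T Phi + A)^-1          A = diag(alpha)
    mu    = sigma^-2 Sigma Phi^T t
    gamma_i = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / mu_i^2
    sigma^2 <- ||t - Phi mu||^2 / (N - sum_i gamma_i)

Binary classification replaces the Gaussian likelihood with a Bernoulli
likelihood through the logistic sigmoid; the posterior mode is found by
iteratively reweighted least squares (a Laplace approximation), giving
Sigma = (Phi^T B Phi + A)^-1 with B the IRLS weight diagonal, and the same
alpha update is applied in the outer loop.  There is no noise variance in
this mode.  The fit is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.spatial.distance import cdist, pdist
from scipy.special import expit

__all__ = [
    "KernelSpec",
    "DesignMatrix",
    "RVMModel",
    "RVMConfig",
    "FitDiagnostics",
    "median_heuristic_gamma",
    "kernel_matrix",
    "design_matrix",
    "regression_posterior",
    "regression_log_marginal",
    "fit_rvm_regressor",
    "fit_rvm_classifier",
    "predict",
]

logger = logging.getLogger(__name__)

PRUNE_THRESHOLD = 1e12
ALPHA_INIT = 1e-6
SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class KernelSpec:
    """Kernel configuration.

    ``gamma=None`` requests the data-scaled default, 1 / median pairwise
    squared distance of the training inputs, resolved when a model is fitted.
    """

    kind: str = "rbf"
    gamma: Optional[float] = None
    include_bias: bool = True

    def __post_init__(self) -> None:
        if self.kind != "rbf":
            raise ValueError(f"unsupported kernel kind {self.kind!r}")
        if self.gamma is not None and not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


@dataclass(frozen=True)
class DesignMatrix:
    """N x (M+1) kernel design matrix (leading ones column when biased)."""

    values: np.ndarray
    basis_points: np.ndarray
    include_bias: bool


@dataclass(frozen=True)
class RVMModel:
    """Fitted sparse Bayesian model, restricted to the surviving basis."""

    mode: str                          # "regression" | "classification"
    kernel: KernelSpec                 # gamma always resolved
    relevance_vectors: np.ndarray      # (M_kept, d) retained basis inputs
    has_bias: bool                     # bias column survived pruning
    weights_mean: np.ndarray           # posterior mean over retained weights
    weights_covariance: np.ndarray     # posterior covariance (Laplace in clf.)
    alphas: np.ndarray                 # retained precisions
    noise_variance: Optional[float]    # sigma^2, regression only
    n_features: int

    @property
    def n_relevance_vectors(self) -> int:
        return int(self.relevance_vectors.shape[0])


@dataclass(frozen=True)
class RVMConfig:
    """Settings forwarded to the fit functions by the pipeline."""

    kernel: KernelSpec = KernelSpec()
    max_iter: int = 1000
    tol: float = 1e-3
    prune_threshold: float = PRUNE_THRESHOLD


@dataclass
class FitDiagnostics:
    iterations_run: int
    converged: bool
    gammas: np.ndarray
    log_marginal_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Kernels and the design matrix
# ---------------------------------------------------------------------------

def median_heuristic_gamma(X: np.ndarray) -> float:
    """1 / median pairwise squared Euclidean distance (1.0 for degenerate X)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        return 1.0
    d2 = pdist(X, metric="sqeuclidean")
    med = float(np.median(d2))
    return 1.0 / med if med > 0 else 1.0


def kernel_matrix(X: np.ndarray, Y: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    if kernel.gamma is None:
        raise ValueError("kernel gamma is unresolved; fit a model or set gamma")
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    return np.exp(-kernel.gamma * d2)


def design_matrix(X: np.ndarray, basis: np.ndarray, kernel: KernelSpec) -> DesignMatrix:
    """Design matrix Phi with Phi[i, j+1] = K(x_i, basis_j) (column 0 = ones)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    if X.shape[1] != basis.shape[1]:
        raise ValueError(
            f"dimension mismatch: inputs have d={X.shape[1]}, basis d={basis.shape[1]}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(basis))):
        raise ValueError("non-finite inputs to design_matrix")
    K = kernel_matrix(X, basis, kernel)
    if kernel.include_bias:
        K = np.hstack([np.ones((X.shape[0], 1)), K])
    return DesignMatrix(values=K, basis_points=basis, include_bias=kernel.include_bias)


# ---------------------------------------------------------------------------
# Numerics
# ---------------------------------------------------------------------------

def _chol_spd(H: np.ndarray):
    """Cholesky with escalating jitter; Sigma inversion can be ill-conditioned
    after aggressive pruning."""
    jitter = 1e-10
    scale = float(np.mean(np.diag(H))) or 1.0
    for attempt in range(4):
        try:
            return cho_factor(H if attempt == 0 else H + jitter * scale * np.eye(H.shape[0]),
                              lower=True)
        except LinAlgError:
            if attempt > 0:
                jitter *= 10.0
    raise LinAlgError("SPD factorization failed even with jitter")


def _spd_solve(H: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cho_solve(_chol_spd(H), b)


def _spd_inverse(H: np.ndarray) -> np.ndarray:
    c = _chol_spd(H)
    inv = cho_solve(c, np.eye(H.shape[0]))
    return 0.5 * (inv + inv.T)


# ---------------------------------------------------------------------------
# Regression posterior (also the module's published oracle-checkable step)
# ---------------------------------------------------------------------------

def regression_posterior(
    Phi: np.ndarray, alpha: np.ndarray, sigma2: float, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior covariance and mean of the weights at fixed (alpha, sigma^2).

    Sigma = (sigma^-2 Phi^T Phi + diag(alpha))^-1,  mu = sigma^-2 Sigma Phi^T t.
    """
    Phi = np.asarray(Phi, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    t = np.asarray(t, dtype=float)
    H = Phi.T @ Phi / sigma2 + np.diag(alpha)
    Sigma = _spd_inverse(H)
    mu = Sigma @ (Phi.T @ t) / sigma2
    return Sigma, mu


def regression_log_marginal(
    Phi: np.ndarray, alpha: np.ndarray, sigma2: float, t: np.ndarray
) -> float:
    """Gaussian evidence log p(t | alpha, sigma^2) with
    Omega = sigma^2 I + Phi A^-1 Phi^T."""
    n = Phi.shape[0]
    Omega = sigma2 * np.eye(n) + (Phi / alpha) @ Phi.T
    c = _chol_spd(Omega)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    quad = float(t @ cho_solve(c, t))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


# ---------------------------------------------------------------------------
# Shared fitting scaffolding
# ---------------------------------------------------------------------------

def _resolve_kernel(kernel: Optional[KernelSpec], X: np.ndarray) -> KernelSpec:
    kernel = kernel or KernelSpec()
    if kernel.gamma is None:
        kernel = replace(kernel, gamma=median_heuristic_gamma(X))
    return kernel


def _finalize(
    mode: str,
    kernel: KernelSpec,
    X: np.ndarray,
    active: np.ndarray,
    mu: np.ndarray,
    Sigma: np.ndarray,
    alpha: np.ndarray,
    sigma2: Optional[float],
) -> RVMModel:
    offset = 1 if kernel.include_bias else 0
    has_bias = kernel.include_bias and 0 in active
    rv_idx = np.array([j - offset for j in active if j >= offset], dtype=int)
    return RVMModel(
        mode=mode,
        kernel=kernel,
        relevance_vectors=X[rv_idx].copy(),
        has_bias=bool(has_bias),
        weights_mean=mu.copy(),
        weights_covariance=Sigma.copy(),
        alphas=alpha.copy(),
        noise_variance=sigma2,
        n_features=X.shape[1],
    )


def _alpha_update(
    alpha: np.ndarray, mu: np.ndarray, Sigma: np.ndarray, prune_threshold: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evidence-maximisation step: returns (new_alpha, gamma, keep_mask).

    gamma_i = 1 - alpha_i Sigma_ii measures how well weight i is determined
    by the data.  mu_i == 0 exactly (which would divide by zero) prunes, as
    does new_alpha above the threshold.
    """
    gamma = 1.0 - alpha * np.diag(Sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        new_alpha = gamma / np.square(mu)
    new_alpha = np.where(mu == 0.0, np.inf, new_alpha)
    # A negative gamma is pure round-off at machine scale; treat as determined-out.
    new_alpha = np.where(new_alpha <= 0.0, np.inf, new_alpha)
    keep = np.isfinite(new_alpha) & (new_alpha <= prune_threshold)
    if not np.any(keep):
        # Never empty the model entirely: keep the best-determined weight.
        keep[int(np.argmin(np.where(np.isfinite(new_alpha), new_alpha, np.inf)))] = True
        new_alpha = np.minimum(new_alpha, prune_threshold)
    return new_alpha, gamma, keep


def _log_alpha_delta(old: np.ndarray, new: np.ndarray, keep: np.ndarray) -> float:
    o = old[keep]
    n = new[keep]
    return float(np.max(np.abs(np.log(n) - np.log(o)))) if o.size else 0.0


# ---------------------------------------------------------------------------
# Regression fit
# ---------------------------------------------------------------------------

def fit_rvm_regressor(
    X: np.ndarray,
    t: np.ndarray,
    kernel: Optional[KernelSpec] = None,
    max_iter: int = 1000,
    tol: float = 1e-3,
    prune_threshold: float = PRUNE_THRESHOLD,
) -> tuple[RVMModel, FitDiagnostics]:
    """Fit the Gaussian-likelihood RVM by evidence maximisation.

    Non-convergence within ``max_iter`` is reported through
    ``FitDiagnostics.converged``, never raised.  Constant targets fit the
    bias-dominated model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    if t.shape != (n,):
        raise ValueError(f"targets must have shape ({n},), got {t.shape}")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite targets")

    kernel = _resolve_kernel(kernel, X)
    Phi_full = design_matrix(X, X, kernel).values
    M = Phi_full.shape[1]

    active = np.arange(M)
    alpha = np.full(M, ALPHA_INIT)
    sigma2 = max(0.1 * float(np.var(t)), 1e-6)

    trace: list[float] = []
    converged = False
    it = 0
    gamma = np.zeros(M)
    Sigma = np.empty((0, 0))
    mu = np.empty(0)
    for it in range(1, max_iter + 1):
        Phi = Phi_full[:, active]
        Sigma, mu = regression_posterior(Phi, alpha, sigma2, t)
        trace.append(regression_log_marginal(Phi, alpha, sigma2, t))

        new_alpha, gamma, keep = _alpha_update(alpha, mu, Sigma, prune_threshold)
        resid = t - Phi @ mu
        denom = max(n - float(np.sum(gamma)), 1e-9)
        sigma2 = max(float(resid @ resid) / denom, SIGMA2_FLOOR)

        delta = _log_alpha_delta(alpha, new_alpha, keep)
        active = active[keep]
        alpha = new_alpha[keep]
        if delta < tol:
            converged = True
            break

    Phi = Phi_full[:, active]
    Sigma, mu = regression_posterior(Phi, alpha, sigma2, t)
    gamma = 1.0 - alpha * np.diag(Sigma)
    model = _finalize("regression", kernel, X, active, mu, Sigma, alpha, sigma2)
    return model, FitDiagnostics(it, converged, gamma, trace)


# ---------------------------------------------------------------------------
# Classification fit (Laplace / IRLS)
# ---------------------------------------------------------------------------

def _bernoulli_loglik(z: np.ndarray, y: np.ndarray) -> float:
    # sum_i [y log sigmoid(z) + (1-y) log(1 - sigmoid(z))], stable form
    return -float(np.sum(np.logaddexp(0.0, -z) * y + np.logaddexp(0.0, z) * (1.0 - y)))


def _irls_mode(
    Phi: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray,
    w0: np.ndarray,
    max_inner: int = 50,
    grad_tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton/IRLS search for the mode of the penalized Bernoulli posterior.

    Returns (w_mode, Sigma, data_loglik_at_mode) with
    Sigma = (Phi^T B Phi + A)^-1 evaluated at the mode.
    """
    w = w0.copy()

    def objective(w_: np.ndarray) -> float:
        return _bernoulli_loglik(Phi @ w_, y) - 0.5 * float(np.sum(alpha * w_ * w_))

    current = objective(w)
    H = None
    for _ in range(max_inner):
        z = Phi @ w
        p = expit(z)
        g = Phi.T @ (y - p) - alpha * w
        if np.max(np.abs(g)) < grad_tol:
            break
        B = np.clip(p * (1.0 - p), 1e-12, None)
        H = (Phi.T * B) @ Phi + np.diag(alpha)
        step_dir = _spd_solve(H, g)
        step = 1.0
        for _ in range(25):  # backtracking keeps Newton monotone
            cand = w + step * step_dir
            val = objective(cand)
            if val >= current - 1e-12:
                break
            step *= 0.5
        if val < current - 1e-10:
            break  # no ascent possible; accept current mode
        w, current = cand, val
    z = Phi @ w
    p = expit(z)
    B = np.clip(p * (1.0 - p), 1e-12, None)
    H = (Phi.T * B) @ Phi + np.diag(alpha)
    Sigma = _spd_inverse(H)
    return w, Sigma, _bernoulli_loglik(z, y)


def fit_rvm_classifier(
    X: np.ndarray,
    y: np.ndarray,
    kernel: Optional[KernelSpec] = None,
    max_iter: int = 1000,
    tol: float = 1e-3,
    prune_threshold: float = PRUNE_THRESHOLD,
) -> tuple[RVMModel, FitDiagnostics]:
    """Fit the Bernoulli-likelihood (sigmoid) RVM classifier.

    Inner loop: IRLS to the posterior mode; outer loop: the same
    ``gamma_i / mu_i^2`` precision update and pruning as the regressor.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 samples for classification, got {n}")
    if y.shape != (n,):
        raise ValueError(f"labels must have shape ({n},), got {y.shape}")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    if classes.size < 2:
        raise ValueError("labels contain a single class")

    kernel = _resolve_kernel(kernel, X)
    Phi_full = design_matrix(X, X, kernel).values
    M = Phi_full.shape[1]

    active = np.arange(M)
    alpha = np.full(M, ALPHA_INIT)
    w = np.zeros(M)

    trace: list[float] = []
    converged = False
    it = 0
    gamma = np.zeros(M)
    Sigma = np.empty((0, 0))
    for it in range(1, max_iter + 1):
        Phi = Phi_full[:, active]
        w, Sigma, data_ll = _irls_mode(Phi, y, alpha, w)
        # Laplace-approximate evidence, recorded for diagnostics
        sign, logdet_Sigma = np.linalg.slogdet(Sigma)
        trace.append(
            data_ll
            - 0.5 * float(np.sum(alpha * w * w))
            + 0.5 * logdet_Sigma
            + 0.5 * float(np.sum(np.log(alpha)))
        )

        new_alpha, gamma, keep = _alpha_update(alpha, w, Sigma, prune_threshold)
        delta = _log_alpha_delta(alpha, new_alpha, keep)
        active = active[keep]
        alpha = new_alpha[keep]
        w = w[keep]
        if delta < tol:
            converged = True
            break

    Phi = Phi_full[:, active]
    w, Sigma, _ = _irls_mode(Phi, y, alpha, w)
    gamma = 1.0 - alpha * np.diag(Sigma)
    model = _finalize("classification", kernel, X, active, w, Sigma, alpha, None)
    return model, FitDiagnostics(it, converged, gamma, trace)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(model: RVMModel, X: np.ndarray) -> np.ndarray:
    """Score new inputs.

    Regression mode returns the posterior predictive mean; classification
    mode returns interaction probabilities ``sigmoid(latent mean)`` in
    (0, 1).  The decision label is ``score >= 0.5``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"dimension mismatch: model was trained on d={model.n_features}, "
            f"inputs have d={X.shape[1]}"
        )
    blocks = []
    if model.has_bias:
        blocks.append(np.ones((X.shape[0], 1)))
    if model.n_relevance_vectors:
        blocks.append(kernel_matrix(X, model.relevance_vectors, model.kernel))
    Phi = np.hstack(blocks) if blocks else np.zeros((X.shape[0], 0))
    latent = Phi @ model.weights_mean if Phi.shape[1] else np.zeros(X.shape[0])
    if model.mode == "classification":
        return expit(latent)
    return latent
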