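"""Spatial gating networks: softmax gates and normalized Gaussian gates.

The mixture weights of the clustering models depend on each voxel's 3D
position v_i through a *gating function* π_k(v_i), so that clusters are
spatially coherent.  Two families are implemented:

* **softmax gates** — multinomial-logistic weights
  π_k(v) = exp(α_kᵀ ṽ) / Σ_l exp(α_lᵀ ṽ) with class K as the zero-vector
  reference; ṽ augments v with a constant 1 (intercept) by default.  Their
  M-step has no closed form and is solved by Newton–Raphson (IRLS).
* **normalized Gaussian gates** — π_k(v) = w_k φ₃(v; μ_k, R_k) / Σ_l w_l
  φ₃(v; μ_l, R_l), with fully closed-form M-step updates (the weighted-GMM
  estimates of w, μ, R).

The spatial covariance of the Gaussian gates is shrunk by a factor
λ ∈ (0, 1] at every M-step, R̃_k = λ R_k.  Because det(λR) = λ³ det(R), λ
directly controls the spatial volume each cluster claims: small λ yields
compact clusters (appropriate for tumors, which are spatially tight), λ = 1
recovers the plain maximum-likelihood estimate.  λ ≈ 0.075 is the default.

All gate evaluations are done in log space and return exact row-stochastic
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import (
    EmptyClusterError,
    NumericalFailureError,
    ParameterError,
    SPDViolationError,
)

#: Default spatial-covariance shrinkage factor.
DEFAULT_LAMBDA = 0.075

#: Relative jitter added to keep covariances positive definite.
SPD_FLOOR_EPS = 1e-6


@dataclass
class SoftmaxGateParams:
    """Parameters of K-class softmax gates over 3D coordinates.

    ``alpha`` is (K−1)×(3+1) with an intercept column last (or (K−1)×3 when
    ``intercept`` is False); class K is the implicit zero-vector reference.
    """

    alpha: np.ndarray
    K: int
    intercept: bool = True

    def __post_init__(self) -> None:
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        ncol = 4 if self.intercept else 3
        if self.K < 1:
            raise ParameterError("K must be >= 1")
        if self.K == 1:
            self.alpha = np.zeros((0, ncol))
        elif self.alpha.shape != (self.K - 1, ncol):
            raise ParameterError(
                f"alpha must be {(self.K - 1, ncol)}, got {self.alpha.shape}"
            )

    @classmethod
    def zeros(cls, K: int, intercept: bool = True) -> "SoftmaxGateParams":
        return cls(alpha=np.zeros((max(K - 1, 0), 4 if intercept else 3)), K=K,
                   intercept=intercept)


@dataclass
class GaussianGateParams:
    """Parameters of normalized Gaussian gates: weights, means, covariances."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    lambda_reg: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        K = self.weights.size
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ParameterError("gate weights must be a probability vector")
        if self.means.shape != (K, 3) or self.covariances.shape != (K, 3, 3):
            raise ParameterError("means must be Kx3 and covariances Kx3x3")
        if not 0.0 < self.lambda_reg <= 1.0:
            raise ParameterError("lambda_reg must lie in (0, 1]")

    @property
    def K(self) -> int:
        return self.weights.size


def _augment(coords: np.ndarray, intercept: bool) -> np.ndarray:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if intercept:
        return np.hstack([coords, np.ones((coords.shape[0], 1))])
    return coords


def log_softmax_gate(coords: np.ndarray, params: SoftmaxGateParams) -> np.ndarray:
    """Row-wise log gate weights, log π_k(v_i; α), shape n×K."""
    X = _augment(coords, params.intercept)
    n = X.shape[0]
    logits = np.zeros((n, params.K))
    if params.K > 1:
        logits[:, : params.K - 1] = X @ params.alpha.T
    return logits - logsumexp(logits, axis=1, keepdims=True)


def softmax_gate(coords: np.ndarray, params: SoftmaxGateParams) -> np.ndarray:
    """Softmax gate weights π_k(v_i; α); each row is an exact simplex."""
    w = np.exp(log_softmax_gate(coords, params))
    return w / w.sum(axis=1, keepdims=True)


def _chol_or_raise(R: np.ndarray) -> np.ndarray:
    Rs = 0.5 * (R + R.T)
    try:
        return np.linalg.cholesky(Rs)
    except np.linalg.LinAlgError as exc:
        raise SPDViolationError("gate covariance is not positive definite") from exc


def log_gaussian_joint(coords: np.ndarray, params: GaussianGateParams) -> np.ndarray:
    """n×K matrix of log[w_k φ₃(v_i; μ_k, R_k)] (the unnormalized gate term)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    out = np.empty((n, params.K))
    for k in range(params.K):
        L = _chol_or_raise(params.covariances[k])
        diff = coords - params.means[k]
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        logw = np.log(params.weights[k]) if params.weights[k] > 0 else -np.inf
        out[:, k] = logw - 0.5 * (3 * np.log(2 * np.pi) + logdet + maha)
    return out


def gaussian_gate(coords: np.ndarray, params: GaussianGateParams) -> np.ndarray:
    """Normalized Gaussian gate weights; each row is an exact simplex."""
    lg = log_gaussian_joint(coords, params)
    w = np.exp(lg - logsumexp(lg, axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


def regularize_covariance(R: np.ndarray, lambda_reg: float) -> np.ndarray:
    """Shrink a 3×3 spatial covariance, R̃ = λR, then floor it to stay SPD.

    The floor adds ε·tr(λR)/3·I (ε = 1e−6), preventing collapse when a
    cluster becomes spatially degenerate (e.g. all mass on one slice).
    """
    if not 0.0 < lambda_reg <= 1.0:
        raise ParameterError("lambda_reg must lie in (0, 1]")
    R = np.asarray(R, dtype=float)
    out = lambda_reg * 0.5 * (R + R.T)
    trace = np.trace(out)
    floor = SPD_FLOOR_EPS * (trace / 3.0 if trace > 0 else 1.0)
    return out + floor * np.eye(3)


def update_gaussian_gate(
    coords: np.ndarray, resp: np.ndarray, lambda_reg: float = DEFAULT_LAMBDA
) -> GaussianGateParams:
    """Closed-form M-step for the Gaussian gates.

    Given responsibilities τ, the maximizers of the gate Q-term are the
    weighted-GMM statistics: w_k = Σᵢτ_ik/n, μ_k the τ-weighted coordinate
    mean, R_k the τ-weighted scatter about μ_k.  R_k is then shrunk by λ and
    SPD-floored.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    resp = np.atleast_2d(np.asarray(resp, dtype=float))
    n, K = resp.shape
    col = resp.sum(axis=0)
    if np.any(col <= 0):
        raise EmptyClusterError("a gate component received zero responsibility")
    weights = col / n
    means = (resp.T @ coords) / col[:, None]
    covs = np.empty((K, 3, 3))
    for k in range(K):
        diff = coords - means[k]
        covs[k] = regularize_covariance(
            (resp[:, k, None] * diff).T @ diff / col[k], lambda_reg
        )
    return GaussianGateParams(
        weights=weights, means=means, covariances=covs, lambda_reg=lambda_reg
    )


def softmax_gate_q(coords: np.ndarray, resp: np.ndarray, params: SoftmaxGateParams) -> float:
    """The gate term of the Q-function, Σᵢ Σ_k τ_ik log π_k(v_i; α)."""
    return float(np.sum(resp * log_softmax_gate(coords, params)))


def update_softmax_gate(
    coords: np.ndarray,
    resp: np.ndarray,
    init: SoftmaxGateParams,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> SoftmaxGateParams:
    """Newton–Raphson (IRLS) ascent of the softmax-gate Q-term.

    Maximizes the weighted multinomial-logistic log-likelihood with the
    responsibilities as soft targets.  Each Newton step is damped by
    step-halving so the Q-term never decreases; iteration stops when the
    gradient max-norm falls below ``tol`` or after ``max_iter`` steps.  On a
    non-finite objective the previous iterate is kept.
    """
    K = init.K
    if K < 2:
        return init
    X = _augment(coords, init.intercept)
    resp = np.atleast_2d(np.asarray(resp, dtype=float))
    n, d = X.shape
    alpha = init.alpha.copy()

    def q_of(a: np.ndarray) -> float:
        p = SoftmaxGateParams(alpha=a, K=K, intercept=init.intercept)
        return softmax_gate_q(coords, resp, p)

    q_cur = q_of(alpha)
    if not np.isfinite(q_cur):
        raise NumericalFailureError("softmax gate objective is non-finite at init")
    for _ in range(max_iter):
        probs = softmax_gate(coords, SoftmaxGateParams(alpha=alpha, K=K, intercept=init.intercept))
        # gradient: per non-reference class k, Σ_i (τ_ik − π_ik) x_i
        grad = (resp[:, : K - 1] - probs[:, : K - 1]).T @ X  # (K-1, d)
        if np.max(np.abs(grad)) < tol:
            break
        # Hessian of the negative objective, blocks H[k,l] = Σ_i π_ik(δ_kl − π_il) x xᵀ
        H = np.zeros(((K - 1) * d, (K - 1) * d))
        for k in range(K - 1):
            for l in range(k, K - 1):
                w = probs[:, k] * ((k == l) - probs[:, l])
                block = (X * w[:, None]).T @ X
                H[k * d:(k + 1) * d, l * d:(l + 1) * d] = block
                if l != k:
                    H[l * d:(l + 1) * d, k * d:(k + 1) * d] = block
        H += 1e-10 * np.eye(H.shape[0])
        try:
            step = np.linalg.solve(H, grad.ravel()).reshape(K - 1, d)
        except np.linalg.LinAlgError:
            step = grad  # fall back to gradient ascent
        # step-halving to guarantee ascent
        scale = 1.0
        for _half in range(30):
            cand = alpha + scale * step
            q_new = q_of(cand)
            if np.isfinite(q_new) and q_new >= q_cur:
                alpha, q_cur = cand, q_new
                break
            scale *= 0.5
        else:
            break  # no ascent direction found; keep current alpha
    return SoftmaxGateParams(alpha=alpha, K=K, intercept=init.intercept)
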