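"""Two-fold spatial mixtures over OLS basis coefficients (SgMVFR / SsMVFR).

Instead of estimating the functional approximation and the clustering
simultaneously, the two-fold approach first projects every decay curve onto
the basis by ordinary least squares (stage 1), then clusters the resulting
r-dimensional coefficient vectors β̂_i with a spatially gated multivariate
Gaussian mixture (stage 2): component k is φ_r(β̂; m_k, C_k) with a full
covariance C_k, and the gates are the same Gaussian or softmax spatial
gating networks used by the one-stage models.  The stage-2 M-step updates
are the classical weighted-GMM statistics; gate updates are shared with the
one-stage EM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .basis import CoefficientVectors, DesignMatrix, ols_projection
from .em_functional import (
    FitConfig,
    FitResult,
    _init_gate,
    _one_hot,
    _prune_empty,
    bayes_allocate,
)
from .errors import EmptyClusterError, ParameterError, SPDViolationError
from .gating import (
    GaussianGateParams,
    log_gaussian_joint,
    log_softmax_gate,
    update_gaussian_gate,
    update_softmax_gate,
)
from .volumes import CurveDataset

#: Relative jitter keeping component covariances positive definite; r can
#: approach the cluster size in small clusters.
COV_FLOOR_EPS = 1e-6


@dataclass
class VectorizedComponent:
    """One multivariate Gaussian component over coefficient vectors."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        r = self.mean.size
        if self.covariance.shape != (r, r):
            raise ParameterError("covariance must be r x r")


def _comp_logpdf(coeffs: np.ndarray, comp: VectorizedComponent) -> np.ndarray:
    r = comp.mean.size
    C = 0.5 * (comp.covariance + comp.covariance.T)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise SPDViolationError("component covariance is not positive definite") from exc
    diff = coeffs - comp.mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (r * np.log(2 * np.pi) + logdet + maha)


def e_step_vectorized(
    coeffs: CoefficientVectors,
    coords: np.ndarray,
    gate_params,
    components: list[VectorizedComponent],
) -> tuple[np.ndarray, float]:
    """Responsibilities and objective for the coefficient-space mixture.

    Gaussian gates: τ_ik ∝ w_k φ₃(v_i; μ_k, R_k) φ_r(β̂_i; m_k, C_k) and
    the objective is joint over (v, β̂); softmax gates: τ_ik ∝
    π_k(v_i; α) φ_r(β̂_i; ...) with the conditional objective.
    """
    X = coeffs.values
    comp_ll = np.column_stack([_comp_logpdf(X, c) for c in components])
    if isinstance(gate_params, GaussianGateParams):
        gate_log = log_gaussian_joint(coords, gate_params)
    else:
        gate_log = log_softmax_gate(coords, gate_params)
    log_joint = gate_log + comp_ll
    log_norm = logsumexp(log_joint, axis=1)
    resp = np.exp(log_joint - log_norm[:, None])
    resp /= resp.sum(axis=1, keepdims=True)
    return resp, float(log_norm.sum())


def m_step_components(
    coeffs: CoefficientVectors, resp: np.ndarray, floor_eps: float = COV_FLOOR_EPS
) -> list[VectorizedComponent]:
    """Weighted mean and scatter of the coefficient vectors per component."""
    X = coeffs.values
    resp = np.atleast_2d(np.asarray(resp, dtype=float))
    r = X.shape[1]
    col = resp.sum(axis=0)
    if np.any(col <= 0):
        raise EmptyClusterError("a component received zero responsibility")
    comps = []
    for k in range(resp.shape[1]):
        mean = resp[:, k] @ X / col[k]
        diff = X - mean
        C = (resp[:, k, None] * diff).T @ diff / col[k]
        trace = np.trace(C)
        C = C + floor_eps * (trace / r if trace > 0 else 1.0) * np.eye(r)
        comps.append(VectorizedComponent(mean=mean, covariance=C))
    return comps


def fit_vectorized(
    dataset: CurveDataset, design: DesignMatrix, config: FitConfig
) -> FitResult:
    """Two-fold fit: OLS projection, then spatially gated GMM by EM.

    Shares initialization, convergence, pruning and allocation contracts
    with :func:`spectclust.em_functional.fit`.  No standardization is
    applied to the coefficient vectors; the full covariances C_k absorb
    scale.
    """
    from .initsearch import voronoi_init

    n = dataset.n_voxels
    if n <= config.K:
        raise ParameterError(f"need n > K, got n={n}, K={config.K}")

    coeffs = ols_projection(dataset, design)
    coords = dataset.coords

    if config.init_labels is not None:
        labels0 = np.asarray(config.init_labels).ravel()
        if labels0.size != n:
            raise ParameterError("init_labels length must equal n")
    else:
        labels0 = voronoi_init(coords, config.K, seed=config.seed)
    K0 = int(labels0.max())
    resp = _one_hot(labels0, K0)

    prune_threshold = design.n_basis + 1
    if config.prune:
        resp, _, _ = _prune_empty(resp, None, list(range(K0)), prune_threshold)

    gate_params = _init_gate(coords, resp, config)
    components = m_step_components(coeffs, resp)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(config.max_iter):
        resp, ll = e_step_vectorized(coeffs, coords, gate_params, components)
        trace.append(ll)
        n_iter = it + 1
        if it > 0 and abs(ll - trace[-2]) <= config.tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
        if config.prune:
            resp, gate_params, components = _prune_empty(
                resp, gate_params, components, prune_threshold
            )
        if config.gate_kind == "gaussian":
            gate_params = update_gaussian_gate(coords, resp, config.lambda_reg)
        else:
            gate_params = update_softmax_gate(
                coords, resp, gate_params, max_iter=config.irls_max_iter
            )
        components = m_step_components(coeffs, resp)

    labels = bayes_allocate(resp)
    return FitResult(
        gate_params=gate_params,
        components=components,
        responsibilities=resp,
        labels=labels,
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        active_K=resp.shape[1],
        objective="joint" if config.gate_kind == "gaussian" else "conditional",
        seed=config.seed,
    )
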