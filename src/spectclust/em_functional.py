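"""One-stage spatial mixtures of functional regressions (SgMFR / SsMFR).

Each cluster k is a functional Gaussian regression: the decay curve of a
voxel assigned to k is modeled as y_i = B(x) β_k + ε, ε ~ N(0, σ_k² I_m),
where B(x) is the shared basis design over the energy axis.  The mixture
weights are spatial gates over the voxel coordinates — normalized Gaussian
gates (SgMFR) or softmax gates (SsMFR).  Parameters are estimated by EM:

* E-step: responsibilities τ_ik ∝ gate_ik · φ_m(y_i; Bβ_k, σ_k²I),
  evaluated in log space with a log-sum-exp normalizer.
* M-step: the gate update is the closed-form weighted-GMM step (Gaussian
  gates, with λ-shrinkage of the spatial covariance) or a damped
  Newton–Raphson ascent (softmax gates); the regression update is a
  responsibility-weighted least-squares solve for β_k and a weighted mean
  squared residual for σ_k².

For Gaussian gates the maximized objective is the *joint* log-likelihood of
(v_i, y_i); for softmax gates it is the *conditional* log-likelihood of
y_i given v_i.  The two traces are not numerically comparable, and
``FitResult.objective`` records which one is reported.  With λ = 1 the
Gaussian-gate trace is non-decreasing by the EM guarantee; λ < 1 replaces
the covariance maximizer with a shrunk estimate and trades exact
monotonicity for spatial compactness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .basis import DesignMatrix
from .errors import (
    EmptyClusterError,
    ParameterError,
    SingularDesignError,
)
from .gating import (
    DEFAULT_LAMBDA,
    GaussianGateParams,
    SoftmaxGateParams,
    log_gaussian_joint,
    log_softmax_gate,
    update_gaussian_gate,
    update_softmax_gate,
)
from .volumes import CurveDataset

#: Variance floor for the regression components, on unit-scale (standardized
#: HU) data.
SIGMA2_FLOOR = 1e-8


@dataclass
class RegressionComponent:
    """One functional Gaussian regressor: basis coefficients and noise variance."""

    beta: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.sigma2 = float(self.sigma2)
        if self.sigma2 <= 0:
            raise ParameterError("sigma2 must be positive")


@dataclass
class FitConfig:
    """Configuration of an EM fit.

    ``gate_kind`` selects the spatial gating family ("gaussian" or
    "softmax"); ``K`` the initial number of clusters; ``lambda_reg`` the
    spatial-covariance shrinkage (Gaussian gates only); ``tol`` the relative
    log-likelihood change below which EM stops; ``standardize`` rescales HU
    curves to zero mean / unit variance internally (undone on output).
    Components whose total responsibility falls below r+1 observations are
    pruned and the fit continues with fewer active clusters.
    """

    gate_kind: str = "gaussian"
    K: int = 5
    lambda_reg: float = DEFAULT_LAMBDA
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    init_labels: np.ndarray | None = None
    standardize: bool = True
    intercept: bool = True
    irls_max_iter: int = 10
    prune: bool = True

    def __post_init__(self) -> None:
        if self.gate_kind not in ("gaussian", "softmax"):
            raise ParameterError(f"unknown gate kind {self.gate_kind!r}")
        if self.K < 1:
            raise ParameterError("K must be >= 1")


@dataclass
class FitResult:
    """Outcome of an EM fit.

    ``labels`` are 1-based hard assignments by the Bayes allocation rule
    (row-argmax of ``responsibilities``); ``loglik_trace`` holds the
    objective value at each E-step; ``objective`` is "joint" (Gaussian
    gates) or "conditional" (softmax gates); ``active_K`` counts the
    clusters that survived pruning.
    """

    gate_params: object
    components: list
    responsibilities: np.ndarray
    labels: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    active_K: int
    objective: str
    seed: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def component_curve_loglik(
    dataset: CurveDataset, design: DesignMatrix, comp: RegressionComponent
) -> np.ndarray:
    """Per-voxel log φ_m(y_i; Bβ_k, σ_k² I) for one regression component."""
    if comp.sigma2 <= 0:
        raise ParameterError("sigma2 must be positive")
    m = dataset.n_energies
    resid = dataset.curves - design.values @ comp.beta
    ss = np.sum(resid**2, axis=1)
    return -0.5 * (m * np.log(2 * np.pi * comp.sigma2) + ss / comp.sigma2)


def _gate_log_weights(dataset: CurveDataset, gate_params) -> np.ndarray:
    """Log gate factor per voxel/component: joint for Gaussian gates,
    conditional for softmax gates."""
    if isinstance(gate_params, GaussianGateParams):
        return log_gaussian_joint(dataset.coords, gate_params)
    return log_softmax_gate(dataset.coords, gate_params)


def e_step_functional(
    dataset: CurveDataset,
    design: DesignMatrix,
    gate_params,
    components: list[RegressionComponent],
) -> tuple[np.ndarray, float]:
    """Posterior responsibilities and the fit objective.

    Gaussian gates: τ_ik ∝ w_k φ₃(v_i; μ_k, R_k) φ_m(y_i; Bβ_k, σ_k²I) and
    the objective is the joint log-likelihood of (v, y).  Softmax gates:
    τ_ik ∝ π_k(v_i; α) φ_m(...) and the objective is the conditional
    log-likelihood of y given v.
    """
    K = len(components)
    comp_ll = np.column_stack(
        [component_curve_loglik(dataset, design, c) for c in components]
    )
    log_joint = _gate_log_weights(dataset, gate_params) + comp_ll
    log_norm = logsumexp(log_joint, axis=1)
    resp = np.exp(log_joint - log_norm[:, None])
    resp /= resp.sum(axis=1, keepdims=True)
    return resp, float(log_norm.sum())


def m_step_regression(
    dataset: CurveDataset,
    design: DesignMatrix,
    resp: np.ndarray,
    sigma2_floor: float = SIGMA2_FLOOR,
) -> list[RegressionComponent]:
    """Closed-form weighted update of the regression components.

    Because the design B is shared by all voxels, the weighted least-squares
    solution reduces to the OLS fit of the responsibility-weighted mean
    curve; σ_k² is the weighted mean squared residual with denominator
    m · Σᵢ τ_ik.
    """
    B = design.values
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")
    resp = np.atleast_2d(np.asarray(resp, dtype=float))
    Y = dataset.curves
    m = dataset.n_energies
    col = resp.sum(axis=0)
    if np.any(col <= 0):
        raise EmptyClusterError("a regression component received zero responsibility")
    comps = []
    for k in range(resp.shape[1]):
        ybar = resp[:, k] @ Y / col[k]
        beta, *_ = np.linalg.lstsq(B, ybar, rcond=None)
        resid = Y - B @ beta
        sigma2 = float(resp[:, k] @ np.sum(resid**2, axis=1) / (m * col[k]))
        comps.append(RegressionComponent(beta=beta, sigma2=max(sigma2, sigma2_floor)))
    return comps


def bayes_allocate(resp: np.ndarray) -> np.ndarray:
    """Hard labels (1-based) by the Bayes allocation rule; ties → lowest k."""
    resp = np.atleast_2d(np.asarray(resp, dtype=float))
    return np.argmax(resp, axis=1) + 1


# ---------------------------------------------------------------------------
# standardization helpers


def _standardize(dataset: CurveDataset) -> tuple[CurveDataset, float, float]:
    center = float(dataset.curves.mean())
    scale = float(dataset.curves.std())
    if scale <= 0:
        scale = 1.0
    std = CurveDataset(
        coords=dataset.coords,
        curves=(dataset.curves - center) / scale,
        energies=dataset.energies,
        index_map=None,
    )
    return std, center, scale


def _unstandardize_components(
    components: list[RegressionComponent],
    design: DesignMatrix,
    center: float,
    scale: float,
) -> list[RegressionComponent]:
    # Bβ' rescaled: y = s·(Bβ') + c.  The constant is mapped back through the
    # basis (exact whenever constants lie in the span, as for clamped
    # B-splines and polynomials).
    beta0, *_ = np.linalg.lstsq(design.values, np.ones(design.n_points), rcond=None)
    return [
        RegressionComponent(
            beta=scale * c.beta + center * beta0, sigma2=c.sigma2 * scale**2
        )
        for c in components
    ]


# ---------------------------------------------------------------------------
# pruning helpers (shared with the vectorized models)


def _drop_softmax_class(params: SoftmaxGateParams, j: int) -> SoftmaxGateParams:
    """Remove class j (0-based) from softmax gates, re-referencing if needed."""
    K = params.K
    if K <= 1:
        raise ParameterError("cannot drop a class from a single-class gate")
    alpha = params.alpha
    if j < K - 1:
        alpha = np.delete(alpha, j, axis=0)
    else:
        # dropping the reference class: make the last remaining class the new
        # reference by subtracting its coefficient vector
        alpha = alpha[:-1] - alpha[-1]
    return SoftmaxGateParams(alpha=alpha, K=K - 1, intercept=params.intercept)


def _drop_gaussian_class(params: GaussianGateParams, j: int) -> GaussianGateParams:
    keep = [k for k in range(params.K) if k != j]
    w = params.weights[keep]
    return GaussianGateParams(
        weights=w / w.sum(),
        means=params.means[keep],
        covariances=params.covariances[keep],
        lambda_reg=params.lambda_reg,
    )


def _prune_empty(resp: np.ndarray, gate_params, components: list, threshold: float):
    """Drop components with total responsibility below ``threshold``."""
    while resp.shape[1] > 1:
        col = resp.sum(axis=0)
        j = int(np.argmin(col))
        if col[j] >= threshold:
            break
        if isinstance(gate_params, GaussianGateParams):
            gate_params = _drop_gaussian_class(gate_params, j)
        elif isinstance(gate_params, SoftmaxGateParams):
            gate_params = _drop_softmax_class(gate_params, j)
        components = [c for k, c in enumerate(components) if k != j]
        resp = np.delete(resp, j, axis=1)
        rows = resp.sum(axis=1, keepdims=True)
        rows[rows <= 0] = 1.0
        resp = resp / rows
    return resp, gate_params, components


def _one_hot(labels: np.ndarray, K: int) -> np.ndarray:
    labels = np.asarray(labels).ravel()
    resp = np.zeros((labels.size, K))
    resp[np.arange(labels.size), labels - 1] = 1.0
    return resp


def _init_gate(coords: np.ndarray, resp: np.ndarray, config: FitConfig):
    if config.gate_kind == "gaussian":
        return update_gaussian_gate(coords, resp, config.lambda_reg)
    init = SoftmaxGateParams.zeros(resp.shape[1], intercept=config.intercept)
    return update_softmax_gate(coords, resp, init, max_iter=config.irls_max_iter)


def fit(
    dataset: CurveDataset, design: DesignMatrix, config: FitConfig
) -> FitResult:
    """Fit a one-stage spatial mixture of functional regressions by EM.

    Initialization is a spatial k-means (Voronoi) partition unless
    ``config.init_labels`` is given.  EM alternates the E-step with the gate
    and regression M-steps until the relative change in the objective falls
    below ``config.tol`` or ``config.max_iter`` iterations are reached.
    """
    from .initsearch import voronoi_init

    n = dataset.n_voxels
    if n <= config.K:
        raise ParameterError(f"need n > K, got n={n}, K={config.K}")

    work = dataset
    center, scale = 0.0, 1.0
    if config.standardize:
        work, center, scale = _standardize(dataset)

    if config.init_labels is not None:
        labels0 = np.asarray(config.init_labels).ravel()
        if labels0.size != n:
            raise ParameterError("init_labels length must equal n")
    else:
        labels0 = voronoi_init(dataset.coords, config.K, seed=config.seed)
    K0 = int(labels0.max())
    resp = _one_hot(labels0, K0)

    prune_threshold = design.n_basis + 1
    if config.prune:
        resp, _, _ = _prune_empty(resp, None, list(range(K0)), prune_threshold)

    gate_params = _init_gate(work.coords, resp, config)
    components = m_step_regression(work, design, resp)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(config.max_iter):
        resp, ll = e_step_functional(work, design, gate_params, components)
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
            gate_params = update_gaussian_gate(work.coords, resp, config.lambda_reg)
        else:
            gate_params = update_softmax_gate(
                work.coords, resp, gate_params, max_iter=config.irls_max_iter
            )
        components = m_step_regression(work, design, resp)

    if config.standardize:
        components = _unstandardize_components(components, design, center, scale)
        # Jacobian of the affine curve rescaling: each of the m HU values per
        # voxel contributes log(scale).
        trace = [t - n * dataset.n_energies * np.log(scale) for t in trace]

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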