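"""EM initialization and the small (K, λ) hyper-parameter search.

EM fits of spatial mixtures are sensitive to their starting point.  For
reproducibility, initialization is a coarse Voronoi tiling of the masked
voxels: seeded k-means on the *spatial coordinates only*, which partitions
the volume into K compact tiles.  One-hot responsibilities from these tiles
then drive a single M-step of the target model to obtain initial gate and
component parameters.

The hyper-parameters K (number of clusters) and λ (spatial-covariance
shrinkage) are chosen by a small grid search over one or more datasets with
known tumor masks: each cell is scored by the merged-tumor Dice (DBt as
tiebreaker) when ground truth is available, otherwise by the mean of the
spatial and spectral Davies–Bouldin indices; per-dataset optima are averaged
(λ arithmetically, K by rounded mean).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.cluster import KMeans

from .basis import DesignMatrix, ols_projection
from .errors import ParameterError, SearchError
from .volumes import CurveDataset


def voronoi_init(coords: np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """Coarse spatial partition: seeded k-means on coordinates only.

    Returns 1-based labels; deterministic given ``seed``; every one of the
    K labels is non-empty.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if K < 1 or n < K:
        raise ParameterError(f"need n >= K >= 1, got n={n}, K={K}")
    if K == 1:
        return np.ones(n, dtype=int)
    if K == n:
        return np.arange(1, n + 1)
    km = KMeans(n_clusters=K, n_init=5, random_state=seed)
    labels = km.fit_predict(coords) + 1
    # k-means can in principle leave a label empty on pathological data;
    # re-seed deterministically from the largest cluster if so
    for missing in set(range(1, K + 1)) - set(np.unique(labels).tolist()):
        biggest = np.bincount(labels)[1:].argmax() + 1
        idx = np.flatnonzero(labels == biggest)
        labels[idx[0]] = missing
    return labels


def init_params_from_labels(
    dataset: CurveDataset,
    design: DesignMatrix,
    labels: np.ndarray,
    model_kind: str = "sgmfr",
    lambda_reg: float | None = None,
):
    """Initial model parameters from a hard labeling.

    One-hot responsibilities followed by one M-step of the target model.
    Clusters smaller than r+1 voxels (too few to identify a regression or a
    coefficient covariance) are merged into the nearest cluster by centroid
    distance, with a warning.  Returns ``(gate_params, components, resp)``.
    """
    from .em_functional import FitConfig, _init_gate, _one_hot, m_step_regression
    from .em_vectorized import m_step_components
    from .gating import DEFAULT_LAMBDA

    if lambda_reg is None:
        lambda_reg = DEFAULT_LAMBDA
    model_kind = model_kind.lower()
    if model_kind not in ("sgmfr", "ssmfr", "sgmvfr", "ssmvfr"):
        raise ParameterError(f"unknown model kind {model_kind!r}")
    gate_kind = "gaussian" if model_kind.startswith("sg") else "softmax"

    labels = np.asarray(labels).ravel().copy()
    r = design.n_basis
    # merge undersized clusters into their nearest neighbor by spatial centroid
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        small = uniq[counts < r + 1]
        if small.size == 0 or uniq.size <= 1:
            break
        s = small[0]
        centroids = {u: dataset.coords[labels == u].mean(axis=0) for u in uniq}
        others = [u for u in uniq if u != s]
        target = min(others, key=lambda u: np.linalg.norm(centroids[u] - centroids[s]))
        warnings.warn(
            f"cluster {s} has fewer than r+1={r + 1} voxels; merged into {target}",
            stacklevel=2,
        )
        labels[labels == s] = target
    # relabel to contiguous 1..K
    uniq = np.unique(labels)
    remap = {int(u): j + 1 for j, u in enumerate(uniq)}
    labels = np.array([remap[int(u)] for u in labels])
    K = uniq.size

    resp = _one_hot(labels, K)
    config = FitConfig(gate_kind=gate_kind, K=K, lambda_reg=lambda_reg)
    gate_params = _init_gate(dataset.coords, resp, config)
    if model_kind.endswith("mvfr"):
        components = m_step_components(ols_projection(dataset, design), resp)
    else:
        components = m_step_regression(dataset, design, resp)
    return gate_params, components, resp


def _fit_model(dataset, design, model: str, K: int, lam: float, seed: int,
               max_iter: int = 200, tol: float = 1e-6):
    from .em_functional import FitConfig, fit
    from .em_vectorized import fit_vectorized

    gate_kind = "gaussian" if model.startswith("sg") else "softmax"
    config = FitConfig(gate_kind=gate_kind, K=K, lambda_reg=lam,
                       max_iter=max_iter, tol=tol, seed=seed)
    if model.endswith("mvfr"):
        return fit_vectorized(dataset, design, config)
    return fit(dataset, design, config)


def grid_search(
    datasets,
    K_grid,
    lambda_grid,
    model: str = "sgmfr",
    design: DesignMatrix | None = None,
    seed: int = 0,
    max_iter: int = 200,
) -> tuple[int, float]:
    """Small grid search for (K, λ) over datasets with optional truth masks.

    ``datasets`` is a list of ``(CurveDataset, truth)`` pairs where ``truth``
    is a set of tumor row indices or ``None``.  Returns ``(K*, λ*)``: the
    rounded mean of per-dataset optimal K and the mean of optimal λ.
    """
    from .basis import build_design_matrix
    from .metrics import davies_bouldin, metrics_report

    K_grid = list(K_grid)
    lambda_grid = list(lambda_grid)
    if not K_grid or not lambda_grid:
        raise SearchError("empty search grid")
    best_K, best_lam = [], []
    for dataset, truth in datasets:
        dm = design if design is not None else build_design_matrix(dataset.energies)
        best_score, best_cell = None, None
        for K in K_grid:
            for lam in lambda_grid:
                try:
                    res = _fit_model(dataset, dm, model, K, lam, seed, max_iter)
                    if truth is not None:
                        rep = metrics_report(dataset, res.labels, truth)
                        dbt = rep.dbt_spatial
                        score = (rep.dice, -(dbt if np.isfinite(dbt) else np.inf))
                    else:
                        db = 0.5 * (
                            davies_bouldin(dataset.coords, res.labels)
                            + davies_bouldin(dataset.curves, res.labels)
                        )
                        score = (-db,)
                except Exception:
                    continue
                if best_score is None or score > best_score:
                    best_score, best_cell = score, (K, lam)
        if best_cell is not None:
            best_K.append(best_cell[0])
            best_lam.append(best_cell[1])
    if not best_K:
        raise SearchError("every grid cell failed on every dataset")
    return int(round(float(np.mean(best_K)))), float(np.mean(best_lam))
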