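"""Cluster-validity and tumor-segmentation metrics.

Three evaluation quantities are computed for a voxel clustering:

* **Davies–Bouldin index (DB)** — for a set of clusters C with centroids
  c̄_k and within-cluster scatters S(c_k) (mean Euclidean distance to the
  centroid), DB = (1/|C|) Σ_k max_{l≠k} (S(c_k)+S(c_l)) / d(c̄_k, c̄_l).
  Lower is better.  Computed on *spatial* content (voxel coordinates) and on
  *spectral* content (raw decay curves).
* **Tumor DB (DBt)** — the same ratio restricted to the merged tumor region
  versus every other cluster: max_l (S(c_tum)+S(c_l)) / d(c̄_tum, c̄_l).
* **Dice score** — 2|A∩B| / (|A|+|B|) between the merged tumor clusters and
  the ground-truth region.

Since a fit may split a tumor into several subpart clusters, the "tumor
clusters" are chosen as the subset of clusters whose union best overlaps the
ground truth — greedy forward selection on the merged Dice score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedMetricError
from .volumes import CurveDataset


@dataclass
class MetricsReport:
    """The five headline metrics plus the selected tumor clusters."""

    dice: float
    db_spatial: float
    db_spectral: float
    dbt_spatial: float
    dbt_spectral: float
    tumor_cluster_ids: set = field(default_factory=set)
    n_clusters: int = 0

    def to_dict(self) -> dict:
        return {
            "Dice": self.dice,
            "spat-DB": self.db_spatial,
            "spec-DB": self.db_spectral,
            "spat-DBt": self.dbt_spatial,
            "spec-DBt": self.dbt_spectral,
            "tumor_clusters": sorted(int(c) for c in self.tumor_cluster_ids),
            "n_clusters": self.n_clusters,
        }


def _cluster_stats(features: np.ndarray, members: list[np.ndarray]):
    centroids = np.stack([features[idx].mean(axis=0) for idx in members])
    scatters = np.array(
        [
            np.linalg.norm(features[idx] - centroids[j], axis=1).mean()
            for j, idx in enumerate(members)
        ]
    )
    return centroids, scatters


def davies_bouldin(features: np.ndarray, labels: np.ndarray) -> float:
    """Davies–Bouldin index over all non-empty clusters (lower = better)."""
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.asarray(labels).ravel()
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise UndefinedMetricError("Davies–Bouldin requires at least 2 clusters")
    members = [np.flatnonzero(labels == u) for u in uniq]
    centroids, scatters = _cluster_stats(features, members)
    K = uniq.size
    total = 0.0
    for k in range(K):
        ratios = []
        for l in range(K):
            if l == k:
                continue
            d = np.linalg.norm(centroids[k] - centroids[l])
            if d == 0:
                raise UndefinedMetricError("coincident cluster centroids")
            ratios.append((scatters[k] + scatters[l]) / d)
        total += max(ratios)
    return total / K


def tumor_davies_bouldin(
    features: np.ndarray, labels: np.ndarray, tumor_ids
) -> float:
    """DB ratio of the merged tumor region versus every other cluster."""
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.asarray(labels).ravel()
    tumor_ids = set(int(t) for t in tumor_ids)
    if not tumor_ids:
        raise UndefinedMetricError("tumor cluster set is empty")
    tumor_members = np.flatnonzero(np.isin(labels, sorted(tumor_ids)))
    if tumor_members.size == 0:
        raise UndefinedMetricError("tumor clusters contain no voxels")
    others = [u for u in np.unique(labels) if u not in tumor_ids]
    if not others:
        raise UndefinedMetricError("no non-tumor cluster to compare against")
    members = [tumor_members] + [np.flatnonzero(labels == u) for u in others]
    centroids, scatters = _cluster_stats(features, members)
    ratios = []
    for l in range(1, len(members)):
        d = np.linalg.norm(centroids[0] - centroids[l])
        if d == 0:
            raise UndefinedMetricError("coincident cluster centroids")
        ratios.append((scatters[0] + scatters[l]) / d)
    return float(max(ratios))


def dice(region_a, region_b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0 when both regions are empty."""
    a, b = set(region_a), set(region_b)
    if not a and not b:
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def select_tumor_clusters(labels: np.ndarray, truth) -> tuple[set, float]:
    """Pick the clusters whose union best covers the ground-truth region.

    Greedy forward selection: repeatedly merge in the cluster that most
    increases the Dice score of the merged region against ``truth`` (a set
    of voxel row indices); stop when no addition improves.  Returns the
    selected cluster ids and the final merged Dice.
    """
    labels = np.asarray(labels).ravel()
    truth = set(int(t) for t in truth)
    if not truth:
        raise UndefinedMetricError("ground-truth region is empty")
    cluster_sets = {int(u): set(np.flatnonzero(labels == u).tolist()) for u in np.unique(labels)}
    selected: set = set()
    merged: set = set()
    best = 0.0
    while True:
        gains = []
        for cid, voxels in cluster_sets.items():
            if cid in selected:
                continue
            cand = dice(merged | voxels, truth)
            gains.append((cand, cid))
        if not gains:
            break
        cand, cid = max(gains, key=lambda t: (t[0], -t[1]))
        if cand <= best:
            break
        selected.add(cid)
        merged |= cluster_sets[cid]
        best = cand
    return selected, best


def metrics_report(
    dataset: CurveDataset, labels: np.ndarray, truth
) -> MetricsReport:
    """Full evaluation: spatial/spectral DB, tumor DBt, and merged Dice.

    Spatial metrics use the voxel coordinates as features; spectral metrics
    use the raw m-point decay curves — a model-agnostic choice valid across
    all fitted variants.  ``truth`` is the set of dataset row indices inside
    the ground-truth tumor region.
    """
    labels = np.asarray(labels).ravel()
    tumor_ids, dice_score = select_tumor_clusters(labels, truth)
    db_spat = davies_bouldin(dataset.coords, labels)
    db_spec = davies_bouldin(dataset.curves, labels)
    if tumor_ids and len(np.unique(labels)) > len(tumor_ids):
        dbt_spat = tumor_davies_bouldin(dataset.coords, labels, tumor_ids)
        dbt_spec = tumor_davies_bouldin(dataset.curves, labels, tumor_ids)
    else:
        dbt_spat = float("nan")
        dbt_spec = float("nan")
    return MetricsReport(
        dice=dice_score,
        db_spatial=db_spat,
        db_spectral=db_spec,
        dbt_spatial=dbt_spat,
        dbt_spectral=dbt_spec,
        tumor_cluster_ids=tumor_ids,
        n_clusters=int(np.unique(labels).size),
    )
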