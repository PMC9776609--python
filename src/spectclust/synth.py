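"""Synthetic spectral data: generative-model samplers and 4D phantoms.

Two kinds of synthetic data support testing and calibration:

* **Direct samplers** from the generative clustering models
  (:func:`sample_sgmfr`, :func:`sample_sgmvfr`) for parameter-recovery
  experiments: sample a cluster label from the gates, a spatial position,
  and a decay curve (or coefficient vector) from the component model.

* **Spectral phantoms** (:func:`make_phantom`): a small 4D volume laid out
  as spatially coherent tissue regions, each with its own smooth mean decay
  curve plus Gaussian HU noise, an embedded "tumor" blob with a known mask,
  and an optional air shell at −1000 HU.  The default phantom is 40×40×4
  voxels × 21 energies (40–140 keV), five clusters: soft-tissue background,
  fat, an enhancing muscle-like tissue, bone (strongly decaying curve —
  high HU at 40 keV falling steeply), and a contrast-enhancing tumor.

Curve families are stored as coefficient vectors on the default cubic
B-spline basis, so the one-stage and two-fold models share the same ground
truth.  All outputs are deterministic functions of the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .basis import BasisConfig, DesignMatrix, build_design_matrix
from .em_functional import RegressionComponent
from .em_vectorized import VectorizedComponent
from .errors import ParameterError, SpectclustError
from .gating import GaussianGateParams, SoftmaxGateParams, softmax_gate
from .volumes import CurveDataset, LabelVolume, SpectralVolume, VoxelMask, default_energy_grid

AIR_HU = -1000.0

#: Analytic mean decay curves (HU as a function of normalized energy t∈[0,1])
#: for the default phantom clusters.  Bone decays steeply; soft tissues and
#: the contrast-enhancing tumor decay mildly; fat sits below water.
_DEFAULT_CURVE_FAMILIES = {
    1: (lambda t: 45.0 + 25.0 * np.exp(-2.0 * t), 15.0**2),   # soft tissue
    2: (lambda t: -70.0 - 30.0 * np.exp(-1.5 * t), 15.0**2),  # fat
    3: (lambda t: 60.0 + 90.0 * np.exp(-2.5 * t), 15.0**2),   # enhancing muscle
    4: (lambda t: 400.0 + 900.0 * np.exp(-3.0 * t), 25.0**2), # bone
    5: (lambda t: 90.0 + 210.0 * np.exp(-2.8 * t), 15.0**2),  # tumor (enhancing)
}


@dataclass
class PhantomSpec:
    """Specification of a synthetic spectral phantom."""

    shape: tuple = (40, 40, 4)
    energies: np.ndarray = field(default_factory=lambda: default_energy_grid(21))
    layout: str = "voronoi_tiles"
    K_true: int = 5
    curve_params: dict | None = None  # cluster id -> (beta, sigma2) on `basis`
    basis: BasisConfig = field(default_factory=BasisConfig)
    tumor_cluster: int = 5
    tumor_radius_frac: float = 0.18
    sites_per_family: int = 1
    boundary_warp: float = 2.0  # amplitude (voxels) of smooth tile-boundary warp
    air_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.K_true < 2:
            raise ParameterError("K_true must be >= 2")
        if not 1 <= self.tumor_cluster <= self.K_true:
            raise ParameterError("tumor_cluster must lie in 1..K_true")
        if not 0.0 <= self.air_fraction < 1.0:
            raise ParameterError("air_fraction must lie in [0, 1)")
        if self.sites_per_family < 1:
            raise ParameterError("sites_per_family must be >= 1")
        if self.layout not in ("voronoi_tiles", "gaussian_blobs"):
            raise ParameterError(f"unknown layout {self.layout!r}")

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "energies" in raw:
            raw["energies"] = np.asarray(raw["energies"], dtype=float)
        if "basis" in raw:
            raw["basis"] = BasisConfig(**raw["basis"])
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        return cls(**raw)


def default_curve_components(
    design: DesignMatrix, K: int = 5
) -> list[RegressionComponent]:
    """Project the built-in analytic curve families onto a basis.

    Returns one :class:`RegressionComponent` per cluster id 1..K; the
    cluster mean curves used by the phantom are exactly Bβ_k.
    """
    t = np.linspace(0.0, 1.0, design.n_points)
    comps = []
    for k in range(1, K + 1):
        fam, sigma2 = _DEFAULT_CURVE_FAMILIES[((k - 1) % 5) + 1]
        beta, *_ = np.linalg.lstsq(design.values, fam(t), rcond=None)
        comps.append(RegressionComponent(beta=beta, sigma2=sigma2))
    return comps


def lambda_study_spec(seed: int = 0) -> PhantomSpec:
    """Phantom spec for studying the spatial-vs-spectral effect of λ.

    The λ shrinkage arbitrates allocation only where spatial and spectral
    information disagree, i.e. near irregular boundaries between tissues
    whose spectra overlap at the noise level.  This spec therefore uses four
    soft-tissue families separated by ~12 HU at 40 keV (about 1σ of the
    15 HU noise per energy), a moderately enhancing tumor, and strongly
    warped tile boundaries.  Small λ then cuts smooth, compact cluster
    boundaries across the true tissue interfaces (low spatial DB, spectrally
    mixed clusters); large λ lets the curves pull labels back to the ragged
    true regions (low spectral DB).
    """
    design = build_design_matrix(default_energy_grid(21), BasisConfig())
    t = np.linspace(0.0, 1.0, 21)
    families = {
        1: 40.0 + 18.0 * np.exp(-2.0 * t),
        2: 48.0 + 22.0 * np.exp(-2.1 * t),
        3: 56.0 + 26.0 * np.exp(-2.2 * t),
        4: 64.0 + 30.0 * np.exp(-2.3 * t),
        5: 90.0 + 60.0 * np.exp(-2.8 * t),
    }
    curve_params = {
        k: (np.linalg.lstsq(design.values, v, rcond=None)[0], 15.0**2)
        for k, v in families.items()
    }
    return PhantomSpec(curve_params=curve_params, boundary_warp=3.0, seed=seed)


# ---------------------------------------------------------------------------
# generative-model samplers


def _sample_labels_and_coords(gate_params, n: int, rng: np.random.Generator,
                              box: tuple = ((0.0, 10.0),) * 3):
    """Sample (labels, coords) from a spatial gating model."""
    if isinstance(gate_params, GaussianGateParams):
        labels = rng.choice(gate_params.K, size=n, p=gate_params.weights) + 1
        coords = np.empty((n, 3))
        for k in range(gate_params.K):
            idx = labels == k + 1
            if idx.any():
                coords[idx] = rng.multivariate_normal(
                    gate_params.means[k], gate_params.covariances[k], size=int(idx.sum())
                )
        return labels, coords
    if isinstance(gate_params, SoftmaxGateParams):
        lo = np.array([b[0] for b in box])
        hi = np.array([b[1] for b in box])
        coords = lo + (hi - lo) * rng.random((n, 3))
        probs = softmax_gate(coords, gate_params)
        u = rng.random(n)
        labels = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1) + 1
        return labels, coords
    raise ParameterError("unknown gate parameter type")


def sample_sgmfr(
    gate_params,
    components: list[RegressionComponent],
    design: DesignMatrix,
    n: int,
    seed: int = 0,
    box: tuple = ((0.0, 10.0),) * 3,
) -> tuple[CurveDataset, np.ndarray]:
    """Sample voxels from a spatial mixture of functional regressions.

    Gaussian gates: position v_i ~ Σ_k w_k φ₃(·; μ_k, R_k) with its component
    label; softmax gates: v_i uniform over ``box``, label from the gate
    probabilities at v_i.  Curves are y_i = Bβ_{Z_i} + ε, ε ~ N(0, σ²I).
    """
    rng = np.random.default_rng(seed)
    labels, coords = _sample_labels_and_coords(gate_params, n, rng, box)
    B = design.values
    m = design.n_points
    curves = np.empty((n, m))
    for k, comp in enumerate(components):
        idx = labels == k + 1
        if idx.any():
            mean = B @ comp.beta
            curves[idx] = mean + rng.normal(
                0.0, np.sqrt(comp.sigma2), size=(int(idx.sum()), m)
            )
    dataset = CurveDataset(coords=coords, curves=curves, energies=design.energies)
    return dataset, labels


def sample_sgmvfr(
    gate_params,
    components: list[VectorizedComponent],
    design: DesignMatrix,
    n: int,
    seed: int = 0,
    box: tuple = ((0.0, 10.0),) * 3,
) -> tuple[CurveDataset, np.ndarray]:
    """Sample from the two-fold generative model.

    Coefficient vectors β_i ~ φ_r(·; m_{Z_i}, C_{Z_i}); curves are the exact
    basis reconstructions y_i = Bβ_i, so the stage-1 OLS projection recovers
    β_i and stage 2 sees draws from the assumed coefficient mixture.
    """
    rng = np.random.default_rng(seed)
    labels, coords = _sample_labels_and_coords(gate_params, n, rng, box)
    B = design.values
    curves = np.empty((n, design.n_points))
    for k, comp in enumerate(components):
        idx = labels == k + 1
        if idx.any():
            betas = rng.multivariate_normal(comp.mean, comp.covariance, size=int(idx.sum()))
            curves[idx] = betas @ B.T
    dataset = CurveDataset(coords=coords, curves=curves, energies=design.energies)
    return dataset, labels


# ---------------------------------------------------------------------------
# phantom construction


def _tumor_blob(shape, radius_frac: float) -> np.ndarray:
    """Boolean ellipsoid centred in the volume."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    center = [(s - 1) / 2.0 for s in shape]
    radii = [max(s * radius_frac, 1.0) for s in shape]
    # keep the through-plane radius covering the thin axis without filling it
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


def make_phantom(
    spec: PhantomSpec,
) -> tuple[SpectralVolume, VoxelMask, VoxelMask, LabelVolume]:
    """Build a 4D spectral phantom with ground truth.

    Returns ``(volume, tissue_mask, tumor_mask, true_labels)``.  The tumor
    cluster occupies a central ellipsoid; the remaining clusters tile the
    rest of the volume (nearest-seed Voronoi tiles, or the maximum-density
    region of random Gaussian blobs).  Air voxels, if requested, form the
    outer shell farthest from the in-plane centre and are set to −1000 HU.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    nvox = int(np.prod(shape))
    design = build_design_matrix(spec.energies, spec.basis)

    if spec.curve_params is not None:
        comps = {
            int(k): RegressionComponent(beta=np.asarray(b, dtype=float), sigma2=float(s2))
            for k, (b, s2) in spec.curve_params.items()
        }
        if sorted(comps) != list(range(1, spec.K_true + 1)):
            raise ParameterError("curve_params must cover cluster ids 1..K_true")
        components = [comps[k] for k in range(1, spec.K_true + 1)]
    else:
        components = default_curve_components(design, spec.K_true)

    labels = np.zeros(shape, dtype=np.int32)
    tumor = _tumor_blob(shape, spec.tumor_radius_frac)
    other_ids = [k for k in range(1, spec.K_true + 1) if k != spec.tumor_cluster]
    coords = np.argwhere(np.ones(shape, dtype=bool)).astype(float)

    if spec.layout == "voronoi_tiles":
        # Well-spread seeds on a jittered ring around the in-plane centre, so
        # every tile is a compact convex region one spatial gate can carry.
        # With sites_per_family > 1, each non-tumor tissue family occupies
        # several tiles spread around the ring, mimicking tissues (bone,
        # muscle) that appear at disconnected anatomical sites.
        J = spec.sites_per_family * len(other_ids)
        cx, cy, cz = [(s - 1) / 2.0 for s in shape]
        radius = 0.35 * min(shape[0], shape[1])
        angles = 2 * np.pi * (np.arange(J) + rng.random(J) * 0.3) / J
        seeds = np.column_stack(
            [
                cx + radius * np.cos(angles),
                cy + radius * np.sin(angles),
                np.full(J, cz) + (rng.random(J) - 0.5) * shape[2] * 0.2,
            ]
        )
        pos = coords
        if spec.boundary_warp > 0:
            # smooth sinusoidal displacement field -> ragged, organ-like
            # tile boundaries instead of straight Voronoi facets
            wavelength = max(min(shape[0], shape[1]) / 3.0, 1.0)
            freq = 2 * np.pi / wavelength
            phases = rng.random((3, 3)) * 2 * np.pi
            disp = np.stack(
                [
                    np.sin(freq * coords[:, (a + 1) % 3] + phases[a, 0])
                    + np.sin(freq * coords[:, (a + 2) % 3] + phases[a, 1])
                    for a in range(3)
                ],
                axis=1,
            )
            pos = coords + 0.5 * spec.boundary_warp * disp
        d = np.linalg.norm(pos[:, None, :] - seeds[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        tile_family = [other_ids[j % len(other_ids)] for j in range(J)]
        labels = np.array([tile_family[j] for j in nearest], dtype=np.int32).reshape(shape)
    else:  # gaussian_blobs
        means = rng.random((len(other_ids), 3)) * np.asarray(shape)
        dens = np.empty((nvox, len(other_ids)))
        for j in range(len(other_ids)):
            scales = np.asarray(shape) * (0.25 + 0.5 * rng.random(3))
            dens[:, j] = -np.sum(((coords - means[j]) / scales) ** 2, axis=1)
        labels = np.array(
            [other_ids[j] for j in dens.argmax(axis=1)], dtype=np.int32
        ).reshape(shape)
    labels[tumor] = spec.tumor_cluster

    # air shell: exactly round(air_fraction * nvox) voxels farthest from the
    # in-plane centre
    tissue = np.ones(shape, dtype=bool)
    n_air = int(round(spec.air_fraction * nvox))
    if n_air > 0:
        cx, cy = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        d2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
        air_rows = np.argsort(-d2, kind="stable")[:n_air]
        flat = tissue.reshape(-1)
        flat[air_rows] = False
        tissue = flat.reshape(shape)
        labels[~tissue] = 0

    present = set(np.unique(labels[tissue]).tolist())
    if present != set(range(1, spec.K_true + 1)):
        raise SpectclustError(
            f"degenerate layout: clusters {sorted(set(range(1, spec.K_true + 1)) - present)} "
            "are empty; change the seed or layout"
        )

    m = design.n_points
    values = np.full((*shape, m), AIR_HU)
    B = design.values
    for k, comp in enumerate(components, start=1):
        idx = (labels == k) & tissue
        nk = int(idx.sum())
        values[idx] = B @ comp.beta + rng.normal(
            0.0, np.sqrt(comp.sigma2), size=(nk, m)
        )

    vol = SpectralVolume(values=values, energies=spec.energies)
    return (
        vol,
        VoxelMask(values=tissue),
        VoxelMask(values=tumor & tissue),
        LabelVolume(values=labels),
    )
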