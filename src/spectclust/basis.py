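"""Design matrices over the energy axis and per-voxel OLS projection.

Each voxel's decay curve is approximated as a smooth function of energy,
``y ≈ B(x) β``, where ``B(x)`` is an m×r evaluation of a polynomial or
B-spline basis shared by every voxel (all voxels are reconstructed at the
same energies).  The OLS projection of each curve onto this basis is the
first stage of the two-fold ("vectorized") clustering models and the
building block of the functional regression components.

Defaults follow standard functional-data practice: a cubic B-spline basis
with 4 equally spaced interior knots on the affinely normalized energy range
[0, 1], giving r = 8 basis functions for m = 21 energies.  Clamped (repeated)
boundary knots are used, so the basis forms a partition of unity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .errors import SingularDesignError, UnderdeterminedBasisError, MetadataError
from .volumes import CurveDataset


@dataclass(frozen=True)
class BasisConfig:
    """Configuration of the functional basis.

    ``kind`` is ``"polynomial"`` or ``"bspline"``; ``degree`` is the
    polynomial/spline degree p; ``n_interior_knots`` (q, B-spline only) is the
    number of equally spaced interior knots; ``normalize`` maps energies
    affinely onto [0, 1] before evaluation.  The number of basis functions is
    r = p+1 for polynomials and r = p+q+1 for B-splines.
    """

    kind: str = "bspline"
    degree: int = 3
    n_interior_knots: int = 4
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("polynomial", "bspline"):
            raise MetadataError(f"unknown basis kind {self.kind!r}")
        if self.degree < 0:
            raise MetadataError("degree must be >= 0")
        if self.kind == "polynomial" and self.n_interior_knots != 0:
            object.__setattr__(self, "n_interior_knots", 0)
        if self.n_interior_knots < 0:
            raise MetadataError("n_interior_knots must be >= 0")

    @property
    def n_basis(self) -> int:
        if self.kind == "polynomial":
            return self.degree + 1
        return self.degree + self.n_interior_knots + 1


@dataclass
class DesignMatrix:
    """The m×r basis evaluation B(x) shared by all voxels."""

    values: np.ndarray
    config: BasisConfig
    energies: np.ndarray

    @property
    def n_basis(self) -> int:
        return self.values.shape[1]

    @property
    def n_points(self) -> int:
        return self.values.shape[0]


def build_design_matrix(energies: np.ndarray, config: BasisConfig | None = None) -> DesignMatrix:
    """Evaluate the configured basis on the energy grid.

    Raises :class:`UnderdeterminedBasisError` if more basis functions than
    energy levels are requested (r > m).
    """
    if config is None:
        config = BasisConfig()
    energies = np.asarray(energies, dtype=float).ravel()
    m = energies.size
    if m > 1 and not np.all(np.diff(energies) > 0):
        raise MetadataError("energies must be strictly increasing and distinct")
    r = config.n_basis
    if r > m:
        raise UnderdeterminedBasisError(
            f"{r} basis functions cannot be identified from {m} energy levels"
        )
    if config.normalize:
        span = energies[-1] - energies[0] if m > 1 else 1.0
        t = (energies - energies[0]) / (span if span > 0 else 1.0)
        lo, hi = 0.0, 1.0 if m > 1 else 0.0
    else:
        t = energies
        lo, hi = energies[0], energies[-1]

    if config.kind == "polynomial":
        values = np.vander(t, N=config.degree + 1, increasing=True)
    else:
        p, q = config.degree, config.n_interior_knots
        interior = np.linspace(lo, hi, q + 2)[1:-1]
        knots = np.concatenate([np.repeat(lo, p + 1), interior, np.repeat(hi, p + 1)])
        values = BSpline.design_matrix(t, knots, p).toarray()
    return DesignMatrix(values=values, config=config, energies=energies)


@dataclass
class CoefficientVectors:
    """n×r matrix of per-voxel OLS basis coefficients β̂_i."""

    values: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_basis(self) -> int:
        return self.values.shape[1]


def ols_projection(dataset: CurveDataset, design: DesignMatrix) -> CoefficientVectors:
    """Project every curve onto the basis by ordinary least squares.

    Row i solves ``min_β ||B β − y_i||²``; with B full column rank this equals
    the normal-equations solution ``(BᵀB)⁻¹ Bᵀ y_i``.  Solved via a QR/SVD
    factorization rather than an explicit inverse.
    """
    B = design.values
    if design.n_points != dataset.n_energies or not np.allclose(
        design.energies, dataset.energies
    ):
        raise MetadataError("design matrix was not built on the dataset's energy axis")
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient (BᵀB singular)")
    coeffs, *_ = np.linalg.lstsq(B, dataset.curves.T, rcond=None)
    return CoefficientVectors(values=coeffs.T)
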