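"""Spectral-volume I/O and volume/curve-dataset conversions.

A dual-energy CT acquisition reconstructed at many virtual monochromatic
energies is a 4D image: three spatial axes plus one energy axis.  Each voxel
carries an *energy decay curve* — the Hounsfield-unit attenuation measured at
each reconstructed energy (typically 40–140 keV in 5 keV steps, m = 21
points).  This module defines the on-disk/in-memory representation of such
volumes, binary voxel masks and label maps, and the conversion between the
4D-grid view and the flattened "n voxels × m energies" analysis view used by
the clustering models.

Volumes are stored as 4D NIfTI images (masks and label maps as 3D NIfTI); the
energy axis, which NIfTI has no standard slot for, travels in a JSON sidecar
``<stem>.energies.json`` with key ``"energies_kev"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    BoundsError,
    DimensionalityError,
    EmptyDatasetError,
    EnergyAxisError,
    InvariantViolationError,
    MetadataError,
)

#: Default energy grid start (keV) and step (keV) used when no axis is given.
DEFAULT_ENERGY_START_KEV = 40.0
DEFAULT_ENERGY_STEP_KEV = 5.0

#: Default air-masking threshold (HU) and reference energy (keV).  65 keV is
#: the virtual monochromatic image closest in contrast to a conventional CT.
DEFAULT_AIR_THRESHOLD_HU = -500.0
DEFAULT_REFERENCE_ENERGY_KEV = 65.0


def default_energy_grid(m: int) -> np.ndarray:
    """Return the default keV grid: ``m`` values from 40 keV in 5 keV steps."""
    return DEFAULT_ENERGY_START_KEV + DEFAULT_ENERGY_STEP_KEV * np.arange(m, dtype=float)


def _validate_energies(energies: np.ndarray, m: int) -> np.ndarray:
    energies = np.asarray(energies, dtype=float).ravel()
    if energies.size != m:
        raise MetadataError(
            f"energy axis has {energies.size} entries but the volume has {m} energy slices"
        )
    if energies.size > 1 and not np.all(np.diff(energies) > 0):
        raise MetadataError("energies must be strictly increasing")
    return energies


@dataclass
class SpectralVolume:
    """A 4D grid of HU values indexed ``(i1, i2, i3, e)`` with its keV axis.

    Parameters
    ----------
    values
        4D real array of Hounsfield units; the 4th axis is energy.
    energies
        Strictly increasing keV vector whose length equals the 4th extent.
    spacing
        Optional mm-per-voxel for the three spatial axes (metadata only;
        voxel coordinates used by the models are index-scale by default).
    """

    values: np.ndarray
    energies: np.ndarray
    spacing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise DimensionalityError(
                f"spectral volume must be 4D, got {self.values.ndim}D"
            )
        if min(self.values.shape) < 1:
            raise DimensionalityError("all volume extents must be >= 1")
        self.energies = _validate_energies(self.energies, self.values.shape[3])
        if self.spacing is not None:
            self.spacing = np.asarray(self.spacing, dtype=float).ravel()
            if self.spacing.size != 3:
                raise MetadataError("spacing must have 3 entries (mm per spatial axis)")
        if not np.all(np.isfinite(self.values)):
            raise MetadataError("volume contains non-finite HU values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_energies(self) -> int:
        return self.values.shape[3]


@dataclass
class VoxelMask:
    """A 3D boolean mask over the spatial grid of a parent volume."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got {self.values.ndim}D")

    @property
    def n_true(self) -> int:
        return int(self.values.sum())


@dataclass
class LabelVolume:
    """A 3D integer label map: 0 = unlabeled/background, 1..K = cluster ids."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DimensionalityError(f"label volume must be 3D, got {self.values.ndim}D")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.array_equal(self.values, np.round(self.values)):
                raise InvariantViolationError("labels must be integers")
            self.values = self.values.astype(np.int32)
        if self.values.min(initial=0) < 0:
            raise InvariantViolationError("labels must be >= 0")


@dataclass
class CurveDataset:
    """Flattened analysis form of a masked spectral volume.

    Each of the ``n`` retained voxels contributes its 3D coordinates
    ``coords[i]`` and its m-point decay curve ``curves[i]`` over the shared
    ``energies`` axis.  ``index_map`` holds the original integer voxel indices
    (n×3) so that per-voxel labels can be written back into a volume; it is
    ``None`` for datasets sampled off-grid (e.g. from a generative model).
    """

    coords: np.ndarray
    curves: np.ndarray
    energies: np.ndarray
    index_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.coords.shape[0] != self.curves.shape[0]:
            raise InvariantViolationError("coords and curves must have the same row count")
        if self.coords.shape[0] < 1:
            raise EmptyDatasetError("dataset must contain at least one voxel")
        if self.coords.shape[1] != 3:
            raise DimensionalityError("coords must be n x 3")
        self.energies = _validate_energies(self.energies, self.curves.shape[1])
        if self.index_map is not None:
            self.index_map = np.atleast_2d(np.asarray(self.index_map, dtype=np.int64))
            if self.index_map.shape != (self.coords.shape[0], 3):
                raise InvariantViolationError("index_map must be n x 3 integer voxel indices")
            if len(np.unique(self.index_map, axis=0)) != self.index_map.shape[0]:
                raise InvariantViolationError("index_map entries must be unique")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_energies(self) -> int:
        return self.curves.shape[1]


# ---------------------------------------------------------------------------
# NIfTI I/O


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return path.with_name(name + ".energies.json")


def load_spectral_volume(path: str | Path, energies: np.ndarray | None = None) -> SpectralVolume:
    """Load a 4D spectral NIfTI volume.

    The energy axis is taken from, in order of precedence: the ``energies``
    argument, a ``<stem>.energies.json`` sidecar, or the default grid starting
    at 40 keV in 5 keV increments.
    """
    path = Path(path)
    img = nib.load(str(path))
    if img.ndim != 4:
        raise DimensionalityError(f"expected a 4D image, got {img.ndim}D: {path}")
    values = np.asarray(img.get_fdata(), dtype=float)
    m = values.shape[3]
    if energies is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
            if "energies_kev" not in meta:
                raise MetadataError(f"sidecar {sidecar} lacks 'energies_kev'")
            energies = np.asarray(meta["energies_kev"], dtype=float)
        else:
            energies = default_energy_grid(m)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return SpectralVolume(values=values, energies=energies, spacing=spacing)


def save_spectral_volume(vol: SpectralVolume, path: str | Path) -> None:
    """Write a spectral volume as 4D NIfTI plus a JSON energy-axis sidecar."""
    path = Path(path)
    spacing = vol.spacing if vol.spacing is not None else np.ones(3)
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float64), affine)
    img.header.set_zooms((*spacing, 1.0))
    nib.save(img, str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"energies_kev": [float(e) for e in vol.energies]}, fh)


def load_mask(path: str | Path) -> VoxelMask:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionalityError(f"expected a 3D mask, got {img.ndim}D")
    return VoxelMask(values=np.asarray(img.get_fdata()) > 0.5)


def save_mask(mask: VoxelMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), np.eye(4)), str(path))


def load_labels(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionalityError(f"expected a 3D label map, got {img.ndim}D")
    return LabelVolume(values=np.asarray(img.get_fdata()).round().astype(np.int32))


def save_labels(labels: LabelVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(labels.values.astype(np.int32), np.eye(4)), str(path))


# ---------------------------------------------------------------------------
# Preprocessing and reshaping


def crop_voi(vol: SpectralVolume, bounds) -> SpectralVolume:
    """Crop a volume of interest given three half-open index ranges.

    ``bounds`` is a sequence of three ``(lo, hi)`` pairs, one per spatial
    axis; the energy axis is never cropped.
    """
    bounds = [tuple(int(b) for b in rng) for rng in bounds]
    if len(bounds) != 3:
        raise BoundsError("bounds must give 3 index ranges")
    slices = []
    for axis, (lo, hi) in enumerate(bounds):
        extent = vol.values.shape[axis]
        if not (0 <= lo < hi <= extent):
            raise BoundsError(
                f"range [{lo}, {hi}) invalid for axis {axis} of extent {extent}"
            )
        slices.append(slice(lo, hi))
    return SpectralVolume(
        values=vol.values[tuple(slices)].copy(),
        energies=vol.energies.copy(),
        spacing=None if vol.spacing is None else vol.spacing.copy(),
    )


def mask_air(
    vol: SpectralVolume,
    threshold_hu: float = DEFAULT_AIR_THRESHOLD_HU,
    reference_energy: float = DEFAULT_REFERENCE_ENERGY_KEV,
) -> VoxelMask:
    """Mask air voxels: true where HU at the reference energy exceeds the threshold."""
    matches = np.isclose(vol.energies, reference_energy)
    if not matches.any():
        raise EnergyAxisError(
            f"reference energy {reference_energy} keV not on the axis "
            f"[{vol.energies[0]}, {vol.energies[-1]}]"
        )
    idx = int(np.flatnonzero(matches)[0])
    return VoxelMask(values=vol.values[..., idx] > threshold_hu)


def flatten(vol: SpectralVolume, mask: VoxelMask | None = None) -> CurveDataset:
    """Flatten the masked voxels of a volume into a :class:`CurveDataset`.

    Coordinates are 0-based voxel indices of the (possibly cropped) volume,
    cast to reals; physical spacing is deliberately not applied (the spatial
    covariance regularization scale was chosen on index-scale coordinates).
    """
    if mask is None:
        mask = VoxelMask(values=np.ones(vol.spatial_shape, dtype=bool))
    if mask.values.shape != vol.spatial_shape:
        raise DimensionalityError("mask shape does not match volume spatial shape")
    idx = np.argwhere(mask.values)
    if idx.shape[0] == 0:
        raise EmptyDatasetError("mask selects no voxels")
    curves = vol.values[mask.values]
    return CurveDataset(
        coords=idx.astype(float),
        curves=curves,
        energies=vol.energies.copy(),
        index_map=idx,
    )


def labels_to_volume(dataset: CurveDataset, labels: np.ndarray, shape) -> LabelVolume:
    """Write per-voxel labels back into a 3D label map (0 elsewhere)."""
    if dataset.index_map is None:
        raise InvariantViolationError("dataset has no voxel index map (off-grid sample)")
    labels = np.asarray(labels).ravel()
    if labels.size != dataset.n_voxels:
        raise InvariantViolationError(
            f"got {labels.size} labels for {dataset.n_voxels} voxels"
        )
    shape = tuple(int(s) for s in shape)
    if any(int(mx) >= s for mx, s in zip(dataset.index_map.max(axis=0), shape)):
        raise BoundsError("index map exceeds the requested volume shape")
    out = np.zeros(shape, dtype=np.int32)
    out[tuple(dataset.index_map.T)] = labels.astype(np.int32)
    return LabelVolume(values=out)
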