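"""Core image-space containers: DWI volumes, tensor fields, scalar maps.

Conventions: voxel indices are 0-based; the 4x4 affine maps voxel indices
(voxel centers) to mm/world coordinates. Tensor fields store the six unique
components in the order (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), in mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


def _check_affine(affine) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    return affine


@dataclass
class DWIVolume:
    """4-D diffusion-weighted data (X, Y, Z, volumes) with a voxel->mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, volume)")
        self.affine = _check_affine(self.affine)

    @property
    def grid_shape(self):
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "DWIVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors.

    ``tensors`` has shape (X, Y, Z, 6) in the (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    order; ``mask`` marks voxels holding a valid fit.
    """

    tensors: np.ndarray
    affine: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 4 or self.tensors.shape[3] != 6:
            raise ValueError("tensors must have shape (x, y, z, 6)")
        self.affine = _check_affine(self.affine)
        if self.mask is None:
            self.mask = np.ones(self.tensors.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.tensors.shape[:3]:
                raise ValueError("mask shape does not match tensor grid")

    @property
    def grid_shape(self):
        return self.tensors.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Full 3x3 symmetric matrices, shape (X, Y, Z, 3, 3)."""
        return components_to_matrices(self.tensors)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.tensors.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path, mask=None) -> "TensorField":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, mask)


@dataclass
class EigenSystem:
    """Per-voxel eigendecomposition, eigenvalues sorted descending.

    ``eigenvalues``: (X, Y, Z, 3) with lambda1 >= lambda2 >= lambda3;
    ``eigenvectors``: (X, Y, Z, 3, 3) with column j the unit eigenvector of
    eigenvalue j; ``negative``: voxels where any eigenvalue is < 0 (kept,
    flagged); ``mask``: valid voxels.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    affine: np.ndarray
    mask: np.ndarray = None
    negative: np.ndarray = field(default=None)

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.affine = _check_affine(self.affine)
        grid = self.eigenvalues.shape[:3]
        if self.mask is None:
            self.mask = np.ones(grid, dtype=bool)
        if self.negative is None:
            self.negative = (self.eigenvalues < 0).any(axis=-1) & self.mask


@dataclass
class ScalarMap:
    """A per-voxel scalar (e.g. FA) with its affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("scalar map must be 3-D")
        self.affine = _check_affine(self.affine)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "ScalarMap":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine)


def components_to_matrices(comps: np.ndarray) -> np.ndarray:
    """(..., 6) unique components -> (..., 3, 3) symmetric matrices."""
    comps = np.asarray(comps, dtype=float)
    m = np.empty(comps.shape[:-1] + (3, 3), dtype=float)
    m[..., 0, 0] = comps[..., 0]
    m[..., 1, 1] = comps[..., 1]
    m[..., 2, 2] = comps[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = comps[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = comps[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = comps[..., 5]
    return m


def matrices_to_components(m: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) unique components."""
    m = np.asarray(m, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )
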