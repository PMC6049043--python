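"""Diffusion gradient tables (FSL-style .bval/.bvec text files)."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np


class GradientTable:
    """b-values and unit gradient directions, one row per DWI volume.

    Parameters
    ----------
    bvals : array-like, shape (V,)
        b-value per volume in s/mm^2. Zero rows are unweighted (b=0) images.
    bvecs : array-like, shape (V, 3)
        Gradient direction per volume. Non-unit vectors at b>0 are
        normalized with a warning; b=0 rows may carry arbitrary (even zero)
        direction entries.
    """

    def __init__(self, bvals, bvecs):
        bvals = np.asarray(bvals, dtype=float).ravel()
        bvecs = np.asarray(bvecs, dtype=float)
        if bvecs.shape == (3, len(bvals)) and bvecs.shape[0] != bvecs.shape[1]:
            bvecs = bvecs.T
        if bvecs.shape != (len(bvals), 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {len(bvals)} b-values"
            )
        weighted = bvals > 0
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(norms[weighted] == 0):
            raise ValueError("zero-norm gradient direction at b>0")
        if not np.allclose(norms[weighted], 1.0, atol=1e-6):
            warnings.warn("non-unit gradient directions normalized", stacklevel=2)
        bvecs = bvecs.copy()
        bvecs[weighted] /= norms[weighted, None]
        self.bvals = bvals
        self.bvecs = bvecs
        if self.n_b0 < 1:
            raise ValueError("gradient table needs at least one b=0 volume")
        if not _has_six_independent(bvecs[weighted]):
            raise ValueError("need >= 6 non-collinear diffusion directions")

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def design_matrix(self) -> np.ndarray:
        """Log-signal design for the single-tensor model.

        Columns: [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] coefficients, i.e.
        ln S = ln S0 - b g^T D g expanded over the six unique components.
        """
        b = self.bvals
        gx, gy, gz = self.bvecs.T
        return np.column_stack(
            [
                np.ones_like(b),
                -b * gx**2,
                -b * gy**2,
                -b * gz**2,
                -2 * b * gx * gy,
                -2 * b * gx * gz,
                -2 * b * gy * gz,
            ]
        )

    def save(self, bval_path, bvec_path) -> None:
        np.savetxt(bval_path, self.bvals[None], fmt="%.6g")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")

    @classmethod
    def load(cls, bval_path, bvec_path) -> "GradientTable":
        bvals = np.loadtxt(Path(bval_path)).ravel()
        bvecs = np.loadtxt(Path(bvec_path))
        return cls(bvals, bvecs)

    def __repr__(self):  # pragma: no cover
        return f"GradientTable({self.n_volumes} volumes, {self.n_b0} b=0)"


def _has_six_independent(dirs: np.ndarray) -> bool:
    """True when the b>0 directions span the 6-dim tensor design space."""
    if len(dirs) < 6:
        return False
    gx, gy, gz = dirs.T
    m = np.column_stack([gx**2, gy**2, gz**2, gx * gy, gx * gz, gy * gz])
    return np.linalg.matrix_rank(m) == 6


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the sphere (spherical Fibonacci)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
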