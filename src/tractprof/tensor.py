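"""Diffusion-tensor fitting, eigendecomposition, and fractional anisotropy.

The single-tensor model relates the measured signal to the local diffusion
tensor D through S = S0 * exp(-b g^T D g). Fitting is done on log-signal
with ordinary (``ols``), variance-stabilized weighted (``wls``), or robust
iteratively-reweighted (``robust``) least squares. The robust mode uses
Geman-McClure weights to downweight per-voxel outlier volumes, in the
spirit of robust tensor estimators that reject corrupted measurements.

FA is computed from the sorted eigenvalues as

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / sqrt(l1^2+l2^2+l3^2)
"""

from __future__ import annotations

import warnings

import numpy as np

from tractprof.containers import (
    DWIVolume,
    EigenSystem,
    ScalarMap,
    TensorField,
    components_to_matrices,
)
from tractprof.gradients import GradientTable

_IRLS_MAX_ITER = 20
_IRLS_TOL = 1e-6


def fit_tensor(dwi: DWIVolume, grads: GradientTable, method: str = "ols") -> TensorField:
    """Fit a diffusion tensor per voxel from a 4-D DWI volume.

    Parameters
    ----------
    dwi : DWIVolume
        4-D data; the last axis must match the gradient table.
    grads : GradientTable
        Needs >= 1 b=0 volume and >= 6 independent directions (enforced by
        the table itself).
    method : {"ols", "wls", "robust"}
        ``ols``: unweighted log-linear fit. ``wls``: weights equal to the
        squared predicted signal (the standard variance stabilization for
        log-transformed data). ``robust``: WLS combined with Geman-McClure
        outlier weights iterated to convergence.

    Returns
    -------
    TensorField
        Voxels whose signals are all zero are masked out. Non-positive
        signals elsewhere are clamped to the smallest positive value in the
        volume (with a warning) so the log transform is defined.
    """
    if method not in ("ols", "wls", "robust"):
        raise ValueError(f"unknown fit method {method!r}")
    if dwi.n_volumes != grads.n_volumes:
        raise ValueError("DWI volume count does not match gradient table")

    X = grads.design_matrix()
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        raise ValueError(
            f"rank-deficient tensor design (rank {rank} < 7): "
            "gradient directions do not span the tensor space"
        )

    grid = dwi.grid_shape
    S = dwi.data.reshape(-1, dwi.n_volumes)
    mask = ~(S <= 0).all(axis=1)
    S = S.copy()
    nonpos = S <= 0
    if nonpos[mask].any():
        smallest = S[S > 0].min()
        warnings.warn(
            "non-positive DWI signals clamped to smallest positive value",
            stacklevel=2,
        )
        S[nonpos] = smallest
    Y = np.log(S[mask])

    beta = _ols(X, Y)
    if method in ("wls", "robust"):
        beta = _wls(X, Y, beta)
    if method == "robust":
        beta = _irls_geman_mcclure(X, Y, beta)

    tensors = np.zeros(grid + (6,), dtype=float)
    tensors.reshape(-1, 6)[mask] = beta[:, 1:]
    return TensorField(tensors, dwi.affine, mask.reshape(grid))


def _ols(X, Y):
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return beta.T


def _solve_weighted(X, Y, W):
    """Per-voxel weighted normal equations. W, Y: (n, V); X: (V, 7)."""
    A = np.einsum("vi,nv,vj->nij", X, W, X)
    b = np.einsum("vi,nv->ni", X, W * Y)
    return np.linalg.solve(A, b[..., None])[..., 0]


def _wls(X, Y, beta):
    w = np.exp(X @ beta.T).T ** 2  # squared predicted signal
    return _solve_weighted(X, Y, w)


def _irls_geman_mcclure(X, Y, beta):
    """Iteratively reweighted fit with Geman-McClure weights.

    Residuals are scaled per voxel by 1.4826 * MAD; weights
    w = 1 / (1 + (r/sigma)^2)^2 multiply the WLS base weights. Iterates to
    convergence (beta change < 1e-6) or 20 iterations.
    """
    for _ in range(_IRLS_MAX_ITER):
        pred = (X @ beta.T).T
        resid = Y - pred
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid, axis=1, keepdims=True)),
                                   axis=1, keepdims=True)
        sigma = np.maximum(sigma, 1e-12)
        w = np.exp(pred) ** 2 / (1.0 + (resid / sigma) ** 2) ** 2
        new_beta = _solve_weighted(X, Y, w)
        if np.max(np.abs(new_beta - beta)) < _IRLS_TOL:
            beta = new_beta
            break
        beta = new_beta
    return beta


def eigensystem(t: TensorField) -> EigenSystem:
    """Eigendecompose a tensor field; eigenvalues sorted descending.

    Voxels with non-finite tensors are masked out. Negative eigenvalues are
    retained in the output and flagged in ``negative``.
    """
    grid = t.grid_shape
    finite = np.isfinite(t.tensors).all(axis=-1)
    mask = t.mask & finite
    mats = components_to_matrices(t.tensors.reshape(-1, 6)[mask.ravel()])
    evals = np.zeros(grid + (3,), dtype=float)
    evecs = np.zeros(grid + (3, 3), dtype=float)
    evecs[..., :, :] = np.eye(3)
    if mats.size:
        w, v = np.linalg.eigh(mats)  # ascending
        w = w[:, ::-1]
        v = v[:, :, ::-1]
        evals.reshape(-1, 3)[mask.ravel()] = w
        evecs.reshape(-1, 3, 3)[mask.ravel()] = v
    return EigenSystem(evals, evecs, t.affine, mask)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalue triples along the last axis.

    Negative eigenvalues are clamped to 0 before evaluation; all-zero
    triples give FA = 0.
    """
    ev = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    d12 = ev[..., 0] - ev[..., 1]
    d23 = ev[..., 1] - ev[..., 2]
    d31 = ev[..., 2] - ev[..., 0]
    num = np.sqrt(d12**2 + d23**2 + d31**2)
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(fa, 0.0, 1.0)


def fractional_anisotropy(e: EigenSystem) -> ScalarMap:
    """FA map from an eigensystem (0 outside the validity mask)."""
    fa = fa_from_eigenvalues(e.eigenvalues)
    fa[~e.mask] = 0.0
    return ScalarMap(fa, e.affine)
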