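"""Deterministic streamline tractography (STT) on a tensor field.

Whole-brain tracking follows the classic streamlines-tracking recipe:
seed every white-matter voxel (FA > 0.3) with 8 sub-voxel seed points,
integrate bidirectionally along the principal eigenvector field with a
fourth-order Runge-Kutta scheme at a 1 mm step, and terminate a track when
the interpolated FA falls below 0.2, the turning angle between two
consecutive segments exceeds 30 degrees, or the track leaves the volume.
Tracks shorter than 20 mm are discarded.

Tensor components are trilinearly interpolated and then eigendecomposed at
every evaluation point (interpolating eigenvectors directly is
sign-ambiguous); eigenvector signs are kept coherent with the previous
direction of travel. All streamlines live in mm (world) coordinates; there
is no randomness anywhere, so repeated runs are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.ndimage import map_coordinates

from tractprof.containers import ScalarMap, TensorField, components_to_matrices


@dataclass
class TrackingParams:
    seed_fa_threshold: float = 0.3
    seeds_per_voxel: int = 8
    step_mm: float = 1.0
    stop_fa: float = 0.2
    max_angle_deg: float = 30.0
    min_length_mm: float = 20.0
    max_steps: int = 500

    def __post_init__(self):
        if not (0 <= self.stop_fa <= self.seed_fa_threshold <= 1):
            raise ValueError("need 0 <= stop_fa <= seed_fa_threshold <= 1")
        if self.step_mm <= 0:
            raise ValueError("step must be positive")
        if self.min_length_mm < self.step_mm:
            raise ValueError("min length must be at least one step")


def streamline_length(points: np.ndarray) -> float:
    """Sum of consecutive point distances (mm)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def seed_points(fa: ScalarMap, params: TrackingParams = None) -> np.ndarray:
    """Seed coordinates (mm): 8 per voxel with FA above the seed threshold.

    Seeds sit on the 2x2x2 sub-grid at +/-0.25 voxel offsets from each
    qualifying voxel center, which keeps seeding regular and deterministic.
    """
    params = params or TrackingParams()
    idx = np.argwhere(fa.data > params.seed_fa_threshold)
    if len(idx) == 0:
        warnings.warn("no voxels above the seed FA threshold", stacklevel=2)
        return np.empty((0, 3))
    offsets = np.array(list(product((-0.25, 0.25), repeat=3)))
    vox = (idx[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    return _vox_to_world(vox, fa.affine)


def _vox_to_world(vox: np.ndarray, affine: np.ndarray) -> np.ndarray:
    return vox @ affine[:3, :3].T + affine[:3, 3]


def _world_to_vox(pts: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


class _Field:
    """Batched evaluation of principal directions and FA at mm points."""

    def __init__(self, tensors: TensorField, fa: ScalarMap):
        self.comps = [np.ascontiguousarray(tensors.tensors[..., k]) for k in range(6)]
        self.fa = fa.data
        self.affine = tensors.affine
        self.shape = np.array(tensors.grid_shape, dtype=float)

    def inside(self, pts: np.ndarray) -> np.ndarray:
        vox = _world_to_vox(pts, self.affine)
        return ((vox >= 0) & (vox <= self.shape - 1)).all(axis=1)

    def fa_at(self, pts: np.ndarray) -> np.ndarray:
        vox = _world_to_vox(pts, self.affine)
        return map_coordinates(self.fa, vox.T, order=1, mode="constant", cval=0.0)

    def directions(self, pts: np.ndarray, ref: np.ndarray) -> np.ndarray:
        """Unit principal eigenvectors at pts, sign-aligned with ref."""
        vox = _world_to_vox(pts, self.affine)
        coords = vox.T
        c = np.stack(
            [map_coordinates(comp, coords, order=1, mode="nearest") for comp in self.comps],
            axis=-1,
        )
        mats = components_to_matrices(c)
        _, vecs = np.linalg.eigh(mats)
        d = vecs[:, :, 2]  # eigenvector of the largest eigenvalue
        flip = np.einsum("ij,ij->i", d, ref) < 0
        d[flip] *= -1
        return d


def _integrate(field: _Field, seeds: np.ndarray, init_dirs: np.ndarray, params: TrackingParams):
    """Track a batch of seeds in one direction.

    Returns (points array (max_steps+1, M, 3) NaN-padded, counts (M,)) where
    counts[i] is the number of valid points of track i (>= 1, the seed).
    """
    m = len(seeds)
    h = params.step_mm
    cos_max = np.cos(np.deg2rad(params.max_angle_deg))
    pts = np.full((params.max_steps + 1, m, 3), np.nan)
    pts[0] = seeds
    counts = np.ones(m, dtype=int)
    pos = seeds.copy()
    prev = init_dirs.copy()
    alive = field.inside(pos) & (field.fa_at(pos) >= params.stop_fa)

    for step in range(params.max_steps):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        p = pos[idx]
        d0 = prev[idx]
        k1 = field.directions(p, d0)
        k2 = field.directions(p + 0.5 * h * k1, k1)
        k3 = field.directions(p + 0.5 * h * k2, k2)
        k4 = field.directions(p + h * k3, k3)
        v = k1 + 2 * k2 + 2 * k3 + k4
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        ok = norm[:, 0] > 1e-12
        v = np.where(ok[:, None], v / np.where(ok[:, None], norm, 1.0), d0)
        new = p + h * v

        keep = ok
        keep &= field.inside(new)
        keep &= field.fa_at(new) >= params.stop_fa
        keep &= np.einsum("ij,ij->i", v, d0) >= cos_max  # turning-angle rule

        kept = idx[keep]
        pts[step + 1, kept] = new[keep]
        counts[kept] += 1
        pos[kept] = new[keep]
        prev[kept] = v[keep]
        alive[idx[~keep]] = False

    return pts, counts


def _seed_directions(field: _Field, seeds: np.ndarray) -> np.ndarray:
    return field.directions(seeds, np.tile([[1.0, 0.0, 0.0]], (len(seeds), 1)))


def _merge_halves(fwd_pts, fwd_counts, bwd_pts, bwd_counts, i):
    forward = fwd_pts[: fwd_counts[i], i]
    backward = bwd_pts[1 : bwd_counts[i], i][::-1]
    return np.vstack([backward, forward])


def track_from_seed(
    t: TensorField, fa: ScalarMap, seed, params: TrackingParams = None
) -> np.ndarray | None:
    """Bidirectional track from a single seed (mm), or None.

    Integrates along +/- the principal eigenvector at the seed, concatenates
    the two half-tracks, and applies the minimum-length filter.
    """
    params = params or TrackingParams()
    field = _Field(t, fa)
    seed = np.asarray(seed, dtype=float).reshape(1, 3)
    if not field.inside(seed)[0] or field.fa_at(seed)[0] < params.stop_fa:
        return None
    d0 = _seed_directions(field, seed)
    fwd_pts, fwd_counts = _integrate(field, seed, d0, params)
    bwd_pts, bwd_counts = _integrate(field, seed, -d0, params)
    line = _merge_halves(fwd_pts, fwd_counts, bwd_pts, bwd_counts, 0)
    if streamline_length(line) < params.min_length_mm:
        return None
    return line


def whole_brain_tracking(
    t: TensorField, fa: ScalarMap, params: TrackingParams = None, seeds=None
) -> list[np.ndarray]:
    """Track from every seed; return length-filtered streamlines (mm).

    Fully deterministic: the output set depends only on the tensor field,
    the FA map, and the parameters, not on seed enumeration order.
    """
    params = params or TrackingParams()
    field = _Field(t, fa)
    if seeds is None:
        seeds = seed_points(fa, params)
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 3)
    if len(seeds) == 0:
        return []
    valid = field.inside(seeds) & (field.fa_at(seeds) >= params.stop_fa)
    seeds = seeds[valid]
    if len(seeds) == 0:
        return []
    d0 = _seed_directions(field, seeds)
    fwd_pts, fwd_counts = _integrate(field, seeds, d0, params)
    bwd_pts, bwd_counts = _integrate(field, seeds, -d0, params)
    out = []
    min_pts = int(np.ceil(params.min_length_mm / params.step_mm))
    for i in range(len(seeds)):
        if fwd_counts[i] + bwd_counts[i] - 1 <= min_pts:
            continue
        line = _merge_halves(fwd_pts, fwd_counts, bwd_pts, bwd_counts, i)
        if streamline_length(line) >= params.min_length_mm:
            out.append(line)
    return out


def save_streamlines(streamlines, path, affine=None, params: TrackingParams = None):
    """Write streamlines as TRK or TCK (chosen by extension) plus a JSON
    sidecar with the tracking parameters."""
    import json
    from pathlib import Path

    import nibabel as nib
    from nibabel.streamlines import Tractogram

    path = Path(path)
    tractogram = Tractogram(list(streamlines), affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        header = nib.streamlines.trk.TrkFile.create_empty_header()
        if affine is not None:
            header["voxel_to_rasmm"] = np.asarray(affine, dtype=np.float32)
            header["voxel_sizes"] = np.linalg.norm(affine[:3, :3], axis=0)
            header["dimensions"] = (1, 1, 1)
        nib.streamlines.save(tractogram, str(path), header=header)
    elif path.suffix == ".tck":
        nib.streamlines.save(tractogram, str(path))
    else:
        raise ValueError("streamline path must end in .trk or .tck")
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(params.__dict__, indent=2))


def load_streamlines(path) -> list[np.ndarray]:
    import nibabel as nib

    tractogram = nib.streamlines.load(str(path)).tractogram
    return [np.asarray(s, dtype=float) for s in tractogram.streamlines]
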