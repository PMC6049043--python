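import numpy as np
import pytest

import tractprof as tp
from tractprof import simulate as sim

VOX = sim.DEFAULT_VOXEL_MM


def _fit_fa(phantom):
    tensors = tp.fit_tensor(phantom.dwi, phantom.grads, method="ols")
    fa = tp.fractional_anisotropy(tp.eigensystem(tensors))
    return tensors, fa


@pytest.fixture(scope="session")
def tube_phantom():
    """Straight ~60 mm tube along z, thin bundle (radius < 1 voxel) so every
    seed voxel sits on the axis row."""
    z0 = 3 * VOX
    spec = sim.PhantomSpec(
        grid_shape=(11, 11, 41),
        bundle_radius=1.6,
        centerline=sim.straight_centerline([5 * VOX, 5 * VOX, z0], [5 * VOX, 5 * VOX, z0 + 60.0], 40),
    )
    return sim.make_bundle_phantom(spec)


def tube_length_mm(phantom) -> float:
    """Tube length oracle from the construction: the extent of bundle voxel
    centers along the tube axis (z)."""
    z_idx = np.flatnonzero(phantom.mask.any(axis=(0, 1)))
    return float((z_idx.max() - z_idx.min()) * phantom.spec.voxel_size)


@pytest.fixture(scope="session")
def tube_tracking(tube_phantom):
    tensors, fa = _fit_fa(tube_phantom)
    streamlines = tp.whole_brain_tracking(tensors, fa, tp.TrackingParams())
    return tensors, fa, streamlines


@pytest.fixture(scope="session")
def kink_phantom():
    """60-degree bend; fine 0.8 mm grid so the orientation transition is
    shorter than the 1 mm integration step."""
    vox = 0.8
    a = np.deg2rad(60.0)
    corner = np.array([5 * vox, 3 * vox, 3 * vox + 30.0])
    start = np.array([5 * vox, 3 * vox, 3 * vox])
    end = corner + 25.0 * np.array([0.0, np.sin(a), np.cos(a)])
    ny = int(np.ceil((end[1] + 5 * vox) / vox))
    nz = int(np.ceil((end[2] + 5 * vox) / vox))
    spec = sim.PhantomSpec(
        grid_shape=(11, ny, nz),
        voxel_size=vox,
        bundle_radius=0.9 * vox,
        centerline=sim.kinked_centerline(start, corner, end, 60),
    )
    phantom = sim.make_bundle_phantom(spec)
    return phantom, corner, np.array([0.0, np.sin(a), np.cos(a)])


@pytest.fixture(scope="session")
def kink_tracking(kink_phantom):
    phantom, corner, leg2_dir = kink_phantom
    tensors, fa = _fit_fa(phantom)
    streamlines = tp.whole_brain_tracking(tensors, fa, tp.TrackingParams())
    return streamlines, corner, leg2_dir, phantom.spec.voxel_size


def make_bundle(n_inliers=49, spread=0.5, planted_offset=None, seed=0, n_pts=40, length=60.0):
    """Synthetic fiber bundle along z; optionally one laterally planted fiber."""
    rng = np.random.default_rng(seed)

    def fiber(dx, dy):
        z = np.linspace(0.0, length, n_pts)
        return np.column_stack([np.full(n_pts, 30.0 + dx), np.full(n_pts, 30.0 + dy), z])

    fibers = [fiber(*rng.normal(0, spread, 2)) for _ in range(n_inliers)]
    if planted_offset is not None:
        fibers.append(fiber(*planted_offset))
    return tp.FiberGroup("bundle", fibers)


@pytest.fixture()
def bundle_with_outlier():
    # planted fiber displaced 20 voxels (36 mm) laterally
    return make_bundle(planted_offset=(36.0, 0.0), seed=0)
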