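"""Synthetic inputs with known ground truth.

Four generators cover everything the pipeline consumes:

* :func:`make_bundle_phantom` — a DWI volume containing a curved anisotropic
  bundle in an isotropic background, built from the single-tensor signal
  equation S = S0 exp(-b g^T D g), with the ground-truth tensor field and
  bundle mask returned alongside.
* :func:`make_profile_cohort` — subjects x 100-node FA profile matrices with
  group, age, and protocol structure and spatially smooth node noise (a
  Gaussian process with squared-exponential correlation across nodes, since
  adjacent-node correlation is what makes cluster statistics meaningful).
* :func:`make_behavior_table` — behavioral score tables drawn per group from
  the reading-measure means/SDs typical of 8-11-year-old typical vs.
  dyslexic readers (the defaults below).
* :func:`make_motion_trace` — per-volume rigid-body parameter traces.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from tractprof.containers import DWIVolume, TensorField, matrices_to_components
from tractprof.gradients import GradientTable, fibonacci_directions
from tractprof.motion import MotionTrace
from tractprof.stats import ProfileDataset

# Default acquisition constants: 1.8 mm isotropic voxels, b = 1000 s/mm^2,
# 72 diffusion directions — a typical pediatric single-shell DTI protocol.
DEFAULT_VOXEL_MM = 1.8
DEFAULT_B_VALUE = 1000.0
DEFAULT_N_DIRECTIONS = 72
DEFAULT_N_B0 = 3
DEFAULT_S0 = 1000.0

# Typical white-matter eigenvalues (mm^2/s): FA ~ 0.87 inside the bundle,
# isotropic 0.8e-3 outside (FA = 0).
EIGENVALUES_INSIDE = (1.7e-3, 0.2e-3, 0.2e-3)
EIGENVALUES_OUTSIDE = (0.8e-3, 0.8e-3, 0.8e-3)

# Group reading/behavior summary statistics: per measure, (mean, sd) for
# typical readers (group 1) and dyslexic readers (group 2). Group sizes in
# the emulated cohort are 13 and 15.
GROUP_SIZES = (13, 15)
BEHAVIOR_DEFAULTS = {
    "age_months": ((111.69, 8.44), (111.13, 6.29)),
    "word_reading_accuracy": ((98.80, 1.76), (90.53, 5.35)),
    "word_reading_fluency": ((118.46, 24.59), (65.60, 20.21)),
    "word_reading_accuracy_t": ((58.37, 4.69), (35.74, 12.71)),
    "word_reading_fluency_t": ((52.99, 9.65), (30.84, 7.55)),
    "spelling_accuracy": ((89.63, 6.76), (68.05, 11.52)),
    "spelling_rt": ((2.48, 0.59), (3.67, 0.91)),
    "letter_sound_matching_accuracy": ((91.11, 4.25), (90.79, 3.86)),
    "letter_sound_matching_rt": ((1.45, 0.25), (1.73, 0.36)),
    "phoneme_deletion_accuracy": ((84.58, 14.07), (64.59, 15.24)),
    "phoneme_deletion_rt": ((2.49, 0.85), (5.55, 2.15)),
    "memory_span_accuracy": ((49.30, 15.13), (40.39, 9.05)),
    "ran_rt": ((9.04, 1.17), (11.39, 1.75)),
    "wisc_similarities": ((10.92, 2.87), (11.50, 1.83)),
    "wisc_block_design": ((9.92, 2.81), (10.57, 2.28)),
    "wisc_digit_span": ((12.58, 3.12), (10.21, 1.81)),
}
# Verbal short-term memory correlates negatively with phonological RT in
# this population; the default inter-measure correlation encodes that.
DEFAULT_MEASURE_CORRELATION = ("wisc_digit_span", "phoneme_deletion_rt", -0.4)


# ---------------------------------------------------------------------------
# DWI bundle phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry, tensor model and acquisition for a bundle phantom.

    ``centerline`` is a polyline of mm coordinates (K x 3); the principal
    eigenvector inside the bundle follows its local tangent. Eigenvalues are
    in mm^2/s with l1 >= l2 >= l3 >= 0.
    """

    grid_shape: tuple = (20, 20, 20)
    voxel_size: float = DEFAULT_VOXEL_MM
    centerline: np.ndarray = None
    bundle_radius: float = 5.0
    eigenvalues_inside: tuple = EIGENVALUES_INSIDE
    eigenvalues_outside: tuple = EIGENVALUES_OUTSIDE
    b_value: float = DEFAULT_B_VALUE
    n_directions: int = DEFAULT_N_DIRECTIONS
    n_b0: int = DEFAULT_N_B0
    s0: float = DEFAULT_S0
    noise_model: str = "none"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.centerline is None:
            lo = np.array(self.grid_shape) * self.voxel_size * 0.1
            hi = np.array(self.grid_shape) * self.voxel_size * 0.8
            self.centerline = np.linspace(lo, hi, 50)
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be (K, 3) mm coordinates")
        for name in ("eigenvalues_inside", "eigenvalues_outside"):
            ev = np.asarray(getattr(self, name), dtype=float)
            if not (ev[0] >= ev[1] >= ev[2] >= 0):
                raise ValueError(f"{name} must satisfy l1 >= l2 >= l3 >= 0")
        if self.n_directions < 6:
            raise ValueError("need at least 6 diffusion directions")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        extent = (np.array(self.grid_shape) - 0.5) * self.voxel_size
        if ((self.centerline - self.bundle_radius < -0.5 * self.voxel_size).any()
                or (self.centerline + self.bundle_radius > extent).any()):
            raise ValueError(
                "bundle (centerline +/- radius) extends outside the voxel grid"
            )

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size
        return a


@dataclass
class Phantom:
    """A generated phantom: DWI, gradients, ground truth, and bundle mask."""

    dwi: DWIVolume
    grads: GradientTable
    tensors: TensorField
    mask: np.ndarray
    spec: PhantomSpec


def _densify_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~step spacing; return points and unit tangents."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    si = np.linspace(0, total, n)
    dense = np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])
    tangents = np.gradient(dense, si, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
    return dense, tangents


def _rotation_from_x(t: np.ndarray) -> np.ndarray:
    """Orthonormal frames (..., 3, 3) whose first column is the unit vector t."""
    t = np.asarray(t, dtype=float)
    helper = np.where(np.abs(t[..., [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    u = np.cross(t, helper)
    u /= np.maximum(np.linalg.norm(u, axis=-1, keepdims=True), 1e-12)
    v = np.cross(t, u)
    return np.stack([t, u, v], axis=-1)


def make_bundle_phantom(spec: PhantomSpec) -> Phantom:
    """Build a DWI phantom of one anisotropic bundle in isotropic background.

    Every voxel whose center lies within ``bundle_radius`` of the centerline
    gets an anisotropic tensor whose principal axis follows the local
    centerline tangent; other voxels get the isotropic outside tensor. The
    DWI signal is S = S0 exp(-b g^T D g) plus optional Gaussian or Rician
    noise. Deterministic given ``spec.seed``.
    """
    grid = tuple(spec.grid_shape)
    vox = spec.voxel_size
    idx = np.indices(grid).reshape(3, -1).T
    centers = idx * vox  # affine = diag(voxel), origin 0

    dense, tangents = _densify_polyline(spec.centerline, vox / 4.0)
    tree = cKDTree(dense)
    dist, nearest = tree.query(centers)
    inside = dist <= spec.bundle_radius

    n_vox = centers.shape[0]
    D = np.empty((n_vox, 3, 3))
    D[~inside] = np.diag(spec.eigenvalues_outside)
    if inside.any():
        R = _rotation_from_x(tangents[nearest[inside]])
        lam = np.diag(spec.eigenvalues_inside)
        D[inside] = R @ lam @ np.swapaxes(R, -1, -2)

    bvals = np.concatenate([np.zeros(spec.n_b0), np.full(spec.n_directions, spec.b_value)])
    bvecs = np.vstack([np.zeros((spec.n_b0, 3)), fibonacci_directions(spec.n_directions)])
    grads = GradientTable(bvals, bvecs)

    comps = matrices_to_components(D)
    X = grads.design_matrix()
    beta = np.column_stack([np.full(n_vox, np.log(spec.s0)), comps])
    signal = np.exp(beta @ X.T)  # (n_vox, V)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "gaussian" and spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    elif spec.noise_model == "rician" and spec.noise_sd > 0:
        n1 = rng.normal(0.0, spec.noise_sd, signal.shape)
        n2 = rng.normal(0.0, spec.noise_sd, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    dwi = DWIVolume(signal.reshape(grid + (grads.n_volumes,)), spec.affine)
    tensors = TensorField(comps.reshape(grid + (6,)), spec.affine)
    return Phantom(dwi, grads, tensors, inside.reshape(grid), spec)


def straight_centerline(start, end, n: int = 50) -> np.ndarray:
    """Straight polyline from start to end (mm)."""
    return np.linspace(np.asarray(start, float), np.asarray(end, float), n)


def kinked_centerline(start, corner, end, n: int = 50) -> np.ndarray:
    """Two straight legs meeting at a corner (mm) — a bend phantom."""
    leg1 = np.linspace(np.asarray(start, float), np.asarray(corner, float), n, endpoint=False)
    leg2 = np.linspace(np.asarray(corner, float), np.asarray(end, float), n)
    return np.vstack([leg1, leg2])


# ---------------------------------------------------------------------------
# profile cohorts
# ---------------------------------------------------------------------------


def default_baseline_profile(n_nodes: int = 100) -> np.ndarray:
    """A smooth, plausible FA profile: ~0.40 at the tract ends, ~0.55 mid-tract."""
    x = np.linspace(0.0, 1.0, n_nodes)
    return 0.40 + 0.15 * np.exp(-(((x - 0.5) / 0.25) ** 2))


@dataclass
class CohortSpec:
    """Ground-truth structure of a simulated two-group profile cohort.

    ``effect_nodes`` is a 1-based inclusive (start, end) node range on which
    group 2 receives an additive FA offset of ``effect_size``. ``age_slope``
    is FA change per month of age; ``age_range`` is in months (defaults span
    roughly ages 8-11). ``smoothness`` is the squared-exponential correlation
    length of the node noise, in nodes.
    """

    n_per_group: tuple = GROUP_SIZES
    n_nodes: int = 100
    baseline_profile: np.ndarray = None
    effect_nodes: tuple | None = None
    effect_size: float = 0.0
    age_slope: float = 0.0005
    age_range: tuple = (97.0, 135.0)
    protocol_offset: float = 0.01
    noise_sd: float = 0.03
    smoothness: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_profile is None:
            self.baseline_profile = default_baseline_profile(self.n_nodes)
        self.baseline_profile = np.asarray(self.baseline_profile, dtype=float)
        if len(self.baseline_profile) != self.n_nodes:
            raise ValueError("baseline_profile length must equal n_nodes")
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.effect_nodes is not None:
            lo, hi = self.effect_nodes
            if not (1 <= lo <= hi <= self.n_nodes):
                raise ValueError("effect_nodes must lie within [1, n_nodes]")


def _gp_noise(rng, n_subjects: int, n_nodes: int, sd: float, length: float) -> np.ndarray:
    if sd == 0:
        return np.zeros((n_subjects, n_nodes))
    if length <= 0:
        return rng.normal(0.0, sd, (n_subjects, n_nodes))
    nodes = np.arange(n_nodes)
    K = np.exp(-((nodes[:, None] - nodes[None, :]) ** 2) / (2 * length**2))
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n_nodes))
    return sd * rng.standard_normal((n_subjects, n_nodes)) @ L.T


def make_profile_cohort(spec: CohortSpec) -> ProfileDataset:
    """Simulate a two-group cohort of 100-node FA profiles.

    Each subject's profile is the baseline plus (for group 2) the additive
    effect on ``effect_nodes``, a linear age effect around the mean age, a
    protocol offset for protocol 2, and smooth Gaussian-process node noise.
    Values are clipped to [0, 1]. Covariates (group, age, protocol,
    digit_span) and a behavioral table are attached.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_per_group
    n = n1 + n2
    group = np.array([1] * n1 + [2] * n2)
    age = rng.uniform(*spec.age_range, n)
    # balanced protocol assignment within each group (deterministic)
    protocol = np.empty(n, dtype=int)
    protocol[:n1] = [1 if i < (n1 + 1) // 2 else 2 for i in range(n1)]
    protocol[n1:] = [1 if i < (n2 + 1) // 2 else 2 for i in range(n2)]

    fa = np.tile(spec.baseline_profile, (n, 1))
    if spec.effect_nodes is not None and spec.effect_size != 0:
        lo, hi = spec.effect_nodes
        fa[group == 2, lo - 1 : hi] += spec.effect_size
    fa += spec.age_slope * (age - age.mean())[:, None]
    fa[protocol == 2] += spec.protocol_offset
    fa += _gp_noise(rng, n, spec.n_nodes, spec.noise_sd, spec.smoothness)
    fa = np.clip(fa, 0.0, 1.0)

    behavior = make_behavior_table(
        BehaviorSpec(seed=int(rng.integers(2**31 - 1))), (n1, n2)
    )
    covariates = pd.DataFrame(
        {
            "group": group,
            "age": age,
            "protocol": protocol,
            "digit_span": behavior["wisc_digit_span"].to_numpy(),
        }
    )
    return ProfileDataset(fa=fa, covariates=covariates, behavior=behavior)


# ---------------------------------------------------------------------------
# behavior tables
# ---------------------------------------------------------------------------


@dataclass
class BehaviorSpec:
    """Per-measure per-group (mean, sd) plus optional inter-measure correlation.

    ``measures`` maps name -> ((m1, sd1), (m2, sd2)). ``correlations`` is a
    list of (measure_a, measure_b, rho) pairs applied within both groups;
    the default encodes the digit-span / phoneme-deletion-RT association.
    """

    measures: dict = field(default_factory=lambda: dict(BEHAVIOR_DEFAULTS))
    correlations: list = field(default_factory=lambda: [DEFAULT_MEASURE_CORRELATION])
    seed: int = 0

    def __post_init__(self):
        for name, ((m1, s1), (m2, s2)) in self.measures.items():
            if s1 < 0 or s2 < 0:
                raise ValueError(f"negative SD for measure {name!r}")
        names = list(self.measures)
        corr = np.eye(len(names))
        for a, b, rho in self.correlations or []:
            if a in names and b in names:
                ia, ib = names.index(a), names.index(b)
                corr[ia, ib] = corr[ib, ia] = rho
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("inter-measure correlation matrix is not PSD")
        self._corr = corr


def make_behavior_table(spec: BehaviorSpec, group_sizes=GROUP_SIZES) -> pd.DataFrame:
    """Draw per-group normal scores with the requested means, SDs and
    inter-measure correlations. Adds a ``group`` column (1, 2)."""
    n1, n2 = group_sizes
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(spec.seed)
    names = list(spec.measures)
    L = np.linalg.cholesky(spec._corr + 1e-12 * np.eye(len(names)))
    out = {"group": np.array([1] * n1 + [2] * n2)}
    z = rng.standard_normal((n1 + n2, len(names))) @ L.T
    for j, name in enumerate(names):
        (m1, s1), (m2, s2) = spec.measures[name]
        mean = np.where(out["group"] == 1, m1, m2)
        sd = np.where(out["group"] == 1, s1, s2)
        out[name] = mean + sd * z[:, j]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# motion traces
# ---------------------------------------------------------------------------


def make_motion_trace(
    n_volumes: int,
    amplitude: float = 0.1,
    spike_at: int | None = None,
    spike_size: float = 2.0,
    seed: int = 0,
) -> MotionTrace:
    """Random-walk rigid-motion trace relative to volume 1.

    ``amplitude`` is the SD of per-volume increments (mm for translations,
    degrees for rotations); the first row is all zeros. ``spike_at`` plants
    an abrupt translation of ``spike_size`` mm at that volume index.
    """
    if n_volumes < 1:
        raise ValueError("need at least one volume")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, amplitude, (n_volumes, 6)) if amplitude > 0 else np.zeros((n_volumes, 6))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    params -= params[0]
    if spike_at is not None:
        if not (0 < spike_at < n_volumes):
            raise ValueError("spike_at must be a volume index > 0")
        params[spike_at, 0] += spike_size
    return MotionTrace(params)
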