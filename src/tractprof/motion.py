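"""Motion quality control from rigid-body realignment parameters.

Head motion is summarized per subject by the root-mean-square absolute
displacement over all N volumes,

    RMS_abs = sqrt( sum_n (x_n^2 + y_n^2 + z_n^2 + a_n^2 + b_n^2 + g_n^2) / N ),

where translations are in mm and each rotation is first converted from
degrees to mm as an arc length on a 50 mm-radius sphere (a standard proxy
for the displacement of the cortical surface). A subject is excluded when
RMS_abs exceeds half the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_SPHERE_RADIUS_MM = 50.0

MOTION_COLUMNS = ("tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg")


@dataclass
class MotionTrace:
    """Per-volume rigid parameters relative to volume 1.

    ``params`` has shape (N, 6): three translations (mm) then three
    rotations (degrees). The first row is all zeros by construction.
    """

    params: np.ndarray

    def __post_init__(self):
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError("motion trace must have 6 columns")
        if self.params.shape[0] < 1:
            raise ValueError("motion trace needs at least one volume")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]

    def save(self, path) -> None:
        np.savetxt(path, self.params, fmt="%.6f")

    @classmethod
    def load(cls, path) -> "MotionTrace":
        return cls(np.loadtxt(Path(path)))


@dataclass
class MotionSummary:
    """RMS_abs displacement and the half-voxel exclusion decision."""

    rms_abs: float
    threshold: float
    excluded: bool


def rotation_to_mm(angle_deg, radius: float = DEFAULT_SPHERE_RADIUS_MM):
    """Rotation angle (degrees) to displacement in mm.

    Arc length swept on the surface of a sphere of the given radius:
    radius * angle_in_radians.
    """
    return radius * np.deg2rad(angle_deg)


def rms_displacement(trace: MotionTrace, radius: float = DEFAULT_SPHERE_RADIUS_MM) -> float:
    """RMS absolute displacement (mm) over all volumes, zero row included."""
    if trace.n_volumes < 1:
        raise ValueError("empty motion trace")
    rot_mm = rotation_to_mm(trace.rotations_deg, radius)
    per_volume = (trace.translations**2).sum(axis=1) + (rot_mm**2).sum(axis=1)
    return float(np.sqrt(per_volume.mean()))


def per_volume_displacement(trace: MotionTrace, radius: float = DEFAULT_SPHERE_RADIUS_MM) -> np.ndarray:
    """Euclidean displacement per volume (mm), rotations converted first."""
    rot_mm = rotation_to_mm(trace.rotations_deg, radius)
    return np.sqrt((trace.translations**2).sum(axis=1) + (rot_mm**2).sum(axis=1))


def qc_decide(rms: float, voxel_size: float) -> bool:
    """Exclusion rule: excluded iff RMS_abs is strictly larger than voxel/2."""
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    return bool(rms > voxel_size / 2.0)


def qc_summary(
    trace: MotionTrace,
    voxel_size: float,
    radius: float = DEFAULT_SPHERE_RADIUS_MM,
    spike_threshold_mm: float | None = None,
) -> MotionSummary:
    """Full QC on one trace: RMS_abs plus the half-voxel rule.

    ``spike_threshold_mm``, if given, additionally excludes subjects with
    any single-volume displacement above it (a reproducible surrogate for
    visual spike inspection).
    """
    rms = rms_displacement(trace, radius)
    excluded = qc_decide(rms, voxel_size)
    if spike_threshold_mm is not None:
        excluded = excluded or bool(
            (per_volume_displacement(trace, radius) > spike_threshold_mm).any()
        )
    return MotionSummary(rms_abs=rms, threshold=voxel_size / 2.0, excluded=excluded)


def qc_report(traces: dict, voxel_size: float, path=None, **kwargs) -> pd.DataFrame:
    """QC table (subject, rms_abs, threshold, excluded) for many subjects."""
    rows = []
    for subject, trace in traces.items():
        s = qc_summary(trace, voxel_size, **kwargs)
        rows.append(
            {
                "subject": subject,
                "rms_abs": s.rms_abs,
                "threshold": s.threshold,
                "excluded": s.excluded,
            }
        )
    report = pd.DataFrame(rows)
    if path is not None:
        report.to_csv(path, sep="\t", index=False)
    return report
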