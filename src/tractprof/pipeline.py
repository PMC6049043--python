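"""End-to-end orchestration: phantom -> tensors -> tracking -> profiles -> stats.

A :class:`RunConfig` names every stage parameter and per-stage seed; a run
writes its artifacts plus a manifest (config snapshot, package version,
SHA-256 of every output) so deterministic stages reproduce identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import yaml

from tractprof import simulate
from tractprof.motion import qc_report
from tractprof.stats import (
    nodewise_correlation,
    permutation_cluster_test,
    rm_ancova,
    summarize_correlation_clusters,
    term_table,
)
from tractprof.tensor import eigensystem, fit_tensor, fractional_anisotropy
from tractprof.tracking import TrackingParams, save_streamlines, whole_brain_tracking
from tractprof.tracts import (
    CleaningParams,
    WaypointROI,
    clean_fibers,
    segment_by_waypoints,
    tract_profile,
)

log = logging.getLogger("tractprof")

STAGES = ("simulate", "fit", "qc", "track", "extract", "stats")


def bonferroni_threshold(family_alpha: float = 0.05, n_tests: int = 16) -> float:
    """Per-test significance threshold alpha / m, rounded half-up to 4
    decimals (0.05 / 16 = 0.003125 -> 0.0031)."""
    if n_tests < 1:
        raise ValueError("need at least one test in the family")
    raw = Decimal(str(family_alpha)) / Decimal(n_tests)
    return float(raw.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with per-stage seeds."""

    output_dir: str = "tractprof_run"
    stages: tuple = STAGES
    # phantom
    grid_shape: tuple = (10, 10, 40)
    voxel_size: float = simulate.DEFAULT_VOXEL_MM
    bundle_radius: float = 5.0
    noise_model: str = "none"
    noise_sd: float = 0.0
    phantom_seed: int = 11
    # tensor fit
    fit_method: str = "wls"
    # motion
    n_motion_subjects: int = 4
    motion_seed: int = 12
    # tracking / cleaning
    tracking: TrackingParams = field(default_factory=TrackingParams)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    roi_paths: tuple = ()
    # cohort + statistics
    cohort_seed: int = 13
    effect_nodes: tuple | None = (20, 45)
    effect_size: float = 0.06
    noise_sd_cohort: float = 0.03
    n_perm: int = 2000
    node_alpha: float = 0.05
    family_size: int = 16
    family_alpha: float = 0.05
    perm_seed: int = 14

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "tracking" in d and isinstance(d["tracking"], dict):
            d["tracking"] = TrackingParams(**d["tracking"])
        if "cleaning" in d and isinstance(d["cleaning"], dict):
            d["cleaning"] = CleaningParams(**d["cleaning"])
        for key in ("stages", "grid_shape", "effect_nodes", "roi_paths"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _demo_phantom_spec(cfg: RunConfig) -> simulate.PhantomSpec:
    nx, ny, nz = cfg.grid_shape
    vox = cfg.voxel_size
    mid = np.array([(nx - 1) / 2 * vox, (ny - 1) / 2 * vox, 0.0])
    start = mid + [0, 0, 3 * vox]
    end = mid + [0, 0, (nz - 4) * vox]
    return simulate.PhantomSpec(
        grid_shape=cfg.grid_shape,
        voxel_size=vox,
        centerline=simulate.straight_centerline(start, end),
        bundle_radius=cfg.bundle_radius,
        noise_model=cfg.noise_model,
        noise_sd=cfg.noise_sd,
        seed=cfg.phantom_seed,
    )


def _demo_rois(cfg: RunConfig, spec: simulate.PhantomSpec) -> tuple[WaypointROI, WaypointROI]:
    c = spec.centerline
    r = 3 * spec.bundle_radius
    lo1 = c[2] - [r, r, spec.voxel_size]
    hi1 = c[2] + [r, r, spec.voxel_size]
    lo2 = c[-3] - [r, r, spec.voxel_size]
    hi2 = c[-3] + [r, r, spec.voxel_size]
    return (
        WaypointROI(name="demo-roi1", box=(lo1, hi1), order=1),
        WaypointROI(name="demo-roi2", box=(lo2, hi2), order=2),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and write a manifest.

    Stage failures abort the run with the stage name in the raised error.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    stage_log: list[dict] = []
    state: dict = {}

    for roi_path in config.roi_paths:
        if not Path(roi_path).exists():
            raise FileNotFoundError(f"stage extract: ROI file not found: {roi_path}")

    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        log.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        stage_log.append({"stage": stage, "seconds": round(time.time() - t0, 3)})
        log.info("stage %s: done", stage)

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "version": _version(),
        "started": started,
        "finished": time.time(),
        "stages": stage_log,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _version() -> str:
    from tractprof import __version__

    return __version__


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> None:
    spec = _demo_phantom_spec(cfg)
    phantom = simulate.make_bundle_phantom(spec)
    phantom.dwi.save(out / "dwi.nii.gz")
    phantom.grads.save(out / "dwi.bval", out / "dwi.bvec")
    state["phantom"] = phantom

    cohort = simulate.make_profile_cohort(
        simulate.CohortSpec(
            effect_nodes=cfg.effect_nodes,
            effect_size=cfg.effect_size,
            noise_sd=cfg.noise_sd_cohort,
            seed=cfg.cohort_seed,
        )
    )
    np.savetxt(out / "cohort_fa.tsv", cohort.fa, delimiter="\t")
    cohort.covariates.to_csv(out / "cohort_covariates.tsv", sep="\t", index=False)
    cohort.behavior.to_csv(out / "cohort_behavior.tsv", sep="\t", index=False)
    state["cohort"] = cohort

    traces = {
        f"sub-{i:02d}": simulate.make_motion_trace(
            phantom.grads.n_volumes, amplitude=0.05 * (i + 1), seed=cfg.motion_seed + i
        )
        for i in range(cfg.n_motion_subjects)
    }
    for name, trace in traces.items():
        trace.save(out / f"motion_{name}.txt")
    state["motion"] = traces


def _stage_fit(cfg: RunConfig, out: Path, state: dict) -> None:
    phantom = state["phantom"]
    tensors = fit_tensor(phantom.dwi, phantom.grads, method=cfg.fit_method)
    eig = eigensystem(tensors)
    fa = fractional_anisotropy(eig)
    tensors.save(out / "tensors.nii.gz")
    fa.save(out / "fa.nii.gz")
    state["tensors"], state["fa"] = tensors, fa


def _stage_qc(cfg: RunConfig, out: Path, state: dict) -> None:
    qc_report(state["motion"], voxel_size=cfg.voxel_size, path=out / "motion_qc.tsv")


def _stage_track(cfg: RunConfig, out: Path, state: dict) -> None:
    streamlines = whole_brain_tracking(state["tensors"], state["fa"], cfg.tracking)
    save_streamlines(
        streamlines, out / "streamlines.tck", affine=state["fa"].affine, params=cfg.tracking
    )
    state["streamlines"] = streamlines


def _stage_extract(cfg: RunConfig, out: Path, state: dict) -> None:
    roi1, roi2 = _demo_rois(cfg, state["phantom"].spec)
    group = segment_by_waypoints(state["streamlines"], roi1, roi2, name="demo-bundle")
    cleaned = clean_fibers(group, cfg.cleaning)
    profile = tract_profile(cleaned, state["fa"], subject="phantom")
    if profile is not None:
        np.savetxt(out / "phantom_profile.tsv", profile.values[None], delimiter="\t")
    state["profile"] = profile


def _stage_stats(cfg: RunConfig, out: Path, state: dict) -> None:
    cohort = state["cohort"]
    terms = rm_ancova(cohort)
    table = term_table(terms)
    table["bonferroni_threshold"] = bonferroni_threshold(cfg.family_alpha, cfg.family_size)
    table["significant"] = table["p"] < table["bonferroni_threshold"]
    table.to_csv(out / "ancova_terms.tsv", sep="\t", index=False)

    clusters = permutation_cluster_test(
        cohort, n_perm=cfg.n_perm, node_alpha=cfg.node_alpha, seed=cfg.perm_seed
    )
    import pandas as pd

    pd.DataFrame(
        [
            {
                "direction": c.direction,
                "start": c.start,
                "end": c.end,
                "size": c.size,
                "p": c.p,
                "significant": c.significant,
            }
            for c in clusters
        ]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    covs = ("age", "group", "digit_span")
    corr = nodewise_correlation(cohort, "word_reading_accuracy", covariates=covs)
    corr.to_csv(out / "correlations_nodes.tsv", sep="\t", index=False)
    cc = summarize_correlation_clusters(
        corr["r"].to_numpy(), corr["p_fdr"].to_numpy(), covariates=covs
    )
    pd.DataFrame(
        [
            {
                "start": c.start,
                "end": c.end,
                "r_avg": c.r_avg,
                "p_fdr_avg": c.p_fdr_avg,
                "covariates": ",".join(c.covariates),
            }
            for c in cc
        ]
    ).to_csv(out / "correlations_clusters.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "qc": _stage_qc,
    "track": _stage_track,
    "extract": _stage_extract,
    "stats": _stage_stats,
}
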