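# tractprof

Tract-profile analysis of white-matter fractional anisotropy (FA) for
two-group diffusion-MRI studies — for example, comparing dyslexic and
typically reading children along 16 major tracts. The package implements a
complete desk-scale pipeline on synthetic inputs with known ground truth:

1. **Simulation** (`tractprof.simulate`) — DWI bundle phantoms from the
   single-tensor signal equation *S = S₀·exp(−b·gᵀDg)*, two-group 100-node
   FA profile cohorts, behavioral score tables, and rigid-motion traces.
2. **Tensor fitting** (`tractprof.tensor`) — OLS / WLS / robust (IRLS with
   Geman–McClure weights) log-linear tensor fits, eigendecomposition, and

   FA = √(1/2) · √((λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²) / √(λ₁² + λ₂² + λ₃²).

3. **Motion QC** (`tractprof.motion`) — RMS absolute displacement
   RMS_abs = √(Σₙ(xₙ²+yₙ²+zₙ²+αₙ²+βₙ²+γₙ²)/N) with rotations converted to
   mm on a 50 mm sphere, and the half-voxel exclusion rule.
4. **Tractography** (`tractprof.tracking`) — deterministic streamline
   tracking (STT): FA > 0.3 seed mask, 8 seeds/voxel, bidirectional RK4 at
   1 mm steps, stopping at FA < 0.2 or turning angle > 30°, minimum length
   20 mm.
5. **Tract model** (`tractprof.tracts`) — waypoint-ROI segmentation,
   iterative outlier cleaning (length > mean + 4 SD; mean per-node
   Mahalanobis core distance > 5), arc-length resampling to 100 nodes, and
   Gaussian-weighted node-wise FA profiles.
6. **Statistics** (`tractprof.stats`) — per tract: (a) repeated-measures
   ANCOVA of the subjects × 100-node profile matrix (Nodes within; Group
   between; Age and Protocol covariates plus Group×Age and Group×Protocol),
   sphericity-assumed F with df (99, 99·(N−p)) and partial η²; (b) node-wise
   unpaired t tests corrected by the permutation null of the maximum
   same-direction run of suprathreshold nodes (directional, 10 000 label
   shuffles); (c) node-wise (partial) correlations with behavioral scores,
   BH-FDR per tract per measure, summarized per contiguous cluster (r_avg,
   p_fdr_avg). A summary-statistic two-group ANOVA (F, η²p from group
   means/SDs) covers published behavioral tables.

`tractprof.pipeline` orchestrates phantom-to-results runs with a config,
per-stage seeds, and a hash manifest; the `tractprof` CLI exposes
`simulate`, `fit`, `qc`, `track`, `extract`, `stats`, and `run-all`.

## Worked example

Simulate a 13 + 15 cohort with a planted FA offset of 0.06 on nodes 20–45
(within-subject node noise SD 0.03) and run the statistics stack:

```python
import tractprof as tp
from tractprof.simulate import CohortSpec, make_profile_cohort

ds = make_profile_cohort(CohortSpec(effect_nodes=(20, 45), effect_size=0.06,
                                    noise_sd=0.03, seed=7))

res = {r.term: r for r in tp.rm_ancova(ds)}
r = res["Nodes:Group"]
print(f"Nodes:Group  F({r.df1},{r.df2}) = {r.F:.2f}, p = {r.p:.2e}, "
      f"eta_p2 = {r.eta_p2:.3f}")
print("Bonferroni threshold (16 tracts):", tp.bonferroni_threshold(0.05, 16))

for c in tp.permutation_cluster_test(ds, n_perm=10_000, seed=1):
    if c.significant:
        who = "dyslexic > typical" if c.direction == -1 else "typical > dyslexic"
        print(f"cluster nodes {c.start}-{c.end} ({who}), p_cluster = {c.p:.4f}")
```

prints

```
Nodes:Group  F(99,2178) = 7.09, p = 1.10e-76, eta_p2 = 0.244
Bonferroni threshold (16 tracts): 0.0031
cluster nodes 20-45 (dyslexic > typical), p_cluster = 0.0042
```

The ANCOVA flags the tract-level Group×Nodes interaction well below the
16-tract Bonferroni threshold, and the cluster permutation test localizes
the group difference to exactly the planted node range: dyslexic-coded
subjects show higher FA over nodes 20–45, with a family-wise-corrected
cluster p of 0.0042.

An end-to-end phantom run (`tractprof run-all --output-dir demo/`) writes
the DWI volume and gradient tables, FA maps, streamlines (TCK), the
phantom's 100-node profile, QC and statistics tables, and a `manifest.json`
with SHA-256 hashes of every output.

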