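# Methods

## Scope and data model

`tractprof` analyzes fractional anisotropy (FA) along white-matter tracts in
a two-group cohort. Real studies of this design acquire single-shell DWI
(here emulated at b = 1000 s/mm², 72 directions, 1.8 mm isotropic voxels),
fit diffusion tensors, track fibers deterministically, extract named tracts
with waypoint ROIs, reduce each tract to a 100-node FA profile per subject,
and compare profiles between groups. No subject-level MRI from any real
cohort ships with the package; every input is produced by the simulation
module with known ground truth, so each stage can be verified against
construction.

## Simulation

**Bundle phantoms.** A phantom is a curved anisotropic bundle in an
isotropic background. Voxels within `bundle_radius` of the centerline carry
a prolate tensor whose principal axis follows the local centerline tangent
(default eigenvalues (1.7, 0.2, 0.2)·10⁻³ mm²/s, FA ≈ 0.87); background
voxels are isotropic (0.8·10⁻³ mm²/s, FA = 0). The DWI signal is the exact
single-tensor forward model S = S₀·exp(−b·gᵀDg), so a noiseless phantom is
exactly consistent with its ground-truth tensors and the log-linear fit
recovers them to machine precision. Optional Gaussian or Rician noise can
be added on the signal; Rician is offered because magnitude MRI noise is
Rician, and the Gaussian option lets tests isolate fit bias from noise-floor
bias. Gradient directions are a spherical Fibonacci set (deterministic,
well-conditioned).

**Profile cohorts.** A cohort is N₁ + N₂ subjects × 100 nodes (defaults
13 + 15, matching the emulated study). Each subject's profile is a smooth
baseline (FA ≈ 0.40 at the tract ends, ≈ 0.55 mid-tract) plus an additive
group effect on a contiguous node range, a linear age effect (default
0.0005 FA/month over an age range of 97–135 months, i.e. roughly ages
8–11), a protocol offset (0.01) for the second acquisition protocol, and
zero-mean Gaussian-process node noise with squared-exponential correlation
(default length 5 nodes, SD 0.03), clipped to [0, 1]. Spatially correlated
noise is essential: cluster-size statistics are only meaningful when
adjacent nodes co-vary, as they do in real tract profiles. Protocol is
assigned balanced within group; age is uniform.

**Behavior tables.** Scores are drawn per group from per-measure means/SDs
typical of 8–11-year-old typical vs. dyslexic readers (reading accuracy and
fluency, spelling, phoneme deletion, rapid naming, WISC digit span, ...).
Digit span and phoneme-deletion RT are drawn with correlation −0.4,
mirroring the verbal short-term-memory / phonological-processing
association observed in such samples; other inter-measure correlations are
configurable but default to zero, since published tables rarely report
them.

**What the generator does not emulate:** eddy-current or susceptibility
distortion, partial-volume mixtures and crossing fibers, spatially varying
noise, site/scanner drift, or realistic tract geometry beyond a single
parametric bundle. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not robustness to all properties of
in-vivo data.

## Tensor fitting and FA

The log-signal design has columns (ln S₀, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
Three estimators are provided: OLS; WLS with weights equal to the squared
predicted signal (the standard variance stabilization after the log
transform); and a robust mode — WLS combined with Geman–McClure weights
w = 1/(1 + (r/σ)²)² on log-residuals, σ = 1.4826·MAD per voxel, iterated to
convergence (tolerance 10⁻⁶, at most 20 iterations). The robust mode serves
the same purpose as outlier-rejecting estimators used in practice (reject
corrupted volumes per voxel); it is deliberately simpler than
signal-domain algorithms with explicit noise-floor estimation and
re-inclusion passes, which are out of scope. On a voxel with one volume
corrupted ×10, its error against ground truth is < 10⁻¹ of the OLS error.

Eigenvalues are sorted descending; negative eigenvalues are *retained* in
the stored eigensystem (they are diagnostic of fit pathologies) and flagged,
but clamped to zero only inside the FA evaluation, which keeps FA in [0, 1].
All-zero voxels get FA = 0 rather than NaN so background masks behave
uniformly downstream.

## Motion QC

RMS_abs = √(Σₙ(xₙ² + yₙ² + zₙ² + αₙ² + βₙ² + γₙ²)/N) over all N volumes
relative to volume 1 (the zero first row is included in the average, since
the formula divides by the full volume count). Rotations are converted to
mm *before* squaring — the only reading under which the sum is
dimensionally consistent — as arc length on a 50 mm-radius sphere
(radius × radians), a standard proxy for cortical-surface displacement. A
subject is excluded when RMS_abs strictly exceeds half the voxel size
(0.9 mm at 1.8 mm voxels). Visual spike inspection is replaced by an
optional reproducible surrogate: a per-volume displacement threshold.

## Tractography

Seeding places 8 seeds per voxel with FA > 0.3, on the 2×2×2 sub-grid at
±0.25-voxel offsets — the count is standard, the regular placement keeps
the algorithm fully deterministic. Integration is bidirectional
fourth-order Runge–Kutta with 1 mm steps along the principal eigenvector
field. At every evaluation point the six tensor components are trilinearly
interpolated and then eigendecomposed (interpolating eigenvectors directly
is sign-ambiguous), and the eigenvector sign is chosen coherent with the
previous direction of travel. A track terminates when interpolated FA at
the new position falls below 0.2, when the turning angle between two
consecutive 1 mm segments exceeds 30°, or when it leaves the volume;
tracks shorter than 20 mm are discarded. Voxels between the stop and seed
FA thresholds can be traversed — only seeding is restricted to FA > 0.3.

Two numerical consequences matter for validation geometry. First, trilinear
FA ramps over one voxel past the last bundle voxel before crossing the stop
threshold, and step quantization adds up to one step per side, so retained
lengths on a straight tube sit within ±2 mm of the bundle's axial extent.
Second, interpolation smears an orientation discontinuity over roughly one
voxel; a 60° bend is therefore only guaranteed to trip the 30°-per-segment
rule when the transition is shorter than the 1 mm step, which the bend
phantom achieves with a 0.8 mm grid. On coarser grids a sharp bend can be
rounded at ≤ 30° per segment — a genuine property of angle-thresholded
streamline tracking, not an implementation artifact.

## Tract extraction and profiles

A streamline joins a tract when it passes through both waypoint ROIs
(masks or mm boxes), tested on the streamline densified at 0.2 mm so the
result is robust to step size; passage order is not enforced during
selection, but members are oriented so the ROI-1 passage comes first,
fixing the anatomical end that carries node 1. Cleaning iterates to a fixed
point: fibers longer than mean + 4 SD of bundle lengths are dropped, then
fibers whose mean per-node Mahalanobis distance from the bundle core (the
pointwise mean of 100-node-resampled fibers, with per-node 3×3 spatial
covariance) exceeds 5. Mahalanobis distances are already in SD units, so
"five standard deviations from the core" is the direct threshold; the
per-node covariance is ridge-regularized (10⁻⁸ of its mean diagonal) so
coincident bundles give zero distance instead of 0/0. Mean-per-fiber
distance (rather than max-per-node) is used, which is less sensitive to a
single noisy node. Cleaning stops with a warning rather than emptying a
bundle below 3 fibers.

Resampling passes a cubic spline (lower order for very short fibers)
through the points, re-parameterizes by arc length via dense sampling
(20× oversampling), and evaluates 100 equally spaced arc-length fractions
with endpoints preserved. The profile value at node k is the Gaussian
core-distance-weighted mean of trilinearly sampled FA over fibers,
wᵢ = exp(−d²ᵢₖ/2) with d in Mahalanobis units (σ = 1; configurable in
principle, but the unit kernel is the conventional choice). The weighted
mean is convex, so every node value lies within the range of the sampled
FA values.

Manual post-hoc fiber inspection and probabilistic-atlas refinement, used
in practice after waypoint segmentation, are not reproducible operations
and are replaced by the deterministic cleaning pass; ROIs are supplied as
explicit masks/boxes rather than derived from an atlas.

## Statistics

**Repeated-measures ANCOVA.** Per tract, the N × 100 profile matrix is
modeled on a 6-column between-subject design: intercept, Group, Age,
Protocol, Group×Age, Group×Protocol, under sum-to-zero coding with centered
age (so main effects remain interpretable next to the interactions), Type
III sums of squares. Within-subject terms (Nodes and Nodes×term) use the
univariate sphericity-assumed statistic on an orthonormal (J−1)-column node
contrast: F = [tr(H)/(df·(J−1))] / [tr(E)/((N−p)(J−1))], giving
df = (99, 99·(N−p)) — (99, 2178) at N = 28 and (99, 2079) at N = 27, the
df structure used when a tract is untracked in one subject (such subjects
are dropped per tract, never imputed). No Greenhouse–Geisser or
Huynh–Feldt correction is applied, consistent with uncorrected df
reporting; the type-I simulation shows the consequence: with white node
noise the Nodes×Group test rejects at 0.053 (α = 0.05, 1000 simulations),
while under the generator's default smooth noise it is liberal (≈ 0.20) —
precisely why the tract-level family threshold and the cluster permutation
layer matter. Partial η² = tr(H)/(tr(H)+tr(E)). Between-subject terms are
tested on node means with df (1, N−p). Tract-level significance is judged
against the Bonferroni family threshold α/16 = 0.0031 (rounded half-up to
4 decimals from 0.003125).

**Summary-statistic ANOVA.** For published behavioral tables,
F = (m₁−m₂)²/(s²(1/n₁+1/n₂)) with the pooled variance, η²p = F/(F+n₁+n₂−2)
— identical to the squared pooled two-sample t. With 13 + 15 subjects this
uses error df 26.

**Cluster permutation.** Follow-up node-wise unpaired pooled-t tests (no
covariates) feed a directional max-cluster-size permutation test: observed
clusters are maximal runs of adjacent nodes with one-tailed p < 0.05 in the
same direction (the node-forming threshold is configurable; directionality
restricts inference to biologically plausible same-direction runs). For
each direction the null is the distribution of the maximum same-direction
run length over group-label shuffles (default 10 000; labels only are
shuffled, covariates stay with the subject), and cluster
p = (1 + #{perm max ≥ observed})/(1 + n_perm) — never exactly zero. When
fewer distinct labelings exist than requested shuffles the test enumerates
all of them exactly and warns. Calibration: over 500 null cohorts with
smooth noise, the per-direction probability of any flagged cluster is
0.038 / 0.050; a planted 0.06-FA effect on nodes 20–45 (noise SD 0.03) is
recovered with ≥ 80% node overlap in 100/100 simulated cohorts.

**Correlations.** Node-wise association between FA and a behavioral
measure: both are residualized on the covariates (plus intercept), Pearson
correlation on residuals, p from t with df = N−2−k; an empty covariate list
gives the plain Pearson correlation (used for age). BH-FDR is applied
across the 100 nodes per tract per measure, and contiguous runs of
significant nodes are summarized by their node range, mean r, and mean
adjusted p. The implementation matches the inverse-correlation-matrix
identity and `pingouin.partial_corr` to 10⁻¹⁰.

## Problem sizes and determinism

Test and demonstration runs use desk-scale problems chosen to exercise
every code path: phantoms of ~10⁴ voxels with a few hundred to a few
thousand streamlines, cohorts of 28 subjects × 100 nodes, 2000 permutations
for calibration sweeps (10 000 in single-dataset analyses), 500 null and
100 planted-effect simulations. Every stochastic component takes an
explicit seed (generators, permutation tests, pipeline stages each have
their own), and tractography is deterministic by construction, so full runs
reproduce bit-identical artifacts — the run manifest records SHA-256 hashes
to make this checkable.

## Known limitations

- Single-tensor model only: no crossing fibers, no multi-shell models.
- The robust fit approximates, rather than reimplements, signal-domain
  outlier rejection with noise-floor handling.
- The sphericity-assumed ANCOVA F is liberal under correlated node noise
  (see above); interpret tract-level p-values jointly with the cluster
  permutation layer.
- Waypoint segmentation without atlas refinement can admit fibers a
  probabilistic atlas would reject.
- Angle-based termination cannot detect bends smeared below the per-step
  threshold by interpolation on coarse grids.
- No image registration anywhere: motion QC consumes given rigid
  parameters; it does not estimate them.
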