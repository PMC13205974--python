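# Methods

This note documents the models, parameter choices and known limitations of
`patellakin`, in the order the pipeline runs.

## Synthetic 4D knee-motion generator

The generator stands in for a dynamic-CT acquisition and segmentation chain:
it produces, per subject, an ordered sequence of patellar surface point
clouds moved rigidly along a phenotype-specific 6-DOF trajectory, with the
generating poses retained as ground truth.

**Patellar geometry.**  A radially perturbed ellipsoid with a flattened
posterior facet and a shallow median-ridge crease, rescaled so the extents
along its first two principal axes equal the subject's transverse and
oblique diameters (drawn per subject around population means of 44.99 and
40.62 mm, SD 3.07 / 4.03 mm).  The azimuthal asymmetry is not cosmetic:
near-ellipsoids of revolution leave rotations about the facet normal
unobservable to point-to-plane matching, and the estimator wobbled by up to
10° before the ridge and apex terms were added.

**Trajectory model.**  Per frame at normalized cycle time t ∈ [0, 1]:

- Tz (proximal–distal) rises to a single interior maximum — a squared-sine
  bump whose peak location is jittered in [0.42, 0.58] by a power warp — and
  returns to zero.  Its depth is drawn per subject at the group values
  (46.97 ± 13.13 / 51.09 ± 17.19 / 48.46 ± 14.67 mm for Types 1–3).
- Tx (lateral) follows the phenotype's profile family (below).
- Ty is a sine arc with group-level amplitude (25.77 / 27.22 / 15.57 mm,
  relative SD 0.30 — the group tables publish no dispersion for this DOF).
- Rotations are smooth low-amplitude oscillations (default scale 10°,
  relative SD 0.30): Rx ∝ sin 2πt, Ry ∝ sin πt, Rz ∝ sin²πt.  The published
  rotation summaries (peaks near 180–330°) imply an angle-accumulation
  convention that is never defined; this package reports conventional
  intrinsic X-Y′-Z″ Euler angles and makes no attempt to match those
  magnitudes, so the generator's rotations are deliberate small-amplitude
  stand-ins.

**Lateral profile families.**  The three phenotype profiles are spanned by
two monotone-cubic basis waveforms — a broad mid-cycle *arc* and a sharp
terminal-extension *hook*:

- S-sign (Type 1): arc + 0.55·hook, fully scaled by the drawn peak — an
  exaggerated lateral excursion elevated through the whole cycle.
- J-sign (Type 2): a **fixed 6.5 mm in-groove arc** plus a peak-scaled hook —
  knees that track the groove at a common moderate offset and differ mainly
  in the terminal hook, the classic J-sign.
- C-sign (Type 3): the pure shallow arc, scaled by the drawn peak.

Two modelling decisions here matter for anyone reusing the generator.
First, the profiles deliberately span a two-dimensional waveform space: the
downstream PCA keeps only the ≥ 95%-variance subspace, and families spanning
a higher-dimensional space lose their distinguishing directions under that
projection.  Second, the J-sign's in-groove arc is amplitude-independent.
If every family were a single curve multiplied by its amplitude, all
subjects would lie on rays through the feature-space origin and K-means
would repartition the resulting amplitude continuum at its own equilibrium
quantile regardless of the generating groups — reproducibly yielding a
~40%/50% split instead of the generating 56%/36%.  Real trajectory clusters
are not rays: a cluster found by K-means is, by construction, a compact
region.  The fixed-arc-plus-scaled-hook structure reproduces that
compactness honestly.  A smooth per-subject waveform deviation (relative
SD 0.10, cubic through seven nodes) adds individual variability; each curve
is rescaled so its sampled cycle maximum equals the drawn peak exactly.

**Amplitude calibration.**  Published group parameters (35.11 ± 6.56,
15.67 ± 6.59, 2.82 ± 2.41 mm) are descriptive statistics of
*cluster-assigned* groups, which occupy bands of the lateral-amplitude axis.
Each phenotype's peak is therefore drawn from a truncated normal supported
on its band (lower edges 24 / 7 / 0 mm — the midlines between adjacent
groups' reported distributions) whose parent mean and SD are solved
numerically so the *truncated* moments equal the reported values.  Naive
truncation at zero would inflate the Type 3 mean from 2.82 to ≈ 3.37 mm and
drop the Type 1 / Type 3 ratio below the published ≈ 12-fold.

**Noise and laterality.**  Isotropic Gaussian perturbation per point,
default SD 0.3 mm — just under the 0.5 mm voxel scale of the emulated
acquisition, a plausible segmentation jitter.  A configurable fraction of
knees (default 30/64) is generated left-sided: the geometry is reflected in
the sagittal plane and the trajectory conjugated by the same reflection,
which is exactly the 6-DOF mirror map [−Tx, Ty, Tz, Rx, −Ry, −Rz].

**What the generator does not emulate.**  CT physics, motion artifacts,
segmentation topology errors, femoral trochlea geometry, cartilage, frame-
to-frame resampling of the surface (the same points move rigidly, so
correspondence is unrealistically clean at zero noise), and any coupling
between rotations and lateral translation.  Passing tests therefore show
that the *analysis chain* is correct and calibrated on data with the
published amplitude structure — not that it would segment or track real CT.

## Pose reconstruction

Frames are first centered at the frame-0 centroid; the patella sits far from
the scanner origin and the lever arm of that offset otherwise dominates the
rotation block of the normal equations.

Pose estimation is sequential with template anchoring: frame k is
warm-started at the frame k−1 pose and refined by alternating
nearest-neighbour correspondence assignment (cKDTree) with damped
Gauss-Newton steps on the se(3) twist, minimizing Huber-robust
point-to-surface residuals against the previous frame (odometry) and, with
weight λ = 1, against the frame-0 template — the template term bounds drift
accumulation over the cycle.  "Point-to-surface" is realized as
point-to-plane residuals with target normals from 10-nearest-neighbour PCA,
falling back to point-to-point where the local neighbourhood is too
anisotropic (smallest-to-middle eigenvalue ratio above 0.5).  The joint
pose-graph alternative is not implemented; sequential estimation with the
template anchor met all recovery targets (max error < 1e-3 mm noiseless,
translation RMSE < 0.15 mm at 0.3 mm noise, < 0.5 mm with 10% gross
outliers).

Numerical choices: Huber corner δ = 1.0 mm (≈ 2× the per-point noise); LM
damping starts at 1e-3, halves on accepted steps, quadruples on rejected
ones; convergence when the twist update norm falls below 1e-7 or after 40
iterations (non-convergence is flagged, not fatal); correspondence ties
break toward the lowest target index; the exponential/log maps use
closed-form Rodrigues formulas with second-order Taylor guards below 1e-10
and refuse rotation angles within 1e-6 of π.

Quality control excludes a sequence when any frame's translation norm
exceeds τ_t or its goodness of fit ε (inlier fraction at δ) falls below
τ_f = 0.5.  τ_t defaults to 150 mm: combined proximal–distal and
anterior–posterior excursion at deep flexion legitimately reaches ~100 mm at
the published group amplitudes, so the gate is set above the physiologic
ceiling and catches only runaway estimates.  Both thresholds are
configurable and every exclusion is reported with its rule.

The anatomical decomposition reports translations along, and intrinsic
X-Y′-Z″ Euler angles (degrees) about, the femoral axes (X medial→lateral
through the condyles, Z distal→proximal along the shaft orthogonalized
against X, Y = Z × X).  The Euler convention is stated prominently because
several circulate in joint kinematics; near gimbal lock (|Ry| ≈ 90°) the
decomposition is flagged and Rx is absorbed into Rz.

## Standardization

Order of operations: mirror → peak detection → biphasic resampling → SG
smoothing → features.  The peak-flexion index is the first argmax of Tz and
must be interior (frames 0 and N−1 are rejected as malformed cycles — a
monitored acquisition implies an interior peak).  Each phase is linearly
interpolated onto 25 uniformly spaced frame-index values including both
endpoints; the junction therefore equals the raw peak-flexion sample
exactly, and linear interpolation cannot overshoot the raw range.  Frame
index, not flexion angle, is the interpolation parameter — flexion angle is
never computed in this pipeline.

Smoothing is a second-order, 7-point Savitzky–Golay filter applied per DOF
*within each phase* (filtering across the junction would blur the
flexion/extension hysteresis corner), with polynomial edge handling so
quadratics pass unchanged.  The filter is extremum-preserving: the
pre-filter extremum samples of each DOF in each phase are restored
afterwards.  Without this, the quadratic kernel attenuates the narrow
J-sign hook by ~3 mm — precisely the geometric feature the smoothing step
must not destroy — and the Table-style peak summaries inherit the bias.

Summaries report, per DOF, the peak (series maximum) and total range
(max − min); maximum lateral displacement, lateral range of motion and
maximum longitudinal displacement are the named clinical aliases.  The
clustering feature vector is the standardized, smoothed Tx series only
(50 values); the other DOFs are standardized for the Table-style statistics.

## Phenotyping

PCA uses centering without per-feature scaling (all 50 features share mm
units); the retained dimension is the smallest reaching 95% cumulative
explained variance.  K-means uses k-means++ with 50 restarts under a fixed
seed; empty clusters are handled by the library's internal relocation.

Cluster-count selection operationalizes "joint elbow/silhouette evaluation"
as follows: the elbow candidate maximizes the second difference of inertia
over K = 2…6; when that curvature clearly dominates every other candidate
(factor ≥ 2) the elbow K is chosen outright, and only ambiguous inflections
are arbitrated by the silhouette among the candidate and its neighbours.
The rationale: with a small extreme phenotype and a broad continuum —
exactly the structure of this cohort — the silhouette at K = 2 (~0.8) always
beats K = 3 (~0.6) no matter how real the finer structure is, so a
silhouette-argmax rule can never select three clusters on such data, while
the inertia curvature identifies K = 3 unambiguously (second difference
≈ 5× the runner-up on the default cohort).

Cluster labels are reordered by the order parameter γ_j, the within-cluster
mean of per-subject maximum lateral displacement, descending — Type 1 is
always the most laterally displaced phenotype.  Ties beyond 1e-9 keep the
original order and emit a warning.  Validity indices (silhouette,
Davies–Bouldin, Calinski–Harabasz) are computed in the latent space with
Euclidean distances.

## Group statistics

Normality is recorded per group with Shapiro–Wilk; the comparison framework
is rank-based throughout.  Kruskal–Wallis provides the omnibus test;
pairwise contrasts use the Brunner–Munzel test (robust to unequal n and
heteroscedasticity), with Benjamini–Hochberg adjustment applied within each
variable's family of three pairwise p values (a global family option exists
but is off by default).  When a rank-variance estimate is zero — constant
samples or complete separation — the t approximation is undefined and a
permutation p value on the relative effect is substituted: full enumeration
up to 2·10⁵ arrangements, otherwise 10⁴ seeded Monte-Carlo resamples.  The
rank-biserial correlation is 2·P̂(x<y) − 1 with ties counted one half, so a
stochastically larger first group yields a negative value.  Group summaries
report mean, SD, median and IQR (Q3 − Q1, linear-interpolation quantiles).
Significance tiers on adjusted p: *** < 0.001, ** < 0.01, * < 0.05.

The sensitivity battery reruns one contrast under eight tests; the
Anderson–Darling entry is the k-sample statistic with a seeded permutation
p value (1999 resamples), since the asymptotic p is tabulated only on a
coarse grid.  The verdict is "consistent-significant" only when all eight
p values fall below 0.05.

Measured calibration: Brunner–Munzel type-I error at α = 0.05 is within
[0.04, 0.06] under equal-variance nulls (n = 20/30) and within [0.03, 0.07]
under a 3-fold variance ratio with n = 10/40 (10 000 replicates each).  At
very small samples (n ≤ 8) the Satterthwaite t approximation deviates from
the exact permutation law by up to ~0.04 — a known property of the
approximation, documented in the tests.

## Problem sizes and determinism

The default study cohort is 64 knees (5/36/23), 20–30 frames per cycle,
500 points per cloud (300 in the end-to-end test and acceptance runs —
recovery error at 300 points is ~0.1 mm, an order of magnitude below the
smallest group separation).  Everything is a pure function of its
configuration and seed; per-subject seeds are spawned from the cohort seed,
and permutation fallbacks take explicit seeds.

## Known limitations

- The generator's rotations and Ty profile are weakly constrained by the
  published summaries; their dispersions are package choices.
- The originally reported cluster-validity indices of the original cohort (silhouette
  0.381 etc.) cannot be reproduced without the patient data and are not
  targeted; the synthetic cohort is cleaner than real kinematics, so its
  indices are better.
- Sequential pose estimation has no global refinement; with the template
  term disabled (λ = 0) drift over a cycle is unbounded.
- One motion cycle per subject; no multi-cycle averaging.
- The K-selection dominance factor (2.0) is a heuristic for "clear
  inflection"; cohorts with genuinely ambiguous structure fall back to the
  silhouette arbiter.
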