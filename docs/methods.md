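# Methods

This note describes the models and procedures implemented in `tractokit`,
the choices made where the design was genuinely open, and what the
synthetic phantoms do and do not establish about behavior on real data.

## Coordinate conventions

All geometry is expressed in world millimeters, RAS (+x right, +y
anterior, +z superior). Affines map 0-based integer voxel indices to the
world coordinates of voxel centers (the NIfTI convention). The
inter-hemispheric midline is the plane x = 0 of world space. A point is
"inside" an ROI iff its nearest integer voxel index — rounding halves
away from zero per axis after inverse-affine mapping — is a mask voxel;
this is deterministic at voxel boundaries. Degenerate streamlines (fewer
than two points, or zero length) are filtered at load time with a logged
count rather than silently dropped or passed through.

## Streamline geometry

Arc-length resampling is linear interpolation on the polyline: the n
output points sit at arc positions i·L/(n−1) along the input curve, with
the endpoints preserved exactly. No spline smoothing is applied, so the
operation is exactly checkable against a dense-interpolation oracle.
The default is 100 nodes everywhere a node count appears.

The minimum-direct-flip (MDF) distance between two streamlines is the
mean pointwise distance after resampling both to a common node count,
minimized over reversing one of them. It is symmetric, non-negative,
flip-invariant, and zero iff the resampled point sets coincide up to a
flip.

Per-axis movement fractions are computed from summed per-segment absolute
displacements (not endpoint-to-endpoint displacement): for axis a,
fraction_a = Σᵢ|Δ_{a,i}| / Σ_a Σᵢ|Δ_{a,i}|. The per-segment definition was
chosen because it penalizes meandering trajectories, which is the point
of a primary-axis criterion; it is the stricter of the two readings.

Touching the midline (x exactly 0) does not count as crossing; a crossing
requires strictly negative and strictly positive x values.

## Bundle recognition

A bundle definition set is an ordered mapping from tract name to a
criteria record in which every criterion is optional. Configured criteria
are applied in a fixed order: prob_map, cross_midline, start, end,
length, primary_axis, include, exclude, shape prior, then the two
set-level cleaners (QuickBundles threshold, Mahalanobis). A streamline
rejected by an earlier criterion is tallied under that criterion only,
which makes the per-tract rejection tallies an audit trail of the
pipeline order. A streamline that survives for several tracts is assigned
to the first tract in the mapping, with a recorded warning naming both.

Open points resolved here:

* **prob_map statistic.** The criterion accepts a streamline iff the
  *mean* trilinearly-sampled probability along the 100-node resampled
  streamline is strictly greater than the threshold (default 0). The
  mean was chosen over the minimum or any-node statistics because a
  single low-probability node (e.g. grazing the map edge) should not
  veto an otherwise well-supported trajectory.
* **Endpoint tolerance.** Start/end ROIs use nearest-voxel membership
  with no tolerance; only inclusion/exclusion ROIs carry millimeter
  tolerances. If a streamline satisfies the start/end pair only after
  reversal, it is flipped and accepted, so recognized bundles come out
  oriented from start to end.
* **cross_midline** is tri-state: required, prohibited, or unconstrained.

The shape prior is a reduced criterion: min MDF (20 comparison points)
to any reference streamline must fall under a centroid threshold. Full
shape-model recognition with streamline-linear registration and cluster
pruning is out of scope; ROIs must already be in subject space.

## Bundle cleaning

**Mahalanobis cleaning** iterates up to `clean_rounds` (default 5)
times. Each round, on the current survivors resampled to `n_points`
(default 100) and flip-aligned to the first streamline: streamlines are
removed whose absolute length z-score exceeds `length_threshold`
(default 4) or whose node-averaged Mahalanobis distance to the node-wise
mean exceeds `distance_threshold` (default 3). Per-node distances use
the 3×3 covariance across streamlines at that node, aggregated by the
*mean* over nodes (the mean is less brittle than the max to a single
distorted node, and matches the averaged character of the length
criterion). Iteration stops when nothing is removed, the round budget is
exhausted, or a removal would drop the bundle below `min_sl` (default
20) — in which case the round is skipped and the guard is logged. These
defaults follow established tractometry cleaning practice and are
config-overridable.

Node covariances are ridge-regularized by 1e−6·(bundle spread)²·I, where
spread² is the mean node-cloud variance (plus a 1e−12 absolute floor),
so exactly collinear phantom bundles remain invertible without
materially altering distances on realistic bundles.

**QuickBundles-threshold cleaning** scans streamlines in order,
resampled to 12 points; each joins the first cluster whose running
centroid (the mean of flip-aligned members) lies within the MDF
threshold, otherwise it opens a new cluster. The *largest* cluster is
retained (ties to the earliest created). Largest-cluster retention is the
conservative reading of a "cleaning" step; cluster assignment depends on
scan order in general, but the retained membership is order-stable for
bundles separated by more than the threshold, which is the regime the
criterion is for.

## Tract profiles

For profile extraction each streamline is resampled to `n_nodes`
(default 100), the scalar map is sampled trilinearly at each node point
(after resampling, not at original vertices), and the profile value at
node n is the weighted mean across streamlines. Weights are Gaussian in
the node-wise Mahalanobis distance, w = exp(−d²/2), normalized to sum to
one per node; the node statistics are the node-wise mean and
ridge-regularized covariance, as in cleaning. The node-wise *median*
reference streamline is used only for orientation: in median mode,
streamlines are first flip-aligned to the first streamline, the node-wise
median of that aligned set is taken as reference, and each streamline is
flipped iff flipping lowers its mean pointwise distance to it. A
single-streamline bundle bypasses weighting (weight 1 at every node)
since no covariance is estimable.

Samples falling outside the scalar grid return 0 with a logged count;
this keeps bundles grazing the field of view usable at the cost of
biasing edge nodes toward zero, which the log surfaces.

## Per-node statistics

The group model fits, at every node of one (tract, metric) pair,
ordinary least squares of the node value on an intercept, a binary group
indicator, and any further covariates (age, sex). Because the design
matrix is shared across nodes, all fits are solved in one pass of the
normal equations; the statsmodels OLS path is used as an independent
cross-check in the test suite. The reported p-value is the two-sided
t-test on the group coefficient (the group factor, not an omnibus test).
Nodes with a constant response get p = 1 with a warning. The
Benjamini–Hochberg step-up controls the FDR across the nodes of the one
(tract, metric) family being tested, mirroring an analysis of a single
tract's 100 nodes; correcting across several tracts is a matter of
concatenating the p-value families before calling `bh_fdr`.

Median imputation replaces missing values with each set's own per-feature
median — train medians never touch the test set.

## Exponential learning curve

The model is R²(x) = α − (α−β)·exp(−(x−x_min)/κ), with x the training-set
size and x_min the smallest size used. α is pinned, not fitted: by
default to the highest observed score. β (performance at x_min) and κ
(the rate, in training-sample units) are fitted by bounded nonlinear
least squares with κ starts at {x_min, 2·x_min, max(sizes)} and β
starting at the lowest score; the lowest-RSS start wins. At
x = x_min + κ the curve has closed exactly 1 − 1/e ≈ 63% of the α−β gap,
which is the operational meaning of κ.

A caveat the package documents and tests: whenever the largest size still
sits on the rising part of the curve, the observed maximum underestimates
the true asymptote, and the pinned-α fit then biases κ low (about −10%
on the canonical six-point grid with a κ of ~400). `fit_learning_curve`
therefore accepts an explicit asymptote when one is known — a generator's
true α, or a plateau established by larger runs — and the round-trip
validations use that form. This is a property of the estimator, not of
the implementation.

## Augmentation operators

Profile tensors are (samples × nodes × channels), one channel per
tract/metric pair. Each operator takes a single magnitude m scaled to the
per-channel value range:

* **jitter** adds iid Gaussian noise with SD = m · channel range;
* **scaling** multiplies each sample/channel's deviations from the
  channel mean by a factor drawn from a unit-mean normal with SD m,
  truncated at zero (so deviations never change sign);
* **time-warping** displaces 4 interior knots of the node axis by
  N(0, m), clips and sorts them into a monotone piecewise-linear warp
  with fixed endpoints, and re-interpolates each channel. First and last
  node values are preserved exactly and node order is preserved.

m = 0 is the identity for all three, and shapes are always preserved.

## Synthetic phantoms

The default phantom is a 60×60×60 grid of 2 mm voxels centered on the
world origin, holding two bundles of 60 streamlines each — a
left-hemisphere circular arc (~79 mm) and a right-hemisphere helix
(~71 mm), separated by far more than 3× their 1.5 mm transverse spread —
plus 100 smoothed-random-walk distractors. Each bundle streamline is the
curve at 100 parameters plus a per-streamline constant Normal(0, spread²)
offset in the curve's normal plane and per-point isotropic noise
(0.2 mm); about half are emitted reversed so orientation handling is
exercised everywhere.

Scalar volumes are painted by nearest-curve-parameter assignment: voxels
within a tube around the curve hold the planted profile p(t) (default
p(t) = 0.3 + 0.2·sin(πt), an FA-like hump), background 0.1 elsewhere.
The painted tube radius is 2×spread *plus the trilinear support radius*
(√3 × voxel size): the extra margin guarantees that every sample point
inside the nominal 2-spread tube interpolates painted voxels only, so
the planted profile is the literal ground truth for profile recovery
rather than a background-blended approximation.

Waypoint ROIs are spheres at t = 0.25 and 0.75 of each curve (radius
2×spread + one voxel), endpoint ROIs at t = 0 and 1. The emitted bundle
definitions derive the endpoint-mask radius and the waypoint inclusion
tolerance from the generated streamlines themselves (the maximum needed
distance plus a margin), so recognition of the phantom's own bundles is
exact by construction for any seed — the phantom tests recognition
logic, not the tail probabilities of Gaussian offsets.

The group-table generator produces, per subject, a shared smooth mean
curve plus a low-order random cosine expansion (amplitude half the node
noise SD) plus iid node noise (SD 0.1); the second group is shifted by
effect_size_sd × noise_sd at the chosen nodes, and age/sex are drawn
independently of group and outcome. Defaults (24 subjects per group, 100
nodes, effect at nodes 40–60 when planted) mirror a two-group clinical
comparison at typical cohort size. All generators are pure functions of
their seed.

**What the phantoms do not emulate:** partial-volume effects and
measurement noise in the scalar maps, anatomically realistic tract
shapes, crossing/kissing geometry, registration error, spatially
correlated or heteroscedastic profile noise, and site effects. Passing
the phantom suite therefore establishes the correctness of the
algorithms under their stated models — not recognition accuracy or
statistical power on real diffusion MRI data.

## Problem sizes used in validation

The standard validation phantom uses 2×60 bundle streamlines plus 100
distractors on the 60³ grid; the calibration study uses 200 simulated
null cohorts of 40 subjects × 100 nodes; learning-curve recovery uses
the canonical six-size grid with 20 noisy replicates; cleaning
robustness uses 50 randomized bundles. These sizes make the full suite
run in well under a minute while keeping every Monte-Carlo check inside
comfortable confidence bands.

## Known limitations

* TRX, BIDS crawling, DICOM, registration/resampling of volumes, and
  tractography itself are out of scope; all volumes must share the
  reference grid, and ROIs must already be in subject space.
* QuickBundles-threshold cleaning implements the single-pass greedy
  variant only (no re-assignment passes or multi-level clustering).
* The per-node model is plain OLS; mixed-effects and GAM-style smooth
  models are not provided.
* Probability maps are used as given; they are not renormalized or
  resampled.
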