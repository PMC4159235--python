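# Methods

## Model and assumptions

The pipeline assumes that voxels inside a seed region differ meaningfully
only in their long-range coupling: voxel *i*'s feature vector is its
Fisher-z correlation profile against a fixed target voxel set, and parcels
are groups of voxels with proportional profiles. Correlation distance
(1 − Pearson r between profile rows) is therefore the natural metric: it is
invariant to per-voxel affine rescaling of profiles, so differences in
overall connectivity strength do not drive the partition, only the *shape*
of the profile does.

Group-level clustering operates on the arithmetic mean of subject z
matrices. The Fisher transform makes correlations approximately
variance-stabilized and additive across subjects; averaging in z rather
than r slightly biases extreme values but keeps the estimator simple and
monotone.

## K-means with correlation distance

Profile rows are centered and scaled to unit norm once; a centroid is the
mean of its members' standardized rows, re-standardized after every update.
For unit-norm zero-mean vectors this update maximizes the summed
row–centroid correlation, so each Lloyd iteration is non-increasing in the
total within-cluster point-to-centroid distance (the reported inertia).
Details that matter for reproducibility:

- initialization: K distinct rows sampled per restart; each restart draws
  from an independent child stream of the master seed, so a run is
  deterministic given `(rng_seed, n_restarts)` and the winner is the
  restart with minimal inertia (100 restarts by default);
- ties in nearest-centroid assignment break to the lowest cluster index;
- an empty cluster is re-seeded at the point farthest from its current
  centroid, and the event is counted on the result object;
- convergence is label stability, capped at 300 iterations.

Spatial cleanup (`remove_isolated_voxels`) flags, per parcel,
face-connected components smaller than 3 voxels (configurable, 18/26
connectivity available). Flagged voxels keep their label but are excluded
from parcel masks and mean time series; they are reported, not reassigned,
so the clustering output remains auditable.

## Split-half stability and choice of K

Each permutation assigns subjects to halves of ⌊n/2⌋ and ⌈n/2⌋ by seeded
shuffle (29/30 for n = 59); both halves' group matrices are clustered at
every K with the same split reused across K, which makes the per-K VI
samples pairable by permutation. Entropies use the natural log, so VI is
in nats and bounded by ln n; the implementation is checked in the tests
against a from-scratch contingency-table oracle at 1e−12 and against an
independent mutual-information routine.

The transition test at K compares VI(K) with VI(K−1) by a paired t test
(pairing by permutation index; a two-sample variant is available via the
`paired` switch). Comparisons start at K = 3 because K = 2 has no
meaningful K − 1 = 1 comparison: two one-cluster solutions always have
VI = 0. Zero differences everywhere yield p = 1 by convention —
indistinguishable solutions must never appear significantly different.
The selected K is the smallest with p ≥ α (default 0.05); if every
transition is significant the result is `None` and the pipeline reports
the absence of a stable plateau rather than guessing.

Because the rule scans upward, it prefers parsimonious stable solutions;
it does not require VI to be monotone in K, and with strongly nested
structure (as in the synthetic default) K values below the true one can
legitimately be stable as well.

## Preprocessing

- **Framewise displacement**: sum of absolute backward differences of the
  six rigid-body parameters, rotations converted to arc length on a 50 mm
  sphere (the standard head-radius convention). Screening is strict:
  max |translation| < 1.5 mm, max |rotation| < 1.5° (traces stored in
  radians, converted explicitly), mean FD < 0.30 mm.
- **Despiking** is deliberately conservative: sign-preserving winsorization
  at robust z = 3 (1.4826·MAD scaling). The threshold and the choice of
  squashing rather than interpolation are configurable and documented here
  because field practice varies.
- **CompCor-style components**: per-voxel linear detrend and unit-variance
  scaling, then the top-5 right singular vectors per compartment, ordered
  by explained variance; fewer are returned with a warning when rank is
  insufficient.
- **Simultaneous band-pass + regression**: both data and the 23-column
  design are band-limited with the same zero-phase brick-wall FFT filter
  (0.009–0.1 Hz) before residualization. Filtering the design too is what
  prevents the regression from reintroducing out-of-band nuisance
  variance. Filtered design columns with no surviving variance (e.g. the
  linear trend, which lives below the passband) are dropped from the
  regression. The brick-wall response slightly overshoots near band edges
  (Gibbs ringing, ≈10% on a pure in-band sinusoid), which is why the
  passband contract is "≥ 90% amplitude retained" rather than exact unity.
- The first 4 frames are discarded before any computation; all stages
  operate on T′ = T − 4.

## Inference on parcel connectivity

Per subject, all parcel mean series enter one GLM per target voxel
(intercept added), so each beta is a partial slope — the parcel's unique
contribution. Group inference is a one-sample t (df = N − 1). Cluster-extent
correction is a sign-flip permutation: under the null of symmetric subject
effects, flipping each subject's map sign is exchangeable; the null
distribution of the maximum suprathreshold component size (over both
signs) calibrates corrected p = (1 + #{null ≥ size})/(1 + n_perm). This is
a deliberate, distribution-free replacement for smoothness-based
topological corrections: it needs no smoothness estimate and is exact at
any n_perm, at the cost of Monte-Carlo granularity in p. Positive and
negative maps are thresholded separately, one-sided at p < 0.001 each.

ROI-to-ROI tests are two-sided by default and FDR-corrected over the full
(parcel, region) table in one family — the most conservative reading —
with a per-parcel family switch. A pair that is identical in every subject
has no sampling variance; it is reported as a certain effect (t = ±inf,
p = 0) rather than dropped.

## Synthetic data: what it does and does not emulate

Seed voxel v in cluster c evolves as `x_v = W_s[c]·S + σ ε_v`, target
voxels carry their network signal plus noise, and a global low-frequency
nuisance signal leaks into every series (removed later by the CompCor
regressors built from the WM/CSF compartments, which mix the same
signal). Network signals are zero-mean Gaussian processes confined to
0.009–0.1 Hz at the configured TR, so the band-pass stage is
approximately signal-preserving by construction. Between-subject
variability is Gaussian jitter on the weight rows (`subject_sd`); network
signals are shared across subjects, which keeps the ground truth a single
M × T matrix and makes group averaging demonstrably variance-reducing.

Defaults: 20 subjects, T = 154 at TR 3.5 s (150 frames after the
discard), K_true = 3 clusters of 20 voxels, M = 3 networks of 30 targets,
mean FD 0.12 mm. The default weight matrix

```
(1.0, 0.5, 0.0)
(0.5, 1.0, 0.0)
(0.0, 0.0, 1.0)
```

gives clusters 1 and 2 shared network support, so the K = 2 solution
merges them reproducibly — a deliberately near-hierarchical structure
matching what seed regions with graded connectivity gradients show.
`noise_sd = 1.6` was calibrated once so a single subject's within-cluster
profile rows correlate at ≈ 0.8: clearly separable at the group level but
far from noiseless at the subject level.

Not emulated: spatial autocorrelation beyond block cluster layout,
scanner-noise spectra, hemodynamic convolution, and subject-specific
spatial misalignment. Consequently, passing tests demonstrate the
correctness and calibration of the algorithms under the assumed
generative structure — not robustness to registration error or
physiological confounds in real scans.

## Problem sizes and numerical choices

Tests and the acceptance script run the recovery experiment at 20 subjects
× 10 replicate studies with 25 split-half permutations and 10–20 K-means
restarts, the familywise-error calibration at 100 null datasets of 216
voxels with 99 sign-flip permutations, and the null voxel calibration at
1e5 voxels — sizes chosen so a replicate is informative while a full run
stays desk-scale. Correlations are clamped to |r| ≤ 1 − 1e−7 before the
Fisher transform; VI values below 1e−12 snap to exact zero; all random
draws flow from spawned `numpy` seed sequences so every artifact records
one master seed.

## Known limitations

- The paired-t transition test treats VI samples as approximately normal;
  with very small n_perm the test is coarse, and with VI distributions
  pinned at zero the p = 1 convention does the work.
- Group averaging in Fisher z has small bias for |r| near 1.
- The NIfTI path resamples masks by nearest neighbor; no interpolation of
  time series across grids is provided (series are extracted on their
  native grid).
- The permutation FWE correction assumes sign-symmetric subject effects
  under the null; strong skew would miscalibrate it.
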