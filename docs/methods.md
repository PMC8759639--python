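# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `rsta`. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## 1. Classification model

The pipeline treats a single epoch as a point on the manifold of
symmetric positive-definite (SPD) matrices and classifies in the
tangent space at the training set's geometric mean.

**xDAWN filters.** For class `k`, filters maximize the generalized
Rayleigh quotient of the prototype energy `P_k P_kᵀ` against the total
signal energy `X Xᵀ`, where `P_k` is the class grand average and `X`
the time-concatenation of all training trials. Implementation:
`scipy.linalg.eigh(P_k P_kᵀ, X Xᵀ)`, keep the `F` leading
eigenvectors, unit-normalize. Determinism conventions: the
largest-magnitude entry of each filter is made positive; equal
eigenvalues are ordered by the channel index of that entry. If
`cond(XXᵀ) > 1e12`, a ridge `1e-10·tr(XXᵀ)/E·I` is added (degenerate,
e.g. noise-free, inputs); a matrix still singular after that is an
error. Default `F = 3`, so the augmented covariance below is 12 × 12
on two classes.

**Augmented covariance.** `Z̃_i = [W_0ᵀP_0; W_1ᵀP_1; WᵀX_i]` (4F rows).
The per-trial covariance is the raw second moment `Z̃ Z̃ᵀ / T` — no mean
removal, divisor = number of time samples — optionally shrunk toward
the scaled identity. The default estimator is OAS (the later-proposed
refinement of Ledoit–Wolf; both available, both via
`sklearn.covariance` with `assume_centered=True`). Shrinkage
guarantees strict positive-definiteness, which the tangent-space step
requires.

**Tangent space.** Karcher mean by fixed-point iteration: at estimate
`S`, average the whitened logs `logm(S^{-1/2} Σ_i S^{-1/2})`, step with
unit step size, stop when the mean tangent-update Frobenius norm falls
below `1e-8` (this quantity is scale-free). Maximum 200 iterations:
convergence is linear and real covariance sets need 60–80; exceeding
the cap is an error, not a silent stop. Initialization: arithmetic
mean. Matrix log/sqrt use symmetric eigendecomposition with a `1e-12`
relative eigenvalue floor that raises rather than clamps — a
non-positive covariance reaching this stage is a bug upstream, not
something to paper over. Vectorization whitens by `Σ_ref^{-1/2}`,
takes the upper triangle with √2 weight off-diagonal; this makes
vector norms equal affine-invariant Riemannian distances exactly
(asserted to 1e-8 in tests on random 12 × 12 pairs).

**Classifier.** L2-regularized logistic regression, `C = 1`, lbfgs,
`max_iter = 2000`. Scores reported downstream are signed distances to
the decision boundary.

**CSP baseline.** Filters are generalized eigenvectors of the class-0
mean covariance against the pooled mean covariance (ridge-guarded like
xDAWN); components are taken in pairs from the two ends of the
eigenvalue spectrum; features are log-variances of the filtered
signals.

## 2. Source-space variant

The sLORETA operator is `T(α) = Kᵀ(KKᵀ + αI)^{-1}` with per-voxel
standardization by the 3 × 3 diagonal blocks `Σ_l` of the resolution
matrix `T(α)K`: `Ĵ_l = Σ_l^{-1/2} T(α)_l X`. The standardization is
block-diagonal — it never mixes voxels — and in the noiseless
single-dipole limit the voxel with maximal time-summed standardized
power is exactly the active one; the tests assert this on 100/100
random instances at `α = 1e-8`. For noisy data the default is the
trace-scaled `α = 1e-2·tr(KKᵀ)/E`. A singular `Σ_l` block raises an
error naming the voxel; a pseudo-inverse mode is opt-in because silent
pseudo-inversion can hide a rank-deficient gain matrix.

Region averaging takes the mean orientation-norm activation over each
region's member voxels (signed orientation components are not used;
the norm is the documented choice, selectable at the
`SourceEstimate.voxel_activation` level). Region time courses then
enter the sensor-space pipeline unchanged, with `F = 3`.

The package constructs only synthetic lead fields (i.i.d. Gaussian
gain with a condition-number retry guard). Real head models can be
supplied through the same `LeadField` container (`K`, voxel positions,
region labels, HDF5 layout in `io_formats`), but no anatomy, BEM/FEM
forward modelling or atlas files are bundled or tested.

## 3. Synthetic data generator

The generator emulates a passive visual-stimulation study: 15 subjects,
96 Checkerboard and 192 Tunnel trials each, 12 scalp electrodes (F3,
Fz, F4, C3, Cz, C4, P3, Pz, P4, O1, Oz, O2), 512 Hz sampling
(configurable up to 2048 Hz), epochs from −500 to +500 ms so that
baseline correction on the pre-stimulus interval is exercisable.

**Class morphology.** Sums of Gaussian-windowed bumps
(latency, width σ, amplitude): Checkerboard = +10 µV at 100 ms
(σ 30 ms) + 4 µV at 220 ms; Tunnel = −4 µV at 100 ms / +4 µV at 140 ms
(biphasic, σ 25 ms) + 4 µV at 220 ms. The Checkerboard's high-amplitude
monophasic P100 versus the Tunnel's lower-amplitude biphasic early
response plus P220 is the discriminative structure; exact study
waveforms are unavailable, so these are idealized morphologies.

**Topography.** Occipital ≫ parietal > central/frontal channel gains
(1.0 / 0.6 / 0.3 / 0.15 by electrode prefix), the classic posterior
dominance of visual evoked responses. Per-bump topographies can
override the profile.

**Noise.** Per-channel 1/f background (γ = 1, SD 4 µV) plus white
sensor noise (SD 1 µV). No ocular or muscular artifacts — artifact
rejection is explicitly upstream of this package.

**Between-subject variability** is the load-bearing part of the
design: per-subject lognormal channel gains (σ = 0.9), a random
orthogonal mixing perturbation (scale 0.7), a global response gain
(SD 0.6) and a per-subject latency offset (SD 50 ms); per-trial
amplitude jitter (SD 0.3) and latency jitter (SD 15 ms). These values
were calibrated once, against the orderings the study design predicts,
not against any absolute accuracy: within-subject trials must be far
more separable than pooled trials, and time-domain (vectorized)
features must degrade across subjects faster than covariance-based
features. The dominant mechanism for the latter is latency
misalignment between subjects, which is why the subject latency offset
is large relative to the component widths. With smaller offsets
(≤30 ms) a vectorized logistic regression generalizes across subjects
almost as well as the Riemannian pipeline and the pipeline ranking is
not recovered.

**What passing tests do and do not show.** The generator reproduces
the *structure* of multi-subject ERP data — class-conditional means,
occipital topography, 1/f background, subject heterogeneity — but not
its full richness: no non-stationarity within a session, no artifacts,
no correlated noise across channels beyond the mixing, no
four-orientation substructure within the Tunnel class. Orderings and
invariances demonstrated on it are evidence about the implementation,
not about expected accuracies on real recordings.

**Source-space generator.** Random well-conditioned lead field
(condition threshold 1e6 on `KKᵀ`, 50 retries), one designated active
voxel per class carrying the class bump waveform along a fixed random
orientation, background activity injected at every voxel through the
same forward model, white sensor noise on top. Ground-truth voxel ids
are returned for localization tests.

## 4. Evaluation harness

LOSO: one fold per subject. Intra-subject: stratified, seeded 4-fold
per subject; the fold (subject × split) is the sampling unit for
distribution comparisons, since a per-fold accuracy distribution is
what the boxplot-style comparisons require. Every supervised stage is
fitted on training folds only; the tangent-space reference is frozen
before held-out projection. Pooled metrics sum raw confusion counts
over folds; ROC/AUC and precision–recall/AP are computed from pooled
decision scores via scikit-learn (trapezoidal AUC; step-wise AP); MCC
is 0 by convention when a confusion marginal is zero. Distribution
comparisons use the two-sided Mann–Whitney U test on fold accuracies,
with p = 1 and a warning when every value is tied.

Class balancing (randomized undersampling of the majority class) is
per subject, seeded, never touches the minority class and preserves
trial order. The baseline-correction wording ambiguity ("divided") is
resolved as subtraction of the pre-stimulus mean — division is
meaningless for zero-mean band-passed signals.

**Desk-scale profile.** `desk_scale_config()`: 6 subjects, 48/96
trials per class, 128 Hz. This is the package's standard evaluation
size: it keeps a full seed-sweep (10 generator seeds × two CV schemes ×
several pipelines plus a 20-permutation null) in the minutes range
while retaining enough trials per fold that pipeline differences are
not drowned by fold-level variance. Halving trials again (16/32) makes
seed-level comparisons unstable.

## 5. Known limitations

- Absolute accuracies on synthetic data are not comparable to
  recordings; only orderings and invariances are designed to transfer.
- The sign-test comparison of the main pipeline against the vectorized
  baseline is underpowered at 10 seeds: with the observed ~8/10 win
  rate an exact sign test cannot reach p < 0.05 (that needs ≥ 9/10);
  the mean ordering and the test's direction are asserted instead.
- The four Tunnel orientations are collapsed into one class; the
  binary task is the only one implemented.
- Real-atlas source analysis (template anatomy, named cortical
  regions) is an interface, not a tested feature; the region count of
  a real parcellation is therefore not reproduced here.
- `run_comparison_suite` refits every pipeline per scheme; it makes no
  attempt to share fitted stages across pipelines beyond identical
  fold structure.
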