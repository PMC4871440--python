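# Methods

## Problem and model

`ortcva` implements a longitudinal spatial-covariance analysis for
task-activation imaging of the kind used to search for compensatory brain
networks in presymptomatic neurodegeneration: subjects perform a sequence
learning task (LEARN), a kinematically matched execution task (MOVE) and a
REST condition at two timepoints, and the question is whether a single
voxel-weight topography exists whose learning-specific (LEARN−MOVE)
expression rises from baseline to follow-up in proportion to each
carrier's disease burden (burden = maximal cohort years-to-onset minus the
subject's YTO, so larger burden means nearer clinical onset).

The derivation is a supervised PCA (ordinal-trend canonical variates
analysis). Let `X` be the matrix of masked, global-mean-adjusted
LEARN−MOVE subtraction images (rows: subject × run × timepoint; columns:
in-mask voxels).

1. **Within-subject centering.** Each subject's mean row is removed, so
   only within-subject change across runs and timepoints remains. This is
   a deliberate reconstruction; some variants of ordinal-trend CVA apply
   an additional condition-level centering whose details are not public,
   and this package documents within-subject centering as its default.
2. **PCA.** SVD of the centered matrix gives orthonormal voxel patterns
   (right singular vectors), row scores `U·s`, and eigenvalues
   `s²/(rows−1)`. Components below `1e−10·λ₁` are treated as numerical
   rank noise; at most `max_k` (default 5) enter model selection.
3. **Burden fit with AIC selection.** For `k = 1..max_k`, burden is
   regressed (OLS with intercept) on the per-subject TP2−TP1 changes of
   the first `k` component scores (runs averaged per timepoint first).
   `AIC = n·ln(RSS/n) + 2(p+1)` with `p` the design columns including the
   intercept; the smallest AIC selects `k`. The composite topography is
   the coefficient-weighted sum of the selected components, renormalized
   to unit Euclidean norm and signed so that mean expression change over
   subjects is non-negative. `r²` of this fit (`r2_yto`) is the quantity
   validated by permutation. Subjects whose composite expression falls
   from TP1 to TP2 are counted as ordinal-trend violators and compared
   with the largest count an exact two-sided binomial test at 0.5 would
   still reject at 5%.

### A small-sample property of the composite

An OLS coefficient for a component scales inversely with the variance of
that component's Δ scores, while all component maps have unit norm.
Consequently, when AIC — a weak penalty at n = 10 — admits a noise
component, its voxel-space share of the composite is of order `1/√n`
*independently of the signal-to-noise ratio*: the expected cosine between
the composite and an embedded ground-truth pattern plateaus near 0.9 and
cannot be pushed to 1 by making the data cleaner. The leading component
itself recovers the embedded pattern at cosine ≈ 0.98. This is a property
of the published selection rule, reproduced deliberately; tests therefore
check recovery at the package's canonical seed rather than asserting a
bound that no AIC-selected composite can guarantee distribution-wide.

## Inference

- **Permutation test.** Each iteration swaps, per subject with
  probability ½, that subject's TP1/TP2 labels (runs move together —
  preserving the within-subject pairing the longitudinal design requires)
  and re-runs the entire derivation. `p = (1 + #{null r² ≥ observed}) /
  (1 + n_iter)` (add-one rule; p is never 0 and is exactly discrete-
  uniform under the null).
- **Bootstrap ICV.** Subjects are resampled with replacement (all scans
  of a drawn subject together; replicates with < 3 unique subjects are
  redrawn), the composite re-derived, and each replicate sign-aligned to
  the point estimate. `ICV = point weight / bootstrap SD` is a z-like
  reliability statistic; SD indistinguishable from 0 at double precision
  is flagged and reported as ±∞.
- **Cluster thresholding.** The weight map is z-scaled by its in-mask SD;
  voxels with `z ≥ z_thresh` (positive) or `z ≤ −z_thresh` (negative) and
  `|ICV| ≥ icv_thresh` form clusters under 26-connectivity (common
  voxel-cluster practice; configurable), discarding components smaller
  than `cluster_min`. Defaults are computed from `critical_value`, not
  hard-coded: one-sided 1% → 2.33 for voxel weights, two-sided 5% → 1.96
  for the ICV gate, cutoff 100 voxels, matching the analysis conventions
  being reimplemented. Note that cluster *count* is not monotone in the
  voxel threshold (components can split); total suprathreshold membership
  is, and that is what tests assert.

## Forward scoring

Expression of a derived pattern in a new masked, adjusted scan is
`Σ_v w_v (scan_v − reference_v)`, with the reference profile the mean
adjusted control MOVE image (scores are then translation-free and
anchored to the control reference task). Raw scores are z-transformed
against the control MOVE scores (n−1 SD, appropriate for a 10-subject
reference), so control MOVE has mean 0 / SD 1 exactly. The learning
response is run-averaged z(LEARN) − z(MOVE) per subject and timepoint;
its TP2−TP1 change is correlated (Spearman) with burden, and identical
machinery applied to REST probes task specificity. Missing runs are
averaged over what exists; a missing condition yields a missing response,
never zero.

## Regional analysis

Spheres (default 5 mm, boundary-inclusive, voxel-center distance through
the affine so anisotropic voxels are handled) centered at cluster peaks
give regional mean rCBF for LEARN and MOVE; the learning response is
their difference, and its longitudinal change is correlated with YTO per
region. No multiple-comparison correction is applied across regions —
deliberately, matching the analysis reimplemented here — and raw
p-values are labeled as such.

## Behavioral statistics

Group sizes of ≤ 10 per arm make asymptotic p-values unreliable, so the
Spearman (n ≤ 10), Wilcoxon signed-rank (n ≤ 15 after zero removal) and
Mann-Whitney (m+n ≤ 20) tests compute exact two-sided p-values by full
enumeration (permutations, sign assignments, and rank-set combinations
respectively), with mid-ranks for ties; above those sizes the standard
tie-corrected approximations take over. The group × time interaction for
a two-group, two-timepoint design is computed as the pooled-variance
two-sample t on the per-subject deltas, with `F = t²`, df (1, n−2) —
algebraically the repeated-measures interaction for this design.
Carriers are split by YTO ≤ 11 y (nearPC/farPC, boundary inclusive) and
by a median split of baseline retrieval index (RI > median → good
learners; ties at the median are assigned to the bad-learner group, a
documented rule). RI per timepoint averages runs (the aggregation rule is
configurable because the source convention is not stated).

## Synthetic cohorts

The generator emulates the study design: `n_phd` carriers scanned at
`timepoints` sessions (2 runs each of LEARN/MOVE/REST per session),
`n_hc` controls at baseline only, on a 16³ grid of 2 mm voxels with an
ellipsoidal gray-matter mask (~1300 voxels) — small enough for
seconds-scale tests, large enough for ≥100-voxel blobs. Each scan is
`g·(B + O_i + s·P + ε)`: `B` a smooth positive baseline (~50 units),
`O_i` a smooth subject offset (SD 0.3), `ε` smoothed voxel noise
(unit-SD-normalized Gaussian-filtered white noise, FWHM 6 mm,
σ = FWHM/(2√(2 ln 2))), and `g` a lognormal global-scale nuisance
(σ = 0.1) — multiplicative, so ratio global-mean adjustment removes it
exactly. The embedded topography `P` is unit-norm and built from signed
Gaussian-profile blobs (support = lattice ball of the blob radius; one
focal increase, three distributed decreases, roughly sum-balanced so the
zero-mean constraint of adjusted subtraction rows barely clips it).
Expression follows `s_LEARN − s_MOVE = offset + (t−1)·slope·burden +
learn_effect` with `s_MOVE = s_REST = 0`; defaults `learn_effect = 0.5`,
`slope = 0.06`/year, `offset = 0`, `noise_sd = 0.005` put the planted
effects well above the voxel noise — defaults are chosen for testability
of the pipeline, not for physiological realism, since no effect-size
estimates exist for the activation data being emulated. YTO is uniform
on (1.5, 25) y; burden = 25 − YTO; controls carry burden 0. The
retrieval index decreases with burden *rank* (gap 2.2 per rank) with
bounded noise smaller than half the gap, so the median RI split recovers
the highest-burden half deterministically, and improves at follow-up in
proportion to burden.

What the generator does **not** emulate: PET physics, head motion,
registration error, anatomically shaped masks, missing runs, or
phenoconversion during follow-up (supported as a YTO override in the
subject table, but not drawn). Passing tests therefore demonstrate the
pipeline's statistical correctness on data with the assumed covariance
structure, not robustness to real-world acquisition artifacts.

## Numerical choices and problem sizes

- Ratio (division) global normalization, not ANCOVA; reflect-padded
  smoothing (mass-conserving on small grids); pipeline order
  mask → adjust → (optional smooth) → subtract, with smoothing off by
  default since synthetic data are generated already smooth.
- Permutation and bootstrap are seeded (`numpy.random.default_rng`);
  identical seeds give bit-identical null vectors, ICV maps, and cohort
  volumes.
- Monte-Carlo sizes in the test suite and acceptance script are scaled
  to 200 permutation / 100 bootstrap iterations, and the null-calibration
  study to 200 replicate cohorts × 50 iterations — chosen so the entire
  validation runs in minutes on one CPU while keeping the add-one p-value
  resolution (1/201) below every significance level asserted.
- Degenerate cases: perfect OLS fits are flagged AIC = −∞ rather than an
  error; constant vectors make rank correlations undefined (reported
  missing, never zero); zero reference SD and empty masks/spheres raise.

## Known limitations

- Two-timepoint designs only; no multi-level (>2 condition) ordinal
  trends.
- The composite's fidelity ceiling under AIC described above.
- The exact Spearman p enumerates n! permutations and is capped at
  n = 10 (≈ 3.6 M permutations, a few seconds); larger n use the
  t-approximation.
- Cluster peaks are reported in mm coordinates only; no anatomical
  labeling.
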