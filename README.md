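# ortcva

Longitudinal spatial-covariance (ordinal-trend) analysis of task-activation
brain imaging, with a synthetic-cohort generator for end-to-end validation.

## What this is for

In presymptomatic neurodegeneration (the motivating case is carriers of the
Huntington's disease mutation), motor-learning deficits can be offset by
*compensatory* brain networks: topographies whose learning-specific
activation rises over time, most strongly in the subjects closest to
clinical onset. Detecting such a network from a small longitudinal cohort —
subjects scanned at two sessions while performing a sequence-learning task
(LEARN), a matched execution task (MOVE), and REST — requires a multivariate
pipeline rather than voxelwise group contrasts. This package implements that
pipeline end to end:

1. **Preprocessing** — gray-matter masking, ratio adjustment for the global
   mean (each scan divided by its in-mask mean), optional 3-D Gaussian
   smoothing, and LEARN−MOVE subtraction images per subject × run ×
   timepoint.
2. **Ordinal-trend derivation (supervised PCA)** — subtraction images are
   centered within subject and decomposed by SVD; for k = 1..K the disease
   burden (max cohort years-to-onset − YTO) is regressed on the per-subject
   TP2−TP1 changes of the first k component scores; the Akaike Information
   Criterion, AIC = n·ln(RSS/n) + 2(p+1), picks k. The composite pattern is
   the coefficient-weighted sum of the selected components, unit-normed and
   signed so expression rises over time; subjects whose expression falls
   are counted as ordinal-trend violators.
3. **Validation** — a permutation test (per-subject timepoint swaps, runs
   moving together; add-one Monte-Carlo p for the burden-fit r²) and a
   subject-level bootstrap giving each voxel's inverse coefficient of
   variation ICV = weight / bootstrap SD. The map is displayed after
   z-scaling at |z| ≥ 2.33 (one-sided p < 0.01), gated by |ICV| ≥ 1.96
   (two-sided p < 0.05), 26-connected clusters above a size cutoff.
4. **Forward scoring** — pattern expression in any new scan, z-anchored so
   the control MOVE scans have mean 0 / SD 1; learning response
   z(LEARN)−z(MOVE) per timepoint, its longitudinal change, and the same
   measure in REST as a specificity control.
5. **Regional and behavioral statistics** — 5 mm spherical VOIs at cluster
   peaks with Spearman burden correlations, and exact small-sample
   nonparametric tests (Spearman, Wilcoxon signed-rank, Mann-Whitney by
   full enumeration) plus the two-group repeated-measures interaction
   (F = t² on deltas).

No imaging data ship with the package. A seeded generator (`ortcva.cohort`)
simulates the full study design — 10 carriers scanned twice 1.5 y apart,
10 controls at baseline, 2 runs per condition — with a known embedded
topography whose LEARN−MOVE expression grows with burden, so every stage is
testable against ground truth.

## Worked example

```python
import ortcva

cfg = ortcva.CohortConfig(seed=0)                  # default study design
pattern = ortcva.cohort.make_true_pattern(
    cfg.grid_shape, cfg.voxel_size_mm,
    ortcva.cohort.default_clusters(cfg.grid_shape, cfg.voxel_size_mm))
scans, subjects = ortcva.generate_cohort(cfg, pattern)

prepped = ortcva.prep.preprocess(scans)            # mask + global adjust
dm = ortcva.subtraction_matrix(prepped, group="pHD")
comp = ortcva.derive_composite(dm, subjects)       # centering→PCA→AIC fit
perm = ortcva.permutation_test(dm, subjects, n_iter=200, seed=1)

scores = ortcva.standardized_scores(comp.as_pattern(), prepped)
resp = ortcva.learning_response(scores)
```

Printed summary of this run:

```
components selected (AIC): k = 5
burden-fit r2            : 0.998
ordinal-trend violators  : 0 / 10
permutation p (200 iter) : 0.0100
recovered/true cosine    : 0.909
delta-expression vs burden rho = 1.000 (p = 5.51e-07)
mean REST change (z)     : -0.0047
```

Reading this: the AIC-selected composite expresses the planted covariance
pattern (cosine 0.909 with the embedded ground truth; the leading component
alone reaches ≈ 0.98 — see `docs/methods.md` on the small-sample AIC
ceiling), its expression rises in every carrier (0 violators), the burden
fit is far beyond chance (permutation p = 0.01, the add-one minimum being
1/201 ≈ 0.005), forward-scored expression change tracks burden perfectly in
rank (ρ = 1.0), and REST expression — where no signal was planted — does
not drift (−0.005 z-units).

The same pipeline is available from the shell:

```
ortcva simulate --out demo/ --seed 0
ortcva derive --scans demo/scans --subjects demo/subjects.tsv \
    --out demo/pattern.nii.gz --report demo/report.json
ortcva full-run --out demo/ --seed 0 --n-iter 200 --cluster-min 10
```

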