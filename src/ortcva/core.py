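"""Ordinal-trend covariance pattern derivation.

The supervised-PCA procedure: subtraction images are centered within
subject (removing each subject's mean map so that only within-subject
change across runs/timepoints remains), decomposed by SVD into orthonormal
voxel patterns (principal components), and a composite pattern is formed
from the leading components by regressing disease burden on the
per-subject change of component expression between timepoints.  The number
of components entering the composite is chosen by the Akaike Information
Criterion; the composite is signed so that expression increases over time
on average.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .datatypes import DataMatrix, Pattern, ensure_burden

EIGENVALUE_RTOL = 1e-10  # components below this fraction of lambda_1 are noise


@dataclasses.dataclass
class PCSet:
    """Orthonormal voxel patterns with row projections.

    components: (k, n_voxels), rows orthonormal.
    eigenvalues: squared singular values / (n_rows - 1), non-increasing.
    scores: (n_rows, k) projections of the centered rows.
    index: row labels (subject, run, timepoint) inherited from the data.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    index: pd.DataFrame
    mask: np.ndarray
    affine: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclasses.dataclass
class CompositePattern:
    """Burden-fitted composite of leading principal components."""

    weights: np.ndarray          # unit-norm, over in-mask voxels
    pc_coefficients: np.ndarray  # regression weights of the k retained PCs
    intercept: float
    k: int
    aic: float
    aic_path: list[float]
    r2_yto: float
    violators: int
    delta_scores: pd.Series      # per-subject TP2-TP1 composite expression
    mask: np.ndarray = None
    affine: np.ndarray = None

    def as_pattern(self) -> Pattern:
        return Pattern(self.weights, self.mask, self.affine)


def center_within_subject(dm: DataMatrix) -> DataMatrix:
    """Subtract each subject's mean row from that subject's rows."""
    X = dm.X.copy()
    for subject, grp in dm.index.groupby("subject", sort=False).groups.items():
        rows = np.asarray(grp)
        if rows.size < 2:
            raise ValueError(f"subject {subject!r} has a single row; "
                             "within-subject centering needs >= 2")
        X[rows] -= X[rows].mean(axis=0)
    return DataMatrix(X, dm.index, dm.mask, dm.affine)


def pca(dm: DataMatrix, n_keep: int | None = None) -> PCSet:
    """SVD of the (already centered) data matrix.

    Components are right singular vectors; scores are row projections
    (U * s); eigenvalues are squared singular values / (n_rows - 1).
    A request beyond numerical rank is truncated with a warning.
    """
    U, s, Vt = np.linalg.svd(dm.X, full_matrices=False)
    tol = EIGENVALUE_RTOL * (s[0] ** 2 if s.size else 1.0)
    rank = int(np.sum(s ** 2 > tol))
    if n_keep is None:
        n_keep = rank
    elif n_keep > rank:
        warnings.warn(f"requested {n_keep} components but numerical rank is "
                      f"{rank}; truncating", stacklevel=2)
        n_keep = rank
    n_rows = dm.X.shape[0]
    eigenvalues = s[:n_keep] ** 2 / max(n_rows - 1, 1)
    return PCSet(Vt[:n_keep], eigenvalues, U[:, :n_keep] * s[:n_keep],
                 dm.index, dm.mask, dm.affine)


def subject_scores(weights: np.ndarray, dm: DataMatrix) -> pd.DataFrame:
    """Expression of a pattern in every row, plus run-averaged values.

    Returns a DataFrame with per-row ``score`` and, via groupby, the mean
    score per (subject, timepoint).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (dm.X.shape[1],):
        raise ValueError("pattern and data matrix voxel sets differ")
    table = dm.index.copy()
    table["score"] = dm.X @ weights
    return table


def timepoint_means(score_table: pd.DataFrame) -> pd.DataFrame:
    """Run-averaged score per subject and timepoint (wide: one column per TP)."""
    wide = (score_table.groupby(["subject", "timepoint"], sort=False)["score"]
            .mean().unstack("timepoint"))
    return wide


def count_violators(score_table: pd.DataFrame) -> int:
    """Subjects whose run-averaged expression decreases from TP1 to TP2."""
    wide = timepoint_means(score_table)
    if wide.shape[1] < 2 or wide.isna().any().any():
        raise ValueError("every subject needs scores at both timepoints")
    tps = sorted(wide.columns)
    return int((wide[tps[-1]] < wide[tps[0]]).sum())


def max_tolerated_violators(n: int, alpha: float = 0.05) -> int:
    """Largest v such that a two-sided exact binomial test of v in n at
    p=0.5 still rejects (p < alpha); used to report ordinal-trend quality."""
    from scipy.stats import binomtest
    v = -1
    for cand in range(n + 1):
        if binomtest(cand, n, 0.5).pvalue < alpha:
            v = cand
        else:
            break
    return max(v, 0)


def ols_aic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Ordinary least squares with intercept and a small-sample AIC.

    AIC = n ln(RSS/n) + 2 (p + 1) with p the number of columns of the
    design including the intercept.  A numerically perfect fit (RSS ~ 0)
    is flagged with AIC = -inf rather than an error, since model selection
    should prefer it.

    Returns (coefficients including leading intercept, RSS, AIC).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    if X.shape[0] != n:
        raise ValueError("X rows must match len(y)")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is collinear")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    p = design.shape[1]
    scale = float(y @ y) if float(y @ y) > 0 else 1.0
    if rss <= 1e-12 * scale:
        return coef, rss, -np.inf
    aic = n * np.log(rss / n) + 2.0 * (p + 1)
    return coef, rss, float(aic)


def fit_composite(pcs: PCSet, subject_table: pd.DataFrame,
                  max_k: int = 5) -> CompositePattern:
    """AIC-selected burden fit over nested prefixes of the leading PCs.

    For k = 1..max_k, burden (max cohort YTO - YTO) is regressed on the
    per-subject TP2-TP1 changes of the first k component scores; the k with
    the smallest AIC wins.  The composite voxel map is the coefficient-
    weighted sum of those components, renormalized to unit norm and signed
    so mean expression change over subjects is >= 0.
    """
    subject_table = ensure_burden(subject_table)
    burden = subject_table.set_index("subject")["burden"]

    # per-subject, per-timepoint run-averaged component scores
    lab = pcs.index.copy()
    deltas = []
    for j in range(pcs.n_components):
        lab["score"] = pcs.scores[:, j]
        wide = timepoint_means(lab)
        tps = sorted(wide.columns)
        if len(tps) < 2:
            raise ValueError("composite fit needs two timepoints")
        deltas.append(wide[tps[-1]] - wide[tps[0]])
    D = pd.concat(deltas, axis=1)
    D.columns = range(pcs.n_components)
    if D.isna().any().any():
        raise ValueError("every subject needs scores at both timepoints")
    subjects = D.index
    missing = [s for s in subjects if s not in burden.index
               or not np.isfinite(burden[s])]
    if missing:
        raise ValueError(f"burden/YTO missing for subjects: {missing}")
    y = burden.loc[subjects].to_numpy(dtype=float)

    n = len(subjects)
    cap = min(max_k, pcs.n_components)
    if n <= cap + 2:
        warnings.warn(f"only {n} subjects; capping candidate components at "
                      f"{max(n - 3, 1)}", stacklevel=2)
        cap = max(min(cap, n - 3), 1)

    aic_path, fits = [], []
    for k in range(1, cap + 1):
        try:
            coef, rss, aic = ols_aic(y, D.to_numpy()[:, :k])
        except ValueError:
            break  # design lost rank (e.g. few unique bootstrap subjects)
        aic_path.append(aic)
        fits.append((coef, rss))
    if not fits:
        raise ValueError("no full-rank burden model could be fitted")
    k_best = int(np.argmin(aic_path)) + 1
    coef, rss = fits[k_best - 1]
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    pc_coef = coef[1:]
    weights = pc_coef @ pcs.components[:k_best]
    nrm = np.linalg.norm(weights)
    if nrm == 0:
        raise ValueError("composite weights are identically zero")
    weights = weights / nrm
    pc_coef = pc_coef / nrm

    delta_comp = pd.Series(D.to_numpy()[:, :k_best] @ pc_coef, index=subjects)
    if delta_comp.mean() < 0:  # sign convention: expression rises over time
        weights, pc_coef, delta_comp = -weights, -pc_coef, -delta_comp
    violators = int((delta_comp < 0).sum())

    return CompositePattern(weights, pc_coef, float(coef[0]), k_best,
                            float(aic_path[k_best - 1]), list(aic_path),
                            float(r2), violators, delta_comp,
                            pcs.mask, pcs.affine)


def derive_composite(dm: DataMatrix, subject_table: pd.DataFrame,
                     max_k: int = 5) -> CompositePattern:
    """Full derivation: within-subject centering -> PCA -> burden-fitted
    composite with AIC model selection."""
    centered = center_within_subject(dm)
    pcs = pca(centered, n_keep=None)
    if pcs.n_components > max_k:
        pcs = PCSet(pcs.components[:max_k], pcs.eigenvalues[:max_k],
                    pcs.scores[:, :max_k], pcs.index, pcs.mask, pcs.affine)
    return fit_composite(pcs, subject_table, max_k=max_k)
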