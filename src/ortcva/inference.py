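"""Nonparametric validation of the derived pattern.

Permutation test: per subject, the two timepoint labels of the subtraction
images are swapped with probability 1/2 (runs move together) and the whole
derivation is re-run, yielding a null distribution for the burden-fit r^2.
Bootstrap: subjects are resampled with replacement and the pattern is
re-derived per replicate; voxel reliability is summarized by the inverse
coefficient of variation ICV = point estimate / bootstrap SD, a z-like
statistic.  Cluster thresholding extracts connected suprathreshold regions
of the z-scaled weight map, optionally gated by |ICV|.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .core import CompositePattern, derive_composite
from .datatypes import DataMatrix, unflatten_to_grid


@dataclasses.dataclass
class PermutationResult:
    observed_r2: float
    null_r2: np.ndarray
    p_value: float
    n_iter: int
    seed: int


@dataclasses.dataclass
class ICVMap:
    icv: np.ndarray            # point / boot SD; +-inf where SD == 0
    point_estimate: np.ndarray
    boot_sd: np.ndarray
    n_iter: int
    degenerate: np.ndarray      # True where boot SD == 0


@dataclasses.dataclass
class Cluster:
    sign: int
    voxels: np.ndarray        # (n, 3) voxel indices
    size: int
    peak_voxel: tuple[int, int, int]
    peak_value: float
    peak_mm: tuple[float, float, float]


@dataclasses.dataclass
class ClusterSet:
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sign": c.sign, "size": c.size,
                 "peak_i": c.peak_voxel[0], "peak_j": c.peak_voxel[1],
                 "peak_k": c.peak_voxel[2],
                 "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1],
                 "peak_z_mm": c.peak_mm[2], "peak_value": c.peak_value}
                for c in self.clusters]
        return pd.DataFrame(rows, columns=["sign", "size", "peak_i", "peak_j",
                                           "peak_k", "peak_x_mm", "peak_y_mm",
                                           "peak_z_mm", "peak_value"])


def monte_carlo_p(observed: float, null: np.ndarray) -> float:
    """Add-one Monte-Carlo p-value: (1 + #{null >= observed}) / (1 + n)."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def _swap_timepoints(dm: DataMatrix, flip: dict) -> DataMatrix:
    idx = dm.index.copy()
    tps = sorted(idx["timepoint"].unique())
    lo, hi = tps[0], tps[-1]
    swap = {lo: hi, hi: lo}
    sel = idx["subject"].map(flip).to_numpy(dtype=bool)
    idx.loc[sel, "timepoint"] = idx.loc[sel, "timepoint"].map(swap)
    return DataMatrix(dm.X, idx, dm.mask, dm.affine)


def permutation_test(dm: DataMatrix, subject_table: pd.DataFrame,
                     n_iter: int = 1000, seed: int = 0,
                     max_k: int = 5) -> PermutationResult:
    """Null distribution of the burden-fit r^2 under timepoint exchange.

    Each iteration independently relabels, per subject with probability
    1/2, that subject's TP1/TP2 subtraction images (runs move together)
    and re-runs the entire derivation.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    observed = derive_composite(dm, subject_table, max_k=max_k).r2_yto
    subjects = dm.subjects
    null = np.empty(n_iter)
    for it in range(n_iter):
        flip = dict(zip(subjects, rng.random(len(subjects)) < 0.5))
        null[it] = derive_composite(_swap_timepoints(dm, flip),
                                    subject_table, max_k=max_k).r2_yto
    return PermutationResult(float(observed), null,
                             monte_carlo_p(observed, null), n_iter, seed)


def align_sign(reference: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Flip a replicate's weights if anti-correlated with the reference."""
    return weights if float(reference @ weights) >= 0 else -weights


def bootstrap_icv(dm: DataMatrix, subject_table: pd.DataFrame,
                  n_iter: int = 1000, seed: int = 0, max_k: int = 5,
                  min_unique: int = 3) -> ICVMap:
    """Voxelwise reliability of the composite weights by subject bootstrap.

    All scans of a drawn subject enter the replicate together; replicates
    with fewer than ``min_unique`` distinct subjects are redrawn.  Each
    replicate's weight map is sign-aligned to the point estimate before
    aggregation (the pattern's overall sign is arbitrary).
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    rng = np.random.default_rng(seed)
    point = derive_composite(dm, subject_table, max_k=max_k)
    subjects = dm.subjects
    n_subj = len(subjects)
    rows_of = {s: np.flatnonzero((dm.index["subject"] == s).to_numpy())
               for s in subjects}
    burden = subject_table.pipe(_burden_by_subject)

    reps = np.empty((n_iter, dm.X.shape[1]))
    for it in range(n_iter):
        while True:
            draw = rng.integers(0, n_subj, n_subj)
            if len(set(draw)) >= min_unique:
                break
        blocks, labels, st_rows = [], [], []
        for copy, j in enumerate(draw):
            subj = subjects[j]
            rows = rows_of[subj]
            blocks.append(dm.X[rows])
            lab = dm.index.iloc[rows][["run", "timepoint"]].copy()
            lab.insert(0, "subject", f"{subj}*{copy}")
            labels.append(lab)
            st_rows.append({"subject": f"{subj}*{copy}",
                            "burden": burden[subj]})
        boot_dm = DataMatrix(np.vstack(blocks),
                             pd.concat(labels, ignore_index=True),
                             dm.mask, dm.affine)
        comp = derive_composite(boot_dm, pd.DataFrame(st_rows), max_k=max_k)
        reps[it] = align_sign(point.weights, comp.weights)

    boot_sd = reps.std(axis=0, ddof=1)
    # SD indistinguishable from zero at double precision counts as degenerate
    degenerate = boot_sd <= 1e-12 * max(float(np.abs(point.weights).max()), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        icv = np.where(degenerate,
                       np.sign(point.weights) * np.inf,
                       point.weights / np.where(degenerate, 1.0, boot_sd))
    icv[degenerate & (point.weights == 0)] = 0.0
    return ICVMap(icv, point.weights.copy(), boot_sd, n_iter, degenerate)


def _burden_by_subject(subject_table: pd.DataFrame) -> pd.Series:
    from .datatypes import ensure_burden
    return ensure_burden(subject_table).set_index("subject")["burden"]


def critical_value(alpha: float, sidedness: str = "two") -> float:
    """Standard-normal critical value for a test at level alpha.

    one-sided: Phi^-1(1 - alpha); two-sided: Phi^-1(1 - alpha/2).
    (0.05, two) -> 1.96; (0.005, two) -> 2.81; (0.01, one) -> 2.33.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    q = 1 - alpha if sidedness == "one" else 1 - alpha / 2
    return float(norm.ppf(q))


_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def threshold_clusters(weights: np.ndarray, mask: np.ndarray,
                       affine: np.ndarray, z_thresh: float,
                       cluster_min: int, icv: np.ndarray | None = None,
                       icv_thresh: float = 0.0) -> ClusterSet:
    """Connected suprathreshold regions of the z-scaled weight map.

    The weight vector is divided by its in-mask SD (z-scaling); positive
    clusters collect voxels with z >= z_thresh and negative clusters those
    with z <= -z_thresh, under 26-connectivity, discarding components
    smaller than ``cluster_min``.  If an ICV map is given, member voxels
    must additionally satisfy |ICV| >= icv_thresh.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    weights = np.asarray(weights, dtype=float)
    sd = weights.std()
    z = weights / sd if sd > 0 else np.zeros_like(weights)
    z3 = unflatten_to_grid(z, mask)
    reliable = np.ones_like(z3, dtype=bool)
    if icv is not None:
        icv3 = unflatten_to_grid(np.abs(np.asarray(icv, dtype=float)), mask)
        reliable = icv3 >= icv_thresh

    clusters: list[Cluster] = []
    for sign in (+1, -1):
        supra = (sign * z3 >= z_thresh) & mask & reliable
        labeled, n_comp = ndimage.label(supra, structure=_STRUCTURE_26)
        for lab in range(1, n_comp + 1):
            vox = np.argwhere(labeled == lab)
            if vox.shape[0] < cluster_min:
                continue
            vals = z3[tuple(vox.T)]
            peak = vox[np.argmax(np.abs(vals))]
            peak_mm = affine[:3, :3] @ peak + affine[:3, 3]
            clusters.append(Cluster(sign, vox, int(vox.shape[0]),
                                    tuple(int(i) for i in peak),
                                    float(z3[tuple(peak)]),
                                    tuple(float(v) for v in peak_mm)))
    clusters.sort(key=lambda c: (-c.sign, -c.size))
    return ClusterSet(clusters)
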