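"""Image preprocessing: masking, global-mean adjustment, smoothing, and
construction of task-subtraction (LEARN-MOVE) images.

Global adjustment is ratio normalization: each scan is divided by its
in-mask mean, which removes multiplicative scanner/flow nuisances exactly
and fixes the in-mask mean of every adjusted scan at 1.  The default
pipeline order is mask -> adjust -> (optional smooth) -> subtract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cohort import FWHM_TO_SIGMA
from .datatypes import DataMatrix, ScanSet, flatten_in_mask


def apply_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every out-of-mask voxel of one volume or a stack of volumes."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape[-mask.ndim:] != mask.shape:
        raise ValueError("volume and mask shapes do not match")
    if not mask.any():
        raise ValueError("mask is empty")
    return np.where(mask, values, 0.0)


def global_adjust(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide each volume by its in-mask mean (result: in-mask mean 1)."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    inmask = flatten_in_mask(values, mask)
    means = inmask.mean(axis=-1)
    if np.any(means <= 0):
        raise ValueError("global (in-mask) mean must be positive")
    if values.ndim == mask.ndim:
        return values / means
    return values / means[:, None, None, None]


def smooth_gaussian(values: np.ndarray, fwhm_mm: float,
                    voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing with per-axis sigma = FWHM/(2*sqrt(2 ln 2))
    in voxel units; reflect boundary handling conserves mass near edges."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    values = np.asarray(values, dtype=float)
    if fwhm_mm == 0:
        return values.copy()
    sigma = [fwhm_mm * FWHM_TO_SIGMA / v for v in np.atleast_1d(voxel_size_mm)]
    if values.ndim == len(sigma) + 1:
        sigma = [0.0] + sigma
    return gaussian_filter(values, sigma=sigma, mode="reflect")


def preprocess(scans: ScanSet, smooth_fwhm_mm: float = 0.0) -> ScanSet:
    """Mask, globally adjust, and optionally smooth every scan."""
    vols = apply_mask(scans.volumes, scans.mask)
    vols = global_adjust(vols, scans.mask)
    if smooth_fwhm_mm > 0:
        voxel_size = np.abs(np.diag(scans.affine)[:3])
        vols = smooth_gaussian(vols, smooth_fwhm_mm, voxel_size)
        vols = apply_mask(vols, scans.mask)
    return ScanSet(vols, scans.index, scans.mask, scans.affine)


def subtraction_image(learn: np.ndarray, move: np.ndarray,
                      learn_labels: dict | None = None,
                      move_labels: dict | None = None) -> np.ndarray:
    """Voxelwise LEARN - MOVE for one matched scan pair."""
    if learn_labels is not None or move_labels is not None:
        for key in ("subject", "run", "timepoint"):
            if (learn_labels or {}).get(key) != (move_labels or {}).get(key):
                raise ValueError(f"scan pair labels differ on {key!r}")
    learn = np.asarray(learn, dtype=float)
    move = np.asarray(move, dtype=float)
    if learn.shape != move.shape:
        raise ValueError("LEARN and MOVE grids do not match")
    return learn - move


def subtraction_matrix(prepped: ScanSet, group: str | None = None) -> DataMatrix:
    """Pair LEARN with MOVE by (subject, run, timepoint) and stack the
    in-mask subtraction images as rows of a data matrix."""
    idx = prepped.index
    keep = np.ones(len(idx), dtype=bool)
    if group is not None:
        keep &= (idx["group"] == group).to_numpy()
    data = prepped.in_mask()

    def rows_of(cond):
        sel = keep & (idx["condition"] == cond).to_numpy()
        sub = idx.loc[sel, ["subject", "run", "timepoint"]].copy()
        sub["row"] = np.flatnonzero(sel)
        return sub.set_index(["subject", "run", "timepoint"])

    learn, move = rows_of("LEARN"), rows_of("MOVE")
    pairs = learn.join(move, how="inner", lsuffix="_L", rsuffix="_M")
    if pairs.empty:
        raise ValueError("no matched LEARN/MOVE pairs found")
    X = data[pairs["row_L"].to_numpy()] - data[pairs["row_M"].to_numpy()]
    labels = pairs.reset_index()[["subject", "run", "timepoint"]]
    return DataMatrix(X, labels, prepped.mask, prepped.affine)
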