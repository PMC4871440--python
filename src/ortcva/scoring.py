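"""Prospective (forward) pattern-expression scoring.

Once a topography is derived, its expression in any new masked,
globally-adjusted scan is the inner product of the voxel weights with the
scan after removing a fixed reference profile (the mean adjusted control
MOVE image).  Raw scores are z-standardized against the control MOVE
scans, so a z of 0 means "like a control performing the reference task".
The learning-related network response is z(LEARN) - z(MOVE) per subject
and timepoint (runs averaged first); its TP2-TP1 change is the
longitudinal quantity related to disease burden, and the same machinery
applied to REST probes task specificity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import Pattern, ScanSet


def reference_profile(prepped: ScanSet, group: str = "HC",
                      condition: str = "MOVE") -> np.ndarray:
    """Voxelwise mean of the reference group's adjusted scans (over mask)."""
    ref = prepped.select(group=group, condition=condition)
    if ref.n_scans == 0:
        raise ValueError(f"no scans for reference {group}/{condition}")
    return ref.in_mask().mean(axis=0)


def score_scan(pattern: Pattern, volume_in_mask: np.ndarray,
               ref_profile: np.ndarray) -> float:
    """raw score = sum_v weights_v * (volume_v - reference_v)."""
    v = np.asarray(volume_in_mask, dtype=float)
    if v.shape != pattern.weights.shape or v.shape != np.shape(ref_profile):
        raise ValueError("pattern, volume, and reference grids do not match")
    return float(pattern.weights @ (v - ref_profile))


def score_scans(pattern: Pattern, prepped: ScanSet,
                ref_profile: np.ndarray | None = None) -> pd.DataFrame:
    """Raw expression of the pattern in every scan of the set."""
    if ref_profile is None:
        ref_profile = reference_profile(prepped)
    data = prepped.in_mask()
    if data.shape[1] != pattern.weights.shape[0]:
        raise ValueError("pattern and scan voxel sets differ")
    table = prepped.index.copy()
    table["raw_score"] = (data - ref_profile) @ pattern.weights
    return table


def z_standardize(score_table: pd.DataFrame,
                  reference_rows: np.ndarray) -> pd.DataFrame:
    """Anchor all scores to the reference rows: z = (raw - mean_ref)/SD_ref.

    SD uses the n-1 denominator.  After the transform the reference rows
    have mean 0 and SD 1 exactly.
    """
    reference_rows = np.asarray(reference_rows, dtype=bool)
    ref = score_table.loc[reference_rows, "raw_score"].to_numpy(dtype=float)
    if ref.size < 2:
        raise ValueError("need at least two reference rows")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("reference scores have zero standard deviation")
    out = score_table.copy()
    out["z_score"] = (out["raw_score"] - ref.mean()) / sd
    return out


def standardized_scores(pattern: Pattern, prepped: ScanSet,
                        ref_group: str = "HC",
                        ref_condition: str = "MOVE") -> pd.DataFrame:
    """Score every scan and z-anchor on the reference group/condition."""
    profile = reference_profile(prepped, ref_group, ref_condition)
    table = score_scans(pattern, prepped, profile)
    ref_rows = ((table["group"] == ref_group)
                & (table["condition"] == ref_condition)).to_numpy()
    return z_standardize(table, ref_rows)


def learning_response(score_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject learning responses and longitudinal deltas.

    Returns one row per subject with run-averaged z(LEARN) - z(MOVE) per
    timepoint (``response_tp{t}``), ``delta_learning`` (TP2 - TP1), the
    REST z per timepoint, and ``delta_rest``.  A condition absent for a
    subject/timepoint yields a missing value, never zero.
    """
    if "z_score" not in score_table.columns:
        raise ValueError("scores must be z-standardized first")
    mean = (score_table
            .groupby(["subject", "group", "timepoint", "condition"],
                     sort=False)["z_score"].mean()
            .unstack("condition"))
    for cond in ("LEARN", "MOVE", "REST"):
        if cond not in mean.columns:
            mean[cond] = np.nan
    mean["response"] = mean["LEARN"] - mean["MOVE"]
    wide = mean[["response", "REST"]].unstack("timepoint")

    out = pd.DataFrame(index=wide.index)
    tps = sorted({tp for _, tp in wide.columns})
    for tp in tps:
        out[f"response_tp{tp}"] = wide[("response", tp)]
        out[f"rest_tp{tp}"] = wide[("REST", tp)]
    if len(tps) >= 2:
        first, last = tps[0], tps[-1]
        out["delta_learning"] = (out[f"response_tp{last}"]
                                 - out[f"response_tp{first}"])
        out["delta_rest"] = out[f"rest_tp{last}"] - out[f"rest_tp{first}"]
    return out.reset_index()
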