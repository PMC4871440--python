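"""Post-hoc regional analysis at network-cluster peaks.

A small sphere (default 5 mm) is centered at the peak voxel of each
network region; regional values are means of the globally-adjusted LEARN
and MOVE scans over the sphere.  The learning-related regional response is
LEARN - MOVE per scan pair; its TP2 - TP1 change per carrier is
correlated (Spearman) with baseline years-to-onset, with no correction
for multiple comparisons across regions (raw p-values are reported).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .behavior import spearman
from .cohort import voxel_centers_mm
from .datatypes import ScanSet
from .inference import ClusterSet


@dataclasses.dataclass
class SphereVOI:
    center_mm: tuple[float, float, float]
    radius_mm: float
    member_voxels: np.ndarray  # (n, 3) voxel indices

    @property
    def size(self) -> int:
        return self.member_voxels.shape[0]


def sphere_voxels(center_mm, radius_mm: float, affine: np.ndarray,
                  mask: np.ndarray) -> SphereVOI:
    """Voxels whose centers lie within ``radius_mm`` of ``center_mm``
    (boundary inclusive), intersected with the mask."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    centers = voxel_centers_mm(mask.shape, affine)
    d2 = np.sum((centers - np.asarray(center_mm, dtype=float)) ** 2, axis=-1)
    inside = (d2 <= float(radius_mm) ** 2) & mask
    members = np.argwhere(inside)
    if members.shape[0] == 0:
        raise ValueError("sphere contains no in-mask voxels")
    return SphereVOI(tuple(float(c) for c in np.atleast_1d(center_mm)),
                     float(radius_mm), members)


def voi_mean(voi: SphereVOI, volume: np.ndarray) -> float:
    """Mean of one 3-D volume over the sphere members."""
    volume = np.asarray(volume, dtype=float)
    idx = tuple(voi.member_voxels.T)
    try:
        return float(volume[idx].mean())
    except IndexError as exc:
        raise ValueError("VOI does not fit the volume grid") from exc


def regional_response(voi: SphereVOI, learn_volume: np.ndarray,
                      move_volume: np.ndarray) -> float:
    """VOI mean of LEARN minus VOI mean of MOVE (volumes already adjusted)."""
    return voi_mean(voi, learn_volume) - voi_mean(voi, move_volume)


def regional_table(vois: dict[str, SphereVOI], prepped: ScanSet) -> pd.DataFrame:
    """Learning-related responses per region x subject x run x timepoint."""
    rows = []
    idx = prepped.index
    move_row = {(r.subject, r.run, r.timepoint): i
                for i, r in idx.iterrows() if r.condition == "MOVE"}
    learn = idx[idx["condition"] == "LEARN"]
    for i, row in learn.iterrows():
        key = (row["subject"], row["run"], row["timepoint"])
        if key not in move_row:
            continue
        j_row = move_row[key]
        for name, voi in vois.items():
            learn_val = voi_mean(voi, prepped.volumes[i])
            move_val = voi_mean(voi, prepped.volumes[j_row])
            rows.append({"region": name, "subject": row["subject"],
                         "group": row["group"], "run": row["run"],
                         "timepoint": row["timepoint"],
                         "rcbf_learn": learn_val, "rcbf_move": move_val,
                         "response": learn_val - move_val})
    return pd.DataFrame(rows)


def regional_longitudinal(table: pd.DataFrame,
                          subject_table: pd.DataFrame) -> pd.DataFrame:
    """Per-region longitudinal change of the learning response and its
    Spearman correlation with baseline YTO across gene carriers.

    Subjects missing a timepoint in a region are excluded from that
    region's correlation; the exclusion count is reported.  A constant
    delta vector yields an undefined (missing) correlation, not zero.
    """
    yto = subject_table.set_index("subject")["yto"]
    out = []
    for region, grp in table.groupby("region", sort=False):
        wide = (grp.groupby(["subject", "timepoint"])["response"]
                .mean().unstack("timepoint"))
        tps = sorted(wide.columns)
        if len(tps) < 2:
            raise ValueError("regional correlation needs two timepoints")
        delta = (wide[tps[-1]] - wide[tps[0]]).dropna()
        n_excluded = wide.shape[0] - delta.shape[0]
        subj_yto = yto.reindex(delta.index)
        ok = subj_yto.notna()
        delta, subj_yto = delta[ok], subj_yto[ok]
        if delta.size >= 3 and np.unique(delta).size >= 2:
            rho, p = spearman(delta.to_numpy(), subj_yto.to_numpy())
        else:
            rho, p = float("nan"), float("nan")
        out.append({"region": region, "n": int(delta.size),
                    "n_excluded": int(n_excluded),
                    "mean_delta": float(delta.mean()) if delta.size else np.nan,
                    "rho_yto": rho, "p_yto": p,
                    "rho_burden": -rho if np.isfinite(rho) else rho})
    return pd.DataFrame(out)


def vois_from_clusters(clusters: ClusterSet, affine: np.ndarray,
                       mask: np.ndarray, radius_mm: float = 5.0
                       ) -> dict[str, SphereVOI]:
    """One sphere per cluster peak, named by sign and rank."""
    vois = {}
    counters = {+1: 0, -1: 0}
    for c in clusters.clusters:
        counters[c.sign] += 1
        tag = "pos" if c.sign > 0 else "neg"
        vois[f"{tag}{counters[c.sign]}"] = sphere_voxels(
            c.peak_mm, radius_mm, affine, mask)
    return vois
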