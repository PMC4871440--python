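"""End-to-end orchestration: simulate -> preprocess -> derive -> validate
-> bootstrap -> score -> regional -> behavioral report."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, cohort, inference, prep, regional, scoring
from .core import derive_composite, max_tolerated_violators
from .datatypes import ScanSet, ensure_burden, save_subject_table

log = logging.getLogger("ortcva")


@dataclasses.dataclass
class PipelineConfig:
    """Run-level settings; defaults reproduce the analysis conventions
    (two-sided 5% ICV gate, one-sided 1% voxel-weight threshold, 100-voxel
    cluster cutoff, 5 mm spheres, YTO split at 11 y, 1000 resamples)."""

    cohort: cohort.CohortConfig = dataclasses.field(
        default_factory=cohort.CohortConfig)
    n_iter: int = 1000
    z_thresh: float | None = None       # default: critical_value(0.01, one)
    icv_thresh: float | None = None     # default: critical_value(0.05, two)
    cluster_min: int = 100
    voi_radius_mm: float = 5.0
    yto_cut: float = 11.0
    max_k: int = 5
    seed: int = 0

    def resolved_z_thresh(self) -> float:
        return (self.z_thresh if self.z_thresh is not None
                else inference.critical_value(0.01, "one"))

    def resolved_icv_thresh(self) -> float:
        return (self.icv_thresh if self.icv_thresh is not None
                else inference.critical_value(0.05, "two"))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def full_run(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage on a synthetic cohort and return the summary report.

    If ``out_dir`` is given, stage artifacts (NIfTI volumes, TSV tables,
    summary JSON) are written there.
    """
    cc = dataclasses.replace(config.cohort, seed=config.seed)
    log.info("simulate: grid=%s n_phd=%d n_hc=%d seed=%d",
             cc.grid_shape, cc.n_phd, cc.n_hc, cc.seed)
    true_pattern = cohort.make_true_pattern(
        cc.grid_shape, cc.voxel_size_mm,
        cohort.default_clusters(cc.grid_shape, cc.voxel_size_mm))
    scans, subjects = cohort.generate_cohort(cc, true_pattern)
    subjects = ensure_burden(subjects)

    log.info("preprocess: mask -> global adjust")
    prepped = prep.preprocess(scans)
    dm = prep.subtraction_matrix(prepped, group="pHD")

    log.info("derive: OrT/CVA composite, max_k=%d", config.max_k)
    composite = derive_composite(dm, subjects, max_k=config.max_k)

    log.info("validate: permutation test, n_iter=%d", config.n_iter)
    perm = inference.permutation_test(dm, subjects, n_iter=config.n_iter,
                                      seed=config.seed + 1, max_k=config.max_k)

    log.info("bootstrap: ICV, n_iter=%d", config.n_iter)
    icv = inference.bootstrap_icv(dm, subjects, n_iter=max(config.n_iter, 2),
                                  seed=config.seed + 2, max_k=config.max_k)

    z_thr, icv_thr = config.resolved_z_thresh(), config.resolved_icv_thresh()
    clusters = inference.threshold_clusters(
        composite.weights, dm.mask, dm.affine, z_thr,
        config.cluster_min, icv=icv.icv, icv_thresh=icv_thr)
    log.info("clusters: %d at z>=%.2f, size>=%d, |ICV|>=%.2f",
             len(clusters), z_thr, config.cluster_min, icv_thr)

    log.info("score: forward expression, z-anchored on control MOVE")
    scores = scoring.standardized_scores(composite.as_pattern(), prepped)
    responses = scoring.learning_response(scores)
    phd_resp = responses[responses["group"] == "pHD"].set_index("subject")
    merged = phd_resp.join(subjects.set_index("subject")[["yto", "burden"]])
    rho_b, p_b = behavior.spearman(merged["delta_learning"], merged["burden"])
    rho_y, p_y = behavior.spearman(merged["delta_learning"], merged["yto"])

    log.info("regional: %d VOIs, radius %.1f mm", len(clusters),
             config.voi_radius_mm)
    vois = regional.vois_from_clusters(clusters, dm.affine, dm.mask,
                                       config.voi_radius_mm)
    if vois:
        reg_table = regional.regional_table(vois, prepped.select(group="pHD"))
        reg_long = regional.regional_longitudinal(reg_table, subjects)
    else:
        reg_table = pd.DataFrame()
        reg_long = pd.DataFrame()

    log.info("behav: group splits and summaries")
    onset = behavior.classify_onset(subjects, config.yto_cut)
    learners = behavior.classify_learners(subjects)
    lab = learners.reindex(phd_resp.index)
    deltas = phd_resp["delta_learning"]
    ok = deltas.notna() & lab.notna()
    if ok.sum() >= 4 and lab[ok].nunique() == 2:
        F, df1, df2, p_f = behavior.interaction_f(lab[ok].to_numpy(),
                                                  deltas[ok].to_numpy())
    else:
        F = df1 = df2 = p_f = float("nan")

    report = {
        "config": {"n_iter": config.n_iter, "z_thresh": z_thr,
                   "icv_thresh": icv_thr, "cluster_min": config.cluster_min,
                   "voi_radius_mm": config.voi_radius_mm,
                   "yto_cut": config.yto_cut, "max_k": config.max_k,
                   "seed": config.seed},
        "derivation": {"k": composite.k, "aic_path": composite.aic_path,
                       "r2_yto": composite.r2_yto,
                       "violators": composite.violators,
                       "max_tolerated_violators": max_tolerated_violators(
                           len(composite.delta_scores)),
                       "delta_scores": composite.delta_scores,
                       "cosine_with_true_pattern": composite.as_pattern()
                       .cosine(true_pattern.as_pattern())},
        "permutation": {"observed_r2": perm.observed_r2,
                        "p_value": perm.p_value, "n_iter": perm.n_iter},
        "clusters": clusters.to_frame().to_dict(orient="records"),
        "expression": {
            "delta_learning_vs_burden": {"rho": rho_b, "p": p_b},
            "delta_learning_vs_yto": {"rho": rho_y, "p": p_y},
            "mean_delta_rest_phd": float(phd_resp["delta_rest"].mean()),
            "group_means": responses.groupby("group")[
                [c for c in responses.columns
                 if c.startswith(("response", "delta"))]]
            .mean().to_dict(),
        },
        "regional": reg_long.to_dict(orient="records"),
        "behavior": {
            "onset_groups": onset.value_counts().to_dict(),
            "learner_groups": learners.value_counts().to_dict(),
            "interaction_f": {"F": F, "df": [df1, df2], "p": p_f},
        },
    }
    report = _jsonable(report)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.write_cohort(out_dir, scans, subjects, true_pattern)
        composite.as_pattern().to_nifti(out_dir / "pattern.nii.gz")
        clusters.to_frame().to_csv(out_dir / "clusters.tsv", sep="\t",
                                   index=False)
        scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
        responses.to_csv(out_dir / "responses.tsv", sep="\t", index=False)
        if not reg_long.empty:
            reg_long.to_csv(out_dir / "regional.tsv", sep="\t", index=False)
        (out_dir / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
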