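"""Within-subject centering, PCA, subject scores, AIC model selection, and
the burden-fitted composite."""

import numpy as np
import pandas as pd
import pytest

from ortcva import DataMatrix, center_within_subject, derive_composite, \
    fit_composite, pca, subject_scores
from ortcva.core import PCSet, count_violators, max_tolerated_violators, \
    ols_aic

MASK2 = np.zeros((2, 1, 1), dtype=bool)
MASK2[:, 0, 0] = True
AFF = np.eye(4)


def _dm(X, subjects, timepoints, runs=None):
    X = np.asarray(X, dtype=float)
    nvox = X.shape[1]
    mask = np.zeros((nvox, 1, 1), dtype=bool)
    mask[:, 0, 0] = True
    idx = pd.DataFrame({"subject": subjects,
                        "run": runs or [1] * len(subjects),
                        "timepoint": timepoints})
    return DataMatrix(X, idx, mask, AFF)


class TestCentering:
    def test_two_row_subject_splits_the_difference(self):
        a, b = np.array([3.0, 1.0]), np.array([1.0, 5.0])
        dm = _dm([a, b], ["s1", "s1"], [1, 2])
        out = center_within_subject(dm)
        assert np.allclose(out.X[0], (a - b) / 2)
        assert np.allclose(out.X[1], (b - a) / 2)

    def test_constant_offset_per_subject_is_removed(self, rng):
        X = rng.normal(size=(4, 5))
        dm = _dm(X, ["s1", "s1", "s2", "s2"], [1, 2, 1, 2])
        shifted = X.copy()
        shifted[:2] += 7.5
        dm2 = _dm(shifted, ["s1", "s1", "s2", "s2"], [1, 2, 1, 2])
        assert np.allclose(center_within_subject(dm).X,
                           center_within_subject(dm2).X)

    def test_idempotent(self, rng):
        X = rng.normal(size=(4, 5))
        dm = _dm(X, ["s1", "s1", "s2", "s2"], [1, 2, 1, 2])
        once = center_within_subject(dm)
        twice = center_within_subject(once)
        assert np.allclose(once.X, twice.X)

    def test_single_row_subject_rejected(self, rng):
        dm = _dm(rng.normal(size=(3, 4)), ["s1", "s1", "s2"], [1, 2, 1])
        with pytest.raises(ValueError, match="single row"):
            center_within_subject(dm)


class TestPCA:
    def test_rank_one_matrix(self):
        v = np.array([1.0, 2.0, 2.0])
        X = np.outer([1.0, -1.0], v)
        dm = _dm(X, ["s1", "s1"], [1, 2])
        with pytest.warns(UserWarning):
            pcs = pca(dm, n_keep=2)
        assert pcs.n_components == 1
        assert np.isclose(abs(pcs.components[0] @ (v / np.linalg.norm(v))), 1.0)

    def test_two_by_two_closed_form(self):
        """[[1,0],[-1,0]]: single component (+-1, 0) with eigenvalue
        (sqrt(2))^2 / (2-1) = 2, matching the 2x2 eigendecomposition of
        X^T X done by hand."""
        dm = _dm([[1.0, 0.0], [-1.0, 0.0]], ["s1", "s1"], [1, 2])
        pcs = pca(dm)
        assert pcs.n_components == 1
        assert np.allclose(np.abs(pcs.components[0]), [1.0, 0.0])
        assert np.isclose(pcs.eigenvalues[0], 2.0)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(6, 10))
        X -= X.mean(axis=0)
        dm = _dm(X, ["s%d" % (i // 2) for i in range(6)], [1, 2] * 3)
        pcs = pca(dm)
        recon = pcs.scores @ pcs.components
        assert np.allclose(recon, X, atol=1e-8)

    def test_components_orthonormal_and_eigenvalues_sorted(self, planted_dm):
        pcs = pca(center_within_subject(planted_dm), n_keep=5)
        gram = pcs.components @ pcs.components.T
        assert np.allclose(gram, np.eye(5), atol=1e-10)
        assert np.all(np.diff(pcs.eigenvalues) <= 1e-12)


class TestSubjectScores:
    def test_zero_pattern_scores_zero(self, rng):
        dm = _dm(rng.normal(size=(2, 4)), ["s1", "s1"], [1, 2])
        out = subject_scores(np.zeros(4), dm)
        assert np.allclose(out["score"], 0.0)

    def test_unit_norm_self_projection_is_one(self):
        row = np.array([0.6, 0.8])
        dm = _dm([row, -row], ["s1", "s1"], [1, 2])
        out = subject_scores(row, dm)
        assert np.isclose(out["score"][0], 1.0)

    def test_linearity_in_pattern(self, rng):
        dm = _dm(rng.normal(size=(2, 4)), ["s1", "s1"], [1, 2])
        w = rng.normal(size=4)
        assert np.allclose(subject_scores(2 * w, dm)["score"],
                           2 * subject_scores(w, dm)["score"])

    def test_voxel_mismatch_rejected(self, rng):
        dm = _dm(rng.normal(size=(2, 4)), ["s1", "s1"], [1, 2])
        with pytest.raises(ValueError):
            subject_scores(np.ones(5), dm)


class TestViolators:
    @pytest.mark.parametrize("deltas,expected", [
        ([1.0, 2.0, 0.5], 0),
        ([-1.0, -2.0, -0.5], 3),
        ([1.0, -0.1, 1.0], 1),
    ])
    def test_counting(self, deltas, expected):
        rows = []
        for i, d in enumerate(deltas):
            rows.append({"subject": f"s{i}", "timepoint": 1, "score": 0.0})
            rows.append({"subject": f"s{i}", "timepoint": 2, "score": d})
        assert count_violators(pd.DataFrame(rows)) == expected

    def test_missing_timepoint_rejected(self):
        df = pd.DataFrame([{"subject": "s0", "timepoint": 1, "score": 0.0},
                           {"subject": "s1", "timepoint": 1, "score": 0.0},
                           {"subject": "s1", "timepoint": 2, "score": 1.0}])
        with pytest.raises(ValueError):
            count_violators(df)

    def test_binomial_tolerance_at_n10(self):
        # 1 of 10 rejects at 5% two-sided (p=0.021); 2 of 10 does not (0.109)
        assert max_tolerated_violators(10) == 1


class TestOlsAic:
    def test_perfect_fit_flagged(self):
        coef, rss, aic = ols_aic(np.array([1.0, 2.0, 3.0, 4.0]),
                                 np.array([[1.0], [2.0], [3.0], [4.0]]))
        assert rss < 1e-12
        assert aic == -np.inf

    def test_matches_hand_normal_equations(self):
        """y=[1,2,3,5] on x=[1..4]: slope 1.3, intercept -0.5, RSS 0.30 from
        the normal equations worked by hand."""
        y = np.array([1.0, 2.0, 3.0, 5.0])
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        coef, rss, aic = ols_aic(y, X)
        assert np.allclose(coef, [-0.5, 1.3])
        assert np.isclose(rss, 0.30)
        assert np.isclose(aic, 4 * np.log(0.30 / 4) + 2 * 3)

    def test_collinear_design_rejected(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(ValueError, match="collinear"):
            ols_aic(y, X)

    def test_noise_predictor_raises_aic_on_average(self, rng):
        """Adding a pure-noise column to an adequate model increases AIC in
        the mean over replicates (simulation oracle)."""
        diffs = []
        for _ in range(200):
            x = rng.normal(size=12)
            y = x + 0.3 * rng.normal(size=12)
            noise = rng.normal(size=12)
            _, _, aic1 = ols_aic(y, x[:, None])
            _, _, aic2 = ols_aic(y, np.column_stack([x, noise]))
            diffs.append(aic2 - aic1)
        assert np.mean(diffs) > 0


class TestComposite:
    def test_perfect_single_pc_selected(self):
        """A PC whose score change equals burden exactly: k=1, r2=1."""
        nvox = 6
        comp = np.zeros((1, nvox))
        comp[0, 0] = 1.0
        burden = {"s0": 1.0, "s1": 3.0, "s2": 2.0, "s3": 5.0}
        rows, scores = [], []
        for s, b in burden.items():
            rows += [{"subject": s, "run": 1, "timepoint": 1},
                     {"subject": s, "run": 1, "timepoint": 2}]
            scores += [[0.0], [b]]
        mask = np.zeros((nvox, 1, 1), dtype=bool)
        mask[:, 0, 0] = True
        pcs = PCSet(comp, np.array([1.0]), np.array(scores),
                    pd.DataFrame(rows), mask, AFF)
        table = pd.DataFrame({"subject": list(burden), "group": "pHD",
                              "burden": list(burden.values())})
        fitted = fit_composite(pcs, table, max_k=1)
        assert fitted.k == 1
        assert np.isclose(fitted.r2_yto, 1.0)
        assert fitted.violators == 0

    def test_planted_cohort_recovery(self, planted_composite, true_pattern):
        cos = planted_composite.as_pattern().cosine(true_pattern.as_pattern())
        assert abs(cos) >= 0.9

    def test_sign_convention_mean_delta_nonnegative(self, planted_composite):
        assert planted_composite.delta_scores.mean() >= 0

    def test_composite_score_is_linear_in_pc_scores(self, planted_dm,
                                                    planted_cohort,
                                                    planted_composite):
        centered = center_within_subject(planted_dm)
        pcs = pca(centered, n_keep=5)
        direct = centered.X @ planted_composite.weights
        via_pcs = pcs.scores[:, :planted_composite.k] \
            @ planted_composite.pc_coefficients
        assert np.allclose(direct, via_pcs, atol=1e-10)

    def test_invariant_to_common_positive_scaling(self, planted_cohort):
        from ortcva import prep
        scans, table = planted_cohort
        scaled = type(scans)(scans.volumes * 3.7, scans.index, scans.mask,
                             scans.affine)
        dm1 = prep.subtraction_matrix(prep.preprocess(scans), group="pHD")
        dm2 = prep.subtraction_matrix(prep.preprocess(scaled), group="pHD")
        c1 = derive_composite(dm1, table)
        c2 = derive_composite(dm2, table)
        assert np.allclose(c1.weights, c2.weights, atol=1e-10)
        assert c1.k == c2.k

    def test_shuffled_burden_r2_matches_null_simulation(self, planted_dm,
                                                        planted_cohort, rng):
        """With burden randomly permuted, the AIC-selected r2 should match
        an independent simulation of the same selection on pure-noise
        regressions within Monte-Carlo error."""
        _, table = planted_cohort
        phd = table[table["group"] == "pHD"].reset_index(drop=True)
        n = len(phd)
        centered = center_within_subject(planted_dm)
        pcs = pca(centered, n_keep=5)
        r2_pipeline = []
        for _ in range(200):
            shuf = phd.copy()
            shuf["burden"] = rng.permutation(shuf["burden"].to_numpy())
            r2_pipeline.append(fit_composite(pcs, shuf, max_k=5).r2_yto)

        # independent oracle: same AIC selection on iid Gaussian designs
        r2_null = []
        for _ in range(200):
            y = rng.normal(size=n)
            X = rng.normal(size=(n, 5))
            best_aic, best_r2 = np.inf, np.nan
            for k in range(1, 6):
                design = np.column_stack([np.ones(n), X[:, :k]])
                beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
                rss = float(np.sum((y - design @ beta) ** 2))
                aic = n * np.log(rss / n) + 2 * (k + 2)
                if aic < best_aic:
                    best_aic, best_r2 = aic, 1 - rss / np.sum((y - y.mean()) ** 2)
            r2_null.append(best_r2)
        se = np.sqrt(np.var(r2_pipeline) / 200 + np.var(r2_null) / 200)
        assert abs(np.mean(r2_pipeline) - np.mean(r2_null)) < 4 * se + 0.02

    def test_max_k_capped_for_tiny_cohorts(self, rng):
        nvox, subs = 8, ["a", "b", "c", "d"]
        rows, data = [], []
        for s in subs:
            for tp in (1, 2):
                for run in (1, 2):
                    rows.append({"subject": s, "run": run, "timepoint": tp})
                    data.append(rng.normal(size=nvox))
        dm = _dm(np.array(data), [r["subject"] for r in rows],
                 [r["timepoint"] for r in rows], [r["run"] for r in rows])
        table = pd.DataFrame({"subject": subs, "group": "pHD",
                              "burden": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="capping"):
            comp = derive_composite(dm, table, max_k=5)
        assert comp.k <= 1
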