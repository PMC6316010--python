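import numpy as np
import pandas as pd
import pytest

from conftest import make_feature_matrix
from vocdx.classify import ScoreSet
from vocdx.evaluate import (
    REPORT_COLUMNS,
    bootstrap_ci,
    build_report,
    operating_point,
    project_lda,
    project_pca,
    read_report,
    roc_auc,
    roc_points,
    score_pvalue,
    write_report,
)


def scoreset(case_scores, control_scores):
    case_scores = list(case_scores)
    control_scores = list(control_scores)
    n = len(case_scores) + len(control_scores)
    return ScoreSet(
        sample_ids=[f"s{i}" for i in range(n)],
        scores=np.array(case_scores + control_scores, dtype=float),
        labels=np.array(
            ["case"] * len(case_scores) + ["control"] * len(control_scores), dtype=object
        ),
    )


def brute_force_auc(case, control):
    wins = sum(
        1.0 if c > k else (0.5 if c == k else 0.0) for c in case for k in control
    )
    return wins / (len(case) * len(control))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(scoreset([2, 3, 4], [0, 1])) == 1.0

    def test_three_of_four_concordant(self):
        assert roc_auc(scoreset([0.35, 0.8], [0.1, 0.4])) == 0.75

    def test_all_ties_is_half(self):
        assert roc_auc(scoreset([1, 1, 1], [1, 1])) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 26, size=2)
        case = rng.integers(0, 10, size=n1).astype(float)  # ints force ties
        control = rng.integers(0, 10, size=n2).astype(float)
        assert roc_auc(scoreset(case, control)) == pytest.approx(
            brute_force_auc(case, control)
        )

    def test_label_swap_complements(self):
        rng = np.random.default_rng(3)
        case, control = rng.normal(size=8), rng.normal(size=6)
        assert roc_auc(scoreset(case, control)) == pytest.approx(
            1.0 - roc_auc(scoreset(control, case))
        )

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(4)
        case, control = rng.normal(size=9), rng.normal(size=7)
        base = roc_auc(scoreset(case, control))
        assert roc_auc(scoreset(np.exp(case), np.exp(control))) == pytest.approx(base)

    def test_single_class_rejected(self):
        ss = ScoreSet(["a"], np.array([1.0]), np.array(["case"], dtype=object))
        with pytest.raises(ValueError, match="class"):
            roc_auc(ss)


class TestOperatingPoint:
    def test_confusion_arithmetic(self):
        # engineered so threshold 0.5 gives TP=9 FN=1 TN=8 FP=2
        ss = scoreset([0.9] * 9 + [0.1], [0.8] * 2 + [0.2] * 8)
        op = operating_point(ss, rule=0.5)
        assert (op.tp, op.fn, op.tn, op.fp) == (9, 1, 8, 2)
        assert op.sensitivity == pytest.approx(0.9)
        assert op.specificity == pytest.approx(0.8)
        assert op.ppv == pytest.approx(9 / 11)
        assert op.npv == pytest.approx(8 / 9)

    def test_perfect_separation_all_ones(self):
        op = operating_point(scoreset([5, 6, 7], [1, 2]))
        assert (op.sensitivity, op.specificity, op.ppv, op.npv) == (1, 1, 1, 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_youden_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        ss = scoreset(rng.normal(0.5, 1, 12), rng.normal(0, 1, 10))
        op = operating_point(ss, rule="youden")
        y = ss.y()
        best_j = max(
            (np.mean(ss.scores[y == 1] >= t) + np.mean(ss.scores[y == 0] < t) - 1.0)
            for t in np.concatenate([ss.scores, [np.inf]])
        )
        assert op.sensitivity + op.specificity - 1.0 == pytest.approx(best_j)

    def test_metrics_match_stored_confusion(self):
        ss = scoreset([0.9, 0.3, 0.7], [0.2, 0.6])
        op = operating_point(ss)
        assert op.sensitivity == op.tp / (op.tp + op.fn)
        assert op.specificity == op.tn / (op.tn + op.fp)

    def test_empty_positive_cell_gives_nan_ppv(self):
        op = operating_point(scoreset([1, 2], [0, 1]), rule=np.inf)
        assert np.isnan(op.ppv)


class TestBootstrap:
    def test_degenerate_interval(self):
        ss = scoreset([1.0] * 5, [0.0] * 5)
        assert bootstrap_ci(ss, "auc", n_boot=200, seed=0) == (1.0, 1.0)

    @pytest.mark.parametrize("metric", ["auc", "sensitivity", "specificity"])
    def test_contains_point_estimate(self, metric):
        rng = np.random.default_rng(5)
        ss = scoreset(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        lo, hi = bootstrap_ci(ss, metric, n_boot=400, seed=1)
        from vocdx.evaluate import _metric_value

        point = _metric_value(metric, ss)
        assert lo <= point + 1e-12 and point - 1e-12 <= hi

    def test_width_shrinks_with_n(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            small = scoreset(rng.normal(0.5, 1, 10), rng.normal(0, 1, 10))
            big = scoreset(rng.normal(0.5, 1, 100), rng.normal(0, 1, 100))
            w_small = np.diff(bootstrap_ci(small, "auc", n_boot=300, seed=seed))[0]
            w_big = np.diff(bootstrap_ci(big, "auc", n_boot=300, seed=seed))[0]
            wins += w_big < w_small
        assert wins >= 4

    def test_min_resamples_enforced(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(scoreset([1], [0]), "auc", n_boot=50)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        ss = scoreset(rng.normal(1, 1, 10), rng.normal(0, 1, 10))
        assert bootstrap_ci(ss, "auc", n_boot=200, seed=3) == bootstrap_ci(
            ss, "auc", n_boot=200, seed=3
        )


class TestScorePvalue:
    def test_identical_distributions_near_one(self):
        assert score_pvalue(scoreset([1, 2, 3], [1, 2, 3])) > 0.8

    def test_separated_small_groups_exact(self):
        assert score_pvalue(scoreset([4, 5, 6], [1, 2, 3])) == pytest.approx(0.1)

    def test_agreement_with_auc_significance(self):
        # p < 0.05 should track the bootstrap AUC CI excluding 0.5
        agree = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            shift = 1.2 if seed % 2 else 0.0
            ss = scoreset(rng.normal(shift, 1, 15), rng.normal(0, 1, 15))
            p = score_pvalue(ss)
            lo, hi = bootstrap_ci(ss, "auc", n_boot=400, seed=seed)
            agree += (p < 0.05) == (lo > 0.5 or hi < 0.5)
        assert agree >= 8


class TestRocPoints:
    def test_curve_starts_origin_ends_corner(self):
        rng = np.random.default_rng(7)
        ss = scoreset(rng.normal(1, 1, 8), rng.normal(0, 1, 8))
        pts = roc_points(ss)
        assert (pts.iloc[0].fpr, pts.iloc[0].tpr) == (0.0, 0.0)
        assert (pts.iloc[-1].fpr, pts.iloc[-1].tpr) == (1.0, 1.0)
        assert pts.fpr.is_monotonic_increasing


class TestProjections:
    def test_pca_line_explains_everything(self):
        t = np.linspace(0, 1, 30)
        X = np.c_[2 * t, -3 * t] + 0.0001 * np.random.default_rng(0).normal(size=(30, 2))
        fm = make_feature_matrix(X)
        coords = project_pca(fm, 2)
        var = coords.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_duplicated_rows_coincide(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        X[5] = X[2]
        coords = project_pca(make_feature_matrix(X), 3)
        assert np.allclose(coords[5], coords[2])

    def test_full_components_preserve_geometry(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 5))
        coords = project_pca(make_feature_matrix(X), 5)
        centered = X - X.mean(axis=0)
        # orthonormal full projection preserves norms <=> zero reconstruction error
        assert np.allclose(
            np.linalg.norm(coords, axis=1), np.linalg.norm(centered, axis=1)
        )

    def test_pca_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        a = project_pca(make_feature_matrix(X), 2)
        b = project_pca(make_feature_matrix(X.copy()), 2)
        assert np.allclose(a, b)

    def test_lda_separates_blobs(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(8, 1, (25, 3))])
        fm = make_feature_matrix(X, ["case"] * 25 + ["control"] * 25)
        coords = project_lda(fm)[:, 0]
        case, control = coords[:25], coords[25:]
        pooled_sd = np.sqrt((case.var() + control.var()) / 2)
        assert abs(case.mean() - control.mean()) > 5 * pooled_sd

    def test_lda_null_separation_small(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 3))
            fm = make_feature_matrix(X, ["case"] * 20 + ["control"] * 20)
            coords = project_lda(fm)[:, 0]
            case, control = coords[:20], coords[20:]
            pooled_sd = np.sqrt((case.var() + control.var()) / 2)
            hits += abs(case.mean() - control.mean()) < 2.0 * pooled_sd
        assert hits >= 9

    def test_lda_collinear_features_ok(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(20, 1))
        X = np.hstack([base, base, base])  # fully collinear
        fm = make_feature_matrix(X, ["case"] * 10 + ["control"] * 10)
        coords = project_lda(fm)
        assert np.all(np.isfinite(coords))


class TestReport:
    def test_single_family_one_row(self):
        rng = np.random.default_rng(6)
        ss = scoreset(rng.normal(2, 1, 12), rng.normal(0, 1, 12))
        table = build_report({"svm": ss}, n_boot=200, seed=0)
        assert len(table) == 1
        assert list(table.columns) == REPORT_COLUMNS
        row = table.iloc[0]
        assert row.auc_lo <= row.auc <= row.auc_hi
        assert 0 <= row.p_value <= 1

    def test_round_trip_through_csv(self, tmp_path):
        rng = np.random.default_rng(7)
        table = build_report(
            {
                "a": scoreset(rng.normal(1, 1, 10), rng.normal(0, 1, 10)),
                "b": scoreset(rng.normal(1, 1, 10), rng.normal(0, 1, 10)),
            },
            n_boot=150,
            seed=1,
        )
        write_report(table, tmp_path / "report.csv")
        back = read_report(tmp_path / "report.csv")
        pd.testing.assert_frame_equal(table, back)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_report({})
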