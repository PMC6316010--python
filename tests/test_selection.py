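from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from conftest import make_feature_matrix
from vocdx.selection import (
    SelectionResult,
    boruta_select,
    rank_sum_pvalues,
    select_top_k,
    wilcoxon_rank,
)


def permutation_pvalue(x, y):
    """Independent oracle: full enumeration of group assignments, rank-sum
    statistic with midranks, two-sided p = 2 * min tail (capped at 1)."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    observed = ranks[:n1].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(n), n1)]
    sums = np.asarray(sums)
    eps = 1e-9
    lo = np.mean(sums <= observed + eps)
    hi = np.mean(sums >= observed - eps)
    return min(1.0, 2.0 * min(lo, hi))


class TestRankSum:
    def test_fully_separated_small_groups_exact(self):
        # all 20 assignments enumerable; both extreme tails = 2/20
        p = rank_sum_pvalues(np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]]))
        assert p[0] == pytest.approx(0.1)

    def test_constant_feature_p_is_one(self):
        g1 = np.full((5, 1), 2.0)
        g2 = np.full((6, 1), 2.0)
        assert rank_sum_pvalues(g1, g2)[0] == 1.0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("sizes", [(4, 4), (5, 3), (8, 8)])
    def test_matches_permutation_enumeration(self, seed, sizes):
        rng = np.random.default_rng(seed)
        n1, n2 = sizes
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        ours = rank_sum_pvalues(x[:, None], y[:, None])[0]
        assert abs(ours - permutation_pvalue(x, y)) <= 0.02

    @pytest.mark.parametrize("seed", range(8))
    def test_ties_use_standard_corrected_approximation(self, seed):
        # heavy ties force the tie-corrected normal path; it should agree with
        # the reference asymptotic implementation and stay within the
        # approximation's known accuracy of the exact enumeration
        rng = np.random.default_rng(100 + seed)
        x = rng.integers(0, 4, size=7).astype(float)
        y = rng.integers(0, 4, size=7).astype(float)
        ours = rank_sum_pvalues(x[:, None], y[:, None])[0]
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(min(1.0, ref), abs=1e-9)
        assert abs(ours - permutation_pvalue(x, y)) <= 0.12

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1, size=40)
        y = rng.normal(0.0, 1, size=40)
        p = rank_sum_pvalues(x[:, None], y[:, None])[0]
        ref = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, abs=5e-3)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: 3 * v + 7, np.cbrt])
    def test_invariant_under_monotone_transforms(self, transform):
        rng = np.random.default_rng(2)
        x = rng.normal(size=9)
        y = rng.normal(0.8, 1, size=9)
        base = rank_sum_pvalues(x[:, None], y[:, None])[0]
        trans = rank_sum_pvalues(transform(x)[:, None], transform(y)[:, None])[0]
        assert trans == pytest.approx(base)


class TestWilcoxonRank:
    def test_ranking_ascending_by_p(self, toy_features):
        result = wilcoxon_rank(toy_features)
        p_sorted = result.p_values[result.ranking]
        assert np.all(np.diff(p_sorted) >= 0)
        assert result.p_values[result.ranking[0]] == result.p_values.min()

    def test_single_class_rejected(self, toy_features):
        labels = np.array(["case"] * toy_features.n_samples, dtype=object)
        with pytest.raises(ValueError, match="class"):
            wilcoxon_rank(toy_features, labels)

    def test_small_class_rejected(self, toy_features):
        labels = np.array(
            ["case"] + ["control"] * (toy_features.n_samples - 1), dtype=object
        )
        with pytest.raises(ValueError, match=">= 2"):
            wilcoxon_rank(toy_features, labels)


class TestSelectTopK:
    def _result(self, p):
        p = np.asarray(p, dtype=float)
        order = np.lexsort((np.arange(p.size), p))
        return SelectionResult(
            method="wilcoxon_topk",
            feature_names=[f"f{i}" for i in range(p.size)],
            decisions=np.array(["selected"] * p.size, dtype=object),
            ranking=order,
            p_values=p,
        )

    def test_k_equals_feature_count(self):
        p = [0.5, 0.1, 0.9, 0.2, 0.3, 0.8, 0.05, 0.6, 0.4, 0.7]
        assert select_top_k(self._result(p), 10) == [6, 1, 3, 4, 8, 0, 7, 9, 5, 2]

    def test_k_larger_than_count_returns_all(self):
        assert len(select_top_k(self._result([0.2, 0.1]), 10)) == 2

    def test_ties_broken_by_index_stably(self):
        p = [0.5, 0.5, 0.5, 0.5]
        assert select_top_k(self._result(p), 2) == [0, 1]
        assert select_top_k(self._result(p), 2) == [0, 1]

    def test_subset_of_ranking(self, toy_features):
        result = wilcoxon_rank(toy_features)
        top = select_top_k(result, 3)
        assert top == list(result.ranking[:3])


class TestBoruta:
    def _planted(self, seed, n=40, p_noise=15):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X = rng.normal(size=(n, p_noise + 1))
        X[:, 0] = y.astype(float)
        labels = np.where(y == 1, "case", "control")
        return make_feature_matrix(X, labels)

    def test_label_copy_confirmed_noise_rejected(self):
        fm = self._planted(0)
        result = boruta_select(fm, forest_size=150, seed=1)
        assert result.decisions[0] == "confirmed"
        assert np.sum(result.decisions == "rejected") >= 10

    def test_confirmed_and_rejected_disjoint(self):
        fm = self._planted(1)
        result = boruta_select(fm, forest_size=100, max_iter=20, seed=2)
        confirmed = set(np.flatnonzero(result.decisions == "confirmed"))
        rejected = set(np.flatnonzero(result.decisions == "rejected"))
        assert confirmed.isdisjoint(rejected)
        assert set(result.ranking) == confirmed

    def test_deterministic_given_seed(self):
        fm = self._planted(2)
        a = boruta_select(fm, forest_size=100, max_iter=15, seed=5)
        b = boruta_select(fm, forest_size=100, max_iter=15, seed=5)
        assert np.array_equal(a.decisions, b.decisions)
        assert a.n_iterations == b.n_iterations

    def test_zero_iterations_everything_tentative(self):
        fm = self._planted(3)
        result = boruta_select(fm, max_iter=0, seed=0)
        assert np.all(result.decisions == "tentative")
        assert result.n_iterations == 0
        assert result.ranking.size == 0

    def test_degenerate_labels_rejected(self):
        fm = self._planted(4)
        labels = np.array(["case"] * fm.n_samples, dtype=object)
        with pytest.raises(ValueError, match="class"):
            boruta_select(fm, labels)

    def test_selection_csv_round_trip(self, tmp_path, toy_features):
        result = wilcoxon_rank(toy_features)
        result.to_csv(tmp_path / "sel.csv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "sel.csv")
        assert list(back.columns) == ["feature_name", "p_value", "decision", "rank"]
        assert len(back) == toy_features.n_features
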