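"""Leakage-safe feature selection: Wilcoxon rank-sum ranking with top-k
retention, and an all-relevant Boruta shadow-feature selector built on
random forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from vocdx.features import FeatureMatrix

DECISIONS = ("selected", "confirmed", "tentative", "rejected")


@dataclass
class SelectionResult:
    """Ranked/decided features.

    ``decisions`` covers every input feature; ``ranking`` orders the
    selected/confirmed features best-first; ``p_values`` is present for the
    Wilcoxon method only.
    """

    method: str
    feature_names: list[str]
    decisions: np.ndarray
    ranking: np.ndarray
    p_values: np.ndarray | None = None
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.decisions = np.asarray(self.decisions, dtype=object)
        self.ranking = np.asarray(self.ranking, dtype=int)
        if self.p_values is not None:
            self.p_values = np.asarray(self.p_values, dtype=float)
            if np.any((self.p_values < 0) | (self.p_values > 1)):
                raise ValueError("p-values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.feature_names)
        rank_col = np.full(n, -1, dtype=int)
        for pos, idx in enumerate(self.ranking):
            rank_col[idx] = pos
        return pd.DataFrame(
            {
                "feature_name": self.feature_names,
                "p_value": (
                    self.p_values if self.p_values is not None else [np.nan] * n
                ),
                "decision": self.decisions,
                "rank": rank_col,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _split_groups(features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    y = features.y()
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    return features.values[y == 1], features.values[y == 0]


@lru_cache(maxsize=64)
def _ranksum_null_counts(n1: int, n_total: int) -> tuple[np.ndarray, int]:
    """Exact null distribution of the rank-sum W of group 1.

    Returns (counts indexed by W, total count C(n_total, n1)); counts[w] is
    the number of n1-subsets of {1..n_total} with element sum w.
    """
    max_w = n1 * n_total
    # dp[k][w]: number of k-subsets seen so far with sum w
    dp = np.zeros((n1 + 1, max_w + 1), dtype=np.int64)
    dp[0, 0] = 1
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n1), 0, -1):
            dp[k, rank:] += dp[k - 1, : max_w + 1 - rank]
    total = int(dp[n1].sum())
    return dp[n1], total


def _exact_ranksum_p(w: float, n1: int, n_total: int) -> float:
    """Two-sided exact p: 2 * min(P(W <= w), P(W >= w)), capped at 1."""
    counts, total = _ranksum_null_counts(n1, n_total)
    w = int(round(w))
    lo = counts[: w + 1].sum() / total
    hi = counts[w:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def rank_sum_pvalues(group1: np.ndarray, group2: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value per feature column.

    Exact-distribution p when both group sizes are <= 10 and the feature has
    no ties; tie-corrected normal approximation with continuity correction
    otherwise. A feature with zero rank variance (all values tied) gets p=1.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.ndim == 2 and g1.shape[1] != g2.shape[1]:
        raise ValueError("group feature counts differ")
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    pooled = np.vstack([g1, g2])
    ranks = stats.rankdata(pooled, axis=0, method="average")
    w1 = ranks[:n1].sum(axis=0)  # rank-sum of group 1

    # tie diagnostics per column
    srt = np.sort(pooled, axis=0)
    has_ties = np.any(srt[1:] == srt[:-1], axis=0)

    mu = n1 * (n + 1) / 2.0
    tie_term = np.zeros(pooled.shape[1], dtype=float)
    for j in np.flatnonzero(has_ties):
        _, counts = np.unique(pooled[:, j], return_counts=True)
        tie_term[j] = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    # vectorized tie-corrected normal approximation with continuity correction
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w1 - mu - 0.5 * np.sign(w1 - mu)) / np.sqrt(var)
    p = np.where(var > 0, np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z))), 1.0)

    if n1 <= 10 and n2 <= 10:
        exact_cols = np.flatnonzero(~has_ties & (var > 0))
        if exact_cols.size:
            counts, total = _ranksum_null_counts(n1, n)
            cdf = np.cumsum(counts) / total
            sf = np.cumsum(counts[::-1])[::-1] / total
            w_int = np.rint(w1[exact_cols]).astype(int)
            p[exact_cols] = np.minimum(
                1.0, 2.0 * np.minimum(cdf[w_int], sf[w_int])
            )
    return p


def wilcoxon_rank(features: FeatureMatrix, labels: np.ndarray | None = None) -> SelectionResult:
    """Per-feature two-sided rank-sum p-values between case and control,
    ranked ascending by p (ties broken by feature index)."""
    if labels is not None:
        features = FeatureMatrix(
            features.values, features.feature_names, features.sample_ids, labels
        )
    g_case, g_control = _split_groups(features)
    if g_case.shape[0] < 2 or g_control.shape[0] < 2:
        raise ValueError("each class needs >= 2 samples")
    p = rank_sum_pvalues(g_case, g_control)
    order = np.lexsort((np.arange(p.size), p))
    return SelectionResult(
        method="wilcoxon_topk",
        feature_names=features.feature_names,
        decisions=np.array(["selected"] * p.size, dtype=object),
        ranking=order,
        p_values=p,
    )


def select_top_k(result: SelectionResult, k: int) -> list[int]:
    """Indices of the k smallest p-values; ties by ascending feature index;
    all features when fewer than k exist."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if result.p_values is None:
        raise ValueError("select_top_k needs a p-value-based SelectionResult")
    return [int(i) for i in result.ranking[:k]]


def _heldout_permutation_importances(
    X: np.ndarray,
    y: np.ndarray,
    forest_size: int,
    rng: np.random.Generator,
    n_repeats: int = 2,
) -> np.ndarray:
    """Permutation importance measured on a held-out third of the data.

    Chance-correlated noise features earn high in-sample (impurity) importance
    but contribute nothing out of sample, so importance must be measured on
    data the forest never fitted — the analogue of the out-of-bag measure the
    reference implementation uses. All permuted copies are scored in a single
    batched predict call.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    idx_fit, idx_val = train_test_split(
        np.arange(y.size), test_size=1 / 3, random_state=seed, stratify=y
    )
    forest = RandomForestClassifier(
        n_estimators=forest_size, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(X[idx_fit], y[idx_fit])
    X_val, y_val = X[idx_val], y[idx_val]
    n_val, p = X_val.shape
    base_acc = float(np.mean(forest.predict(X_val) == y_val))

    batch = np.tile(X_val, (p * n_repeats, 1))
    for j in range(p):
        for r in range(n_repeats):
            block = slice((j * n_repeats + r) * n_val, (j * n_repeats + r + 1) * n_val)
            batch[block, j] = rng.permutation(X_val[:, j])
    preds = forest.predict(batch).reshape(p, n_repeats, n_val)
    permuted_acc = np.mean(preds == y_val[None, None, :], axis=(1, 2))
    return base_acc - permuted_acc


def _forest_importances(
    X: np.ndarray,
    y: np.ndarray,
    forest_size: int,
    rng: np.random.Generator,
    importance: str,
) -> np.ndarray:
    if importance == "permutation":
        # held-out scoring needs >= 2 samples per class on each side
        if np.bincount(y).min() >= 6:
            return _heldout_permutation_importances(X, y, forest_size, rng)
        # too few samples to hold out a stratified third; fall back
    seed = int(rng.integers(0, 2**31 - 1))
    forest = RandomForestClassifier(
        n_estimators=forest_size,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest.feature_importances_


def boruta_select(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    alpha: float = 0.05,
    max_iter: int = 100,
    forest_size: int = 500,
    seed: int = 0,
    importance: str = "permutation",
) -> SelectionResult:
    """All-relevant Boruta selection against shuffled shadow features.

    Each iteration appends a freshly shuffled shadow copy of every original
    feature, fits a random forest on confirmed + undecided + shadow columns,
    and records a hit for every undecided feature whose importance exceeds
    the maximum shadow importance. After each iteration every undecided
    feature's hit count is tested against Binomial(iterations, 0.5)
    two-sided with Bonferroni correction over the undecided features at level
    ``alpha``: significantly many hits confirms, significantly few rejects.
    Features still undecided at ``max_iter`` are tentative.

    The shadow pool always spans all p original features (rather than only
    the undecided ones) so the hit bar — the maximum over p freshly
    shuffled null features — stays matched to the selection effect over the
    p real features; a shrinking pool progressively lowers the bar and lets
    the chance-best surviving noise feature accumulate spurious hits.
    """
    if labels is not None:
        features = FeatureMatrix(
            features.values, features.feature_names, features.sample_ids, labels
        )
    y = features.y()
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    if features.n_features < 2:
        raise ValueError("need at least 2 features")
    if importance not in ("impurity", "permutation"):
        raise ValueError(f"unknown importance measure: {importance!r}")

    X = features.values
    p = features.n_features
    rng = np.random.default_rng(seed)
    status = np.array(["tentative"] * p, dtype=object)  # tentative = undecided
    hits = np.zeros(p, dtype=int)
    n_iter = 0
    for _ in range(max_iter):
        undecided = np.flatnonzero(status == "tentative")
        if undecided.size == 0:
            break
        keep = np.flatnonzero(status != "rejected")
        shadows = X.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        design = np.hstack([X[:, keep], shadows])
        imp = _forest_importances(design, y, forest_size, rng, importance)
        real_imp = imp[: keep.size]
        shadow_max = imp[keep.size :].max()
        pos_in_keep = {feat: i for i, feat in enumerate(keep)}
        for feat in undecided:
            if real_imp[pos_in_keep[feat]] > shadow_max:
                hits[feat] += 1
        n_iter += 1

        n_undecided = undecided.size
        for feat in undecided:
            p_two = stats.binomtest(int(hits[feat]), n_iter, 0.5).pvalue
            if p_two * n_undecided <= alpha:
                status[feat] = (
                    "confirmed" if hits[feat] > n_iter / 2 else "rejected"
                )

    confirmed = np.flatnonzero(status == "confirmed")
    order = confirmed[np.lexsort((confirmed, -hits[confirmed]))]
    return SelectionResult(
        method="boruta",
        feature_names=features.feature_names,
        decisions=status,
        ranking=order,
        p_values=None,
        n_iterations=n_iter,
    )


def selected_indices(result: SelectionResult, k: int | None = None) -> list[int]:
    """Uniform accessor: top-k for Wilcoxon results, confirmed set for Boruta."""
    if result.method == "wilcoxon_topk":
        return select_top_k(result, k if k is not None else 10)
    return [int(i) for i in result.ranking]
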