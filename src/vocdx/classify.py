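"""Four classifier families under the leakage-safe training protocol:
stratified 70/30 split, k-fold cross-validation with in-fold feature
selection, and hyperparameter tuning by out-of-fold validation error.
"""

from __future__ import annotations

import itertools
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from vocdx.features import FeatureMatrix
from vocdx.selection import (
    SelectionResult,
    boruta_select,
    rank_sum_pvalues,
    select_top_k,
    wilcoxon_rank,
)

FAMILIES = ("sparse_logistic", "random_forest", "gaussian_process", "svm")

#: Families whose fit is sensitive to feature scale (standardized in-fold).
SCALE_SENSITIVE = frozenset({"sparse_logistic", "gaussian_process", "svm"})

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "sparse_logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [500]},
    "gaussian_process": {"length_scale": [0.3, 1.0, 3.0]},
    "svm": {"C": [0.1, 1.0, 10.0]},
}

MODEL_FORMAT_VERSION = 1


@dataclass
class SelectorSpec:
    """In-fold feature-selection recipe."""

    method: str = "wilcoxon_topk"  # or "boruta"
    k: int = 10
    alpha: float = 0.05
    max_iter: int = 50
    forest_size: int = 200
    importance: str = "permutation"
    seed: int = 0

    def fit(self, features: FeatureMatrix) -> tuple[list[int], SelectionResult]:
        """Selected feature indices plus the full selection record."""
        if self.method == "wilcoxon_topk":
            y = features.y()
            if min((y == 1).sum(), (y == 0).sum()) >= 2:
                result = wilcoxon_rank(features)
            else:
                # degenerate single-sample class: rank-sum is defined but the
                # wilcoxon_rank contract requires >=2 per class
                p = rank_sum_pvalues(
                    features.values[y == 1], features.values[y == 0]
                )
                order = np.lexsort((np.arange(p.size), p))
                result = SelectionResult(
                    method="wilcoxon_topk",
                    feature_names=features.feature_names,
                    decisions=np.array(["selected"] * p.size, dtype=object),
                    ranking=order,
                    p_values=p,
                )
            return select_top_k(result, self.k), result
        if self.method == "boruta":
            result = boruta_select(
                features,
                alpha=self.alpha,
                max_iter=self.max_iter,
                forest_size=self.forest_size,
                seed=self.seed,
                importance=self.importance,
            )
            idx = [int(i) for i in result.ranking]
            # all-relevant selection may confirm nothing; fall back to the
            # full feature set so downstream fitting stays defined
            return (idx if idx else list(range(features.n_features))), result
        raise ValueError(f"unknown selector method: {self.method!r}")


@dataclass
class ClassifierSpec:
    family: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}

    def combos(self) -> list[dict]:
        keys = sorted(self.grid)
        return [
            dict(zip(keys, values))
            for values in itertools.product(*(self.grid[k] for k in keys))
        ]


def _make_estimator(family: str, params: dict, seed: int):
    if family == "sparse_logistic":
        import sklearn

        common = dict(
            solver="liblinear", C=params.get("C", 1.0),
            random_state=seed, max_iter=5000,
        )
        if tuple(int(v) for v in sklearn.__version__.split(".")[:2]) >= (1, 8):
            return LogisticRegression(l1_ratio=1.0, **common)  # penalty= is deprecated
        return LogisticRegression(penalty="l1", **common)
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 500),
            random_state=seed, n_jobs=1,
        )
    if family == "gaussian_process":
        kernel = 1.0 * RBF(length_scale=params.get("length_scale", 1.0))
        return GaussianProcessClassifier(
            kernel=kernel, optimizer=None, random_state=seed
        )
    if family == "svm":
        return SVC(kernel="rbf", C=params.get("C", 1.0), gamma="scale",
                   random_state=seed)
    raise ValueError(f"unknown family: {family!r}")


def _score_samples(family: str, estimator, X: np.ndarray) -> np.ndarray:
    """Continuous case-likelihood score; probability for probabilistic
    families, decision-function value for the SVM."""
    if family == "svm":
        return estimator.decision_function(X)
    proba = estimator.predict_proba(X)
    case_col = int(np.flatnonzero(estimator.classes_ == 1)[0])
    return proba[:, case_col]


def score_threshold(family: str) -> float:
    """Misclassification threshold for tuning: 0.5 for probabilities, 0 for
    decision values."""
    return 0.0 if family == "svm" else 0.5


@dataclass
class ScoreSet:
    """Continuous per-sample scores with truth labels and provenance."""

    sample_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    provenance: str = "held_out_test"  # or "out_of_fold"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.sample_ids) == self.scores.size == self.labels.size):
            raise ValueError("sample_ids, scores and labels must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def y(self) -> np.ndarray:
        return (self.labels == "case").astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "score": self.scores,
                "label": self.labels,
                "provenance": self.provenance,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class TrainedModel:
    """Fitted classifier plus everything needed to score new samples on the
    exact feature subset and scaling learned from the training set."""

    family: str
    params: dict
    feature_names: list[str]
    selected_indices: list[int]
    scaler_mean: np.ndarray | None
    scaler_sd: np.ndarray | None
    estimator: object
    selection: SelectionResult
    fold_record: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        payload = {"format_version": MODEL_FORMAT_VERSION, "model": self}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {payload.get('format_version')}")
        return payload["model"]


def split_train_test(
    features: FeatureMatrix, test_fraction: float = 0.3, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified random split preserving class proportions within one sample."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = features.y()
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples to split")
    idx = np.arange(features.n_samples)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    return features.take_samples(np.sort(train_idx)), features.take_samples(np.sort(test_idx))


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def cv_train(
    train: FeatureMatrix,
    spec: ClassifierSpec,
    selector: SelectorSpec | None = None,
    n_folds: int = 10,
) -> tuple[TrainedModel, ScoreSet]:
    """Cross-validated training with in-fold selection.

    Within each stratified fold, feature selection is fitted on the fold's
    training portion only, the classifier is fitted on the selected
    (standardized, for scale-sensitive families) features, and the held-out
    portion is scored. Hyperparameters minimize the mean out-of-fold
    misclassification error; the final model is refitted on the whole
    training set with selection re-run on it. Returns the model and the
    best combo's out-of-fold ScoreSet.
    """
    selector = selector or SelectorSpec()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = train.y()
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("each class needs >= 2 training samples")
    if n_folds > int(np.bincount(y, minlength=2).min()):
        raise ValueError(
            f"n_folds={n_folds} would leave a fold without both classes "
            f"(smallest class has {int(np.bincount(y, minlength=2).min())} samples)"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    combos = spec.combos()
    oof_scores = {c: np.full(train.n_samples, np.nan) for c in range(len(combos))}
    fold_record: list[dict] = []

    for fold_no, (tr_idx, va_idx) in enumerate(skf.split(train.values, y)):
        y_tr = y[tr_idx]
        if len(np.unique(y_tr)) < 2 or len(tr_idx) < 2:
            raise ValueError(f"fold {fold_no} training portion lacks both classes")
        fold_train = train.take_samples(tr_idx)
        sel_idx, sel_result = selector.fit(fold_train)
        X_tr = fold_train.values[:, sel_idx]
        X_va = train.values[np.ix_(va_idx, sel_idx)]
        if spec.family in SCALE_SENSITIVE:
            mean, sd = _standardize_fit(X_tr)
            X_tr = (X_tr - mean) / sd
            X_va = (X_va - mean) / sd
        for ci, params in enumerate(combos):
            est = _make_estimator(spec.family, params, spec.seed)
            est.fit(X_tr, y_tr)
            oof_scores[ci][va_idx] = _score_samples(spec.family, est, X_va)
        fold_record.append(
            {
                "fold": fold_no,
                "train_ids": [train.sample_ids[i] for i in tr_idx],
                "selected": [train.feature_names[i] for i in sel_idx],
                "selection": sel_result,
            }
        )

    thr = score_threshold(spec.family)
    errors = [
        float(np.mean((oof_scores[ci] >= thr).astype(int) != y))
        for ci in range(len(combos))
    ]
    best = int(np.argmin(errors))  # ties -> first combo in grid order

    sel_idx, sel_result = selector.fit(train)
    X_full = train.values[:, sel_idx]
    mean = sd = None
    if spec.family in SCALE_SENSITIVE:
        mean, sd = _standardize_fit(X_full)
        X_full = (X_full - mean) / sd
    estimator = _make_estimator(spec.family, combos[best], spec.seed)
    estimator.fit(X_full, y)

    model = TrainedModel(
        family=spec.family,
        params=combos[best],
        feature_names=list(train.feature_names),
        selected_indices=[int(i) for i in sel_idx],
        scaler_mean=mean,
        scaler_sd=sd,
        estimator=estimator,
        selection=sel_result,
        fold_record=fold_record,
    )
    oof = ScoreSet(
        sample_ids=list(train.sample_ids),
        scores=oof_scores[best],
        labels=train.labels,
        provenance="out_of_fold",
    )
    return model, oof


def predict_scores(
    model: TrainedModel, features: FeatureMatrix, provenance: str = "held_out_test"
) -> ScoreSet:
    """Score samples on the model's stored feature subset and scaling."""
    if list(features.feature_names) != model.feature_names:
        missing = set(model.feature_names) - set(features.feature_names)
        extra = set(features.feature_names) - set(model.feature_names)
        raise ValueError(
            f"feature names do not match training: missing={sorted(missing)[:5]} "
            f"extra={sorted(extra)[:5]} (order must match too)"
        )
    X = features.values[:, model.selected_indices]
    if model.scaler_mean is not None:
        X = (X - model.scaler_mean) / model.scaler_sd
    scores = _score_samples(model.family, model.estimator, X)
    return ScoreSet(
        sample_ids=list(features.sample_ids),
        scores=scores,
        labels=features.labels,
        provenance=provenance,
    )
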