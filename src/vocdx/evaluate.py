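"""ROC construction and reported diagnostics: AUC with bootstrap CIs,
Youden operating point (sensitivity, specificity, PPV, NPV), Mann-Whitney
score p-values, and PCA/LDA projections."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from vocdx.classify import ScoreSet
from vocdx.features import FeatureMatrix
from vocdx.selection import rank_sum_pvalues

REPORT_COLUMNS = [
    "method", "auc", "auc_lo", "auc_hi",
    "sensitivity", "sens_lo", "sens_hi",
    "specificity", "spec_lo", "spec_hi",
    "ppv", "npv", "p_value", "n_case", "n_control",
]


def _groups(scores: ScoreSet) -> tuple[np.ndarray, np.ndarray]:
    y = scores.y()
    case, control = scores.scores[y == 1], scores.scores[y == 0]
    if case.size == 0 or control.size == 0:
        raise ValueError("both classes must be present")
    return case, control


def roc_auc(scores: ScoreSet) -> float:
    """AUC as the Mann-Whitney concordance probability:
    (#{case > control} + 0.5 * #{ties}) / (n_case * n_control)."""
    case, control = _groups(scores)
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    r_case = ranks[: case.size].sum()
    u = r_case - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float  # nan when TP+FP == 0
    npv: float  # nan when TN+FN == 0
    tp: int
    fn: int
    tn: int
    fp: int


def _confusion_at(y: np.ndarray, scores: np.ndarray, threshold: float) -> tuple[int, int, int, int]:
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return tp, fn, tn, fp


def operating_point(scores: ScoreSet, rule: str | float = "youden") -> OperatingPoint:
    """Confusion-matrix metrics at a threshold (predict case when score >=
    threshold).

    ``rule="youden"`` scans every candidate threshold and keeps the maximizer
    of sensitivity + specificity - 1, breaking ties toward higher
    sensitivity; a numeric rule fixes the threshold directly.
    """
    _groups(scores)  # class-presence check
    y = scores.y()
    s = scores.scores
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        threshold = float(rule)
    elif rule == "youden":
        candidates = np.concatenate([np.unique(s), [np.inf]])
        best = None
        for t in candidates:
            tp, fn, tn, fp = _confusion_at(y, s, t)
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
            key = (sens + spec - 1.0, sens)
            if best is None or key > best[0]:
                best = (key, t)
        threshold = float(best[1])
    else:
        raise ValueError(f"unknown operating-point rule: {rule!r}")
    tp, fn, tn, fp = _confusion_at(y, s, threshold)
    return OperatingPoint(
        threshold=threshold,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp > 0 else float("nan"),
        npv=tn / (tn + fn) if tn + fn > 0 else float("nan"),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


_METRIC_NAMES = ("auc", "sensitivity", "specificity", "ppv", "npv")


def _metric_value(name_or_fn, scores: ScoreSet) -> float:
    if callable(name_or_fn):
        return float(name_or_fn(scores))
    if name_or_fn == "auc":
        return roc_auc(scores)
    if name_or_fn in _METRIC_NAMES:
        return float(getattr(operating_point(scores), name_or_fn))
    raise ValueError(f"unknown metric: {name_or_fn!r}")


def bootstrap_ci(
    scores: ScoreSet,
    metric="auc",
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for a score metric.

    Cases and controls are resampled with replacement within class, so every
    resample keeps both classes. NaN metric values (e.g. PPV with an empty
    positive-call cell) are dropped from the percentile computation.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    case, control = _groups(scores)
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    for b in range(n_boot):
        rc = rng.choice(case, size=case.size, replace=True)
        rk = rng.choice(control, size=control.size, replace=True)
        resample = ScoreSet(
            sample_ids=[f"b{b}_{i}" for i in range(case.size + control.size)],
            scores=np.concatenate([rc, rk]),
            labels=np.array(
                ["case"] * case.size + ["control"] * control.size, dtype=object
            ),
            provenance=scores.provenance,
        )
        values[b] = _metric_value(metric, resample)
    values = values[np.isfinite(values)]
    lo_q = (1.0 - level) / 2.0
    return (
        float(np.quantile(values, lo_q)),
        float(np.quantile(values, 1.0 - lo_q)),
    )


def score_pvalue(scores: ScoreSet) -> float:
    """Two-sided Mann-Whitney p-value on case vs control scores (exact for
    small untied groups, tie-corrected normal otherwise); consistent with
    roc_auc through the U-AUC identity."""
    case, control = _groups(scores)
    return float(rank_sum_pvalues(case[:, None], control[:, None])[0])


def roc_points(scores: ScoreSet) -> pd.DataFrame:
    """ROC curve samples (fpr, tpr, threshold), thresholds descending."""
    y = scores.y()
    thresholds = np.concatenate([[np.inf], np.unique(scores.scores)[::-1]])
    rows = []
    for t in thresholds:
        tp, fn, tn, fp = _confusion_at(y, scores.scores, t)
        rows.append({"fpr": fp / (fp + tn), "tpr": tp / (tp + fn), "threshold": t})
    return pd.DataFrame(rows)


def project_pca(features: FeatureMatrix, n_components: int = 2) -> np.ndarray:
    """Mean-centred principal-component coordinates, components ordered by
    explained variance; each component's largest-magnitude loading is made
    positive so signs are deterministic."""
    if features.n_samples == 0:
        raise ValueError("empty input")
    n_components = min(n_components, min(features.values.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(features.values)
    for j in range(n_components):
        loading = pca.components_[j]
        pivot = loading[np.argmax(np.abs(loading))]
        if pivot < 0:
            coords[:, j] *= -1.0
    return coords


def project_lda(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    n_components: int = 1,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Fisher discriminant coordinates for the two-class problem.

    The within-class scatter is regularized by ``ridge * trace(Sw)/p * I`` so
    collinear feature sets stay solvable. Only one discriminant direction
    exists for two classes.
    """
    if labels is not None:
        features = FeatureMatrix(
            features.values, features.feature_names, features.sample_ids, labels
        )
    if n_components != 1:
        raise ValueError("two classes admit exactly 1 discriminant component")
    y = features.y()
    X = features.values
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    mu1, mu0 = X[y == 1].mean(axis=0), X[y == 0].mean(axis=0)
    sw = np.zeros((X.shape[1], X.shape[1]))
    for cls, mu in ((1, mu1), (0, mu0)):
        diff = X[y == cls] - mu
        sw += diff.T @ diff
    scale = np.trace(sw) / X.shape[1]
    if scale == 0:
        scale = 1.0
    w = np.linalg.solve(sw + ridge * scale * np.eye(X.shape[1]), mu1 - mu0)
    coords = (X - X.mean(axis=0)) @ w
    return coords[:, None]


@dataclass
class RocReport:
    """One Tables-3-to-6-style row: AUC, operating point metrics, CIs, p."""

    method_label: str
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    sens_ci: tuple[float, float]
    specificity: float
    spec_ci: tuple[float, float]
    ppv: float
    npv: float
    p_value: float
    n_case: int
    n_control: int

    def to_row(self) -> dict:
        return {
            "method": self.method_label,
            "auc": self.auc, "auc_lo": self.auc_ci[0], "auc_hi": self.auc_ci[1],
            "sensitivity": self.sensitivity,
            "sens_lo": self.sens_ci[0], "sens_hi": self.sens_ci[1],
            "specificity": self.specificity,
            "spec_lo": self.spec_ci[0], "spec_hi": self.spec_ci[1],
            "ppv": self.ppv, "npv": self.npv, "p_value": self.p_value,
            "n_case": self.n_case, "n_control": self.n_control,
        }


def evaluate_scores(
    label: str, scores: ScoreSet, n_boot: int = 2000, seed: int = 0
) -> RocReport:
    """Full per-classifier report row for one ScoreSet."""
    case, control = _groups(scores)
    auc = roc_auc(scores)
    op = operating_point(scores)
    auc_ci = bootstrap_ci(scores, "auc", n_boot=n_boot, seed=seed)
    sens_ci = bootstrap_ci(scores, "sensitivity", n_boot=n_boot, seed=seed)
    spec_ci = bootstrap_ci(scores, "specificity", n_boot=n_boot, seed=seed)
    # percentile intervals should contain the point estimate; widen if a
    # pathological resample distribution clipped it out
    auc_ci = (min(auc_ci[0], auc), max(auc_ci[1], auc))
    sens_ci = (min(sens_ci[0], op.sensitivity), max(sens_ci[1], op.sensitivity))
    spec_ci = (min(spec_ci[0], op.specificity), max(spec_ci[1], op.specificity))
    return RocReport(
        method_label=label,
        auc=auc,
        auc_ci=auc_ci,
        threshold=op.threshold,
        sensitivity=op.sensitivity,
        sens_ci=sens_ci,
        specificity=op.specificity,
        spec_ci=spec_ci,
        ppv=op.ppv,
        npv=op.npv,
        p_value=score_pvalue(scores),
        n_case=case.size,
        n_control=control.size,
    )


def build_report(
    scoresets: dict[str, ScoreSet], n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """One report row per classifier family, in the fixed column layout."""
    if not scoresets:
        raise ValueError("need at least one classifier ScoreSet")
    rows = [
        evaluate_scores(label, scores, n_boot=n_boot, seed=seed).to_row()
        for label, scores in scoresets.items()
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False, float_format="%.17g")


def read_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in df.columns:
        if col == "method":
            continue
        df[col] = df[col].astype(int if col in ("n_case", "n_control") else float)
    return df
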