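"""FeatureMatrix: the samples-by-features currency shared by every stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

LABELS = ("case", "control", "unknown")


@dataclass
class FeatureMatrix:
    """Named feature matrix with aligned sample metadata.

    Invariants enforced at construction: values are finite, feature names are
    unique, rows align with sample_ids and labels.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2D, got ndim={self.values.ndim}")
        self.feature_names = list(self.feature_names)
        self.sample_ids = list(self.sample_ids)
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite (no missing values)")
        if self.labels is None:
            self.labels = np.array(["unknown"] * n, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (n,):
            raise ValueError("labels must align with sample rows")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def y(self) -> np.ndarray:
        """Binary label vector: case=1, control=0. Errors on 'unknown'."""
        if "unknown" in set(self.labels):
            raise ValueError("cannot binarize: some labels are 'unknown'")
        return (self.labels == "case").astype(int)

    def take_samples(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            values=self.values[idx],
            feature_names=self.feature_names,
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
        )

    def take_features(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            sample_ids=self.sample_ids,
            labels=self.labels,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)
        df.index.name = "sample_id"
        return df
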