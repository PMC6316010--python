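"""FAIMS sample data model, file I/O, and 2D wavelet feature extraction.

A FAIMS scan sweeps the compensation voltage (CV, -6 V to +6 V, 512 steps)
once per dispersion-field (DF) step (0-99%, 51 steps) per ion polarity, so a
sample is a 512x102 ion-current matrix: rows are CV steps, columns 0-50 the
positive-polarity DF sweep, columns 51-101 the negative-polarity sweep —
52,224 values in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from vocdx import wavelets
from vocdx.features import FeatureMatrix, LABELS

N_CV_STEPS = 512
N_DF_STEPS = 51
N_POLARITIES = 2
FAIMS_SHAPE = (N_CV_STEPS, N_DF_STEPS * N_POLARITIES)


@dataclass
class FaimsSample:
    """One FAIMS dispersion matrix plus sample metadata."""

    sample_id: str
    matrix: np.ndarray
    label: str = "unknown"
    age_days: float = 0.0
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != FAIMS_SHAPE:
            raise ValueError(
                f"FAIMS matrix shape {self.matrix.shape} != expected {FAIMS_SHAPE}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("FAIMS matrix must contain only finite values")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.age_days < 0:
            raise ValueError("age_days must be non-negative")

    @property
    def positive(self) -> np.ndarray:
        """Positive-polarity block (512 x 51)."""
        return self.matrix[:, :N_DF_STEPS]

    @property
    def negative(self) -> np.ndarray:
        """Negative-polarity block (512 x 51)."""
        return self.matrix[:, N_DF_STEPS:]


def read_faims_sample(
    path: str | Path,
    dialect: str = "plain_csv",
    sample_id: str | None = None,
    label: str = "unknown",
    age_days: float = 0.0,
    replicate_index: int = 0,
) -> FaimsSample:
    """Read one FAIMS sample matrix.

    ``plain_csv`` is a headerless 512-row, 102-column comma-separated numeric
    block; ``lonestar_export`` is the same block preceded by '#'-prefixed
    metadata lines, which are skipped.
    """
    path = Path(path)
    if dialect not in ("plain_csv", "lonestar_export"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if dialect == "lonestar_export":
                    continue
                raise ValueError(
                    f"{path}:{lineno}: metadata line in plain_csv dialect"
                )
            cells = line.split(",")
            row = []
            for colno, cell in enumerate(cells, start=1):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {lineno}, column {colno}: {cell!r}"
                    ) from None
            rows.append(row)
    n_rows = len(rows)
    n_cols = len(rows[0]) if rows else 0
    if any(len(r) != n_cols for r in rows) or (n_rows, n_cols) != FAIMS_SHAPE:
        found = (n_rows, n_cols if rows else 0)
        raise ValueError(
            f"{path}: matrix shape {found} != expected {FAIMS_SHAPE}"
        )
    matrix = np.array(rows, dtype=float)
    return FaimsSample(
        sample_id=sample_id or path.stem,
        matrix=matrix,
        label=label,
        age_days=age_days,
        replicate_index=replicate_index,
    )


def write_faims_sample(sample: FaimsSample, path: str | Path, dialect: str = "plain_csv") -> None:
    """Write a sample in a dialect :func:`read_faims_sample` accepts."""
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "lonestar_export":
            fh.write(f"# sample_id: {sample.sample_id}\n")
            fh.write(f"# label: {sample.label}\n")
            fh.write(f"# age_days: {sample.age_days}\n")
        elif dialect != "plain_csv":
            raise ValueError(f"unknown dialect: {dialect!r}")
        for row in sample.matrix:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _faims_filename(sample_id: str, replicate_index: int) -> str:
    # replicates of one biological sample get distinct files
    return f"{sample_id}.csv" if replicate_index == 0 else f"{sample_id}.r{replicate_index}.csv"


def write_faims_cohort(
    cohort: list[FaimsSample], directory: str | Path, dialect: str = "plain_csv"
) -> Path:
    """Write per-sample matrices plus a metadata CSV; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["sample_id,label,age_days,replicate_index"]
    for sample in cohort:
        write_faims_sample(sample, directory / _faims_filename(sample.sample_id, sample.replicate_index), dialect=dialect)
        lines.append(
            f"{sample.sample_id},{sample.label},{sample.age_days!r},{sample.replicate_index}"
        )
    (directory / "metadata.csv").write_text("\n".join(lines) + "\n")
    return directory


def read_faims_cohort(directory: str | Path, dialect: str = "plain_csv") -> list[FaimsSample]:
    """Read a cohort written by :func:`write_faims_cohort`."""
    import csv

    directory = Path(directory)
    cohort = []
    with open(directory / "metadata.csv") as fh:
        for row in csv.DictReader(fh):
            rep = int(row.get("replicate_index") or 0)
            cohort.append(
                read_faims_sample(
                    directory / _faims_filename(row["sample_id"], rep),
                    dialect=dialect,
                    sample_id=row["sample_id"],
                    label=row["label"],
                    age_days=float(row["age_days"]),
                    replicate_index=rep,
                )
            )
    return cohort


def average_replicates(samples: list[FaimsSample]) -> FaimsSample:
    """Average technical replicates of one biological sample into one matrix.

    Averaging before any train/test split prevents replicate leakage.
    """
    if not samples:
        raise ValueError("no replicates to average")
    ids = {s.sample_id for s in samples}
    if len(ids) != 1:
        raise ValueError(f"replicates span multiple sample_ids: {sorted(ids)}")
    mean = np.mean([s.matrix for s in samples], axis=0)
    first = samples[0]
    return FaimsSample(
        sample_id=first.sample_id,
        matrix=mean,
        label=first.label,
        age_days=first.age_days,
        replicate_index=0,
    )


def dwt2_features(
    sample: FaimsSample, levels: int = 4, keep: str = "all_levels"
) -> tuple[list[str], np.ndarray]:
    """Named wavelet coefficient vector of one dispersion matrix.

    Runs the periodized Daubechies-4-tap multilevel 2D DWT on the full
    512x102 matrix (polarity blocks concatenated) and flattens the retained
    subbands; names follow ``L{level}_{band}_{row}_{col}``.
    """
    dec = wavelets.wavedec2(sample.matrix, levels)
    return wavelets.flatten_coefficients(dec, keep=keep)


def extract_faims_features(
    cohort: list[FaimsSample], levels: int = 4, keep: str = "all_levels"
) -> FeatureMatrix:
    """Wavelet FeatureMatrix for a cohort: one row per sample, fixed ordering."""
    if not cohort:
        raise ValueError("cohort is empty")
    shapes = {s.matrix.shape for s in cohort}
    if len(shapes) != 1:
        raise ValueError(f"mixed matrix shapes in cohort: {sorted(shapes)}")
    names: list[str] | None = None
    rows = []
    for sample in cohort:
        feat_names, vec = dwt2_features(sample, levels=levels, keep=keep)
        if names is None:
            names = feat_names
        rows.append(vec)
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        sample_ids=[s.sample_id for s in cohort],
        labels=np.array([s.label for s in cohort], dtype=object),
    )
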