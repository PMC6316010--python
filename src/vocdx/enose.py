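"""eNose sample data model, I/O, and sensor-response feature extraction.

An eNose sample is 18 metal-oxide sensor resistance traces recorded for
180 s at 1 Hz. The per-sensor features implemented here are the normalized
response (R0 - RT)/R0, the maximum resistance over the baseline resistance,
and the maximum windowed variance of the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vocdx.features import FeatureMatrix, LABELS

N_SENSORS = 18
N_TIMEPOINTS = 180

# FOX 4000 sensor array reference names (array metadata, not chemistry).
DEFAULT_SENSOR_NAMES = (
    "LY2/LG", "LY2/G", "LY2/AA", "LY2/GH", "LY2/gCTL", "LY2/gCT",
    "T30/1", "P10/1", "P10/2", "P40/1", "T70/2", "PA/2",
    "P30/1", "P40/2", "P30/2", "T40/2", "T40/1", "TA/2",
)

FEATURE_FAMILIES = ("response", "max_over_baseline", "max_variance")


@dataclass
class EnoseSample:
    """18 resistance traces x 180 s plus per-sensor baselines and metadata."""

    sample_id: str
    traces: np.ndarray
    sensor_names: tuple[str, ...] = DEFAULT_SENSOR_NAMES
    baselines: np.ndarray | None = None
    label: str = "unknown"
    age_days: float = 0.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.shape != (N_SENSORS, N_TIMEPOINTS):
            raise ValueError(
                f"traces shape {self.traces.shape} != expected ({N_SENSORS}, {N_TIMEPOINTS})"
            )
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must contain only finite values")
        self.sensor_names = tuple(self.sensor_names)
        if len(self.sensor_names) != N_SENSORS:
            raise ValueError(f"need {N_SENSORS} sensor names")
        if len(set(self.sensor_names)) != N_SENSORS:
            raise ValueError("sensor names must be unique")
        if self.baselines is None:
            self.baselines = self.traces[:, 0].copy()
        self.baselines = np.asarray(self.baselines, dtype=float)
        if self.baselines.shape != (N_SENSORS,):
            raise ValueError("need one baseline per sensor")
        if np.any(self.baselines <= 0):
            raise ValueError("baselines must be strictly positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.age_days < 0:
            raise ValueError("age_days must be non-negative")


def read_enose_sample(
    path: str | Path,
    baseline_path: str | Path | None = None,
    sample_id: str | None = None,
    label: str = "unknown",
    age_days: float = 0.0,
) -> EnoseSample:
    """Read a per-sample CSV: header row of 18 sensor names, 180 numeric rows.

    R0 is taken as the first trace row unless a baseline sidecar CSV
    (columns sensor,R0) is supplied.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape != (N_TIMEPOINTS, N_SENSORS):
        raise ValueError(
            f"{path}: table shape {df.shape} != expected ({N_TIMEPOINTS}, {N_SENSORS})"
        )
    traces = df.to_numpy(dtype=float).T
    baselines = None
    if baseline_path is not None:
        side = pd.read_csv(baseline_path).set_index("sensor")["R0"]
        try:
            baselines = side.loc[list(df.columns)].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError(f"baseline sidecar missing sensors: {exc}") from None
    return EnoseSample(
        sample_id=sample_id or path.stem,
        traces=traces,
        sensor_names=tuple(df.columns),
        baselines=baselines,
        label=label,
        age_days=age_days,
    )


def write_enose_sample(sample: EnoseSample, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(sample.traces.T, columns=list(sample.sensor_names))
    df.to_csv(path, index=False, float_format="%.17g")


def write_enose_cohort(cohort: list[EnoseSample], directory: str | Path) -> Path:
    """Write per-sample trace CSVs, baseline sidecars and a metadata CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["sample_id,label,age_days,replicate_index"]
    for sample in cohort:
        write_enose_sample(sample, directory / f"{sample.sample_id}.csv")
        side = pd.DataFrame(
            {"sensor": list(sample.sensor_names), "R0": sample.baselines}
        )
        side.to_csv(directory / f"{sample.sample_id}.baseline.csv", index=False,
                    float_format="%.17g")
        lines.append(f"{sample.sample_id},{sample.label},{sample.age_days!r},0")
    (directory / "metadata.csv").write_text("\n".join(lines) + "\n")
    return directory


def read_enose_cohort(directory: str | Path) -> list[EnoseSample]:
    """Read a cohort written by :func:`write_enose_cohort`."""
    import csv

    directory = Path(directory)
    cohort = []
    with open(directory / "metadata.csv") as fh:
        for row in csv.DictReader(fh):
            base = directory / f"{row['sample_id']}.baseline.csv"
            cohort.append(
                read_enose_sample(
                    directory / f"{row['sample_id']}.csv",
                    baseline_path=base if base.exists() else None,
                    sample_id=row["sample_id"],
                    label=row["label"],
                    age_days=float(row["age_days"]),
                )
            )
    return cohort


def sensor_response(r0: float, rt: float) -> float:
    """Normalized sensor response (r0 - rt) / r0; r0 must be positive."""
    if r0 <= 0:
        raise ValueError(f"baseline resistance must be positive, got {r0}")
    return (r0 - rt) / r0


def max_over_baseline(trace: np.ndarray, r0: float) -> float:
    """max(trace) / r0; r0 must be positive, trace non-empty."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace is empty")
    if r0 <= 0:
        raise ValueError(f"baseline resistance must be positive, got {r0}")
    return float(np.max(trace) / r0)


def max_variance_feature(trace: np.ndarray, window: int | None = None) -> float:
    """Maximum population variance over all contiguous length-``window``
    segments of the trace; ``window=None`` (or the full length) degenerates
    to the plain population variance."""
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if window is None:
        window = n
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    # var over sliding windows via cumulative first/second moments
    c1 = np.concatenate(([0.0], np.cumsum(trace)))
    c2 = np.concatenate(([0.0], np.cumsum(trace**2)))
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    var = s2 / window - (s1 / window) ** 2
    return float(max(np.max(var), 0.0))


def extract_enose_features(
    cohort: list[EnoseSample],
    feature_set: tuple[str, ...] | str = ("max_variance",),
    window: int | None = None,
) -> FeatureMatrix:
    """Per-sensor features for a cohort, named ``{sensor}_{family}``.

    ``response`` is (R0 - R_T)/R0 at the final time point; ``max_over_baseline``
    and ``max_variance`` as defined above.
    """
    if isinstance(feature_set, str):
        feature_set = (feature_set,)
    if not cohort:
        raise ValueError("cohort is empty")
    unknown = set(feature_set) - set(FEATURE_FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")
    name_sets = {s.sensor_names for s in cohort}
    if len(name_sets) != 1:
        raise ValueError("cohort mixes sensor layouts")
    sensor_names = cohort[0].sensor_names
    names = [
        f"{sensor}_{family}" for family in feature_set for sensor in sensor_names
    ]
    rows = []
    for sample in cohort:
        row = []
        for family in feature_set:
            for i in range(N_SENSORS):
                trace, r0 = sample.traces[i], sample.baselines[i]
                if family == "response":
                    row.append(sensor_response(r0, trace[-1]))
                elif family == "max_over_baseline":
                    row.append(max_over_baseline(trace, r0))
                else:
                    row.append(max_variance_feature(trace, window=window))
        rows.append(row)
    return FeatureMatrix(
        values=np.array(rows, dtype=float),
        feature_names=names,
        sample_ids=[s.sample_id for s in cohort],
        labels=np.array([s.label for s in cohort], dtype=object),
    )
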