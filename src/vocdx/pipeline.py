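"""Study orchestration: cohort generation/ingestion, age stratification,
per-instrument feature paths, leakage-safe selection + classification, and
report writing, all reproducible from a manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import vocdx
from vocdx import enose, faims
from vocdx.classify import (
    FAMILIES,
    ClassifierSpec,
    ScoreSet,
    SelectorSpec,
    cv_train,
    predict_scores,
    split_train_test,
)
from vocdx.evaluate import build_report, write_report
from vocdx.features import FeatureMatrix
from vocdx.synthetic import SyntheticConfig, generate_enose_cohort, generate_faims_cohort

log = logging.getLogger("vocdx")

AGE_PRESETS = {"1y": 365.0, "18m": 548.0}


@dataclass
class StudyConfig:
    """Everything needed to rerun a study end to end."""

    instrument: str = "faims"
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    age_cutoff_days: float | None = None
    selector: SelectorSpec = field(default_factory=SelectorSpec)
    families: tuple[str, ...] = FAMILIES
    test_fraction: float = 0.3
    n_folds: int = 10
    seed: int = 0
    n_boot: int = 2000
    out_dir: str = "study_out"
    # FAIMS feature path
    faims_levels: int = 4
    faims_keep: str = "all_levels"
    faims_dialect: str = "plain_csv"
    # eNose feature path
    enose_feature_set: tuple[str, ...] = ("max_variance",)
    enose_window: int | None = None
    # explicit split override (sample-id lists), e.g. for leakage audits
    train_ids: tuple[str, ...] | None = None
    test_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.instrument not in ("faims", "enose"):
            raise ValueError(f"instrument must be faims or enose, got {self.instrument!r}")
        if self.age_cutoff_days is not None and self.age_cutoff_days <= 0:
            raise ValueError("age_cutoff_days must be positive")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown classifier families: {sorted(unknown)}")
        if self.synthetic is None and self.input_dir is None:
            raise ValueError("need a synthetic config or an input directory")

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["package_version"] = vocdx.__version__
        d["numpy_version"] = np.__version__
        import sklearn

        d["sklearn_version"] = sklearn.__version__
        return d


def filter_by_age(cohort: list, cutoff_days: float | None) -> list:
    """Retain samples with age_days <= cutoff; errors list offending ids."""
    if cutoff_days is None:
        return list(cohort)
    missing = [s.sample_id for s in cohort if s.age_days is None]
    if missing:
        raise ValueError(f"samples missing age metadata: {missing}")
    kept = [s for s in cohort if s.age_days <= cutoff_days]
    log.info("age filter <= %.0f d: kept %d of %d samples", cutoff_days, len(kept), len(cohort))
    return kept


def _load_cohort(config: StudyConfig) -> list:
    if config.synthetic is not None:
        if config.instrument == "faims":
            return generate_faims_cohort(config.synthetic)
        return generate_enose_cohort(config.synthetic)
    if config.instrument == "faims":
        cohort = faims.read_faims_cohort(config.input_dir, dialect=config.faims_dialect)
        # collapse technical replicates before any splitting
        by_id: dict[str, list] = {}
        for s in cohort:
            by_id.setdefault(s.sample_id, []).append(s)
        if any(len(v) > 1 for v in by_id.values()):
            cohort = [faims.average_replicates(v) for v in by_id.values()]
        return cohort
    return enose.read_enose_cohort(config.input_dir)


def _extract_features(config: StudyConfig, cohort: list) -> FeatureMatrix:
    if config.instrument == "faims":
        return faims.extract_faims_features(
            cohort, levels=config.faims_levels, keep=config.faims_keep
        )
    return enose.extract_enose_features(
        cohort, feature_set=config.enose_feature_set, window=config.enose_window
    )


def _split(config: StudyConfig, features: FeatureMatrix) -> tuple[FeatureMatrix, FeatureMatrix]:
    if config.train_ids is not None or config.test_ids is not None:
        if not (config.train_ids and config.test_ids):
            raise ValueError("split override needs both train_ids and test_ids")
        pos = {sid: i for i, sid in enumerate(features.sample_ids)}
        missing = [s for s in (*config.train_ids, *config.test_ids) if s not in pos]
        if missing:
            raise ValueError(f"split override names unknown samples: {missing}")
        overlap = set(config.train_ids) & set(config.test_ids)
        if overlap:
            raise ValueError(f"split override overlaps: {sorted(overlap)}")
        train = features.take_samples([pos[s] for s in config.train_ids])
        test = features.take_samples([pos[s] for s in config.test_ids])
        return train, test
    return split_train_test(features, config.test_fraction, seed=config.seed)


def run_study(config: StudyConfig) -> dict:
    """Execute the full study and write report files under ``out_dir``.

    Returns a dict with the output paths, the per-family ScoreSets, and the
    report frames. Fully reproducible given the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        cohort = _load_cohort(config)
        log.info("loaded %d samples (%s)", len(cohort), config.instrument)
        stage = "age_filter"
        cohort = filter_by_age(cohort, config.age_cutoff_days)
        stage = "features"
        features = _extract_features(config, cohort)
        log.info("feature matrix: %d x %d", features.n_samples, features.n_features)
        stage = "split"
        train, test = _split(config, features)
        log.info("split: %d train / %d test", train.n_samples, test.n_samples)

        oof_sets: dict[str, ScoreSet] = {}
        test_sets: dict[str, ScoreSet] = {}
        for family in config.families:
            stage = f"cv_train[{family}]"
            spec = ClassifierSpec(family=family, seed=config.seed)
            model, oof = cv_train(train, spec, selector=config.selector, n_folds=config.n_folds)
            stage = f"predict[{family}]"
            test_scores = predict_scores(model, test)
            oof_sets[family] = oof
            test_sets[family] = test_scores
            log.info(
                "%s: selected %d features, params %s",
                family, len(model.selected_indices), model.params,
            )
            oof.to_csv(out / f"scores_{family}_oof.csv")
            test_scores.to_csv(out / f"scores_{family}_test.csv")
            model.selection.to_csv(out / f"selection_final_{family}.csv")
            fold_frames = []
            for rec in model.fold_record:
                frame = rec["selection"].to_frame()
                frame.insert(0, "fold", rec["fold"])
                fold_frames.append(frame)
            pd.concat(fold_frames, ignore_index=True).to_csv(
                out / f"selection_folds_{family}.csv", index=False, float_format="%.17g"
            )

        stage = "report"
        report_test = build_report(test_sets, n_boot=config.n_boot, seed=config.seed)
        report_oof = build_report(oof_sets, n_boot=config.n_boot, seed=config.seed)
        write_report(report_test, out / "report_test.csv")
        write_report(report_oof, out / "report_oof.csv")
        (out / "report_test.json").write_text(
            report_test.to_json(orient="records", indent=2)
        )

        stage = "manifest"
        manifest = config.to_manifest()
        manifest["n_samples"] = features.n_samples
        manifest["train_sample_ids"] = list(train.sample_ids)
        manifest["test_sample_ids"] = list(test.sample_ids)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"study failed at stage {stage!r}: {exc}") from exc

    return {
        "out_dir": out,
        "report_test": report_test,
        "report_oof": report_oof,
        "oof_scores": oof_sets,
        "test_scores": test_sets,
        "train": train,
        "test": test,
    }
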