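# vocdx

A two-instrument urinary-VOC diagnostic analysis pipeline:

* **FAIMS path** — 512x102 ion-current dispersion matrices (512
  compensation-voltage steps x 51 dispersion-field steps x 2 polarities,
  52,224 values per scan), decomposed with a periodized Daubechies-4-tap 2D
  multilevel wavelet transform; coefficients ranked in-fold by two-sided
  Wilcoxon rank-sum p-value with top-k retention.
* **eNose path** — 18 metal-oxide sensor resistance traces (180 s at 1 Hz)
  reduced to per-sensor response features (normalized response
  `(R0 - RT)/R0`, max-over-baseline, windowed max variance); features
  screened with an all-relevant Boruta shadow-feature selector built on
  random forests with held-out permutation importance.

Both paths feed a leakage-safe protocol — stratified 70/30 split, k-fold
cross-validation with selection re-fitted inside every fold, hyperparameters
tuned on out-of-fold error — across four classifier families (L1 logistic
regression, random forest, Gaussian process, RBF SVM), and end in a full ROC
report (AUC, stratified-bootstrap CIs, Youden operating point with
sensitivity/specificity/PPV/NPV, Mann-Whitney p-value) with optional
sample-age stratification. A synthetic cohort generator plants class effects
and exponential storage-age signal decay so every stage is testable without
clinical data.

## CLI

```bash
# generate a synthetic cohort on disk
vocdx simulate --instrument faims --out cohort/ --seed 1 \
    --n-case 73 --n-control 67 --effect-size 2 --age-decay-rate 0.0016

# run the full study (features -> selection -> 4 classifiers -> ROC report)
vocdx run --instrument faims --in cohort/ --out study/ --seed 1 \
    --age-cutoff 1y --selector wilcoxon_topk --k 10

# run directly on a synthetic cohort (no files needed)
vocdx run --instrument enose --out study/ --seed 1 --selector boruta

# rebuild a report table from stored score CSVs
vocdx report --scores study/scores_svm_test.csv --out report.csv
```

`--age-cutoff` accepts days or the presets `1y` (365) and `18m` (548).
Study outputs: `report_test.csv` / `report_oof.csv` (one row per classifier:
`method,auc,auc_lo,auc_hi,sensitivity,...,p_value,n_case,n_control`),
per-family score and selection CSVs (in-fold selections included, for
leakage audits), and a `manifest.json` that makes the run byte-reproducible.

## Library layout

| module              | contents                                                        |
| ------------------- | --------------------------------------------------------------- |
| `vocdx.synthetic`   | `SyntheticConfig`, FAIMS/eNose cohort generators                 |
| `vocdx.wavelets`    | periodized D4 2D multilevel DWT (orthonormal, exact inverse)     |
| `vocdx.faims`       | `FaimsSample`, CSV dialects, wavelet feature extraction          |
| `vocdx.enose`       | `EnoseSample`, trace I/O, response/variance features             |
| `vocdx.selection`   | Wilcoxon rank-sum ranking + top-k, Boruta                        |
| `vocdx.classify`    | split/CV/tuning protocol, the four classifier families           |
| `vocdx.evaluate`    | ROC/AUC, bootstrap CIs, operating points, PCA/LDA projections    |
| `vocdx.pipeline`    | `StudyConfig`, `run_study`, age stratification                   |

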