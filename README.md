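# igri

A 0–1 continuous glaucoma severity index combining six routine examination
features — PSD and MD from the visual field test, superior/inferior/temporal
RNFL thickness from OCT, and IOP — into a single interpretable score:

1. **Normalization** — each feature is min-max scaled onto [0, 1] with
   published bounds (out-of-range values saturate), and the features whose
   clinical direction opposes severity (MD and the three RNFL sectors) are
   flipped via `1 − x`, so larger always means more severe.
2. **NNI** — a synthesized seventh feature: the fraction of glaucoma-labeled
   cases among the 5 nearest reference cases in the normalized space.
3. **Index** — `igri = 0.8 · (wᵀx) + 0.2 · NNI`, with importance weights
   `(0.27, 0.14, 0.11, 0.31, 0.10, 0.07)` derived from a gradient-boosted
   classifier. Classification: glaucoma iff `igri > 0.36` (strict). Staging
   within glaucoma uses raw MD bins (advanced < −12 dB, intermediate
   [−12, −5], early above).

The package also provides recalibration from a labeled cohort (importance
weights, decision threshold, mixing-ratio sweep), a synthetic two-class
cohort generator (truncated multivariate Gaussians anchored to typical
glaucoma/normal profiles) standing in for the original hospital data, and
an evaluation surface (misclassification, group separation, NNI ablation
with histogram-overlap comparison, MD correlation, stage-wise summaries).

## CLI

```sh
# Generate a labeled synthetic cohort (and its normalized reference)
igri simulate --seed 1 --output cohort.csv --reference-output ref.csv

# Score examinations against a reference dataset
igri score --input exams.csv --reference ref.csv --output scores.csv

# Recalibrate weights + threshold from a labeled cohort
igri calibrate --cohort cohort.csv --seed 17 --output model.json

# Full numeric evaluation report
igri evaluate --cohort cohort.csv --reference ref.csv --report report.json
```

Exam/cohort CSVs carry columns `PSD, MD, RNFL_S, RNFL_I, RNFL_T, IOP`
(any order, case-insensitive) plus optional `label` (0 normal / 1 glaucoma).
The default model configuration (bounds, weights, ratios, threshold,
staging bins) ships with the package (`src/igri/data/default_config.json`)
and can be overridden with `--config`.

## Layout

- `src/igri/core_model.py` — domain types, validation, default constants
- `src/igri/normalization.py` — min-max scaling, reversal, record transform
- `src/igri/nni.py` — nearest-neighbor index (deterministic tie-breaking)
- `src/igri/index.py` — base/final index, classification, MD staging
- `src/igri/calibration.py` — importance derivation, threshold search, ratio sweep
- `src/igri/synthetic_cohort.py` — cohort generator and reference builder
- `src/igri/evaluation.py` — evaluation metrics and reports
- `src/igri/cli_io.py`, `src/igri/cli.py` — file formats and the `igri` CLI
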