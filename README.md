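# rhythm-mtl

Behavioral-rhythm feature extraction and multi-task learning for
predicting fine-grained momentary (EMA) symptom scores from smartphone
sensing streams — with a synthetic-cohort generator that plants known
rhythm structure, sparse weight supports, and patient subtypes so the
whole pipeline is testable without any restricted clinical data.

## What's inside

| module | role |
|---|---|
| `rhythm_mtl.synthetic` | cohort generator: sinusoid-driven continuous streams, inhomogeneous-Poisson event streams, EMA labels from a sparse linear map of the true rhythm features, planted subtypes |
| `rhythm_mtl.hourly` | sensor-stream containers, hourly binning, gap filling |
| `rhythm_mtl.metrics` | rhythm metrics: multiscale sample entropy, periodogram band power, M10/L5, relative amplitude, deviation-from-template, interday stability, intraday variability |
| `rhythm_mtl.features` | windowed feature extraction; canonical `[Modality]⊗[Metric]⊗[Window]` feature space with ultradian/circadian/infradian tags |
| `rhythm_mtl.models` | personalized/pooled LASSO, l2,1-regularized multi-task regression (across symptoms or across patients, proximal-gradient solver), multi-output least-squares SVR (linear/RBF) |
| `rhythm_mtl.evaluation` | protocols A–G (fivefold, semi-LOSO, LOSO, chronological 80/20), RMSE tables, paired Wilcoxon signed-rank, Holm–Bonferroni |
| `rhythm_mtl.interpretation` | feature ranking, per-dimension factor contributions, K-Means subtyping with silhouette model selection |
| `rhythm_mtl.pipeline` / `rhythm_mtl.cli` | end-to-end orchestration with deterministic outputs |

## CLI

```bash
# full pipeline: generate -> extract -> evaluate -> interpret
rhythm-mtl run --out out/demo --seed 7

# or stage by stage
rhythm-mtl generate --out out/cohort --seed 7
rhythm-mtl extract  --cohort out/cohort/manifest.json --out out/features
rhythm-mtl evaluate --cohort out/cohort/manifest.json \
    --algorithms B,C,F --scheme chronological --out out/eval.csv
rhythm-mtl interpret --cohort out/cohort/manifest.json --out out/interp
```

A YAML config (`--config`) can override the cohort design (patients,
days, modalities, subtype spec, noise), the algorithm list (A–G), the
evaluation schemes, and the regularization. Identical config + seed
gives bit-identical outputs.

## Protocol ids

A m-SVR (linear) · B m-SVR (RBF) · C MTL-patients (l2,1) ·
D personalized MTL-symptoms · E generalized MTL-symptoms ·
F personalized LASSO · G generalized LASSO
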