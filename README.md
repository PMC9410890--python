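# punctasurv

Longitudinal single-neuron survival analysis from two-channel fluorescence
time-lapse movies, with coefficient-of-variation (CV) based aggregate
classification.

## The problem

In longitudinal imaging assays of neurodegeneration, transfected primary
neurons are imaged once every 24 h for 10 timepoints. A constitutive cell-fill
fluorophore (the *tracking* channel) identifies each neuron and reveals its
death as loss of signal; a GFP-tagged construct (the *reporter* channel) shows
whether the protein of interest is distributed diffusely or condensed into
inclusions (aggregates). Two quantitative questions follow:

1. **Which neurons carry aggregates?** The aggregate score is the coefficient
   of variation of reporter intensity within a neuron's ROI,
   CV = σ/μ (population standard deviation over mean, background-subtracted).
   Diffuse neurons have low spatial variability; punctate neurons high. The
   rule **CV ≥ 1.0 ⇒ aggregated** is validated by ROC analysis on a labeled
   ROI set (n = 50 per class), reporting AUC, the Youden-optimal threshold
   (argmax TPR − FPR), sensitivity and specificity.
2. **Do aggregates change survival?** Each neuron contributes a
   right-censored survival record (death interval × 24 h, or censoring at
   240 h). Cumulative risk of death is estimated as 1 − Ŝ(t) with the
   Kaplan–Meier product-limit estimator, and hazard ratios come from the Cox
   proportional-hazards model

   λ(t | x) = λ₀(t) · exp(βᵀx),

   maximized via the partial likelihood with the **Efron correction** for the
   heavy ties produced by the 24 h grid (Newton–Raphson from β = 0; Wald and
   likelihood-ratio tests; 95% CIs on the log-HR scale).

Because no imaging data accompany the assay, the package ships a calibrated
**synthetic cohort generator**: neurons with known (planted) aggregate status,
per-interval geometric death hazards modified by aggregate status, conserved
reporter flux between phenotypes, Poisson shot noise + Gaussian read noise,
and per-interval centroid drift. Every stage of the pipeline — segmentation
(Otsu threshold on the tracking channel), greedy mutual-nearest-neighbour
track linking, death calling, CV classification, survival modeling — is
therefore testable against exact ground truth. Pearson and Manders (M1/M2,
plus a pixel-count M2 variant) colocalization metrics for two-channel
confocal images round out the toolkit.

## Worked example

```python
import json
from punctasurv import GeneratorConfig, GroupSpec, PipelineConfig, run_pipeline

config = PipelineConfig(
    generator=GeneratorConfig(
        seed=1,
        n_neurons_per_group=300,
        groups=(
            GroupSpec("nGFP", aggregate_probability=0.0,
                      baseline_hazard_per_interval=0.02),
            GroupSpec("CGG", aggregate_probability=0.485,
                      baseline_hazard_per_interval=0.03,
                      aggregate_hazard_multiplier=2.0),
        ),
    )
)
report = run_pipeline(config, out_dir="out/demo")
print(json.dumps(report.calibration, indent=2))
print(json.dumps(report.groups, indent=2))
```

prints (abridged):

```
"calibration": {"auc": 1.0, "youden_threshold": 0.997,
                "applied_threshold": 1.0,
                "sensitivity": 0.98, "specificity": 1.0}
"nGFP": {"n_analyzed": 296, "aggregate_bearing_pct": 0.0,
         "cumulative_risk_final": 0.169}
"CGG":  {"n_analyzed": 284, "aggregate_bearing_pct": 46.1,
         "cumulative_risk_final": 0.324}
group model: HR[CGG vs nGFP] = 2.13 (p = 1.8e-05)
CGG aggregate model: HR = 1.58 (95% CI 1.05-2.39, p = 2.9e-02)
```

Reading the output: the CV classifier, calibrated on a 50 + 50 labeled ROI
set rendered by the same engine, separates the classes at a Youden threshold
of ≈1.0 and makes no false aggregate calls in the diffuse-only control group;
the planted 48.5% aggregate-bearing fraction is recovered as 46.1% of the 284
analyzable CGG neurons; CGG neurons die at about twice the control hazard,
and within the CGG group aggregate-bearing neurons carry an additional ~1.6×
hazard. The reported Youden threshold, percentages, hazard ratios and
p-values vary with the seed.

The same stages are available from the shell:

```bash
punctasurv simulate --out sim/ --seed 1
punctasurv track --movie sim/CGG_w0.tif --out tracks.csv
punctasurv classify --tracks tracks.csv --threshold 1.0 --out calls.csv
punctasurv survive --records records.csv --model "group+aggregate" --out fit.json
punctasurv run --out run1/ --seed 1          # full pipeline + report.json
```

## Layout

- `punctasurv.synthetic` — ground-truth cohort sampling, movie rendering,
  labeled ROI sets
- `punctasurv.imaging` — background subtraction, segmentation, linking,
  death calling, CV
- `punctasurv.aggregation` — ROC/AUC, Youden threshold, ROI/neuron calls,
  sklearn-style `CVThresholdClassifier`
- `punctasurv.survival` — records, Kaplan–Meier, Cox (Efron/Breslow),
  Wald/LR tests
- `punctasurv.coloc` — Pearson, Manders M1/M2 (+ pixel-count variant)
- `punctasurv.pipeline` / `punctasurv.cli` — orchestration, formats, report
- `docs/methods.md` — model assumptions, parameter choices, limitations
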