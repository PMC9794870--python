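# brainage-bag

Multimodal brain-age prediction and brain-age-gap analysis on synthetic
cohorts and imaging phantoms.

The difference between a person's chronological age and the "biological"
age a model reads from their brain MRI — the **brain age gap (BAG)** — is a
candidate biomarker for deviation from healthy brain aging.  Estimating it
well raises a chain of methodological questions: hand-crafted morphometric
features versus raw images as model input, single- versus multi-modal data
(T1-weighted MRI for tissue, time-of-flight MR angiography for arteries),
how to fuse several estimators, how to remove the systematic age bias of
age-regression models, and how to test BAG associations with cardiovascular
risk factors.  This package implements that entire analysis as a tested,
reproducible pipeline.  Because clinical cohorts of this kind are
access-restricted, it ships a first-class synthetic-data module: cohorts
with known demographics and a hidden per-subject brain-age offset driven by
the risk factors, a 223-column T1 morphometry table, and 3-D T1-like and
TOF-MRA-like phantoms with age-dependent atrophy and artery thinning —
so every stage can be validated against known ground truth.

The pipeline, per age-stratified 5-fold cross-validation fold:

1. **Features** — artery segmentation, Lee-style 3-D thinning to a
   centerline, distance-transform thickness, and aggregation into 24
   artery features (11 segment diameters, 6 territory diameters, 6
   territory densities, 1 global diameter).
2. **Predictors** — MLPs on feature tables (223 T1 features; 24 artery
   features + total brain volume) and compact fully-convolutional 3-D CNNs
   on volumes (conv–batchnorm–maxpool–ReLU blocks with 32/64/128/256
   filters), trained with Adam on MSE, checkpointing on the lowest
   validation loss.
3. **Fusion** — stacked linear regression: chronological age ~ the models'
   validation predictions; weights applied to test predictions; Wilcoxon
   signed-rank comparisons of absolute errors.
4. **Bias correction** — fit `predicted = α·age + β` on validation,
   correct test predictions by `pred + [age − (α·age + β)]`;
   BAG = corrected − age.
5. **Associations** — per model and risk factor,
   `BAG = β₁·age + β₂·sex + β₃·z(factor)`, with Benjamini–Hochberg FDR
   over the 4 × 5 test family.
6. **Saliency** — SmoothGrad voxel maps for CNNs and feature rankings for
   MLPs.

See `docs/methods.md` for the generative model, estimators and numerical
conventions.

## Worked example

```python
from brainage_bag import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(n_subjects=400, grid_size=48, seed=1))
print(result.metrics.round(2))
```

takes ~9 minutes on one CPU (the `desk` training profile) and prints:

```
                mae  mae_sd  pearson_r  pearson_r_sd  bias_r  bias_r_sd
model
Null          11.12    0.24        NaN           NaN   -1.00       0.00
MLP_T1         5.55    0.66       0.86          0.06   -0.50       0.17
MLP_TOF        7.95    0.71       0.70          0.05   -0.71       0.12
CNN_T1         5.51    1.03       0.92          0.01   -0.75       0.20
CNN_TOF        8.23    0.66       0.69          0.05   -0.83       0.03
Combined_T1    4.38    0.37       0.92          0.01   -0.35       0.13
Combined_TOF   7.68    0.66       0.71          0.05   -0.71       0.04
Combined_MLP   5.30    0.41       0.88          0.04   -0.47       0.12
Combined_CNN   4.55    0.51       0.92          0.01   -0.38       0.14
All_combined   4.46    0.38       0.92          0.00   -0.36       0.12
```

Reading the table: every model beats the null baseline of 11.1 years
(training-mean prediction), the T1 modality out-predicts the artery-only
TOF inputs, and stacking helps — the all-model combination (MAE 4.46,
r 0.92) edges out the CNN-only stack.  The `bias_r` column is the
age-related bias r(predicted − age, age): all raw models over-predict young
and under-predict old subjects (negative values; the null model is −1 by
construction).  After the validation-fitted linear correction
(`result.corrected_metrics`) those biases collapse to |r| ≤ 0.05, and the
association stage then finds the risk-factor signal that the generator
injected — e.g. in this run BMI and WHR significant for the MLP-based
BAGs and BP for the TOF models (β₃ ≈ 0.7–1.8 years per sd, all positive:
higher risk burden looks like an older brain), with alcohol null:

```python
print(result.associations[result.associations.significant])
print(result.corrected_metrics.round(2))
```

A thin CLI wraps the same functions:

```bash
brainage-bag run --seed 1 --out-dir runs/demo       # full experiment
brainage-bag simulate cohort --n 1658 --seed 0 --out cohort.csv
brainage-bag extract-vessels --tof sub-00000_tof.nii.gz --out features.csv
```

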