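# Methods

`brainage-bag` re-creates, end to end and on fully synthetic data, a
multimodal brain-age analysis: estimate a biological brain age from brain
MRI-derived inputs, fuse several estimators, correct the systematic
age-related bias of age regression, and test whether the resulting brain age
gap (BAG) is associated with cardiovascular risk factors.  This note
describes the generative model, the estimators, the statistical procedures
and the numerical choices, and states what the synthetic setting can and
cannot show.

## The generative model

**Cohort.**  Subjects carry chronological age, sex and five cardiovascular
risk factors: systolic blood pressure (BP, mmHg), body-mass index (BMI,
kg/m²), waist-to-hip ratio (WHR), smoking status (ordinal 0–4) and alcohol
consumption (ordinal 0–3).  Ages follow a truncated normal on [21, 81]
whose *truncated* mean and sd equal the configured 49.9 / 13.7 — the
parent parameters are solved numerically, because a cohort whose summary
table prints those moments exhibits them after truncation.  All other
marginals are configurable; defaults are a 909:749 female:male split,
BP ~ N(126.0, 16.4), BMI ~ N(27.3, 4.2), WHR sex-conditional
N(0.82, 0.06)/N(0.94, 0.07), smoking weights (668, 56, 347, 266, 321) and
alcohol weights (112, 458, 963, 125).  Factor–age correlations default to
zero and can be switched on through a Gaussian copula on the latent
normals, which preserves every marginal.

**Hidden brain-age offset.**  Each subject receives a latent offset δ
(years), the ground-truth brain age gap:

    δ = Σ_f γ_f · z_f + ε,   ε ~ N(0, 5²)

with loadings γ (years per sd of factor) of 0.7 for BMI, 0.6 for WHR, 0.5
for BP, 0.3 for smoking and 0 for alcohol — obesity markers strongest,
alcohol null, matching the direction of the associations the pipeline is
meant to detect.  Every age-dependent generator responds to the *effective*
age `age + δ`.  Two consequences are deliberate: (i) no model can beat an
MAE floor of roughly E|δ − E[δ|x]|, so prediction accuracy saturates at a
realistic few years instead of collapsing to zero on synthetic data; and
(ii) a model that recovers effective age well has BAG ≈ δ, so the
association stage has a real signal to find.

**T1 morphometry table.**  223 features named in a FastSurfer-like schema
(31 subcortical/global volumes + 64 cortical structures × area / gray
volume / thickness; the name list ships as package data).  Each feature is
linear in effective age, sex and the standardized risk factors, plus
independent Gaussian noise; per-feature intercepts, slopes and noise sds
are drawn once per seed from ranges that mimic structural aging (cortical
thinning ≈ 0.003–0.008 mm/yr, ventricular expansion, total brain volume
−1800 mm³/yr, male offsets positive for areas/volumes) and are returned in
the `GroundTruth` object for recovery tests.

**T1-like phantom.**  A bright tissue ellipsoid whose outer extent shrinks
with effective age (atrophy, 0.0006 of the grid per year) around a dark
ventricle ellipsoid that grows (0.0012/yr) with a small per-subject size
jitter; Gaussian noise; the volume is center-scaled to zero mean / unit sd.

**TOF-like phantom and atlas.**  Eleven artery segments (PCA L/R, MCA-M1
L/R, MCA-M2 L/R, BA, ICA L/R, ACA-A1, ACA-A2) are drawn as bright tubes
along fixed piecewise-linear centerlines.  Tube radius per segment is
`baseline − 0.010 mm/yr · (effective age − 21) + caliber + jitter`, with a
per-subject common caliber (sd 0.12 mm) and per-segment jitter (sd
0.08 mm), clamped at one voxel.  The deterministic ROI atlas labels six
flow territories (ACA/MCA/PCA × L/R, tiling the brain mask by two coronal
planes and the sagittal midplane) and the eleven segments as
nearest-centerline capture regions.  The A1/A2 segments run along the
midline and carry single labels, which is also how the 24-feature schema
(11 segment diameters + 6 territory diameters + 6 territory densities + 1
global diameter) stays consistent.

Phantom design notes: centerline control points snap to voxel centers and
straight segments carry a one-voxel lateral drift, because a tube axis
lying between voxel centers has a blocky cross-section whose distance
transform saturates below the nominal radius; baseline radii are placed so
the lifetime thinning sweep avoids the gaps in the discrete spectrum of
attainable distance-transform values (after 1.41 and 2.24 voxels).  These
are grid-resolution considerations, not anatomy.

## Vessel morphometry

Segmentation is a threshold at `mean + k·sd` (default k = 2; phantoms are
high contrast) with connected components under 10 voxels removed; any
externally produced mask can be substituted.  The centerline comes from
topology-preserving 3-D thinning (Lee-style, via scikit-image).  Thickness
at each centerline voxel is the Euclidean distance transform of the mask
(spacing-aware, distance to the nearest *background voxel center* — an
overestimate of the true boundary distance by up to half a voxel; a single
isolated voxel has thickness one voxel spacing).  Reported diameters are
2 × thickness.  Aggregation takes per-segment and per-territory means over
centerline voxels and per-territory density = mask voxels / territory
voxels; empty regions yield 0 with a logged warning.  Junction regions
bias segment means slightly low (the skeleton cuts corners where tubes
merge); on noiseless phantoms the per-segment error stays within one voxel
spacing.

## Age predictors

Two MLPs (223 T1 features; 24 artery features + total brain volume) and
two 3-D CNNs (T1-like and TOF-like volumes).  The CNN is a compact fully
convolutional regressor: four blocks of [3×3×3 conv (same padding),
batch-norm, 2×2×2 max-pool, ReLU] with 32/64/128/256 filters, a 1×1×1
conv block with 64 filters, then global average pooling, dropout 0.5 and a
linear unit.  Inputs must be ≥ 16 per axis to survive the four poolings.
MLPs use ReLU hidden layers from the candidate grids (256), (256,128),
(256,128,64), (256,128,64,32) for T1 and (32), (16,32), (8,16,32),
(4,8,16,32) for TOF; defaults are two and three hidden layers
respectively, and `select_mlp_architecture` can re-run the grid per fold
on validation MAE.  MLP inputs are z-scored with a scaler fitted on the
training fold only; the learning rate of 0.1 is only workable on scaled
inputs.

The models are trained with a hand-written numpy engine (dense and 3-D
convolution layers with explicit backward passes, Adam, MSE loss; float32
by default, float64 available for gradient verification, which the test
suite does against central differences).  Having the backward pass in
hand also supplies the exact input-space gradients SmoothGrad needs.
Training protocol: Adam, MSE; MLP lr 0.1 / batch 200 / 1000 epochs, CNN
lr 0.001 / batch 8 / 200 epochs; validation loss is evaluated after every
epoch and the returned model is the checkpoint with the lowest validation
loss, never simply the last epoch.  Targets are mean-centered on the
training fold (offset restored at inference): with raw targets near 50
years, Adam's effectively fixed-magnitude steps cannot move the output
head far enough at any usable learning rate, and centering is what lets
the noiseless-target test converge below 0.5 years MAE.  Augmentation
draws, for a random half of each batch, per-axis rotations uniform in ±5°
and integer translations uniform in ±10 voxels, applied as a single
linear-interpolation affine pass with the median corner intensity as fill.

**Training profiles.**  The `full` profile trains the complete protocol above
on native grids.  The `desk` profile, used by the test suite and the
reproduction script, is sized for a single CPU: volumes down-sampled 2×
before the CNN, narrower filters (8/16/32/64), 8 CNN epochs and 300 MLP
epochs, translations ±3 voxels on the coarser grid.  Phantom age signals
are strong and low-dimensional, so the slim CNNs reach their plateau
within a few epochs; the profile is a sizing choice of this package, and
all structural conclusions (models beat the null, stacking helps, bias
correction works) are unchanged between profiles.

## Evaluation, fusion, bias correction, associations

**Cross-validation.**  Age-stratified 5-fold CV: subjects are ranked into
10 age-quantile bins and dealt round-robin to test folds (a global counter
keeps fold sizes within one subject).  Per fold, `round(0.15 · n)`
validation subjects are drawn age-stratified (largest-remainder allocation
over bins) from the training portion — 249 per fold at n = 1,658.  The
validation set serves three purposes: checkpoint selection, stack fitting
and bias-parameter estimation; test subjects touch none of them.  The null
model predicts the training-mean age.  Metrics: MAE, Pearson r(age,
predicted), and age bias r(predicted − age, age), reported per fold with
mean and sd.  Conventions: constant predictions give r = NaN with a
warning; a constant gap gives bias 0; the null model's bias is −1 under
this signed convention (a printed value of +1 for a null model refers to
the magnitude).

**Stacking.**  Per fold, OLS of chronological age on the individual
models' validation predictions (intercept included by default, flag to
disable); the weights are applied to the fold's test predictions.  Five
combinations are reported: T1 pair, TOF pair, MLP pair, CNN pair, and all
four.  Coefficients are also reported as shares normalized by the
coefficient sum — they always sum to 1 and can be negative.  Collinear
designs (condition number > 1e8) warn and fall back to the minimum-norm
solution.  Fitting per fold rather than pooling avoids leaking validation
data across folds.  Pairs of models are compared by two-sided Wilcoxon
signed-rank tests on pooled per-subject absolute test errors (zeros
dropped; exact distribution for ≤ 25 pairs, normal approximation with tie
correction above).

**Bias correction and BAG.**  Per fold and model, OLS of predicted on
chronological age over the validation set gives (α, β); test predictions
are corrected by `pred + [age − (α·age + β)]` and BAG = corrected − age.
On the fitting set this makes the BAG exactly mean-zero and
age-orthogonal (OLS residual identity, asserted to 1e-10); on test folds
it shrinks the bias without nulling it, which is the expected behavior.

**Associations.**  Per model and factor, OLS of BAG on chronological age,
sex (0 female / 1 male) and the factor z-scored over the analysis
subjects, with an intercept (the printed three-coefficient form of such
models omits it, but the reference implementation fits one, and with
standardized factors it is immaterial).  Two-sided p-values for the
factor coefficient are Benjamini–Hochberg corrected over the joint
4 models × 5 factors = 20-test family; q < 0.05 is called significant.
Only the factor coefficient enters the FDR family.

**Saliency.**  SmoothGrad: mean |∂output/∂input| over n = 25 copies of the
input perturbed with Gaussian noise of sd 10 % of the input range
(absolute-value aggregation; σ → 0 recovers the plain gradient map).  For
MLPs the per-feature map is returned as a descending ranking with
schema-order tie-breaks.

## Reproducibility

Every generator and training run takes an explicit seed; the experiment
driver fans one root seed out through `numpy.random.SeedSequence`
children, so a full run is bit-reproducible from its config (the pipeline
test runs the miniature experiment twice and compares tables exactly).
Intermediates are written in open formats: NIfTI volumes, CSV/TSV tables,
YAML configs and ground truth.

## What the synthetic setting shows — and does not

Passing tests show that the machinery is correct: generators with known
structure, feature extraction against analytic oracles, exact OLS and
rank-test identities, checkpointing, leakage-free CV, and an end-to-end
run in which every model beats the null, stacking at least matches the
best pair, bias correction shrinks the age bias, and the injected
risk-factor loadings surface as significant associations in the expected
direction.  They do not show radiological realism: phantoms have no
texture, no registration error, no scanner effects; TOF phantoms carry
artery signal only, so the TOF CNN and the artery-feature MLP converge to
similar accuracy, whereas on real angiography a CNN can exploit
incidental tissue contrast and do better; and the morphometry table is
linear in its generators, which flatters MLPs relative to real cortical
measurements.  Absolute MAEs on synthetic data are set by the chosen δ
variance and are not comparable to values reported on clinical cohorts.

## Known limitations

* Segment mean diameters are biased low near junctions and saturate at
  the discrete distance-transform spectrum for sub-voxel radii; phantom
  radii are chosen where the grid resolves them.
* The vessel segmenter is a threshold; it is a stand-in interface for a
  proper vascular segmentation method and is only adequate for
  high-contrast phantoms.
* Batch-norm running statistics come from momentum-0.9 averaging over
  training batches; with very few epochs inference statistics can lag,
  which is visible in the miniature pipeline test as near-constant CNN
  predictions (the desk and full profiles train long enough for this not
  to matter).
* The experiment driver holds all phantom volumes in memory
  (~350 MB at n = 400, 48³ float32); cohort sizes beyond a few thousand
  at this grid would need the on-disk NIfTI path instead.
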