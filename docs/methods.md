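# Methods

## Problem and model

`mrct` translates 2-D sagittal T1-weighted MR slices into CT-like images in
Hounsfield units (HU), for radiotherapy workflows that need an
electron-density surrogate and CT-comparable soft-tissue contrast when no
CT is available. The core difficulty is twofold: (i) CT spans roughly
−1000 HU (air) to 2000+ HU (dense bone), while nearly all soft-tissue
contrast lives in a ~200 HU band around water, so a naive regression loss
is dominated by air/bone errors; (ii) on T1 images both air and cortical
bone are nearly signal-free, so the MR→HU mapping is not a pointwise
intensity lookup — the model must use spatial context.

The method addresses (i) by partitioning the HU axis into three windows —
air (−∞, −100), soft tissue [−100, 100], bone (100, ∞) — and regressing
three *channel images* at once: each channel equals the CT inside its
window and 0 HU outside. The windows partition the intensity axis, so
splitting and then summing the channels is an exact identity; at inference
the predicted channels are summed back into one HU image with no clamping
or re-masking. The boundary convention (closed tissue interval, open
air/bone) is our fixed choice; the identity holds for any placement of the
endpoints as long as the three sets partition the line.

The translation network is a U-Net: an encoder of `depth` stages that
halves resolution and doubles filters per stage (strided 3×3
convolutions), a mirrored decoder (2×2 stride-2 transpose convolutions),
and channelwise concatenation of the resolution-matched encoder feature
map before each decoder convolution. Every convolution is followed by
batch normalization and Leaky ReLU (slope 0.2) except the final 3×3
projection to the 3 channels, which is linear — outputs are unbounded
regression values in normalized channel space. Two profiles are
predefined: full scale (depth 5, base 64 — the last decoder stage has 64
channels, so the final convolution maps 64 → 3) and a desk profile (depth
3, base 8) that trains in minutes on one CPU.

The objective is, per channel, MAE + MSE of the normalized channel values,

L_tot = Σ_c [ (1/n) Σ_i |X_c,i − Y_c,i| + (1/n) Σ_i (X_c,i − Y_c,i)² ],

with the three channels equally weighted (weights are exposed in the
configuration for ablation). The MSE is the mean *squared difference*; a
difference-of-squared-values form is signed and cannot serve as a
distance, so it is not implemented. Optimization is Adam; convolution
weights are initialized N(0, 0.01²), biases 0, batch-norm scale/shift 1/0,
from a seeded generator.

The network stack (convolutions, batch norm, transpose convolutions,
backprop, Adam) is implemented in numpy inside the package (`mrct.nn`),
with convolutions evaluated as BLAS matrix products on im2col patch
matrices. The backward passes are validated in the test suite against
central finite differences.

## Normalization constants

Inputs and each output channel are mapped to network space by fixed affine
constants (never data-derived), with zero offsets so masked-out 0 HU stays
0. The relative per-channel scales are a real design choice:

* scaling each window by its own dynamic range (air/bone ÷1000, tissue
  ÷100) equalizes the three channel losses, but in HU terms it
  under-penalizes air/bone channel *leakage* — nonzero air/bone channel
  output at soft-tissue pixels that corrupts the recombined sum (on
  phantoms we measured 19 + 13 HU of leakage against < 3 HU of
  tissue-channel error);
* uniform scaling makes every HU error equally expensive, which
  reinstates exactly the air/bone dominance the channel split is meant to
  remove.

The defaults sit in between — tissue ÷100, air and bone ÷200, MR ÷100 —
selected by a small sweep on phantom cohorts as the best recombined
soft-tissue accuracy. All constants live in `NormalizationSpec` and are
stored inside every checkpoint, so a checkpoint is self-describing.

## Training protocol

Mini-batch Adam over aligned (MR, CT) slice pairs. The full-scale protocol
is batch 32, 150 epochs, 5-fold cross-validation; folds are split by
patient (never by slice — neighboring slices are near-duplicates and
slice-level splitting would leak them into validation), shuffled
deterministically, sizes differing by at most one (47 patients → 10, 10,
9, 9, 9). Augmentation applies one identical random transform to MR and
CT: an optional 90° grid rotation (lossless) and a random crop with
per-axis fraction in [0.8, 1.0] resized back to the grid (bilinear).
Cropping happens *before* the CT is split into channels; interpolating
already-split channels could manufacture out-of-window values. The loss is
computed in normalized space; reported evaluation MAE is always in HU
after denormalization. Each run records per-epoch training/validation
loss, aborts with a diagnostic on non-finite loss, and keeps both the
final and the best-validation checkpoint; the best-validation weights are
used for evaluation. An optional one-step learning-rate decay
(`decay_factor` at `decay_at_frac` of the epochs) is available and is used
by the desk profile.

Adam defaults are lr 2e−4, betas (0.9, 0.999) at full scale; the desk
profile uses batch 8, lr 1e−2 with a ×0.2 step-down after 75% of 60
epochs, and no augmentation. These values were tuned on phantoms for the
small network; none of them is data-derived at run time.

## Synthetic phantoms

Paired clinical MR/CT volumes cannot be redistributed, so all end-to-end
behavior is demonstrated on parametric sagittal head phantoms: an
elliptical head with scalp, bony skull shell, cortical gray-matter band,
white matter, a CSF ventricle and an air-filled frontal sinus. Per-slice
in-plane geometry scales like cross-sections of an ellipsoid along the
left-right axis, with a symmetric lateral-offset schedule (mirrored
offsets give identical geometry — the left-right symmetry that motivates
sagittal training). Tissue means place every class safely inside its
window (air −1000, CSF 10, white 25, gray 40, scalp 60, bone 1000 HU); MR
means give soft tissues distinct values (CSF 20, gray 60, scalp 70, white
80) while air (0) and bone (5) overlap under the default MR noise (σ = 5)
by more than 50% — so low bone/air error demonstrably requires spatial
context. Noise is additive Gaussian, independent per pixel (CT σ = 15 HU
by default); boundaries are crisp unless a smoothing width is set.

What the phantoms do *not* model: real neuroanatomy, MR bias fields and
sequence physics, partial-volume mixtures, motion, immobilization
hardware. Passing desk-scale tests therefore demonstrates that the
pipeline is implemented correctly and that the architecture can exploit
spatial context on data with the assumed statistical structure — not
clinical-grade accuracy.

## Desk-scale study conditions

All quoted learning results use one fixed configuration
(`mrct.experiments`): 10 noiseless phantom patients of twenty 48×48 slices
each (about 200 slices), 8 for training and 2 held out, the depth-3/base-8
profile, and the desk schedule above (~2 minutes per run on one CPU).
Reported metrics: recombined-image MAE per tissue region within the
analytic head mask, the tissue-channel MAE against the split ground-truth
channel, and the analytic best-constant baselines for both (the constant
minimizing MAE is the median; any useful model must beat it). At this
scale the trained model's tissue-channel MAE falls far below its constant
baseline and the tissue-region MAE is well under 30 HU, while the
tissue-region MAE does not drop below its own ~13 HU constant baseline —
residual air/bone channel leakage at window boundaries dominates; a finer
grid and longer schedule reduce it. The data-volume experiment retrains
from identical initialization on 10% vs 100% of the training slices and
compares held-out MAE (one training patient serves as the
validation monitor so the test patients never influence checkpoint
selection).

## Evaluation

Synthetic CT is compared with ground truth inside a head mask, voxelwise
and per region, where regions are the *ground-truth* CT's window
memberships — this keeps the metric independent of where the model thinks
boundaries are. Empty regions report a count of 0 and an undefined (NaN)
MAE, never 0. The exact identity `MAE_all = Σ count_r · MAE_r / Σ count_r`
holds by construction and is tested. Cohort summaries report mean,
*population* standard deviation (divisor n — the convention that
reproduces the published reference table), minimum and maximum. Head masks
are either the phantom's analytic mask or computed from MR by Otsu
thresholding → morphological closing → largest connected component → hole
filling; cropping at the inferior skull border is not attempted.

## Numerical and degenerate-input choices

Float32 tensors throughout training; losses accumulated in float64 in the
public metric functions. HU ingest may be clamped to [−1024, 3000].
Non-finite pixels are rejected at channel splitting (with a count of
offending pixels), shape mismatches name both shapes, empty masks and
empty cohorts are errors, normalization state is tracked on every channel
stack and mixed states are rejected. The |d| subgradient at 0 is taken as
0. Inputs whose height/width are not divisible by 2^depth are
symmetrically zero-padded and cropped back after prediction.

## Known limitations

* Phantom realism as above; no claim of clinical accuracy transfers.
* The desk profile's hyperparameters are tuned for 48×48 phantoms and do
  not transfer unchanged to full-scale images.
* Air MAE within the mask is dominated by the small sinus region and
  converges slowest; at desk scale it remains the largest regional error.
* Single-device training only; no mixed precision, no hyperparameter
  search, no adversarial or perceptual objectives.
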