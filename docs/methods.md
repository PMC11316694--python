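# Methods

This note records the scientific and numerical choices behind
`adiposeg`: what is modelled, which parameters matter, what the
synthetic data generator does and does not emulate, and where the design
was genuinely open.

## Problem setting

Abdominal adipose tissue on two-point Dixon MRI separates into a
subcutaneous ring (SAT) and visceral fat scattered among the organs
(VAT). Volumes of both compartments, and their change between repeated
scans, are the quantities of clinical interest. Segmentation is posed as
3-class voxel labelling (background / SAT / VAT) of a full
field-of-view multi-contrast volume: the opposed-phase echo, the water
image and the fat image are stacked as input channels and the whole
stack is processed in one forward pass — no 2D slices, no 3D patches —
so the network can use global in-plane and through-plane context. That
context is what makes VAT separable from fat-bright non-VAT structures
(vertebral bone marrow, bowel contents) that share its intensity.

## Network families

All three families are encoder–decoders over `(C, x, y, z)` arrays and
end in a 1×1×1 convolution to 3 classes followed by a channel softmax.

* **`unet3d`** — classic 3D U-Net: per resolution level, two 3×3×3
  convolutions each followed by batch normalization and ReLU; 2×2×2 max
  pooling; 2×2×2 transposed-convolution upsampling; skip concatenation.
  With widths 64/128/256/512 this builds to 22 403 011 trainable scalars
  (weights, biases, normalization affine pairs), i.e. 22.4 M at one
  decimal — the figure the acceptance script recomputes.
* **`acd_unet3d`** — the competitive dense variant. Within a block,
  incoming feature maps compete by element-wise maximum before each
  convolution, holding the channel width constant instead of letting
  dense concatenation grow it; the decoder also merges the upsampled
  path with the skip path by maximum rather than concatenation. The
  bottleneck appends a convolutional attention block: a channel gate
  from average- and max-pooled descriptors through a shared
  reduction-8 MLP, then a spatial gate from a 3×3×3 convolution over
  channel-pooled maps. The maxout skip merge is why this family is
  *smaller* than the plain U-Net (20.1 M at full width) despite the
  added attention parameters.
* **`nnunet_like`** — the resolved nnU-Net-style configuration only
  (self-configuration heuristics are out of scope): instance
  normalization, leaky ReLU (slope 0.01), strided-convolution
  downsampling, transposed-convolution upsampling, widths starting at 32
  and doubling per stage with a hard cap of 320 channels, default five
  stages with anisotropy-aware pooling (the slice axis stops being
  pooled after two halvings, reflecting thick-slice axial stacks).

Inputs whose spatial shape is not divisible by the cumulative pooling
factors are zero-padded symmetrically for inference and cropped back;
direct training-time forwards require divisible shapes and raise
otherwise. Weights are He-normal initialized from the configuration
seed, so construction is fully reproducible.

The networks run on a compact numpy reverse-mode autodiff engine written
for this package (`adiposeg.nn.autodiff`): convolution via patch-matrix
multiplication, exact gradients for every operation, verified against
central finite differences in the test suite. This keeps the full
pipeline executable and deterministic on a single CPU core; it is not a
performance substitute for GPU frameworks and is sized for the desk-
scale experiments described below.

## Loss functions

Both losses are soft Dice over the 3 classes (background included by
default so false positives on background stay penalized; excludable by
configuration). With predicted probabilities `p_ln`, one-hot reference
`r_ln`, voxel weights `m_n` and smoothing `ε = 1e-5`:

    D_l  = (2 Σ_n m_n p_ln r_ln + ε) / (Σ_n m_n p_ln + Σ_n m_n r_ln + ε)
    loss = 1 − Σ_l w_l D_l,   Σ_l w_l = 1.

* **WDL** (weighted Dice loss): `m_n = 1`; class weights uniform by
  default or manual.
* **FBDL** (frequency-balancing boundary-emphasizing Dice loss):
  `w_l ∝ 1/freq_l` with class frequencies taken over the training set
  by default (per-batch as an ablation mode) and a one-voxel-equivalent
  frequency floor so absent classes never divide by zero; and
  `m_n = 1 + (β−1)·1[n within d voxels of a reference label boundary]`
  with defaults `β = 2`, `d = 1`. Boundaries are the morphological
  gradient of each one-hot reference channel under a 6-connected
  structuring element, dilated to band width `d`.

FBDL here is a reconstruction from the loss's name and stated purpose —
balance the SAT/VAT class imbalance and emphasize the boundary voxels
where adipose segmentations fail — with both components isolated behind
configuration so alternative published forms can be swapped in. It is
not claimed to be numerically identical to any specific prior
implementation. With `β = 1` and equal class frequencies it reduces
exactly to uniform-weight WDL (tested). Both losses are differentiable
in the probabilities everywhere (no argmax inside); the training path
uses the same arithmetic through the autodiff engine and is tested to
match the reference numpy implementation.

## Synthetic Dixon phantom

Because suitable clinical Dixon data cannot be redistributed, every
stage is exercised on a parametric abdominal phantom with exact ground
truth. Per slice, the torso is an ellipse (default semi-axes 150×110 mm
inside a 400 mm FOV, tapering 5% toward the stack ends); the SAT ring
has mean thickness 25 mm with ±20% angular modulation; the cavity holds
water-dominant "organ" tissue, VAT, and fat-bright confounders. VAT is
the union of `k = 6` random ellipsoids plus a smoothed-noise roughness
field, thresholded by rank so that VAT occupies *exactly* the target
fraction of eligible cavity voxels (default 25%) — which also makes the
longitudinal change parameter exact by construction and nests the
timepoint-1 VAT inside a grown timepoint-2 VAT. The confounder (a
vertebral-body/marrow cylinder on the posterior midline, optional bowel
specks) carries the *same* fat signal as adipose tissue and the label
0: no intensity threshold can separate it, so learning spatial context
is required — the synthetic counterpart of manually removing vertebral
marrow from thresholded annotations.

Signal model per voxel (magnitude images): `F = f + n`, `W = w + n`,
`TE_IP = w + f + n`, `TE_OP = |w − f| + n`, with independent additive
Gaussian noise per channel clipped at zero (a Rician approximation
chosen to keep analytic volume oracles simple; true Rician sampling is a
flag). Default intensities are `fat = 1000`, `water = 600`, `σ = 30` —
arbitrary units; no public intensity distributions exist for the target
acquisitions, so these are configuration defaults, not calibrated
values. An `adiposity_score` covariate (a standardized BMI surrogate)
scales ring thickness (+15%/unit) and VAT fill (+25%/unit) so cohort
stratification has a real covariate to balance; `age_like`
(mean 50.4, SD 14 — typical of adult overweight/obesity cohorts) has no
geometric effect by design. Longitudinal pairs share every anatomical
draw and differ only in the scale parameters ((1+δ) on ring thickness
and VAT fill) and acquisition noise.

What the phantom does *not* emulate: organ anatomy, respiratory motion,
bias fields, fat–water swaps, k-space effects, inter-scanner variation.
Passing the mini-experiment therefore demonstrates that the pipeline —
losses, optimization, inference, volumetry, longitudinal statistics —
is correct and well-conditioned, not that the networks reach clinical
accuracy on real MRI.

A voxelization note: binary masks are cut at voxel centres, so a stack
of geometrically identical slices repeats the same in-plane quantization
error 51 times; the default superior–inferior taper decorrelates it,
which is why voxel-count volumes track the analytic ellipse-ring volumes
to well under 1% at acquisition resolution (and the tests check the
error shrinks as the grid is refined).

## Geometry bookkeeping

The landmark-based stack rule mirrors abdominal protocols: the analysis
stack is the landmark slice (e.g. the iliac crest, supplied as an index
— automatic landmark detection is out of scope) plus 50 slices counted
superior, inclusive, giving 51 slices = 255 mm at 5 mm thickness.
Internally everything is RAS+ with superior = increasing slice index;
files with other orientations are reoriented on read. All slice ranges
are 0-based and inclusive–inclusive.

## Training protocol

Full-volume batches (minimum 2 for the nnU-Net-style family), gradients
zeroed before each batch, Adam (default learning rate 1e-4; 1e-3 is
what the desk-scale experiment selects on validation) or Nesterov SGD
(µ = 0.99, lr 0.01) for the nnU-Net-style arm; **no data augmentation**
anywhere in the pipeline, so a fixed seed makes delivered batches, and
hence whole runs, bit-reproducible on one device (cross-device equality
is not promised). The returned model carries the weights of the epoch
with minimum validation loss, not the last epoch. Input normalization is
tied to the family: per-channel rescaling to [0, 255] for the U-Net
variants (per-channel rather than joint, so water and fat each span the
full dynamic range), per-image z-scoring for the nnU-Net-style model; a
constant channel normalizes to zeros rather than raising.

Cohorts are split 70/10/20 at the *subject* level with largest-remainder
rounding; both timepoints inherit the subject's split, and timepoint-2
evaluation uses the timepoint-1-trained model with no weight update
(enforced, with split leakage a hard error). Stratification bins
subjects by joint covariate quantiles; the balance report includes
Kruskal–Wallis p per covariate and the split re-draws (bounded retries)
if any p ≤ 0.05.

## Metrics and statistics

Per subject: hard-label 3D Dice per tissue (both-masks-empty defined as
1 — perfect agreement on absence — and logged); FP% and FN% pooled over
the SAT and VAT indicator channels, so a SAT voxel predicted as VAT
counts in SAT's FN and VAT's FP (degenerate zero denominators return 0%
with a warning); voxel-count volumes in mL. Cohort level: medians with
IQR (linear-interpolation percentiles), ICC with the conventional
poor/moderate/good/excellent categories at 0.5/0.75/0.9, regression of
predicted on reference volumes, and per-tissue regression of predicted
on reference ΔVolume = Volume₂ − Volume₁. The ICC variant is two-way
random effects, absolute agreement, single measurement — absolute
agreement because a volume *bias* must count against a quantification
method — with the consistency form available by configuration; the
variant is recorded in every result. Group comparisons: Kruskal–Wallis,
Wilcoxon signed-rank (zeros discarded; all-zero differences return
p = 1), Benjamini–Hochberg step-up at FDR 0.05.

## Desk-scale experiment sizes

The end-to-end experiment trains the base-8 `acd_unet3d` (widths
8/16/32/64) with FBDL and Adam (lr 2e-3, batch 2, 18 epochs;
learning rate and epoch count selected on the validation subjects) on
30 subjects at 64×64×24 voxels of 6×6×10 mm — the full-resolution torso
geometry on a coarser grid — with 2 validation subjects for checkpoint
selection, and evaluates 10 held-out subjects at both timepoints. These
sizes are the package's chosen desk-scale operating point: large enough
that SAT, VAT and the confounder are all several voxels across and the
evaluation statistics are stable, small enough that the whole cycle
runs in minutes on one CPU core. The capacity check overfits one
48×48×16 phantom to a training loss below 0.05.

A residual behaviour of this operating point is worth understanding,
because it is a property of the loss rather than a bug: under FBDL's
inverse-frequency class weights (≈ 0.04 background / 0.28 SAT / 0.67
VAT) the trained model reliably learns to keep the fat-bright vertebral
confounder *out of VAT* — VAT errors are expensive — but tends to label
it SAT, whose errors cost little against the large background class.
Misclassifying the whole ~190 mL structure moves the loss by under
0.01, inside the converged residual, so validation loss does not expose
it. The consequence is a near-constant positive SAT volume offset on
this phantom (VAT volumes are essentially exact), which depresses the
*absolute-agreement* SAT ICC while Dice, consistency agreement and
ΔVolume slopes remain high — ΔVolume subtracts the constant offset
away. Longer training, a larger SAT weight, or a confounder-aware
voxel-weight map would remove it; within this experiment's
single-CPU-minutes budget and the loss as defined, it is documented
instead of hidden.

## Known limitations

* The numpy engine is single-device and unaccelerated; full-resolution
  (192×192×51, width-64) training is out of its intended range, though
  construction, parameter accounting and inference at that size work.
* FBDL's exact published functional form is not reproduced, only its
  stated mechanism (see above); the ACD parameter count is reported as
  a diagnostic rather than asserted against the published figure, since
  the published block internals are not fully specified.
* The phantom's realism limits are listed above; none of the reported
  phantom metrics should be read as clinical performance.
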