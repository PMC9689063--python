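# Methods

`nodulecad` implements a two-stage computer-aided detection (CAD)
system for pulmonary nodules in low-dose CT, together with a synthetic
phantom generator and the evaluation machinery (FROC/CPM, CAD
performance, paired significance testing) used to characterise such
systems. This note records the models, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## The detection problem

A chest CT volume contains zero or more roughly spherical nodules of
3–30 mm diameter embedded in lung parenchyma, alongside confusable
structures (vessels, airway walls, the lung boundary). The system
must output candidate nodules — centre, diameter, confidence — with
high sensitivity at a low false-positive (FP) rate per scan.

The pipeline is:

1. **Preprocessing.** The raw scan (Hounsfield units) is resampled to
   1 mm isotropic spacing (linear interpolation), thresholded at
   −600 HU (air/lung strictly below), the exterior air is region-grown
   from the 8 volume corners (6-connectivity), its complement's
   largest connected component is the body, air inside the body is the
   coarse lung mask, and a spherical dilation of radius 6 voxels
   closes vessels and the pleural interface. The volume is cropped to
   the mask bounding box, HU in [−1200, 600] are mapped linearly to
   gray [0, 255] (floor, then clip) and everything outside the lung
   mask is filled with gray 170. The crop offset is kept so detections
   map back to scanner coordinates.
2. **Candidate detection (MSFD-Net).** A multi-scale feature extractor
   (MSFE) — a 3D encoder–decoder with squeeze-and-excitation residual
   blocks — produces feature maps at stride 4 (S2) and stride 8 (S3).
   Anchor cubes of diameter {5, 8, 11} voxels sit on every S2 grid
   point and {15, 21} on every S3 point; for a 96³ patch that is
   3·24³ + 2·12³ = 44 928 anchors. Two small prediction heads emit a
   logit and four regression offsets per anchor,

       r_i = (g_i − b_i) / b_d  (i = z, y, x),   r_d = ln(g_d / b_d),

   where `g` is the ground-truth box and `b` the anchor.
3. **Candidate suppression.** Lung-mask suppression (LMS) computes the
   mean mask density Cm over each candidate's digital sphere and keeps
   candidates with Cm ≥ 0.8; non-maximum suppression (IoU threshold
   0.001 over axis-aligned cubes) keeps the most confident detection of
   each cluster. LMS runs before NMS.
4. **False-positive reduction (CS-Net).** A lightweight MSFE scores
   32³ gray patches centred on each candidate; per-scale 1³
   convolutions to 128 channels followed by global average pooling
   yield a 256-vector, classified through a small fully connected head
   with a sigmoid. Candidates with score below Cs (default 0.05) are
   discarded.

Default architecture widths are calibrated so the detector holds
≈3.30 M and the scorer ≈1.52 M trainable parameters (the encoder widths
are (16, 32, 56, 64, 64) with block counts (2, 2, 3, 3) and a 64-wide
decoder; the scorer uses (16, 24, 40, 64, 78) with (1, 1, 2, 2) and a
32-wide decoder).

## Losses and label assignment

Each training patch (1×96×96×96 by default) is cropped around an
annotated nodule so the nodule lands uniformly inside the patch, with
random flips, axis transposition, and mild zoom ([0.9, 1.1]) as online
augmentation. Per label, one anchor drawn uniformly among those with
IoU ≥ 0.5 (falling back to the arg-max anchor) is positive; 4000
anchors with IoU ≤ 0.02 against every label are negatives; the rest
are ignored. Classification uses the focal loss

    L_f(p*, 1) = −α (1−p*)^γ ln p*,   L_f(p*, 0) = −(1−α) (p*)^γ ln(1−p*)

with α = 0.5, γ = 2, combined with online hard negative mining: only
the β·K highest-probability negatives are kept (K positives; β = 10
for the detector, 5 for the scorer), and the loss averages over the
K + βK selected samples. Regression uses the piecewise smooth-L1 form
(squared below 1, absolute above; no 0.5 scaling), summed over the
four offsets and averaged over positives. The total loss is the
unweighted sum. A nodule of diameter d mm is loaded 1 + ⌊3d/10⌋ times
per epoch, read as a deterministic repetition count.

Numerical details worth noting:

* Probabilities are affinely clamped away from {0, 1} (ε = 1e−7)
  before the logarithm.
* Classification-head biases are initialised to −4 so the initial
  foreground probability is ≈2 %. Without this, the focal loss spends
  the first hundreds of optimiser steps driving all outputs to the
  background prior before any discrimination emerges — prohibitive in
  short CPU training runs.
* OHNM ties are broken by index; negative sampling is without
  replacement under a seeded generator, so label assignment is
  reproducible.

## The neural-network engine

All networks run on a small reverse-mode automatic-differentiation
engine written on NumPy (`nodulecad.nn`): tensors carry a backward
closure; 3D convolution (stride 1) is an `sliding_window_view`
im2col followed by one BLAS matmul, with the input gradient computed
as a full correlation with the spatially flipped kernel; max-pooling,
kernel-2/stride-2 transposed convolution, batch normalisation, linear
layers and the elementwise activations have hand-written backward
passes, each verified against central finite differences in the test
suite. Adam uses the conventional moment estimates (β₁ = 0.9,
β₂ = 0.999).

**Batch-norm evaluation statistics.** The engine's batch-norm layer
supports two evaluation modes. With the very small batches these
models train under on a CPU (batch 4 for the detector), the function
the network learns depends on within-batch normalisation; evaluating
with running-average statistics then shifts activations off the
learned manifold and collapses the detector's discrimination. The
detector therefore evaluates with per-sample instance statistics
("input" mode) — deterministic and batch-composition independent —
while the scorer, trained with batch 64 where running averages are
faithful, uses the textbook running-statistics mode. This is a
deliberate small-batch design choice, configurable per model.

## Inference

Pre-images are tiled by a sliding window (240³ patches, stride 210 by
default; the last tile is clamped to the volume edge, undersized
volumes are padded with gray 170). Anchors with sigmoid probability
≥ Cth (default 0.75) are decoded and shifted into pre-image
coordinates; pooled candidates pass LMS then NMS, then CS-Net
rescoring with threshold Cs. Setting Cs = 0 disables the second stage.
Final candidates are reported in world millimetres through the crop
offset and volume geometry.

## Evaluation

A candidate hits an annotation when the centre distance is strictly
below the annotation radius; each candidate is attributed to at most
the nearest covering annotation, so duplicates neither raise
sensitivity nor count as FPs; candidates hitting "excluded"
annotations count as neither. The FROC curve sweeps candidate
confidence; the CPM is the mean sensitivity at FPs/scan ∈
{0.125, 0.25, 0.5, 1, 2, 4, 8}, read from the step function at the
largest achieved FPs/scan ≤ each target (no interpolation — the
conservative readout). Size-stratified reporting uses half-open bins
[3, 10), [10, 20), [20, 30) mm. The paired t-test on per-fold
precisions uses τ = |√k · μ/σ| with σ the sample standard deviation of
the per-fold differences (divisor k−1) against the two-sided t
critical value (2.262 at α = 0.05, k = 10).

## Synthetic phantoms

A phantom is an elliptic-cylinder body (+40 HU) in air (−1000 HU)
holding two ellipsoidal lung fields (−800 HU). Nodules are spheres
with HU uniform in [−100, 100], diameters drawn from a log-normal law
(median 7 mm, σ = 0.55) truncated to [3, 30] mm — reproducing the
small-nodule-dominated size distribution of screening datasets (mean
≈ 8.3 mm) — placed strictly inside a lung field, pairwise
non-overlapping, with bounded retries. Vessel confounders are
random-walk tubes of radius 1–3 voxels at nodule-like HU. Gaussian
noise (σ = 20 HU) is added last. Generation is bit-deterministic per
seed.

What the phantom does *not* emulate: real parenchymal texture, partial
volume effects, lobar and airway anatomy, juxtapleural nodule
morphology, scanner artefacts, and anisotropic acquisition. Passing
the synthetic end-to-end study therefore demonstrates that the
pipeline's mechanics (label assignment, losses, suppression, scoring,
bookkeeping) are correct and trainable, not that the trained weights
transfer to clinical data.

## The desk-scale end-to-end study

`nodulecad.experiments.run_reduced_study` trains and evaluates the
whole system at CPU scale: 30 training and 10 held-out phantoms of
96³ voxels (1 mm spacing) with 3–5 nodules each, diameters 5–18 mm
(96-voxel lungs cannot host 30 mm spheres), and 6 vessel confounders;
a width-halved detector on 48³ patches; the compact scorer variant on
the detector's own candidates. Of the 30 training phantoms, 24 supply
training patches and 6 are held aside for threshold calibration.
Choices specific to this scale:

* **Offline patch extraction.** Detector training iterates over a
  fixed, pre-sampled set of 96 patches (drawn from the
  diameter-weighted pool) rather than resampling every epoch. With
  only ~1500 optimiser steps available, revisiting the same views is
  substantially more sample-efficient than a stream of fresh crops, at
  an accepted cost in augmentation diversity. Decoder dropout is
  disabled (regularisation noise costs more convergence than it buys
  generalisation in runs this short), and batches of 2 at learning
  rate 1.5e−3 are used: halving the batch and the rate preserved
  per-step progress while doubling the steps a CPU-second buys.
* **Hard-example phase.** After 22 epochs, each training nodule's
  detection probability is measured on a centred crop, and a second
  96-patch set is drawn with weights ∝ (1.05 − p); 8 further epochs at
  5e−4 concentrate capacity on the nodules the model still misses — a
  sample-level analogue of OHNM. Mining once helps; a second round was
  observed to erode generalisation and is not done.
* **Calibrated operating point.** Candidates are pooled at a
  permissive threshold (0.3) with a 24-voxel tile stride (denser
  tiling lets marginal small nodules be seen near a tile centre) and
  at most 150 anchors per tile before suppression. The operating
  threshold Cth is selected **on the six calibration phantoms**, which
  the patch set never saw: the smallest threshold whose calibration
  FPs/scan is at most 1.8. (Calibrating on the patch-training scans
  themselves overstates the usable threshold — the model is confident
  on nodules it memorised — and collapses held-out sensitivity.)
* **Scorer training and threshold.** Scorer positives are the
  detector's true-positive candidates on the patch-training scans,
  augmented 2× (zoom [0.8, 1.25], ±4-voxel shifts, the full octahedral
  flip/transposition group); heavier positive augmentation (the 40×
  used at full scale to offset rare positives) inverts the class
  balance here and collapses the scorer toward the positive class.
  Negatives are the pool's false positives plus an extra permissive
  low-threshold pass (0.15, coarse stride), at most 700, 70 % redrawn
  per epoch — the easy negatives anchor the scorer's low-score tail.
  The score threshold Cs is then set from the calibration phantoms:
  as high as the 25th percentile of calibration false-positive scores,
  but never above half the lowest calibration true-positive score
  (clipped to [0.002, 0.15]). Held-out true positives can score below
  the calibration minimum, so the margin is generous; the second stage
  prunes clear non-nodules without touching marginal detections.

Runtimes are a few minutes for detector training and under a minute
for everything else, per run, on one CPU core.

## Known limitations

* The autodiff engine is stride-1/kernel-3-or-1 specific and
  single-threaded beyond what BLAS parallelises; it is sized for the
  models in this package, not a general framework.
* Anchor boxes are cubes, and IoU is computed over cubes; spherical
  IoU would differ slightly for the same diameters.
* The desk-scale scorer is orders of magnitude smaller and sees
  orders of magnitude fewer candidates than a full-scale run; its FP
  discrimination is correspondingly coarser, which bounds how far the
  second stage can push precision in the synthetic study.
* Table-style benchmark numbers from full 10-fold cross-validation on
  real screening data are outside what this package computes; the
  evaluation module reproduces the arithmetic (CPM, t-test) exactly
  and is exercised on synthetic data end to end.
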