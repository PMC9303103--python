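# Methods

## Problem and approach

Fetal echocardiography's three-vessel view shows the pulmonary artery (PA),
aorta (AO) and superior vena cava (SVC) in cross-section.  Automatic
segmentation of the three vessels is hard for the usual ultrasound reasons —
speckle, low contrast, blurred boundaries — and additionally because the
vessels occupy a small fraction of the image, so a network trained on
full-size images spends most of its capacity on background and tends to miss
the smallest vessel (the SVC) entirely.

`vesselkd` implements a teacher–student remedy.  A **teacher** is trained
only on the region of interest: the tight bounding box of all labelled
vessel pixels, padded by a fixed margin on each edge (50 px at the native
512×512 scale), clipped at image borders, and resized — anisotropically —
to the square model input.  Zoomed in this way, the vessels dominate the
input and the teacher learns fine-grained boundaries.  The teacher cannot be
deployed, because at test time there is no ground truth to crop by.  A
**student** therefore trains on full-size images, and the teacher's
knowledge is transferred through its logits: for each training sample the
teacher's crop-space logits are resized back and placed at the recorded crop
coordinates in full-image space, and a channel-wise distillation loss aligns
the two networks there.

## Losses

Two different softmaxes are used, deliberately:

* **Per-pixel class softmax** across the C channels, feeding the
  cross-entropy loss (mean over pixels of −log p of the true class) and a
  multi-class soft Dice loss (averaged over all C classes, smoothing
  ε = 1e-6).
* **Channel-wise spatial softmax** φ: within each class channel, logits are
  divided by a temperature τ and softmaxed *over the W·H pixels*, turning
  each channel into a spatial probability distribution.  The distillation
  loss is the KL divergence between teacher and student distributions,
  summed over channels and pixels and scaled by τ²/C:

      L_KD = (τ²/C) Σ_c Σ_i φ(yᵀ)_{c,i} · log( φ(yᵀ)_{c,i} / φ(yˢ)_{c,i} ).

The total objective is `α·CE + β·Dice + γ·KD` with α = β = 1 throughout,
γ = 0 for the teacher (and the baseline), and γ = 3, τ = 4 for the student's
distillation stage — the reference operating point.  C counts all classes
including background (C = 4 here).

Design choices the loss definitions leave open, and how they are resolved:

* **Dice form.** Multi-class soft Dice including the background channel,
  symmetric with the CE treatment; ε = 1e-6 for stability.
* **KD support.** The restored teacher map carries no information outside
  the ROI, so by default the spatial softmax and the KL sum are restricted
  to pixels inside the restored box (`kd_support="roi"`, using the validity
  mask that the restore step returns).  `kd_support="full"` lets the fill
  value participate instead, for comparison.
* **Gradients.** All losses have hand-derived analytic gradients with
  respect to the student logits, pinned against central differences in the
  tests; the teacher side is a constant target.

## ROI coordinate mapping

Crop boxes are 0-based, half-open, and serialised as JSON.  Padding is
applied to the tight foreground bounding box and then clipped at the image
border (the crop never leaves the recorded image).  Resizing to the square
model input does **not** preserve aspect ratio; restoration inverts the
anisotropic scale per axis.  The resampler uses the half-pixel-centre
convention with edge replication, implemented locally so that an equal-size
resize is the identity to the bit — which makes the unit-scale
crop→restore round trip exact, a property the distillation plumbing and its
tests rely on.  Masks are resampled with nearest neighbour (value set
preserved), continuous maps bilinearly.

## Network

A small DeepLab-flavoured encoder–decoder: a strided conv encoder
(InstanceNorm + ReLU blocks, widths doubling per stage and capped at 8×
base width), an optional atrous spatial pyramid at the bottleneck (a 1×1
branch plus one 3×3 dilated branch per rate, concatenated and projected),
and a decoder that upsamples (nearest, ×2) with a skip concatenation from
each encoder stage, ending in a 1×1 head.  Output resolution equals input
resolution, as pixel-aligned distillation requires.  Teacher and student
share the architecture.

The network and its training are implemented directly on numpy arrays with
explicit forward/backward passes and an Adam optimizer; the backward pass of
every layer and of the whole graph is verified against central differences.
InstanceNorm keeps no running statistics, so inference is identical to the
training-mode forward pass and whole-run determinism follows from the seeds
alone.  This stack deliberately replaces the original full-scale design
(Xception-65 backbone, external pretraining): the object of study is the
training scheme, not the backbone, and a desk-scale network keeps every
experiment reproducible in minutes on a CPU.

## Training procedure

Both roles train in two stages with Adam:

| stage | lr (full-scale default) | encoder | γ |
|---|---|---|---|
| 1 | 5e-4 | frozen | 0 |
| 2 | 5e-5 | trainable | 0 (teacher/baseline) or 3 (student) |

The learning rate decays as `lr_init · 0.92^(epoch−1)` (the decay unit is
configurable to steps).  Early stopping watches the validation combined
loss with patience 5 by default; the best — not last — weights of each
stage are kept, and stage 2 starts from stage 1's best.  Since each stage
optimises a different objective, "best" is tracked within stage.

Augmentation (train split only) applies scale, shift, rotation and flips
jointly to image and mask (mask via nearest neighbour) plus
brightness/contrast jitter on the image — the grayscale counterpart of
colour jittering.  Distillation targets are computed on the fly from each
*augmented* sample, so teacher and student always see geometrically
consistent content; a sample whose augmented mask lost all foreground is
re-augmented up to 5 times and then used without a distillation term.

A student run with γ = 0 in every stage never touches the teacher and is
code-path identical to baseline training: given equal seeds the epoch logs
are byte-identical.  This reduction is enforced by a test.

## Synthetic phantoms

The generator emulates what the method needs from the clinical data, not
ultrasound physics: a dark field containing three bright-rimmed elliptical
vessel cross-sections (filled interior, brighter wall), arranged roughly
collinearly as in the three-vessel view, with per-sample jitter and
rotation, strictly non-overlapping and inside the frame.  The SVC is
strictly smallest by area, and the three vessels together cover only a few
percent of the image.  Speckle is unit-mean multiplicative gamma noise
(`speckle_scale` = its standard deviation, default 0.30) followed by a
Gaussian blur (default 1.5 px at 512); both are disabled by setting them to
0, in which case the image is an exact piecewise-constant rendering of the
mask.  Every sample is a deterministic function of (seed, index); datasets
regenerate byte-identically.

What the phantoms do **not** model: probe geometry, attenuation, shadowing,
anatomical context (atria, trachea), operator variability, or annotation
noise.  Passing tests on phantoms therefore demonstrate that the training
scheme works when its assumptions hold — small bright structures in noisy
low-contrast images — not clinical-grade performance.

## Desk-scale study conditions

The full-scale study (1040/130/130 images at 512×512, a pretrained
backbone) is out of desk-scale reach; the package's own
experiments run a scaled replicate, frozen in `vesselkd.experiments.SCALED`:
200/20/30 phantoms at 64×64, base width 8, depth 2, ASPP rates (2, 4), ROI
pad 6 px (50 px rescaled to the 64 px grid), batch 8, teacher 6+5 epochs,
student and baseline 6+12 epochs each.  Learning rates are 2e-3 / 5e-4 —
larger than the full-scale defaults because no stage starts from a
pretrained backbone at this scale; γ = 3 and τ = 4 are kept verbatim.
Student and baseline differ *only* in γ.  At these sizes one replicate
(teacher + student + baseline + evaluation) takes a few minutes on one CPU
core.

The characteristic result mirrors the full-scale finding in direction: the
baseline, seeing mostly background, is slow to pick up the small SVC, while
the distilled student inherits the teacher's sharply localised channel
distributions and segments it reliably within the same budget.  The
acceptance suite asserts only the direction (median student mean-IoU ≥
median baseline over 3 replicates), never the magnitude, which depends on
phantom difficulty.

## Numerical notes

* Softmaxes are computed with max-subtraction; KD uses log-softmax
  differences, never raw ratios.
* Loss arithmetic is float64; network arithmetic defaults to float32
  (configurable), and runs are bit-reproducible for fixed seeds.
* Undefined metrics (zero denominators) are reported as missing values and
  excluded from means — never silently 0 or 100.  Mean rows average the
  three vessel classes only.
* PA is implemented exactly as defined — intersection over *predicted*
  area — although that quantity is conventionally called precision.
* Micro (pixel-count) aggregation is the default; per-image averaging is
  provided and labelled, since either convention is defensible.

## Known limitations

* Absolute accuracies on phantoms are not comparable to clinical numbers;
  only within-package contrasts (student vs baseline) are meaningful.
* The numpy network is practical up to roughly 128×128 inputs; the
  architecture is configurable but not optimised for larger scales.
* Automatic ROI detection at inference time is out of scope: the ROI is
  only ever taken from ground-truth masks during training, which is exactly
  what makes the teacher undeployable and the student necessary.
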