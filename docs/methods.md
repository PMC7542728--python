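# Methods

## Overview

`cardiosynth` implements a three-part study on synthetic cardiac MR imagery:

1. a **progressive GAN** that synthesizes grayscale cardiac MR frames,
2. a **multi-scale sliced Wasserstein** similarity index that audits how close
   the synthetic frames are to the training distribution (and whether any are
   memorized copies), and
3. a **U-Net** chamber-segmentation stage whose performance when trained on
   synthetic frames is compared — per chamber, with Dice and percent area
   variation, paired Wilcoxon tests and median [IQR] reporting — against
   training directly on real frames.

Because no patient imagery ships with the package, a **cardiac phantom
generator** stands in for the patient dataset.  Every stage of the study runs
end to end on phantoms, deterministically from a single master seed.

## Phantom model

Phantoms emulate single cine frames in two planes.  Short axis (SAX): the left
ventricle (LV) is a bright circular blood pool inside a darker myocardial
annulus, with the right ventricle (RV) as a crescent-shaped pool wrapping
around it.  Four-chamber long axis (LAX): LV, RV and right atrium (RA) are
adjacent elliptical pools separated by myocardial walls.  Tissue classes are
piecewise constant with additive Gaussian noise clipped to [0, 1]; the
contrast ordering blood pool > myocardium > background is enforced by
construction (the background level and two positive contrast gaps are drawn
independently).

Geometry is stored in resolution-free units (fractions of the frame side), so
one parameter draw can be rasterized at any power-of-two resolution from 4 to
256; masks are the exact rasterized blood-pool regions.  Anatomy is randomized
by drawing each parameter uniformly within a ±`variability` band around fixed
anatomical midpoints (default `variability = 0.2`); a damping factor of 0.8 on
the relative jitter keeps every size and contrast strictly positive even at
`variability = 1`.  The default noise standard deviation is 0.03 (in [0, 1]
intensity units), capped at 1/2.5 of the blood–myocardium gap so that the
blood pools remain reliably brighter than their surrounding walls.

What the phantom deliberately does **not** model: pathology-specific anatomy,
3-D structure, temporal (cine) dynamics, coil-inhomogeneity bias fields
(available as an option but off by default), and the rich texture of real
MRI.  Results on phantoms therefore demonstrate that the pipeline's machinery
works and that its statistics behave as designed — not that any particular
accuracy level transfers to patient data.

## Progressive GAN

The generator maps a 64-dimensional standard-normal latent vector through a
dense 4×4 projection and stacked resolution blocks (nearest-neighbor 2×
upscale + two 3×3 convolutions, leaky ReLU 0.2, pixelwise feature
normalization after every convolution) to a grayscale image; a 1×1 `to_image`
convolution exists at every stage.  The critic mirrors this design in reverse
(1×1 `from_image`, two 3×3 convolutions per block, 2×2 average pooling), adds
the minibatch-standard-deviation channel before its final block, and reduces
the last 4×4 map to a scalar score.  Filter counts for the seven resolution
blocks default to 48, 32, 24, 16, 16, 16, 16; batch size shrinks from 64 to 16
as resolution grows.

Training grows the networks stage by stage from 4×4.  During the first
`fade_fraction` (default 0.5) of each stage the new block is blended in with a
linearly increasing weight alpha: the output is
`(1−alpha)·upscale(coarse) + alpha·fine`, and at alpha = 0 the new stage
reproduces the upscaled previous-stage path exactly.  All existing layers
remain trainable after growth.

The objective is the Wasserstein critic loss
(`mean(fake) − mean(real)` for the critic, `−mean(fake)` for the generator)
with a small drift term (`10⁻³·mean(real²)`) that pins the score scale.  Two
stabilizers are available:

* **weight clipping** (default, limit 0.01 in effective-weight units, 1.0 on
  the unit-scale stored weights when equalized learning rate is on), and
* a **finite-difference directional gradient penalty**: at points on the
  real→fake line, the directional derivative of the critic along that line is
  estimated by a forward difference and pulled toward unit slope.  This is a
  first-order estimator of the usual unit-gradient-norm constraint; the exact
  interpolated-gradient form needs second-order differentiation, which this
  package's hand-written backprop stack does not provide.

At the desk scales the test-suite exercises (hundreds of steps per stage),
weight clipping gave far more reliable convergence than the finite-difference
penalty and is therefore the default.

Optimization is Adam with learning rate 10⁻³, β₁ = 0, β₂ = 0.99.  Weights use
He initialization; **equalized learning rate** (unit-scale stored weights
multiplied by the He constant at run time) is available as a config flag and
is switched on in the desk-scale pipeline configuration — in short runs it is
the single most important setting for the generator to pick up the two-pool
chamber structure rather than a single blur.  The generator output is linear;
frames are mapped affinely from the training range [−1, 1] to [0, 1] on
export.  Two independent models are intended per study (one SAX, one LAX).

The networks are built on a minimal numpy layer stack written for this
package (im2col convolutions over BLAS matmul, explicit backward passes,
float32 throughout).  With a fixed seed, runs are bitwise reproducible on a
given BLAS build; the test suite relies on this determinism contract.

An interpretation note: the training budget of the original progressive-GAN
recipe is quoted in "epochs" but is treated here as minibatch iterations
(`steps_per_stage`), since full dataset passes at that count are implausible
on the reported hardware.

## Multi-scale sliced Wasserstein similarity

Each image is decomposed into a Laplacian pyramid built with the separable
5-tap binomial filter [1, 4, 6, 4, 1]/16; upsampling is polyphase
(zero-insertion followed by the 2×-gain filter, with constant-preserving
boundary phases), and the bands reconstruct the input exactly by
construction.  The pyramid floor is 16×16; the coarsest entry is the low-pass
residual.

From every band, 7×7 patches are sampled at uniformly random positions
(128 per image, up to 512 per level and side for set comparisons) and
standardized per patch to mean 0 / sd 1 (constant patches become zero
vectors), which removes trivial brightness matches.  Two descriptor clouds are
compared by the sliced Wasserstein distance: the average, over 256 random unit
projections, of the exact 1-D Wasserstein-1 distance between the projected
samples (mean absolute difference of the sorted projections).  The per-level
distances and their mean form the similarity result.

For memorization auditing, a query frame is compared against every reference
with seeds fixed per pair; references are ranked by ascending average
distance.  A bitwise copy of a reference scores exactly zero.  When set sizes
differ, an equal number of descriptors is drawn from each side (uniformly
across that side's images), keeping the two empirical distributions the same
size so the sorted-difference form stays exact.

## U-Net segmentation

Classic encoder/decoder with two 3×3 same-padded convolutions + ReLU per
level, 2×2 max pooling, channel doubling at each contraction (default depth 4,
base 64 at the full 128×128 configuration; the desk-scale tests use depth 3,
base 8 at 32–64 px), 2×2 up-convolutions (nearest upsample + 2×2 convolution)
and concatenation skips; a final 1×1 convolution yields one logit map per
class (background + chambers).  Loss is per-pixel softmax cross-entropy
(soft-Dice available), Adam with learning rate 10⁻⁴ by default (the
desk-scale configurations use 10⁻³ to converge within their short epoch
budgets), validation split 5% held out after a seeded shuffle.  Prediction is
the per-pixel argmax, ties broken toward the lower class index; predicted
chamber masks are disjoint by construction.

Augmentation draws one affine transform per pair within the recipe limits —
rotations ±20°, width/height shifts of 5%, shear up to 0.20, zoom up to 10%,
flips disabled — and applies it identically to the frame (bilinear) and the
label image (nearest neighbor, so labels are preserved).  Dataset expansion
applies `factor` independent seeded transforms per pair.

## The synthetic-training pathway

In the emulated study, frames sampled from the trained GAN must be annotated
before a U-Net can train on them.  The package's stand-in for manual expert
annotation is a rule-based annotator: blood pools are thresholded with the
upper multi-Otsu boundary of the three-tissue histogram, cleaned
morphologically, and connected components are assigned to chambers by shape
and position (SAX: the most circular bright component is the LV, the largest
remaining is the RV; LAX: the lowest component is the RA, the rightmost upper
one the LV).  Frames whose components cannot be assigned are rejected, the
analogue of an annotator discarding uninterpretable frames; the pipeline
reports the annotation yield.  On rendered phantoms the annotator agrees with
the ground truth at Dice ≈ 0.99, so annotation noise is not the limiting
factor in the comparison.

## Evaluation statistics

Dice is 2|A∩B|/(|A|+|B|), defined as 1 when both masks are empty.  Percent
area variation is |area(pred) − area(truth)|/area(truth), undefined (an
error) for empty truth.  Frames whose ground truth lacks a chamber are
excluded from that chamber's rows.  Paired model comparison uses the
two-sided Wilcoxon signed-rank test (zero differences dropped, average ranks
for ties, exact null for n ≤ 25 without ties, tie-corrected normal
approximation otherwise; the computation is delegated to scipy and
cross-checked in the tests against an exhaustive sign-flip enumeration).  The
paired design mandates the signed-rank test; the unpaired rank-sum variant is
available behind a flag.  Quartiles use linear interpolation, recorded in the
report metadata.  No multiple-testing correction is applied; p-values are
reported raw, one per view × chamber × metric cell.

## Pipeline and problem sizes

`run_pipeline` executes: phantom cohorts (defaults: 200 GAN-training frames,
60 direct-training frames, 24 held-out test frames, all SAX at 32×32) →
progressive GAN training (4→8→16→32, 150/180/250/350 steps, batch 16,
equalized learning rate, weight clipping) → sampling of 120 synthetic frames
→ sliced-Wasserstein audit (synthetic vs. training set, uniform noise as the
reference scale, plus nearest-reference rankings) → rule-based annotation of
the synthetic frames → augmentation (factor 2) → two U-Net trainings
(synthetic-trained and phantom-trained, 12 epochs) → held-out comparison
report.  These sizes are the package's desk-scale defaults, chosen so the
whole study runs in minutes on a single CPU core while every qualitative
property of the full-scale design (stable growth, similarity gap to noise,
high-Dice segmentation from both training sources) is measurable.  All stage
seeds derive from the master seed through named seed streams; a rerun with
the same configuration reproduces `report.json` bitwise.

## Numerical choices and degenerate inputs

* float32 network arithmetic; float64 for statistics and the similarity index.
* Pixelnorm epsilon 10⁻⁸; minibatch-stddev variance epsilon 10⁻⁸.
* Constant patches standardize to zero vectors; empty descriptor sets and
  mismatched set sizes are errors rather than silent broadcasts.
* Dice of two empty masks is 1; percent variation of an empty truth mask is
  an error; all-zero paired differences are a flagged degenerate comparison,
  not a p-value.
* Non-finite losses abort training with the partial log attached.
* Multi-frame DICOM requires an explicit frame index; there is no silent
  first-frame default.

## Known limitations

* The hand-written numpy stack is single-threaded BLAS-bound; full 256²
  training at realistic budgets is out of reach (configurations up to 256²
  are constructible and unit-tested structurally).
* The finite-difference gradient penalty is a directional estimator, not the
  exact interpolated-gradient penalty, and underperforms weight clipping at
  short schedules.
* The phantom's simplicity means segmentation Dice values here are far above
  what real cardiac MRI yields; only the *comparative* structure of the
  report (synthetic-trained vs. real-trained) is meaningful.
* Cine dynamics (latent-space interpolation over the cardiac cycle) are not
  modeled or tested.
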