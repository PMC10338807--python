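# Methods

## Problem setting

LIDC-style lung-CT datasets attach up to four radiologists' annotations to
every nodule: a pixel-level segmentation, a 1–5 malignancy rating, and
eight ordinal semantic features (subtlety, internal structure,
calcification, sphericity, margin, lobulation, spiculation, texture).
Inter-observer disagreement is the norm, and most learning pipelines either
treat each reader as an independent case (discarding the panel's view) or
average readers into a single label (discarding the individual's view).
This package implements a model that keeps both: every training case is one
(nodule, reader) pair, the inputs carry both observer-invariant information
(the nodule cube) and observer-specific information (that reader's mask
cube), and the supervision mixes the reader's opinion with the panel
consensus.

## Cohorts and labels

* Individual cohort: nodules read by at least three radiologists on scans
  with slice thickness under 3 mm; each retained annotation is an
  independent case; ratings 1–3 map to benign, 4–5 to malignant.
* Panel cohort: unambiguous nodules whose mean rating differs from 3
  (mean < 3 benign, > 3 malignant, = 3 excluded). Exclusion is applied per
  experiment: panel-excluded annotations stay in the individual cohort.
* Semantic features binarise per feature: calcification level 6 (absent)
  versus 1–5; every other feature levels 4–5 versus 1–3. On the 1–4
  internal-structure scale level 4 alone forms the upper class, the
  consistent reading of the 4/5-versus-rest rule for a four-level scale.
* Ratings are validated, never clamped: silent clamping hides data errors.
* Nodule identity: explicit annotation keys when present; otherwise greedy
  centroid clustering with a 5-voxel threshold. Key groups whose centers
  spread beyond 20 voxels are flagged ambiguous and dropped from cohorts
  rather than raising, since ambiguity is a data property, not a bug.

## Preprocessing

Scans are resampled to (0.68, 0.68, 1.75) mm voxels with nearest-neighbour
interpolation (masks therefore stay binary), windowed to [−1200, 600] HU
and rescaled to [0, 1]. An 80×80×80-voxel cube is cropped around the
rounded mean of the readers' centers; each reader's mask is cropped with
identical geometry so cube and mask are voxel-aligned. The cube side is
interpreted in voxels, not millimetres: 80 mm at the target spacing would
give ≈118×118×46 voxels and contradict the network's 80³ input. Regions
outside the scan are zero-filled (zero is air after windowing). Rounding is
half-up per axis.

## Architecture

The shared extractor is a four-stage 3D residual network whose bottleneck
blocks replace the single middle convolution with a *multi-kernel split*:
the reduced feature map is split along channels into parallel branches,
each branch passes through its own grouped 3D convolution (kernel 3, 5 or
7; groups 1, 4 or 8), and the branches are re-concatenated, preserving the
channel count. Stage widths are 48/96/192/384 with expansion ×4
(192/384/768/1536) and block counts 3/4/6/3 — a 50-layer budget. A 7³
stride-2 stem maps the 2-channel 80³ input to 40³; the first block of
stages 2–4 strides by 2 (in the 1³ reduce convolution and the shortcut
projection — the table of stage outputs fixes only the 40/20/10/5 ladder);
global average pooling and a final fully connected layer produce the
1024-d shared feature. Unstated details resolved as: stem width 64, no
stem pooling, per-branch batch normalisation, conv→BN→ReLU branch order,
same-padding k//2, biasless convolutions, and a biased, linear 1536→1024
projection.

Ten parallel heads (FC 1024→256, BN, ReLU, dropout 0.5, FC 256→2,
softmax) emit the eight semantic predictions and the initial individual
and panel diagnoses. The refinement stage concatenates the ten probability
vectors — post-softmax probabilities, in the fixed canonical feature order,
then individual, then panel — into a 20-d fusion feature and maps it
through two unshared branches (FC 20→32, BN, ReLU, FC 32→2, softmax) to
the refined diagnoses. Hidden width 32 is a configurable default, chosen
small relative to the 20-d input. Class convention everywhere: index 0 =
benign, 1 = malignant.

## Loss

For the individual head with individual label y0 and panel label y1, the
target is q' = (1−ε)·onehot(y0) + ε·onehot(y1) with ε = 0.6, and the loss
is cross-entropy against q' (natural log, probability floor 1e−12). The
panel head is supervised symmetrically with the roles swapped; the
smoothing weight attaches to the panel opinion in both targets, so the
panel head keeps 0.6 on its own label and 0.4 on the individual reference
(both weights configurable in `LossConfig`). Semantic heads use plain
cross-entropy averaged over the
eight heads — the softening construction is defined only for diagnosis
opinions. With ε = 0 the whole objective reduces to conventional
per-annotation cross-entropy training. In the joint stage the two refined
heads receive the same collaborative losses; all terms are equal-weighted.

A consequence worth stating: with two classes, every head's soft target is
a mixture of the same two one-hot vectors, so at the default ε the
individual and panel heads receive near-symmetric supervision. What
separates the panel pipeline in practice is its conventions — model
selection on panel-head validation accuracy and per-nodule
mean-probability aggregation at scoring time — rather than an asymmetry of
the loss itself.

## Training

Two stages: epochs 1–40 train the backbone and the ten heads only
(learning rate 0.01) with the refinement branches frozen and their loss
excluded; epochs 41–80 train everything jointly at 0.0001 (a single global
rate). SGD with momentum 0.9 (no weight decay by default), batch size 8,
Xavier-uniform weights, zero biases, unit/zero batch-norm parameters, all
reproducible from one seed. The checkpoint with the best validation
accuracy on the selected refined head (panel for panel experiments,
individual otherwise) is restored at the end, considering joint-stage
epochs only — before that the refinement branches are untrained; ties go
to the later epoch.
Augmentation is online: per sample, integer translation with per-axis step
from [0, 5] voxels (sign drawn separately), axis-permutation plus in-plane
rotation by 45/135/225° (linear interpolation for intensities, nearest
neighbour for masks), and independent per-axis flips; each fires with
probability 0.5. Malignant cases are replicated until class counts balance
(keyed to the individual label by default).

## Evaluation

Accuracy, sensitivity, specificity, precision and F1 with malignant as the
positive class; undefined ratios are reported as NaN with a warning, never
silently zeroed. Panel experiments use stratified five-fold
cross-validation at nodule level; individual experiments use four
stratified subsets with the roles train/train/validation/test rotated over
the four rotations and results averaged. All annotations of one nodule
stay in one fold. Panel scoring aggregates the refined panel head's
probability vectors over a nodule's annotations by the arithmetic mean
before taking the argmax (majority voting is available as an alternative
path through the same per-annotation outputs). Decision threshold is the
argmax, i.e. 0.5 on the malignant probability. Per-fold means and sample
standard deviations are reported.

## Synthetic phantoms

The generator produces the statistical structure the model assumes, not
radiological realism. A phantom is an ellipsoid (radii ≈ 0.11–0.15 of the
cube side, scaled up mildly with malignancy) with optional radial spikes
(spiculation), surface lobes (lobulation), a bright calcification core
(intensity 0.95, 15% prevalence), Gaussian margin blur, and a texture
class (solid 0.7, part-solid 0.55, ground-glass 0.42) on a smoothed-noise
background in [0, 0.3]. The latent malignancy score is a fixed monotone
map, clip(1 + 3.2·spike_amp + 0.45·lobes, 1, 5); benign phantoms draw
spike amplitude from [0, 0.25] and 0–1 lobes (latent < 3), malignant ones
from [0.75, 1] and 2–4 lobes (latent > 3.5). Default conditions: 4
readers, 80³ cubes (32³/16³ for micro runs), malignant fraction 0.36
(assigned deterministically to hit the target count), rating noise sd 0.7,
mask jitter 2 voxels.

Readers are simulated with a per-reader bias b ~ N(0, sd): the rating is
clip(round(latent + b), 1, 5) and the mask is dilated (b > 0) or eroded
(b < 0) with radius ≈ |b| capped by the jitter and by a Dice ≥ 0.7 floor
against the truth. Coupling rating and mask perturbation makes the
observer-specific mask channel informative about that reader's opinion —
the premise of the dual-input design. Semantic ground truth comes from
documented monotone maps of the shape parameters (e.g. spiculation =
1 + 4.5·spike_amp binned; margin decreasing in blur; sphericity from the
radii anisotropy), with ±1 reader noise clipped to each feature's range.

What the phantoms do **not** emulate: anatomical context (vessels, pleural
attachment), realistic texture, reader-specific systematic styles, or
class overlap in image appearance beyond the rating noise. Passing the
learning-sanity tests therefore shows that the pipeline can learn a
separable 3D shape/intensity signal end to end and that its plumbing is
correct — not that it reaches any particular accuracy on real CT.

## Problem sizes and numerical choices

The engine is float32 NumPy; convolution is im2col plus BLAS matrix
multiplication, grouped convolutions loop over groups. Evaluation-mode
forward passes are pure functions of (weights, input); training is
bit-reproducible per seed on one machine. The test suite exercises three
scales: a tiny 16³/4-stage model for unit tests, the quarter-width
half-depth 32³ model for the learning-sanity run (100 phantoms, 10
epochs), and the full-size 80³ architecture for structural contracts and
single forward passes; full-size training is out of scope on CPU. The
learning-sanity run uses one reader per phantom because with zero rating
noise and zero mask jitter additional readers duplicate samples exactly,
and a 6+4 epoch split at rates 0.01/0.001 — a from-scratch refinement
stage trained for four epochs needs a larger step than the 0.0001 used to
fine-tune a 40-epoch model. The direction check (panel pipeline versus
individual head under reader noise) averages five seeded training
replicates at rating-noise sd 1.3 and mask jitter 2 on 32³ cubes. The cube
size matters: the Dice ≥ 0.7 floor on perturbed masks means a one-voxel
dilation is only admissible for nodule radii above ≈4.5 voxels, so on
smaller cubes the observer channel degenerates to the true mask and the
two heads become exchangeable. It is a directional, stochastic claim and
is tested as such.

## Known limitations

* No GPU path; the full-size model trains far too slowly on CPU to
  reproduce real-data accuracies, which are out of scope.
* The LIDC-style XML dialect is a simplified reader (per-slice polygon
  contours, header-declared volume shape), not a complete LIDC schema
  parser; JSON manifests are the native interchange format.
* Batch-norm statistics make training-mode outputs batch-dependent;
  evaluation mode uses running statistics and is deterministic.
* Momentum buffers reset at the stage-1/stage-2 boundary when the
  optimizer is rebuilt over the enlarged parameter set.
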