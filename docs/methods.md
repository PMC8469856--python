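# Methods

`peckseg` implements an annotation-quality-improvement pipeline for
camera-based detection of pecking injuries in turkey flocks.  The scientific
problem is not the segmentation model itself but the labels: pixel-exact
annotation of small, ambiguous wounds on top-view barn imagery is so
unreliable — inter-observer IoU in the *fair* band, intra-observer barely
*moderate* — that a network trained on first-pass ("naive") annotations
largely learns annotation noise.  The pipeline therefore treats annotations
as data to be validated: every labeled detection is re-judged by three
independent observers, training sections are sampled only from regions the
observers agree about, and the resulting model's proposals are edited by a
human to produce cleaner ("network-assisted") training data.

## Data model

An annotation is a set of *drawing layers*: one sparse pixel set per injured
animal (`InjuryMask`), grouped per image and source (`AnnotationSet`) with a
stage tag (`ground_truth`, `naive`, `network`, `network_assisted`, `hqa`).
Coordinates are 0-based `(row, col)`, origin top-left, half-open bounds.
On disk a set is a 16-bit instance-label PNG (0 = background, k = k-th
layer; 16 bits allow more than 255 instances) plus a JSON sidecar carrying
run-length-encoded pixel lists, annotator and stage; the round trip is
lossless and is property-tested.  A sparse coordinate store is equivalent
information to any spatial index an interactive tool might use; at library
scale nothing more is needed.  Overlapping layers are rejected at write
time: per-animal layers imply disjoint injuries, and a label image cannot
represent overlap anyway.  The store does not constrain whether one animal
carries one layer per wound or one layer covering several; callers decide.

## Synthetic scenes and simulated observers

Real barn footage is not publicly available, so a generator
(`synthetic_scenes`) emulates its decision-relevant structure: white
elliptical birds (body + head disc + snood appendage) on dark textured
litter; compact irregular reddish injuries placed on a bird with a location
class drawn as plumage/head/snood with weights 0.85/0.12/0.03 (plumage
overwhelmingly dominant, snood rare — the qualitative ordering reported for
real flocks); and off-bird reddish distractors (pecking objects, equipment)
that are *never* ground truth.  An optional green tint desaturates wound
redness, emulating darkening blinds.  Defaults: 384×384 px, 6 birds,
injury probability 0.7 per bird, injury area 40–150 px, 3 distractors.
Rendering is deliberately non-photorealistic — ellipses and blended noise
fields — because the pipeline under test is annotation logistics, not
vision realism.  Consequences: passing tests show the *workflow* behaves
correctly and that label quality measurably changes model quality; they do
not show that any model generalizes to real barn imagery, with its
occlusion, posture variation, dust and lighting changes.

A simulated observer redraws each true mask with (a) a random translation,
(b) a smooth boundary-noise field, (c) a systematic dilation/erosion bias,
and may miss injuries (`miss_prob`) or add spurious annotations
(`fp_rate`), placed preferentially on distractors — the dominant real error
mode.  Noise is split into a *structural* stream (persistent per observer:
which injuries they miss, where their false positives sit, 65 % of the
boundary field) and a *session* stream refreshed on re-annotation.  This
two-stream design makes intra-observer reliability a first-class concept:
re-annotating with a fresh session seed reproduces the observer's biases
but not their session jitter.

The frozen defaults (`default_roster`) were calibrated once by Monte-Carlo
over 30 scenes before the rest of the pipeline was built: boundary sigma
1.8/2.0/1.9 px, miss 0.10/0.12/0.11, false positives 0.70/0.80/0.75 per
image, bias +1/−1/0.  They yield mean pairwise whole-image IoU of
0.25–0.33 between observers (the *fair* band) and ≈ 0.59–0.61 for the same
observer twice — the reliability regime reported for trained human
annotators on this task (inter 0.25–0.43, intra 0.56).

## Agreement and detection metrics

Pixel-exact agreement is plain IoU of pixel sets; both-empty is defined as
1.0 (perfect agreement that nothing is injured).  Qualitative banding
follows Landis–Koch with the printed two-decimal edges read as partition
points: slight [0, 0.21), fair [0.21, 0.41), moderate [0.41, 0.61),
substantial [0.61, 0.81), almost perfect [0.81, 1].

Detection-level agreement boxes every mask (tightest axis-aligned box) and
matches predictions to references one-to-one by **box** IoU at a threshold
(default 0.5), greedily in descending IoU with deterministic tie-breaks.
Greedy matching is tested equivalent to exhaustive optimal assignment on
all random instances with ≤ 4 boxes per side.  The pixel-mask IoU of each
matched pair is recorded and averaged as the mean detection IoU.
Corpus-level precision/recall/F1 are micro-aggregated (TP/FP/FN pooled over
images, then recomputed), which keeps F1 the harmonic mean of the pooled
precision and recall.

## Consensus review

Images are cut into fixed-size pieces (default 600×600, clamped inward at
borders rather than padded), one per labeled detection.  The scheduler
always serves the piece closest to completion (2 opinions before 1 before
0; ties by piece id) so pieces finish at the earliest opportunity, and
never serves a piece twice to one observer.  A rejection for poor quality
blacklists the entire source image and voids its pending results.

Resolution semantics reconcile two partitions of the same finished set:
a detection *counts as an injury* when the majority (≥ 2 of 3) verdict is
injury, while *agreement* means all three verdicts identical.  The location
class of an injury is the modal location among its injury verdicts; a tie
leaves it unresolved rather than inventing a winner.  Percentages are
reported relative to finished (non-blacklisted) detections, rounded to one
decimal.  An image qualifies as fully high-quality-annotated when every
finished detection on it is unanimous.

## Section sampling

Consensus outcomes are rasterized into a tri-state agreement map:
unanimous-injury pixels are positive labels, non-unanimous detections are
exclusion zones, and unanimous-no-injury detections revert to background —
all three observers agree nothing is there, so they are safe negatives.
Training sections (default 256×256; 96×96 in the scaled-down experiment)
are drawn uniformly over window origins; any window containing an exclusion
pixel is rejected and redrawn (up to 1000 tries, then a logged skip).
The accepted-origin distribution is tested uniform over the brute-force
valid-origin set.  Train/validation splitting is by *source image* at an
80/20 fraction so overlapping crops never leak across the split; a
train fraction of 1.0 is rejected because early stopping needs validation
data.

## Segmentation model and training

No GPU autodiff stack is assumed: the model is a compact fully-convolutional
pixel classifier written in NumPy.  A fixed multi-scale feature transform
computes, per pixel, the RGB channels, a redness index `R − (G+B)/2` raw
and Gaussian-smoothed at σ = 1.5 and 4, luminance, large-scale luminance
context (σ = 8 — injuries sit on bright birds, distractors on dark litter),
and local luminance texture (σ = 3).  A small MLP head (16 tanh units,
sigmoid output) is applied at every pixel and trained by minibatch Adam
(batch 2048, learning rate 0.04) with analytically derived gradients of the
focal loss

    L(gt, pr) = −gt·α(1−pr)^γ·log(pr) − (1−gt)·α·pr^γ·log(1−pr)

with α = 0.25 and γ = 2.0, probabilities clipped to [1e−7, 1−1e−7].  The
focusing exponent down-weights the abundant easy background pixels so the
rare injury pixels drive the gradient; at γ = 0, α = 1 the loss reduces to
binary cross-entropy (tested to 1e−6).  Training pixels are sampled
uniformly from sections (1500 per section, all positives always kept,
200 k cap), preserving the class imbalance the loss is designed for.
Early stopping monitors validation loss (patience 3, min_delta 0) and the
parameters of the best epoch are returned.  Prediction thresholds the
probability map at 0.5 and extracts 8-connected components of at least
10 px as injury instances.  All of this is deterministic given the seed.

## The two-arm experiment

`run_experiment` executes the full comparison at desk scale (defaults:
60 scenes of 384×384, 40 training images per arm, the remainder held out;
review pieces 128 px, sections 96 px, 6 per image, ≤ 10 epochs):

1. generate scenes with ground truth;
2. a primary observer produces naive annotations of the training images;
3. **arm NA** trains directly on those labels;
4. naive annotations plus arm NA's own detections go through three-observer
   consensus review;
5. an interim model trains on disagreement-free sections;
6. its proposals are edited by the simulated reviewer (keep/redraw true
   detections, delete background proposals, re-add misses) to give
   network-assisted annotations;
7. **arm NAA** trains on those;
8. both arms are evaluated on the held-out scenes — against ground truth
   *and* against a fresh annotation session of the human observer, which is
   the only reference available in a real barn.

Both arms see exactly the same number of annotated images and the same
held-out set; the held-out ids intersect no training stage.  Because
training is stochastic, the pipeline's directional claim — the
network-assisted arm's F1 against the human reference is at least the naive
arm's — is asserted by majority vote over three seeded replicates, not a
single run.  Reporting both references is deliberate: the ground-truth
column separates model error from annotator noise, which the human-only
column (the realistic one) conflates.  A characteristic finding on
synthetic data: the naive arm scores *higher against ground truth* than
against the human reference (its reference is noisy), and the assisted arm
agrees better with the human than the naive arm does — the direction the
validation work steps are meant to buy.

## Numerical and degenerate-input choices

Empty-vs-empty IoU = 1.0; empty annotation sets are legal everywhere
except where a mask is required (bounding boxes, pieces).  Masks must be
non-empty and in-bounds; perturbed masks are guaranteed non-empty (centroid
fallback).  Scene placement retries are bounded and failure raises rather
than loops.  Sampling under-delivery is signalled by a short return plus a
warning, not an exception.  Seeds are combined with stable CRC-32 hashes of
string ids, never Python's process-salted `hash`.

## Known limitations

* The renderer omits occlusion, posture, motion blur and dust; absolute
  detection scores on synthetic scenes are far higher than anything
  reachable on real footage and only the *relative* arm comparison is
  meaningful.
* Verdict simulation derives the "true" verdict from overlap with ground
  truth (≥ 25 % of the detection), which real reviewers do not have.
* The pixel classifier has no learned spatial hierarchy; on real imagery a
  U-Net-class architecture behind the same `TrainConfig` surface would be
  the natural extension point (`architecture` is an enum for this reason).
* Location-tie resolution (unresolved rather than forced) and the
  image-level high-quality criterion (all finished detections unanimous)
  are interpretations; both are documented at the API.
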