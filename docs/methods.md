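# Methods

## The recognition problem

Two mid-lumbar transverse ultrasound planes are discriminated: PTV-TP,
whose landmark is the transverse process (T), and PTFV, whose landmark is
the intervertebral foramen (F). The recognizer is a two-stage pipeline —
single-class semantic segmentation of the bony landmark, then
classification of the landmark's spatial layout — evaluated under a strict
patient-level split. The central hypotheses it operationalizes are (a)
merging F and T into one foreground class yields better segmentation than
keeping them separate when annotated data are scarce, and (b) a classifier
on explicit spatial features of the segmented landmark beats an end-to-end
image CNN in the small-sample regime.

## Synthetic phantom

Clinical images are replaced by a phantom whose two shape classes carry
the geometric contrast the second-stage classifier relies on:

* **F (foramen, PTFV)** — a wide, shallow "goat-peak" ridge: two Gaussian
  bumps over a baseline, filled downward. By construction the upper
  contour has exactly two local maxima separated by one trough, and at
  most 4 curvature sign changes.
* **T (transverse process, PTV-TP)** — an irregular star-convex polygon
  with random radial offsets at `n_control_points` control points
  (default 10), drawn narrower and taller than wide, like the stem of the
  Shamrock sign; its upper contour has at least 5 curvature sign changes.

Both generators verify their contour contract with the shared oracle
(smoothed top-of-foreground profile; extrema from first-difference sign
runs, inflections from second-difference sign runs) and resample on the
rare discretization failure, so the two classes separate with zero overlap
at the documented threshold of 4.5 inflections. The geometric distinction
(wide/smooth/shallow vs narrow/irregular/tall) is deliberate: it mirrors
the anatomical contrast the clinical classifier exploits, and without it
grid-occupancy features would carry no signal.

Rendering composes, in order: soft-tissue background at echo level 0.40
overlaid with two to four undulating echogenic bands (fascial planes and
muscle interfaces of random depth, brightness and undulation — nuisance
texture that varies image to image and carries no class information), the
bone interior elevated to 0.85 (bone interior texture differs from soft
tissue; this also keeps the landmark's lower boundary physically
recoverable), a Gaussian-profile hyperechoic rim (σ = 5 px) along the bone
surface, multiplicative acoustic shadow (`shadow_attenuation`, default
0.45) applied to every pixel strictly below the surface, per-image gain
U(0.85, 1.15), multiplicative speckle `1 + σz` with σ = 0.15, Gaussian
blur σ = 1.5 px, and clipping to [0, 1]. The nuisance bands matter for the
model comparison: without appearance variability an end-to-end image
classifier can match the two-stage pipeline on phantoms, whereas real
scans vary in exactly the global-texture ways that hurt such models.
Images render at the native 960×720 raster and are resized to 224×224
(bilinear for images, nearest-neighbour for label masks) on load, so the
resize step of a real pipeline is exercised.

Cohorts draw one view class per patient. Each patient owns a geometry
anchor (centre within ±2× the jitter range, scale ×U(0.85, 1.15), base
rotation); images of that patient jitter around the anchor. This makes
images of one subject strongly correlated — which is exactly what makes
patient-level splitting (and its leakage tests) meaningful. Default desk
cohort: 56 patients × 2 images, balanced 50/50.

What the phantom does *not* emulate: muscle-layer anatomy (the Shamrock
"leaves"), curvilinear probe fan geometry, Rayleigh/log-compressed speckle
statistics, multi-structure scenes, operator and device variability.
Passing tests therefore demonstrate that the pipeline recovers the
*constructed* geometric contrast through realistic-style degradations at
small sample sizes — not clinical performance.

## Patient-level splitting

Patients are shuffled by seed and allocated 70/10/20 by largest-remainder
rounding (ties broken train > val > test). For 425 patients this gives
298/42/85. The split object is computed once per run and shared verbatim
by the segmenter, the feature stage and the classifier.

## Stage 1: segmentation

A symmetric encoder–decoder with skip connections; `depth` pooling stages,
encoder channels `base_channels · 2^level`, two 3×3 conv+ReLU per block,
nearest-neighbour upsampling in the decoder, 1×1 logit head. Implemented
on the package's own numpy engine (im2col-free shifted-matmul
convolutions, Adam, manual backprop); everything is float32 and
deterministic given the seed.

Training: Adam at fixed learning rate, combined BCE + soft-Dice loss
(cross-entropy + mean foreground Dice in the multi-class variant), no
augmentation, checkpoint selected by validation loss. Binarization
threshold 0.5 (exposed). Desk-scale defaults — depth 3, base 4 channels,
15 epochs, batch 4, lr 1e-3 — train in about two minutes on one core;
`SegConfig` scales to paper-size capacity (depth 4, base 64) unchanged.
Two stability measures matter at this scale: the logit-head bias is
initialized to the ≈10% foreground prior (−2.2), and the learning rate is
kept at 1e-3 — larger steps can settle into the all-background local
minimum of the imbalanced objective on some seeds. The soft-Dice term is
computed as one overlap over the whole batch rather than per image, which
keeps its gradient well-conditioned for batch size 4.

## Stage 2: features and classification

Predicted masks are vectorized on a 16×16 grid of 14×14-px cells
(row-major, c_0 top-left); bit j is 1 iff cell j contains foreground. The
"16 × 16 subregions" wording is read as a 16-by-16 *grid* (256 cells), the
only reading that yields 256 features from a 224×224 mask. The SVM trains
on features of the *predicted* masks of the training subset (mirroring
deployment, where ground truth is unavailable), with a ground-truth-mask
option. Empty predicted masks vectorize to the all-zero vector, are
flagged "no structure detected", and still receive a (default) label so
downstream counts stay consistent.

Kernel choice: the pipeline default is RBF with C = 1. A linear margin on
256 near-separable binary dimensions memorizes desk-scale training sets
outright (train accuracy 1.0, held-out ≈ 0.75 in bring-up measurements),
while RBF at the same C generalizes across patient placement; linear
remains available and is the `train_svm` signature default.

The CNN baseline is a fixed small convnet (three conv-pool stages, two
further poolings to a 7×7 map, dense 32 head) trained on raw images with
cross-entropy; flattening rather than global average pooling is used
because the discriminative signal is the coarse spatial layout, which GAP
destroys. It is deliberately untuned — a "standard CNN" reference point.

## Evaluation

IoU per image with both-empty = 1.0 and one-empty = 0.0 conventions;
headline segmentation score is the mean of per-image IoUs, with the
pixel-pooled ratio also reported (the two differ when mask sizes vary).
Multi-class comparator score: mean of the two foreground-class IoUs,
background excluded, classes absent from both masks skipped — so
right-shape-wrong-class predictions score 0. The four-way comparison
(`run_comparison`) trains, per seed, the single-class segmenter (shared by
the two-stage row and the segmenter-alone row, which therefore print the
same IoU), the multi-class segmenter, and the CNN baseline, all on one
fixed split. The segmenter-alone row classifies by a mask-only statistic —
the bounding-box aspect ratio (wider than tall ⇒ foramen), the gross
geometric contrast that survives downsampling to network resolution; it is
a documented reconstruction of an otherwise unspecified comparison row and
its absolute accuracy is not a supported result.

## Numerical and design choices

* Contour oracle: profile smoothing σ = 6 px, slope tolerance 0.08 px,
  curvature tolerance 0.004 px — chosen for native-resolution masks to
  suppress pixel-quantization jitter without hiding real bumps. At 224×224
  the fine contour irregularity is lost, which is why the mask-only
  heuristic falls back to the aspect ratio.
* Resize protocol: full-frame resize without aspect preservation (960×720
  → 224×224). Phantom and pipeline share the distortion.
* Degenerate inputs: empty masks raise in the contour oracle, vectorize to
  all-zero features elsewhere; an empty feature matrix is an error, not a
  0-row matrix.
* All randomness flows from one master seed expanded per stage by SHA-256
  (`stage_seed`), keeping every stage independently reseedable and every
  run one-flag reproducible.
* Problem sizes in the test suite (8–56 patients, depth-2/3 nets, 2–15
  epochs) are chosen so the whole suite trains several networks in
  minutes on one CPU core; the reduced-scale comparison uses 24 patients
  × 2 images over three seeds — the small-sample regime where the
  two-stage design's advantage over the end-to-end CNN expresses itself.

## Known limitations

* The phantom's class contrast is constructed, so absolute IoU/accuracy on
  phantoms say nothing about clinical values; only directional claims
  (single-class > multi-class IoU; two-stage ≥ CNN accuracy at small n)
  and pipeline mechanics transfer.
* The numpy engine is single-threaded and desk-scale; paper-scale capacity
  trains, but slowly.
* One landmark per image is assumed throughout (view classification and
  region labelling coincide under this assumption; scenes with both F and
  T are out of scope).
* No significance testing across seeds; the comparison reports means.
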