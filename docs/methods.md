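# Methods

This note records the models, parameter choices and numerical decisions
behind `eartrack`, and what its synthetic validation does and does not
establish.

## Synthetic arena

The generator emulates the overhead geometry of an open-field test: a
uniformly bright floor (intensity 220 of 255) with Gaussian pixel noise
(default sd 2), dark filled-ellipse bodies (intensity 60) and two small ear
disks (intensity 140) per animal. Ears sit on the ±35° rays off the heading
near the head focus of the body ellipse, pulled inward just enough
(boundary radius + 0.3·ear radius, capped by the focal distance) that each
disk stays 8-connected to the body at every discretised heading — at
exactly the focus the disk detaches for some body shapes and would split
the blob. Motion is a constant-speed random walk with Gaussian heading
diffusion (sd 0.3 rad/frame) and reflective walls; this produces both
wall-following and genuine crossing events without tuning. When crossings
are expected (≥2 subjects roaming farther than the arena diagonal) the
simulator retries fixed seed offsets until at least one frame shows
touching subjects, and records the seed used.

A subject's *occluded* flag is true exactly when its rendered pixel set is
8-adjacent to another subject's (dilated-mask intersection). This is the
condition under which foreground segmentation merges the two into one
blob, so blob-count frame classification agrees with the flags *exactly*
on noise-free renders — a property the tests exploit as an oracle.

What the generator does **not** emulate: fur texture, shadows, bedding
clutter, illumination gradients, camera distortion, rearing (body
foreshortening), or low ear/body contrast. Tests passing on this substrate
validate the pipeline's logic — classification, identity propagation,
small-object localisation, association, linking, metric arithmetic — not
robustness to real-video nuisance factors.

Desk-scale study conditions used by the system-level tests, chosen once:
128×128 px arena, body semi-axes (11, 5.5) px, ear radius 3 px (6–7 px
boxes, the few-pixel regime the detector is built for), 40 frames/s, speed
2.5 px/frame, noise sd 2; 500-frame two-subject target clips and a
320-frame single-subject training clip.

## Preprocessing

Frames are linearly rescaled to mean 128 so illumination drift cancels;
all thresholds live on that scale. The background is the pixel-wise
average of evenly subsampled frames; the labelling and pipeline paths use
the pixel-wise *median* instead, because a single subject dwelling in one
corner leaves a ghost in a mean background that segments as a spurious
blob (any pixel occupied in a minority of samples takes the true floor
value under a median). Foreground is |frame − background| > 30, in
8-connected components of at least 50 px at 1280×720 scale (scaled by
arena area); absolute difference handles both dark-on-light and
light-on-dark subjects. The defaults 30 (blob/body) and 60 (ear intensity
floor) sit mid-band for the synthetic intensity scheme: body contrast ≈
94, ear contrast ≈ 47, ear absolute intensity ≈ 82 versus body ≈ 35 after
normalisation.

Automatic ear labelling for single-subject clips is double thresholding:
segment subject from floor, crop to the body blob's bounding box,
re-threshold inside the crop (foreground ∧ intensity > 60), keep the two
largest components. Frames with ≠2 ear components are skipped and logged.
On noise-free synthetic clips the auto-labels equal the rendered ear boxes
(IoU 1.0 in the tests). Left/right identities are assigned by
minimum-displacement continuity between consecutive frames.

Frames with *more* blobs than subjects are treated as occlusion frames:
the area filter removes noise blobs first, so a surplus indicates an
unresolved scene rather than a countable population.

## Overlap tracker

Per frame pair, identities are inherited by a globally optimal one-to-one
assignment maximising shared-pixel counts — a per-blob "most overlap" rule
is ambiguous when two blobs claim one predecessor, and the bijection
enforces the one-blob-one-individual model. The score is lexicographic by
construction: overlap count, then IoU (weight 0.45 < 1, so an integer
overlap difference always dominates), then a deterministic preference
pairing lower incumbent identities with earlier (larger-area) blobs, and a
tiny nearest-centroid term (1e-4) that only decides when every overlap is
zero — logged as the fallback the design prescribes.

## Ear detector

Architecture (`eartrack.ear_detector`): a Focus stem (lossless 2×2
space-to-depth), a backbone of Conv+BatchNorm+LeakyReLU (CBL) stages with
one CSP-style residual split per stage and an SPP multi-scale max-pool
fusion at stride 32, a PANet-style neck (top-down then bottom-up fusion),
and 1×1 box/objectness heads per level. The baseline pyramid predicts at
strides {8, 16, 32}; the *improved* variant routes a fourth information
stream from the stride-4 backbone layer into the neck with its own head.
Widths are config-scaled (default base width 8 → ≈111 k parameters
improved, ≈99 k baseline); batch-norm layers carry running statistics for
inference.

Anchors and assignment. One anchor per level, fit to the training labels:
each label is routed to the level whose stride best matches its scale
(object size ≈ 1.5 grid cells), and each level's anchor is the mean size
of its routed labels. Routing by anchor-size IoU alone is degenerate on
single-scale data — near-identical anchors scatter labels across levels by
quantisation noise, and a 6-px ear assigned to stride 16 cannot be
localised (measured mAP collapse). A label must clear an anchor IoU ≥ 0.3
floor at its level; it is regressed from its centre cell and the two
nearest neighbour cells (the decode spans ±0.5 cell: centre =
(2σ(t)−0.5+g)·stride, size = (2σ(t))²·anchor), and cell collisions resolve
to the nearer box centre.

Loss. Three terms: (1) GIoU box loss on positive cells (GIoU keeps a
gradient when a prediction drifts disjoint from its target, where plain
IoU is flat); (2) an auxiliary sigmoid-space coordinate MSE (weight 20)
whose well-conditioned surface lets the short desk-scale schedule converge
— the published-scale regime runs tens of thousands of optimiser steps,
this package runs hundreds; (3) objectness BCE over all cells in which
negatives are focal-weighted (0.02 + p², so easy background fades while
confident false positives keep pressure regardless of grid area) and
positives carry a fixed 10% share of the total weight, with the *detached
predicted-box IoU* as their target so badly-regressing cells learn low
confidence. Box weight 3.

Training. SGD with momentum 0.937 under a one-cycle cosine schedule
decaying to 0.2× the initial rate, 10% linear warm-up, batch 8; the config
defaults (50 epochs, lr 0.01) are the published-scale settings, while the
desk-scale tests use 80–120 epochs at lr 0.02 on 40 frames strided from a
320-frame clip. Horizontal/vertical flips are the only augmentation: a
single short clip cannot cover positions and headings otherwise (held-out
mAP@0.5 0.63 → 0.85 at 128² when added); the heavier augmentation suites
of full-scale detectors are out of scope. Training is bitwise reproducible
per seed on a fixed thread count. Inference decodes cells above the
confidence threshold (default 0.4 in the pipeline), clips boxes to the
frame and applies greedy NMS at IoU 0.45.

At these settings the improved model reaches mAP@0.5 ≈ 0.85–0.96 on
held-out synthetic splits, and beats the 3-level baseline on mAP@0.5:0.9
in every paired seeded run of the acceptance suite — the architectural
point of the stride-4 connection, reproduced directionally at desk scale.

## Dual-Siamese similarity and assignment

Ear observations are fixed 32×32 crops (edge-padded) centred on the
detection, with centroids normalised by the frame size for the coordinate
branch. The image branch is three stride-2 CBL stages plus a linear map to
a 16-d embedding; the coordinate branch is a 2→16→8 MLP; both are applied
with the same parameters to the two inputs of a pair (weight sharing by
construction). Each branch minimises a contrastive loss on its embedding
distance (margin 1.0: same-ear pairs pay d², others pay max(0, 1−d)²); the
two distances feed a 2→16→1 fully connected head trained with BCE, whose
sigmoid output is the pair score; scoring averages both input orders so it
is symmetric by contract.

Pairs: positives are the same ear identity in consecutive kept frames;
negatives are observations more than 60 s apart (configurable; short test
clips shrink the gap to a quarter of the clip). The pipeline builds
positives at the *full* tracking frame rate so the coordinate branch
learns tracking-time displacements: with subsampled positives it tolerated
20-px jumps and allowed identity swaps during crossings (measured: 71 → 10
switch errors when changed). Training: SGD momentum 0.937, one-cycle, 30
epochs over 800 pairs, ≈10 s CPU; held-out pair AUC ≥ 0.99 on synthetic
data, and a shuffled-label control sits at chance.

Assignment between frames is a Hungarian matching on 1 − score; matches
below min_score 0.2 stay unassigned and surface as misses downstream.
During an occlusion fragment the tracker matches each frame's detections
against the *last seen* observation of every ear identity (a one-frame
detector dropout does not kill the track). Ear identities are fixed on the
seeding flank frame by grouping detections to the identified blobs (two
slots per blob, distance cost with a containment bonus); an individual's
position is the mean of its visible ear centroids, one ear sufficing.
Fragments with no preceding flank are seeded from the following one and
walked in reverse; fragments with no flanks at all are left as gaps.

## Linking and gaps

Ear-track individuals are matched to blob identities on flank frames by
mask containment, falling back to centroid distance, as an optimal
one-to-one matching. The earlier flank labels the occlusion frames; the
composition of both flank matchings relabels the following fragment, with
a nearest-to-last-known-position fallback (logged) when the hand-over is
incomplete or the flanks disagree. Unresolvable frames are explicit gaps —
positions are never interpolated, so downstream statistics are computed
only from observed positions.

## Evaluation

`score_tracks` matches predictions to ground truth per frame by nearest
centroid within `match_radius` (Hungarian). An unmatched truth identity is
a miss (and FN); a matched one is a switch when the prediction identity
contradicts the majority mapping over the preceding 30 frames, a drift
when the mapping is consistent but the error exceeds `drift_radius`
(default half the match radius; the pipeline sets it to the body's full
minor axis, so an ear-derived head position never counts as drift), and
correct otherwise. IDSW follows the usual change-against-last-match
semantics, so MOTA's FN/FP/IDSW tallies are computed independently of the
Miss/Switch/Drift tallies. ICR and MOTA then follow their definitions;
MOTA may be negative. AP uses greedy highest-IoU matching per frame in
descending confidence and all-points interpolation; mAP@0.5:0.9 averages
thresholds {0.5 … 0.9}, deliberately not the 0.5:0.95 COCO ladder. The
"N−1" chi-squared test scales the Pearson statistic of the 2×2 table by
(N−1)/N with one degree of freedom.

## Behaviour analytics

Speeds are per-step displacements × frame rate / px-per-cm (the pixel
calibration is user-supplied; synthetic tests fix it by construction), and
block means aggregate non-overlapping 300 s windows; steps spanning a gap
are excluded everywhere. The 2-D spatial standard deviation uses the
population (divide-by-n) form and reduces to the 1-D population SD when
one coordinate is constant. The occupancy grid is the canonical central
12-region layout (x 320–960, y 240–720, 160×160 cells at 1280×960-class
resolution; `RegionGrid.for_arena` scales it to other arenas), numbered
row-major left-to-right then top-to-bottom — an explicit permutation can
override the numbering if a different convention is needed. The rank-sum
test uses the exact null distribution up to a combined n of 20 without
ties and the tie-corrected normal approximation otherwise; fully tied data
degenerate to p = 1 with a log message. For paired designs (the same
subjects across conditions) a signed-rank test would be the appropriate
tool; this package deliberately ships the unpaired rank-sum comparison as
its group-level test.

## Reproducibility and numerics

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; the pipeline fans a single global seed into
per-stage seeds by fixed offsets, so stages are individually reproducible.
Training arrays are float32; the autodiff core is dtype-agnostic and its
operations are verified against central finite differences in float64.
Box arithmetic uses half-open pixel rectangles so areas and intersections
are exact for pixel-aligned boxes. Degenerate inputs (all-zero frames,
empty ground truth, zero-margin tables, single-class pair sets) raise
validation errors rather than returning conventional values, except where
a convention is standard (empty blob list; p = 1 for fully tied samples).

## Known limitations

- Validation is synthetic-only; no claim is made about fur-textured,
  low-contrast or cluttered laboratory video.
- The detector and Siamese models are desk-scale (≈10⁵ parameters, minutes
  of CPU training) and are trained from random initialisation; transfer
  learning from large pretrained backbones is out of scope.
- The coordinate branch dominates identity decisions when all ears look
  alike (as in the synthetic renders); appearance-based disambiguation is
  only as good as the visual variation in the training crops.
- Occlusion fragments bounded by no non-occlusion frame on either side
  cannot be labelled and remain gaps.
- A prolonged full cover of both ears of one animal defeats the
  last-seen-observation matching; the trajectory shows a gap until the
  animal separates again.
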