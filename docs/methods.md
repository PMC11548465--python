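# Methods

## Problem and approach

`fruitrack` counts fruit in orchard video by tracking-by-detection: a
detector proposes per-frame boxes, an online tracker links them into
identities, and the count is the largest identity issued. The failure mode
that ruins counts in orchards is the identity switch — a fruit occluded by
a branch (or lost to a pan) re-emerges and is treated as a new fruit.
The tracker here, a multi-rematching variant of the BoT-SORT recipe,
attacks exactly that: after each IoU-based association stage it *rematches*
leftover detections to leftover tracks by appearance, and guards each
appearance match with a displacement-consistency validation.

## Tracker

**State.** Each track carries an 8-dimensional Kalman state
(cx, cy, w, h and per-frame velocities), a constant-velocity motion model,
and size-scaled noise (position std = size/20, velocity std = size/160 —
the standard box-tracking choice at video frame rates; width and height
are modeled directly, not as aspect ratio).

**Per-frame pipeline.**

1. *Camera-motion compensation.* ORB keypoints matched between consecutive
   frames (cross-checked), robust affine fit by RANSAC (min 3 samples,
   2 px residual, 100 trials, seeded). Fallbacks to identity: fewer than 6
   matches or inliers, or a 2×2 determinant outside [0.5, 2]. The affine
   warps track positions and velocities; width/height are untouched
   (pan-dominant motion). Frame features are cached so each frame is
   processed once.
2. *Confidence split.* Detections split at `track_high_thresh` (0.5) and
   `track_low_thresh` (0.1).
3. *Stage A.* Hungarian assignment of high-confidence detections to all
   live tracks (active, lost, tentative) on cost 1 − IoU, gate
   `match_thresh` (0.5). Ties are broken row-major by an infinitesimal
   index perturbation, so assignment is deterministic.
4. *Rematch A.* Leftover high-confidence detections × leftover tracks on
   VLAD cosine distance, gate `appearance_thresh` (0.5), then the
   validation check (below).
5. *Stage B / Rematch B.* The same pair of stages for low-confidence
   detections against the remaining tracks.
6. *Lifecycle.* Matched tracks get a Kalman measurement update; a new
   high-confidence detection (score ≥ `new_track_thresh` = 0.7) seeds a
   tentative track; a second consecutive match confirms it and assigns the
   next sequential id; unmatched tentative tracks are dropped; unmatched
   confirmed tracks go lost and are removed after `track_buffer` (30)
   unseen frames. Lost tracks stay eligible for every association stage —
   this is what makes re-identification after a full occlusion possible.

**Output convention.** Only confirmed tracks are reported or counted, and
rows accumulated while a track was still tentative are emitted
retroactively on confirmation. Without this backfill, every track's first
frame would be a structural miss and even a perfect detector could not
reach MOTA 1. Reported boxes are the matched detections (not the filtered
state), so a perfect detector reproduces ground truth exactly.

**Counting.** Ids are sequential from 1 with no gaps, so the count equals
the maximum id issued.

## Appearance model

Crops (detection box padded 10%) are described by local keypoint
descriptors and aggregated into a VLAD signature: residuals to the nearest
of K = 8 k-means centroids, accumulated per centroid, concatenated, signed
square root, L2 normalization. The codebook is fitted once per video from
the first frames' pooled descriptors (≥ max(4K, 40) descriptors) with the
run's seed. Crops without keypoints yield a degenerate all-zero signature
that never participates in appearance matching — this is deliberate:
aggregated-residual matching on textureless regions is noise, and the
validation mechanism exists precisely because such matches are unreliable.

Two numerical choices matter on small fruit:

* crops whose short side is under 48 px are upscaled by a **fixed** 3×
  factor before extraction. The factor must not adapt to the (jittering)
  box size: a size-dependent factor makes the same fruit's descriptors
  flip between physical scales frame to frame and destroys similarity.
* the default backend is SIFT (scikit-image, internal pre-upsampling off
  since crops arrive upscaled). ORB is available but its binary
  descriptors proved brittle under box-localization jitter at these crop
  sizes: on jittered synthetic crops, same-fruit cosine similarity drops
  to ≈0.6 under ORB but stays ≈0.88 under SIFT, while different-fruit
  similarity stays below ≈0.37 for both. SURF is not available in any
  maintained Python library; the module's contract is descriptor-agnostic.

Signatures are refreshed from matched detections at most every 5 frames
(`appearance_refresh_interval`) — appearance drifts slowly, extraction is
the dominant cost, and a slightly stale signature is exactly what the
rematch needs after an occlusion anyway.

**Validation mechanism.** Two regions of the same scene must move together
between frames. A candidate appearance match (lost track ↔ detection) is
accepted only if its displacement agrees with that of an anchor — the
highest-IoU already-matched pair of the same frame. Both displacements are
normalized by their frame gap (a track re-emerging after k frames has
travelled k frames' worth of scene motion), and the tolerance is
max(10 px × frame_width/1920, 0.3 × √(box area)). The second term is a
noise floor: box-localization jitter perturbs displacement estimates by a
fraction of the box side, while a *wrong* match is typically inconsistent
by tens of pixels, so the floor costs little discrimination. With no
anchor available the check passes vacuously.

## Detector building blocks

Forward-only numpy operators, no training, batch norm folded to identity:

* **Dynamic convolution** — n kernels, each modulated elementwise by four
  non-negative attention factors (spatial k×k, input channel, output
  filter, scalar), summed, applied as one cross-correlation. The
  attention-generating squeeze network is out of scope; attentions are
  inputs. The operator is linear in the input for fixed attentions.
* **Global attention gate** — channel stage: per-position two-layer MLP
  (reduction 4, ReLU), sigmoid, multiplicative gate over the full
  h×w×c map; spatial stage: two same-padding convolutions (kernel 7,
  channel-preserving overall, ReLU between), sigmoid, second gate.
* **Soft pooling** — per window, softmax-of-activation weighted mean,
  stabilized by subtracting the window max; same-padding uses −∞ pads
  that carry zero weight. Output lies between average- and max-pooling
  for non-negative inputs.
* **Soft spatial pyramid layer** — CSP-style: branch A 1×1 conv; branch B
  1×1 conv → parallel stride-1 soft pools at kernels {3, 5, 9, 13} →
  concat with the un-pooled tensor → 1×1 conv; branches concatenated →
  1×1 conv. Kernel 3 is the added small-object receptive field. A max-pool
  substitution switch exists for oracle tests.

## Metrics

Detection: precision/recall as exact ratios (`None` for 0/0), AP by
all-point interpolation (precision envelope, step integration) with greedy
score-ordered matching at IoU ≥ 0.5, mAP as the class mean. Tracking:
CLEAR-MOT — per frame, previous pairs persist while above the gate, the
rest matched by IoU-gated optimal assignment; a mismatch is counted when a
ground-truth identity's result id changes between its consecutive matched
frames; MOTA = 1 − (misses + false positives + mismatches)/Σgt. Counting:
MAE is the mean per-video relative error, plus an OLS fit of predicted on
true counts with R². All internal values are fractions; percent formatting
happens at the CLI.

## Synthetic orchard simulator

The simulator emulates the phenomenology of hand-held orchard clips at
desk scale: 320×240 frames (the acceptance studies use 120 frames at
30 fps metadata), 12–25 round fruit of radius 8–16 px, static in world
coordinates, on a smoothed-noise foliage background. Each fruit gets a
Lambertian-style shading gradient plus a per-fruit speckle pattern drawn
from one of two density families (0.12 / 0.40), so keypoint detectors find
structure and appearance signatures can discriminate individuals. The
camera pans at a piecewise-constant velocity (`camera_turns` lets the pan
reverse mid-clip, as back-and-forth row scanning does); opaque vertical
strips occlude whatever passes behind them for a frame interval.

Ground truth follows tracking-benchmark convention: the box of the visible
region, annotated with its visibility fraction, and omitted once more than
80% of the fruit is covered or out of frame. Identities are stable across
occlusion. Everything is deterministic given the seed.

The corruption operator models detector imperfection: boxes dropped with
probability `miss_prob`, Gaussian corner jitter, Poisson false positives
per frame at low confidence (0.10–0.45), and confidence tied to visibility
(0.55 + 0.45·visibility + N(0, 0.05), clipped) — fully visible fruit seed
tracks, heavily clipped slivers fall into the low-confidence band, as real
single-stage detectors behave. The occlusion studies use miss 0.05, jitter
1.5 px, 0.2 false positives/frame — moderate noise for a well-trained
detector at this resolution.

What the simulator does **not** model: photorealistic lighting, leaves and
branches beyond rectangular strips, fruit motion in wind, perspective and
depth, motion blur during tracking (it exists only as a training-set
augmentation op). Passing tests therefore demonstrate the tracking and
counting *mechanisms* — exact counting when detections are clean, identity
persistence through occlusion, the differential value of appearance
rematching — not field-level accuracy on real videos.

## Study conditions and what they show

* **Clean study** (10 seeds): static camera, no occluders, identity
  corruption. The tracker must count 25/25 with zero switches and MOTA 1 —
  any failure is a logic bug, not noise.
* **Occlusion study** (20 seeds): pan 2 px/frame reversing mid-clip, two
  occluder strips, moderate corruption, tracked with and without the
  rematch stages (camera-motion compensation off in both arms so the two
  arms differ only in the mechanism under test; the Kalman velocity state
  absorbs the smooth pan). Identity switches drop by roughly a third with
  rematching (one-sided sign test across seeds, p < 10⁻⁵).
* **Counting study** (7 videos, 12–30 fruit): the full pipeline, MAE and
  the count-vs-truth regression. Under these deliberately noisy
  conditions counts inflate at frame edges (fruit entering as low-visibility
  slivers fragment), which the regression's slope > 1 reflects honestly.

## Known limitations

* The appearance model presumes stable per-fruit texture; fruit whose
  appearance changes (lighting bursts, heavy blur) will not rematch.
* The validation anchor is a single highest-IoU pair; a frame with no IoU
  match validates vacuously.
* Counting uses maximum id, so any residual fragmentation inflates counts;
  fragmentation at frame borders is the dominant error under camera pan.
* The evaluation assumes one object class; the mean-AP helper is
  class-count-agnostic but no multi-class matching is provided.
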