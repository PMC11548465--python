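# fruitrack

Tracking-by-detection fruit counting for orchard video.

Yield estimation from video reduces to a multi-object tracking problem:
a detector proposes a box for every visible fruit in every frame, a
tracker links boxes across frames into identities, and the number of
fruit in the clip is the largest identity issued. The hard part is not
detection but *identity*: a fruit hidden by a branch for twenty frames
and re-found as "new fruit #90" silently inflates the count.

`fruitrack` implements a multi-rematching tracker for this problem,
together with everything needed to exercise it without any external data:

* **Tracker** — constant-velocity Kalman prediction over (cx, cy, w, h)
  states, camera-motion compensation (ORB + RANSAC affine), two-stage
  Hungarian association on IoU cost with a high/low confidence split, and
  an appearance *rematch* after each IoU stage: leftover detections are
  compared to leftover tracks by cosine similarity of VLAD signatures
  (k-means codebook over local keypoint descriptors, aggregated residuals,
  signed-sqrt + L2 normalization), with a displacement-consistency
  validation — a candidate match must move like an independently matched
  anchor region in the same frame pair.
* **Detector building blocks** — forward-only numpy reference operators
  for the attention/pooling modules of an occlusion-robust YOLO-style
  backbone: omni-dimensional dynamic convolution (per-kernel spatial /
  channel / filter / scalar attentions), a global channel+spatial
  attention gate, softmax-weighted (soft) pooling, and a CSP-style soft
  spatial pyramid layer with kernels {3, 5, 9, 13}.
* **Metrics** — precision / recall / AP / mAP for detection; CLEAR-MOT
  tallying (MOTA = 1 − Σ(mₜ + fpₜ + mmeₜ)/Σgₜ, identity switches) for
  tracking; mean relative counting error MAE = (1/m)·Σ|yᵢ − gtᵢ|/gtᵢ and
  the count-vs-truth OLS line with R² for counting.
* **Synthetic orchard simulator** — textured fruit, panning (and
  reversing) camera, occluder strips, exact MOT ground truth with
  visibility annotations, a detector-imperfection model, and the usual
  training-set augmentation transforms.
* **MOT I/O** — MOTChallenge CSV reading/writing and mask / polygon / box
  annotation conversion to normalized center format.

## Worked example

Simulate a small occlusion scene, count it with and without appearance
rematching, and see the identity switch the rematch prevents:

```python
from fruitrack import SceneConfig, Occluder, simulate_orchard, corrupt_detections
from fruitrack import CorruptionConfig, TrackerConfig, count_video

scene = SceneConfig(
    n_apples=20, n_frames=120,
    camera_velocity=(2.0, 0.0), camera_turns=[(60, (-2.0, 0.0))],
    occluders=[Occluder(100, 140, 30, 55), Occluder(190, 230, 60, 90)],
    texture_seed=1,
)
frames, gt = simulate_orchard(scene)
dets = corrupt_detections(
    gt, CorruptionConfig(miss_prob=0.05, jitter_sigma=1.5, fp_rate=0.2, seed=1),
    frame_size=scene.frame_size, n_frames=scene.n_frames,
)
for rematch in (True, False):
    cfg = TrackerConfig(seed=1, with_rematch=rematch, with_gmc=False)
    rep = count_video(frames, dets, cfg, ground_truth=gt)
    print(f"rematch={rematch}: count={rep.count} (true {rep.gt_count}) "
          f"MOTA={rep.mota:.3f} IDS={rep.ids}")
```

prints

```
rematch=True: count=37 (true 20) MOTA=0.927 IDS=19
rematch=False: count=53 (true 20) MOTA=0.914 IDS=34
```

The clip is deliberately hostile (pan reversal during occlusions, jittered
and missing detections): both configurations fragment some tracks at the
frame borders, but the appearance rematch recovers occluded identities —
far fewer identity switches and a count sixteen closer to truth. On a clean
static scene both count exactly (see the test suite). The same pipeline is
available from the shell:

```sh
fruitrack simulate --config scene.yaml --out sim/
fruitrack track --detections sim/det.txt --frames sim/img1 --gt sim/gt.txt --out run/
fruitrack eval  --gt sim/gt.txt --results run/results.txt --out eval/
fruitrack demo  --out demo/            # simulate → count → eval in one shot
```

Tracker thresholds (`track_high_thresh=0.5`, `track_low_thresh=0.1`,
`new_track_thresh=0.7`, `match_thresh=0.5`, `track_buffer=30`,
`appearance_thresh=0.5`) ship as defaults and can be overridden by YAML
config. See `docs/methods.md` for the full model description and the
design rationale.

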