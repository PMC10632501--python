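# synthrig

Procedural generation of annotated synthetic training data for articulated
animal models, with exporters to common computer-vision training formats, a
detection-based multi-animal tracker, and the evaluation statistics used to
score detection, tracking, pose estimation and segmentation on such data.

Hand-annotating images of insects and other small animals — boxes, identities,
dozens of keypoints, per-pixel masks — is the bottleneck of most quantitative
behaviour studies. `synthrig` sidesteps it by *domain randomization*: a rigged
3D subject model is multiplied into a digital population (random scale, hue,
brightness, contrast, saturation), dropped into procedurally randomized scenes
(noise-displaced terrain, scattered assets, random lights and cameras), and
rendered into co-registered image passes from which pixel-perfect ground truth
is computed automatically. Training images are deliberately over-varied so
that real footage falls inside the training distribution.

It is aimed at researchers building detectors, pose estimators, trackers or
segmentation networks for lab and field recordings of insects and similar
animals, who need large annotated datasets without annotating anything.

## What it computes

**Generation.** Each iteration renders four co-registered passes: an RGB
render, an **ID pass** (each subject's pixels carry its unique RGB identity,
background exactly `(0,0,0)`), a depth pass (camera-plane distance) and
surface-normal passes. From these the toolkit derives, per subject: the
bounding box (smallest rectangle enclosing all projected 2D keypoints), 2D and
camera-relative 3D keypoint coordinates with per-keypoint occlusion flags, and
the occupancy fraction of the box. Subjects are posed by contact: downward ray
casts find foot targets and a joint-limited cyclic-coordinate-descent IK
solver bends each leg chain to them, so animals *stand on* the randomized
geometry rather than floating in it.

**Evaluation.** Five statistics, in the field's standard notation:

- Center-based average precision over descending confidence thresholds
  (13 equally spaced on [0.2, 0.8]); a detection is correct when its center is
  within 5% of the image width of an unmatched ground-truth center:
  `AP = Σₙ (Rₙ − Rₙ₋₁) Pₙ` with the seed point `R₀ = 0, P₀ = 1`
  (no trapezoidal interpolation), and `mAP` the mean of per-case APs.
- Multiple object tracking accuracy,
  `MOTA = 1 − (Σ FNₜ + FPₜ + IDSₜ) / Σ ŷₜ`,
  with Hungarian per-frame matching gated at `d_max` (50 px at 4k, otherwise
  2% of the frame width). Identity switches are counted once per reassigned
  ground-truth id, after which the new correspondence is considered correct;
  while two ground-truth tracks are closer than `d_max` (an overlap event),
  correspondence changes are suppressed and only FN/FP accumulate.
- Relative pose error `δȳ = 100 · Δȳ / l`, the mean pixel error over
  keypoints above a confidence threshold (default 0.6), normalized by the
  body length `l` in pixels.
- Average class-wise recall for segmentation,
  `ACR = (100/c) Σᵢ (1/n) Σⱼ (ŷⱼ − (FPᵢⱼ + FNᵢⱼ)) / ŷⱼ`,
  over classes `i` and images `j`.

**Tracking.** A buffer-and-recover tracker: per-frame confidence/size
filtering and greedy NMS (defaults 0.5 / 0.45 / 20 px), constant-velocity
Kalman prediction, Hungarian association on center distance, coasting through
detection gaps for a buffer period before termination, fresh never-reused ids
for new detections.

## Worked example

A built-in rigged hexapod ("stick") and primitive asset meshes make the
pipeline self-contained. Generate a tiny dataset, export it, and score a
simulated detector:

```bash
cat > demo.yaml <<EOF
general:
  n_samples: 2
  resolution: [96, 96]
  dataset_name: demo
subjects:
  population_size: 2
environment:
  terrain_resolution: 48
  terrain_extent: 12.0
debug:
  seed: 5
EOF

synthrig generate -c demo.yaml -o out
# dataset written to out/demo

synthrig export --dataset out/demo --format yolo --out out/yolo
# YOLO labels: 3 boxes written, 1 skipped

synthrig simulate-tracks --targets 4 --frames 50 --seed 2 --out gt.csv
synthrig simulate-detections --gt gt.csv --seed 2 --out det.csv
synthrig track --detections det.csv --out tracks.csv
# 5 tracks over 50 frames -> tracks.csv
synthrig eval-track --gt gt.csv --tracks tracks.csv
# {"mota": 0.995, "fn": 0, "fp": 1, "ids": 0, "gt_detections": 200}
```

Reading the numbers: of the 4 simulated subjects' 200 ground-truth detections,
every one was recovered at the correct identity (`fn = 0`, `ids = 0`); one
clutter detection briefly became a fifth track (`fp = 1`), costing 1/200 =
0.005 of the score. The YOLO export wrote one normalized
`class cx cy w h` line per subject visible in each image and skipped one
subject that projected outside the frame.

`out/demo/` contains `batch.json` (population table: instance ids, ID-pass
colors, classes, scales), `samples/NNNNNN.json` (camera matrices plus
per-subject boxes, keypoints, visibility and occupancy) and
`passes/{render,id,depth,normal,normal_world}/NNNNNN.png`. Identical seeds
reproduce a dataset bitwise; changing only `debug.subject_seed` repopulates
identical scenes with different subjects.

Other exporters: `--format coco` (detection + keypoints + RLE or polygon
instance masks), `keypoints` (wide per-instance CSV for pose-estimation
trainers, plus a skeleton file), `masks` (8-bit label maps, binary or
per-class), `pose3d` (camera intrinsics/extrinsics with camera-relative 3D
keypoints).

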