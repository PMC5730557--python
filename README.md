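# depthherd

Automated tracking and behaviour monitoring of group-housed pigs from
overhead depth video.

Pig pens in commercial settings house too many animals for staff to watch
closely, yet changes in standing, feeding, drinking and locomotor behaviour
are early indicators of health and welfare problems.  `depthherd`
implements a complete monitoring pipeline for a pen instrumented with
ceiling-mounted time-of-flight depth cameras:

1. **Back projection** — each depth raster (16-bit millimetre PNG) becomes a
   3D point cloud: `X = (u − c_x) d / f_x`, `Y = (v − c_y) d / f_y`, `Z = d`.
2. **Cloud pre-processing** — pen-region filtering by known coordinates,
   voxel-grid downsampling (0.02 m cells), statistical outlier removal
   (mean distance to the k = 50 nearest neighbours, threshold
   μ + 0.25 σ), and surface-normal estimation in a 0.06 m radius.
3. **Detection** — region growing on the normals: one animal's smooth back
   forms one region; the normal discontinuity in the crease between
   touching animals keeps them separate.
4. **Tracking** — frame-to-frame identity linking by minimum-total-distance
   (Hungarian) assignment of detection centroids, two-camera merging into
   the pen frame via the ceiling offsets, and window-5 median smoothing, at
   a 7 Hz processing clock.
5. **Behaviour** — standing via a two-component univariate Gaussian mixture
   over centroid depth Z (EM, k-means initialisation, 10,000-sample
   training, two-sample Kolmogorov–Smirnov validation); feeding/drinking
   via stay points (0.05 m radius, 1 s threshold) gated by standing posture
   and the feeder/drinker areas; ground-plane speed and distance; spatial
   entropy `H = −Σ p_i ln(p_i / q_i)` over a 3 × 6 grid; all aggregated
   into 5-minute intervals using the total-time convention.
6. **Evaluation** — CLEAR-MOT tracking metrics

       MOTA = 1 − Σ_t (FN_t + FP_t + IDSW_t) / Σ_t GT_t
       MOTP = Σ_{i,t} d_t^i / Σ_t c_t

   plus mean track duration, a 30-second-fold cross-validation protocol,
   and behaviour-series validation with R², RMSE, an F-test and AUC.

Because no public depth recordings of this kind exist, the package ships a
first-class **synthetic scene generator**: ellipsoidal animal bodies at
posture-dependent heights, behaviour driven by a continuous-time Markov
chain or deterministic schedules, time-of-flight-like depth noise, a 7 fps
capture clock, and exact ground-truth annotations.  Every stage of the
pipeline is tested against these scenes and against independent brute-force
oracles.

## Worked example

```python
import numpy as np
from depthherd import (
    CameraIntrinsics, PenGeometry, BehaviourParams, compare_series,
    evaluate_tracking, track_sequence,
)
from depthherd.behaviour import measure_behaviour
from depthherd.synthetic_scene import demo_scene, scripted_standing_series

pen = PenGeometry()                      # 4.02 x 2.36 m, cameras at 1.98 m
intr = CameraIntrinsics.wide_demo()

# 19 animals, 60 s, 0.01 m depth noise
states, frames, gt = demo_scene(seed=1)
tracks = track_sequence(frames, intr, pen)

mot = evaluate_tracking(gt, tracks)
print(f"MOTA {mot.mota:.3f}  MOTP {mot.motp:.3f} m")

params = BehaviourParams(interval=10.0, train_sample=5000)
intervals, model = measure_behaviour(tracks, pen, params, seed=1)
auto = {iv.start: iv.standing_s for iv in intervals}
truth = scripted_standing_series(states, 10.0)
keys = sorted(set(auto) & set(truth))
r = compare_series(np.array([auto[k] for k in keys]),
                   np.array([truth[k] for k in keys]))
print(f"standing R^2 {r.r2:.3f}   mixture means "
      f"{model.mu_stand:.2f} / {model.mu_other:.2f} m")
```

Output:

```
MOTA 0.916  MOTP 0.036 m
standing R^2 0.941   mixture means 1.35 / 1.87 m
```

`MOTA 0.916` means 91.6% of ground-truth animal-frames survive after
subtracting misses, false detections and identity switches; `MOTP 0.036 m`
is the mean localisation error of the matched detections on the ground
plane.  The mixture means sit at the two depth clusters an overhead camera
sees — standing backs near 1.35 m and lying bodies near 1.87 m below the
1.98 m camera — and the standing component is the one nearer the camera.

## Command-line interface

```bash
depthherd simulate --config run.yaml          # render a synthetic scene
depthherd track    --config run.yaml          # depth frames -> tracks.csv
depthherd behave   --config run.yaml          # tracks -> behaviour.csv
depthherd evaluate --config run.yaml          # tracks vs annotations
depthherd track    --config run.yaml --set tracker.fps=7
```

All parameters live in one YAML file; every default reproduces the study
configuration (voxel 0.02 m, k = 50, 0.25 SD, 0.06 m normals, window-5
median, 7 fps, 0.05 m / 1 s stay points, 10,000-sample mixture training,
3 × 6 entropy grid, 5-minute intervals).

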