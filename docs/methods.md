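# Methods

This note documents the models, algorithms and numerical choices behind
`depthherd`, and what the synthetic validation does and does not show.

## Scene model and coordinate frames

The pen is a 4.02 m × 2.36 m rectangle with 2.14 m walls and two depth
cameras mounted 1.98 m above the floor, pointing straight down
(`PenGeometry` defaults).  The **pen frame** has its origin at a floor
corner, x along the length, y along the width, z up.  Each **camera
frame** has X along image-u, Y along image-v and Z along the optical axis
toward the floor; a camera's XY origin sits at its ceiling offset, so
pen-frame coordinates are camera coordinates plus that offset.  Depth
values are distances along the optical axis (not ray lengths), which makes
the floor a constant-depth plane at the mount height.

Internal units are metres and seconds throughout.  The file dialect for
depth frames is 16-bit single-channel PNG in millimetres with 0 marking
invalid pixels, named `<camera_id>_<epoch_ms>.png`; annotations and tracks
are plain CSV with floats written via `repr` so round trips are bit-exact.

## Synthetic animals

Bodies are ellipsoids.  The top surface sits at the posture height:
standing 0.68 m, sitting 0.45 × that, lying 0.19 × that (= 0.13 m).  Under
a 1.98 m camera these defaults place the standing depth cluster near
1.30–1.35 m and the lying cluster near 1.85–1.89 m, the separation the
standing model exploits.  Body dimensions (0.62 × 0.26 m footprint) are
plausible for a ~9-week pig but are configuration defaults, not measured
values.

A standing body is rendered as a torso slab — a full ellipsoid of vertical
extent 0.30 m whose top is at the posture height — rather than a
ground-attached half-ellipsoid.  A 0.68 m half-ellipsoid over a 0.13 m
half-width is a ridge whose surface normals turn ~40° per 0.02 m step; no
normal-based segmentation could hold it together, and it is also not what
an overhead camera sees of a real pig (a broad back carried on thin legs
that are rarely visible from above).  Lying and sitting bodies compress
onto the floor.  Rendering solves the ray–ellipsoid quadratic per pixel
within each animal's projected bounding box, composites against a
precomputed floor-and-walls background, and adds zero-mean Gaussian noise
(default 0.01 m, within the sensor's stated sub-0.02 m accuracy class).
With zero noise the render is exact: back-projecting and taking the
minimum Z over an animal recovers mount height minus top height to 1e-6 m.

Behaviour is driven per animal by a continuous-time Markov chain over
{lying, sitting, standing, feeding, drinking, walking}, sampled at the 7 Hz
capture clock with the exact one-step kernel `expm(Q Δt)`, which preserves
the chain's stationary law — the closed-form oracle the occupancy tests
use.  Transitions into feeding/drinking are gated by position: an animal
sampled into feeding while away from its feeder slot walks toward it
(labelled walking) and engages on arrival, so the state invariants
(feeding ⇒ standing inside a feeder area) hold at every instant and
trajectories stay continuous with displacement ≤ walking speed × Δt.
Occupancy oracles therefore use scripts without feeding/drinking, where no
gating perturbs the chain.  Deterministic schedules (`ScheduleScript`) are
available for scripted-bout tests.  Movement uses fixed per-animal home
anchors with bounded wander and a minimum-separation blocking rule
(0.7 body lengths), so bodies may touch but never interpenetrate — an
unphysical overlap would merge two animals into one unsegmentable blob.
Animals engaged at a feeder face its wall, as side-by-side feeders do.

The bundled demo scene (19 animals, 60 s) uses a disturbance-style
schedule: the group starts mostly lying, rises into a staggered wave of
standing/walking/feeding, and settles again.  This gives the scripted
standing series genuine between-interval variance, which is what validating
an automated series against observations requires; on a stationary scene a
series-R² would only measure the tracker's miss bias.

### Camera intrinsics

Intrinsics are configuration: the native default is 512 × 424 at 365 px
focal (217,088 pixels); the demo scene uses 256 × 212 at 140 px focal.
The reduced pixel count changes almost nothing after 0.02 m voxel
downsampling (the pixel footprint on the floor is below the voxel size),
and the wider field of view lets the two cameras jointly cover the pen at
standing-animal height — with narrower optics part of the pen is invisible
to both cameras at 0.68 m and the tracking floor would measure geometric
coverage, not algorithm quality.

## Point-cloud pipeline

Stage order: pen-region filter → voxel downsample → outlier removal →
normals.  Conventions chosen for bit-reproducibility:

* **Pen filter**: an axis-aligned camera-frame box — the pen rectangle
  inset 0.03 m (removes walls/gates) and a depth cut 0.05 m above the
  floor (removes floor returns; 5σ of the default noise).  Points strictly
  inside are kept.
* **Voxels**: half-open cells `[i·s, (i+1)·s)` anchored at the origin;
  each occupied cell is replaced by the arithmetic centroid of its points.
* **Outliers**: single pass; per-point mean Euclidean distance to its
  k = 50 nearest neighbours (excluding itself); remove points above
  μ + 0.25 σ of these values.  One-sided by default — the target is stray
  far returns; a two-sided variant is available in configuration.
* **Normals**: eigenvector of the smallest eigenvalue of the 0.06 m-radius
  neighbourhood covariance; curvature = λ_min / (λ₀+λ₁+λ₂); orientation
  flipped to nz ≤ 0 (facing the ceiling sensor) so angle comparisons are
  consistent; points with < 3 neighbours are flagged undefined.  The
  computation is vectorised: neighbour pairs accumulate first and second
  moments, then a batched 3 × 3 eigendecomposition.

## Detection and tracking

Region growing is implemented as curvature-gated connected components on
the radius-neighbour graph (0.04 m): an edge joins two points whose
normals differ by less than the smoothness angle; components are computed
over low-curvature points only, and high-curvature points (crease points
between touching bodies) may attach to an adjacent region but never bridge
two regions — the vectorised equivalent of classical seed-promotion
region growing.  Defaults: smoothness 20°, curvature cap 0.10, cluster
size 60–6000 points.  At 0.02 m resolution a pig-torso cross-section
(curvature radius ≈ 0.11 m) turns ~10° per neighbour step, so thresholds
much below that disconnect smooth bodies, while the crease between
touching bodies jumps ≥ 45°; any threshold in roughly 15–50° separates
cleanly, and 20° leaves margin for depth noise.  All thresholds are
configuration-exposed.

Each detection carries the member-point mean (`centroid`) and a
minimum-area oriented box (convex hull + rotating calipers).  The **track
coordinate** is the box centre plus the mean depth: an obliquely viewed
body hides its far side, which biases the point mean ~0.05 m toward the
camera, while the silhouette extremes that define the box are unbiased.

Linking is globally optimal gated assignment per frame
(`scipy.optimize.linear_sum_assignment` with large-cost padding; gate
0.5 m ≈ 3.5 m/s at 7 fps).  Track life cycle: immediate birth for
unmatched detections, death after 3 consecutive unmatched frames, ids
never reused.  Per-camera tracks are translated by the ceiling offsets and
fused when two tracks from different cameras observe the same animal
simultaneously (mean distance below 0.3 m over common ticks): common ticks
are averaged, the rest concatenated.  Tracks are median-smoothed per
coordinate with window 5, ends handled by symmetric window shrinkage.
Input sequences are resampled to the 7 Hz processing clock by keeping the
frame nearest each tick.

## Behaviour measurement

**Standing.**  A two-component univariate Gaussian mixture over centroid
depth Z, fitted by EM (`sklearn.mixture.GaussianMixture`, k-means
initialisation, ≤ 100 iterations) on a seeded uniform subsample of 10,000
values per pen-day.  The component with the smaller mean takes the
standing role — standing animals are nearer a ceiling camera.
Classification is by posterior (standing iff posterior ≥ 0.5), not a fixed
depth threshold, so the model adapts to animal growth without
recalibration.  Validation is a two-sample Kolmogorov–Smirnov test of the
held-out data against an equal-size seeded sample from the fitted mixture
(pass iff p ≥ 0.01); on failure the model is refitted once with a fresh
subsample and otherwise flagged unvalidated.

**Feeding/drinking.**  Stay points: from anchor sample i, extend j while
point j stays within 0.05 m of point i (boundary ties inside); emit when
the spanned time reaches 1 s; resume after the segment, so stays never
overlap.  The scan runs only over track segments that are simultaneously
standing-classified and inside a feeder (resp. drinker) area, which is
what prevents pigs lying at the trough from scoring as feeding.  A stay's
duration is last-minus-first timestamp, so a dropped interior frame loses
nothing.

**Locomotion.**  Distance is the sum of consecutive ground-plane (XY)
steps — Z is excluded so posture transitions do not register as movement —
and speed uses a trailing 7-frame window with elapsed time taken from
timestamps.

**Spatial entropy.**  `H = −Σ p_i ln(p_i/q_i)` over a 3 (width) × 6
(length) grid with the uniform reference `q = 1/18`; `p` is read as the
*proportion* of positions per bin so that H is independent of group size;
H ∈ [−ln 18, 0], 0 at uniform occupancy.  Empty inputs are an error
(missing, not zero).

**Aggregation.**  All measures land in 5-minute intervals using the
total-time convention: durations sum over animals, so two pigs standing a
full interval contribute 600 s.  Each track sample's standing time covers
the gap to the next sample (the last covers one frame period), making
totals robust to frame drops.  Quality-control windows are merged, samples
inside them are discarded, coverage spans and stay durations are clipped
at window boundaries (so retained + excluded time is conserved), steps
across a window are dropped rather than bridged, and an interval fully
covered by QC is emitted as missing — never as zero.

## Evaluation

CLEAR-MOT protocol per frame: existing ground-truth↔hypothesis
correspondences persist while within the 0.3 m match threshold; the
remainder are matched by minimal-total-distance assignment; an identity
switch is counted whenever a ground-truth object's matched hypothesis id
differs from its last one.  MOTA = 1 − (FN+FP+IDSW)/GT (exact, may be
negative); MOTP is the mean matched centroid distance in metres on the
ground plane.  An oriented-box IoU distance (`motp_from_box_pairs`,
shapely-backed) is provided for box-level evaluation; metres is the
default.  Error rates are normalised by ΣGT so the MOTA decomposition is
exact.  The cross-validation protocol evaluates contiguous 30 s folds
with frame order intact and reports mean ± SEM.

Series comparison: R² = 1 − SS_res/SS_tot of observed against automated
(negative when the automated series fits worse than the observed mean),
RMSE in series units, an F-test of the one-regressor fit against the
intercept-only null (α = 0.001 recorded as metadata, not gated), and
trapezoidal AUC over time.  Pairs with missing entries are dropped.

## What the synthetic validation shows — and does not

Passing the synthetic suite shows the pipeline's stages are individually
correct against independent oracles and that the chain holds together
end-to-end under ellipsoid-body geometry, Gaussian depth noise and
Markovian behaviour.  On the bundled demo scene the pipeline reaches
MOTA ≈ 0.92, MOTP ≈ 0.04 m and standing-series R² ≈ 0.94 — engineering
floors of ≥ 0.85, ≤ 0.08 m and ≥ 0.9 are enforced in the tests.  The
generator does **not** reproduce: articulated bodies (legs, head dips into
troughs), occlusion by pen furniture or humans, reflective-surface and
flying-pixel sensor artefacts, piled or mounting animals, or social
dynamics.  Real-data performance therefore cannot be inferred from these
numbers; they demonstrate implementation correctness, not field accuracy.
Drinking shares the feeding stay-point parameters; with the tiny drinker
areas this measure is the least constrained by validation — consistent
with it being the weakest behaviour to automate from low-resolution
position data.

## Problem sizes and determinism

The default test/acceptance scene is 19 animals for 60 s at 7 fps on two
256 × 212 cameras (~420 ground-truth frames, ~5–8 × 10³ cloud points per
frame after downsampling); oracle-equivalence suites use ≥ 100 seeded
instances of ≤ a few hundred points each; mixture recovery uses 20
pen-days of 10,000 samples.  Every stochastic component takes an explicit
seed (`numpy.random.default_rng`), and identical seeds reproduce outputs
byte-for-byte, including the CSV artefacts.
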