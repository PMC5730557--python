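"""Behaviour measurement from pen-frame animal tracks.

Standing is classified from the overhead-camera depth (Z) of each tracked
centroid with a two-component univariate Gaussian mixture: standing animals
are nearer the ceiling camera (smaller Z) than lying/sitting animals, and
the component with the smaller mean takes the "standing" role.  Feeding and
drinking presence is registered with stay points — maximal trajectory
segments remaining within a small radius for a minimum time — gated by
standing posture and by the feeder/drinker floor areas.  Locomotion is
speed and Euclidean distance on the ground plane (XY only, so posture
transitions do not register as movement).  Spatial entropy summarises how
positions distribute over a 3 x 6 grid of the pen floor relative to a
uniform reference.  All measures aggregate into 5-minute intervals using
the total-time convention (summed over animals, so two pigs standing for a
full interval count 10 minutes), with quality-control windows excluded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .detect_track import Track
from .synthetic_scene import PenGeometry, point_in_rects

__all__ = [
    "BehaviourParams",
    "StandingModel",
    "StayPoint",
    "BehaviourInterval",
    "fit_standing_model",
    "validate_standing_model",
    "classify_standing",
    "detect_stay_points",
    "measure_area_visits",
    "measure_locomotion",
    "spatial_entropy",
    "count_standing",
    "aggregate_intervals",
    "measure_behaviour",
]


@dataclass
class BehaviourParams:
    stay_radius: float = 0.05  # m
    stay_min_duration: float = 1.0  # s
    speed_window: int = 7  # frames
    entropy_grid: tuple[int, int] = (3, 6)  # (rows, cols) over (width, length)
    interval: float = 300.0  # s
    train_sample: int = 10_000  # Z measurements per pen-day model
    em_max_iter: int = 100
    ks_alpha: float = 0.01

    def __post_init__(self) -> None:
        if min(
            self.stay_radius,
            self.stay_min_duration,
            self.interval,
            self.ks_alpha,
        ) <= 0 or min(self.speed_window, self.train_sample, self.em_max_iter) < 1:
            raise ValueError("behaviour parameters must be positive")


@dataclass
class StandingModel:
    """Two-component Gaussian mixture over centroid depth Z.

    Component 0 is always the standing role (smaller mean: standing animals
    are nearer the ceiling camera).
    """

    weights: tuple[float, float]
    means: tuple[float, float]  # (mu_stand, mu_other)
    variances: tuple[float, float]
    n_train: int
    seed: int
    pen: str | None = None
    day: str | None = None
    ks_statistic: float | None = None
    ks_p: float | None = None
    validated: bool | None = None

    def __post_init__(self) -> None:
        w1, w2 = self.weights
        if not (0 < w1 < 1 and 0 < w2 < 1 and abs(w1 + w2 - 1) < 1e-9):
            raise ValueError("weights must lie in (0,1) and sum to 1")
        if min(self.variances) <= 0:
            raise ValueError("variances must be positive")
        if not self.means[0] < self.means[1]:
            raise ValueError("standing mean must be smaller than the other mean")

    @property
    def mu_stand(self) -> float:
        return self.means[0]

    @property
    def mu_other(self) -> float:
        return self.means[1]

    def posterior_standing(self, z: np.ndarray | float) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        comp = np.stack(
            [
                w * stats.norm.pdf(z, m, math.sqrt(v))
                for w, m, v in zip(self.weights, self.means, self.variances)
            ]
        )
        total = comp.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(total > 0, comp[0] / total, 0.5)
        return post

    def sample(self, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        comp = rng.random(n) >= self.weights[0]
        mu = np.where(comp, self.means[1], self.means[0])
        sd = np.where(comp, math.sqrt(self.variances[1]), math.sqrt(self.variances[0]))
        return rng.normal(mu, sd)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "weights": list(self.weights),
            "means": list(self.means),
            "variances": list(self.variances),
            "roles": {"standing": 0, "other": 1},
            "n_train": self.n_train,
            "seed": self.seed,
            "pen": self.pen,
            "day": self.day,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "validated": self.validated,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "StandingModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=tuple(d["weights"]),
            means=tuple(d["means"]),
            variances=tuple(d["variances"]),
            n_train=d["n_train"],
            seed=d["seed"],
            pen=d.get("pen"),
            day=d.get("day"),
            ks_statistic=d.get("ks_statistic"),
            ks_p=d.get("ks_p"),
            validated=d.get("validated"),
        )


@dataclass
class StayPoint:
    track_id: int
    anchor: tuple[float, float]
    start: float
    end: float
    area_label: str | None = None  # e.g. "feeder:0", "drinker:2", None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BehaviourInterval:
    start: float  # interval start, aligned to the interval grid
    standing_s: float = 0.0
    feeding_s: float = 0.0
    drinking_s: float = 0.0
    distance_m: float = 0.0
    mean_speed_mps: float = 0.0
    spatial_entropy: float | None = None
    n_tracks: int = 0
    qc_excluded: bool = False


# ---------------------------------------------------------------------------
# Standing model
# ---------------------------------------------------------------------------

def fit_standing_model(
    z_values: np.ndarray,
    params: BehaviourParams | None = None,
    seed: int = 0,
    pen: str | None = None,
    day: str | None = None,
) -> StandingModel:
    """Fit the two-component depth mixture on a uniform random subsample.

    EM with k-means initialisation, at most ``em_max_iter`` iterations,
    trained on ``min(train_sample, n)`` values drawn without replacement
    with the given seed.  Deterministic given (data, seed).
    """
    params = params or BehaviourParams()
    z = np.asarray(z_values, dtype=float).ravel()
    min_n = max(4, int(2 * params.train_sample / 10))
    if len(z) < min_n:
        raise ValueError(
            f"too few Z measurements ({len(z)} < {min_n}) to fit a mixture"
        )
    if not np.all(np.isfinite(z)) or np.any(z <= 0):
        raise ValueError("Z measurements must be finite and positive")
    if np.ptp(z) == 0:
        raise ValueError("degenerate data: all Z measurements identical")
    rng = np.random.default_rng(seed)
    n_train = min(params.train_sample, len(z))
    sample = rng.choice(z, size=n_train, replace=False)
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        max_iter=params.em_max_iter,
        init_params="kmeans",
        n_init=1,
        random_state=int(seed) % (2**32),
    )
    gmm.fit(sample.reshape(-1, 1))
    means = gmm.means_.ravel()
    variances = gmm.covariances_.reshape(-1)
    weights = gmm.weights_.ravel()
    order = np.argsort(means)  # smaller mean -> standing role
    return StandingModel(
        weights=(float(weights[order[0]]), float(weights[order[1]])),
        means=(float(means[order[0]]), float(means[order[1]])),
        variances=(float(variances[order[0]]), float(variances[order[1]])),
        n_train=n_train,
        seed=seed,
        pen=pen,
        day=day,
    )


def validate_standing_model(
    model: StandingModel,
    holdout: np.ndarray,
    alpha: float = 0.01,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """Two-sample Kolmogorov-Smirnov test of the fit against held-out data.

    The holdout is compared with an equal-size seeded sample from the fitted
    mixture; the model passes when p >= alpha.  Updates the model's K-S
    record in place and returns (statistic, p, passed).
    """
    holdout = np.asarray(holdout, dtype=float).ravel()
    if len(holdout) == 0:
        raise ValueError("holdout is empty")
    synth = model.sample(len(holdout), seed=seed)
    ks = stats.ks_2samp(holdout, synth)
    passed = bool(ks.pvalue >= alpha)
    model.ks_statistic = float(ks.statistic)
    model.ks_p = float(ks.pvalue)
    model.validated = passed
    return float(ks.statistic), float(ks.pvalue), passed


def classify_standing(model: StandingModel, z: np.ndarray | float) -> np.ndarray:
    """Standing flag by posterior argmax (posterior of standing >= 0.5)."""
    return model.posterior_standing(z) >= 0.5


# ---------------------------------------------------------------------------
# Stay points
# ---------------------------------------------------------------------------

def detect_stay_points(
    track: Track,
    radius: float = 0.05,
    min_duration: float = 1.0,
) -> list[StayPoint]:
    """Anchor-based single-pass stay-point scan.

    From anchor index i, extend j while point j stays within ``radius`` of
    point i (boundary ties count as inside); emit a stay point when the
    spanned time reaches ``min_duration``, anchored at the member centroid.
    The scan resumes after the segment, so stay points never overlap.
    """
    xy = track.as_array()[:, :2] if len(track.times) else np.empty((0, 2))
    times = np.asarray(track.times)
    n = len(times)
    out: list[StayPoint] = []
    i = 0
    while i < n:
        j = i + 1
        while j < n and np.hypot(*(xy[j] - xy[i])) <= radius:
            j += 1
        # members i .. j-1
        if times[j - 1] - times[i] >= min_duration:
            anchor = xy[i : j].mean(axis=0)
            out.append(
                StayPoint(
                    track_id=track.track_id,
                    anchor=(float(anchor[0]), float(anchor[1])),
                    start=float(times[i]),
                    end=float(times[j - 1]),
                )
            )
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Area visits (feeding / drinking)
# ---------------------------------------------------------------------------

def measure_area_visits(
    tracks: list[Track],
    standing_flags: dict[int, np.ndarray],
    pen: PenGeometry,
    params: BehaviourParams | None = None,
    t_origin: float | None = None,
    qc_windows: list[tuple[float, float]] | None = None,
) -> dict[float, dict[str, float]]:
    """Per-interval feeding and drinking seconds from standing-gated stay points.

    Stay points are searched only over maximal track segments whose samples
    are simultaneously standing and inside a feeder (resp. drinker) area;
    each qualifying stay contributes its first-to-last duration (clipped
    against any QC windows), split over the 5-minute intervals it spans.
    """
    params = params or BehaviourParams()
    qc = _merge_windows(qc_windows or [])
    totals: dict[float, dict[str, float]] = {}
    for kind, areas in (("feeding", pen.feeder_areas), ("drinking", pen.drinker_areas)):
        if not areas:
            continue
        for tr in tracks:
            flags = standing_flags.get(tr.track_id)
            if flags is None:
                continue
            xy = tr.as_array()[:, :2]
            inside = point_in_rects(xy[:, 0], xy[:, 1], areas)
            ok = inside & np.asarray(flags, dtype=bool)
            for seg in _contiguous_runs(ok):
                sub = _subtrack(tr, seg)
                for sp in detect_stay_points(
                    sub, params.stay_radius, params.stay_min_duration
                ):
                    for s, e in _clip_span(sp.start, sp.end, qc):
                        for start, length in _split_over_intervals(
                            s, e, params.interval, t_origin
                        ):
                            totals.setdefault(
                                start, {"feeding": 0.0, "drinking": 0.0}
                            )
                            totals[start][kind] += length
    return totals


def _contiguous_runs(mask: np.ndarray) -> list[np.ndarray]:
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    return [seg for seg in np.split(idx, breaks + 1)]


def _subtrack(tr: Track, indices: np.ndarray) -> Track:
    sub = Track(track_id=tr.track_id)
    for k in indices:
        sub.append(tr.times[k], tr.centroids[k], tr.camera_ids[k])
    return sub


def _interval_start(t: float, interval: float, origin: float) -> float:
    return origin + math.floor((t - origin) / interval) * interval


def _split_over_intervals(
    start: float, end: float, interval: float, origin: float | None
) -> list[tuple[float, float]]:
    """Split a [start, end] span into (interval_start, covered_seconds) pieces."""
    org = origin if origin is not None else 0.0
    if end <= start:
        # zero-length spans still belong to one interval
        return [(_interval_start(start, interval, org), 0.0)]
    out = []
    t = start
    while t < end:
        istart = _interval_start(t, interval, org)
        t_next = min(end, istart + interval)
        out.append((istart, t_next - t))
        t = t_next
    return out


# ---------------------------------------------------------------------------
# Locomotion
# ---------------------------------------------------------------------------

def measure_locomotion(
    track: Track,
    window: int = 7,
    interval: float = 300.0,
    t_origin: float | None = None,
    qc_windows: list[tuple[float, float]] | None = None,
) -> dict[float, dict[str, float]]:
    """Per-interval ground-plane distance and time-weighted mean speed.

    Distance sums consecutive XY Euclidean steps (Z is ignored so posture
    transitions do not count as locomotion); speed at frame k is the
    cumulative distance over the trailing ``window`` frames divided by the
    elapsed time of that window.  Durations come from timestamps, so a
    dropped frame does not lose the distance travelled across it.  Steps
    whose time span touches a QC window are discarded, not bridged.
    """
    xy = track.as_array()[:, :2] if len(track.times) else np.empty((0, 2))
    times = np.asarray(track.times)
    org = t_origin if t_origin is not None else 0.0
    qc = _merge_windows(qc_windows or [])
    out: dict[float, dict[str, float]] = {}
    if len(times) < 2:
        return out
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dts = np.diff(times)
    for k in range(len(steps)):
        if any(a < times[k + 1] and times[k] < b for a, b in qc):
            continue
        mid = (times[k] + times[k + 1]) / 2.0
        istart = _interval_start(mid, interval, org)
        d = out.setdefault(istart, {"distance": 0.0, "elapsed": 0.0})
        d["distance"] += float(steps[k])
        d["elapsed"] += float(dts[k])
    for d in out.values():
        d["mean_speed"] = d["distance"] / d["elapsed"] if d["elapsed"] > 0 else 0.0
    return out


def window_speeds(track: Track, window: int = 7) -> np.ndarray:
    """Instantaneous speed per frame over the trailing ``window`` frames."""
    xy = track.as_array()[:, :2]
    times = np.asarray(track.times)
    n = len(times)
    speeds = np.zeros(n)
    if n < 2:
        return speeds
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    for k in range(1, n):
        k0 = max(0, k - (window - 1))
        dt = times[k] - times[k0]
        speeds[k] = (cum[k] - cum[k0]) / dt if dt > 0 else 0.0
    return speeds


# ---------------------------------------------------------------------------
# Spatial entropy
# ---------------------------------------------------------------------------

def spatial_entropy(
    positions: np.ndarray,
    pen: PenGeometry,
    grid: tuple[int, int] = (3, 6),
) -> float:
    """Relative entropy of animal positions over a grid of the pen floor.

    H = -sum_i p_i ln(p_i / q_i) with p the occupancy proportions over the
    rows x cols bins (3 across the pen width, 6 along its length) and
    q = 1/(rows*cols) the uniform reference.  H is 0 at the uniform
    distribution and -ln(rows*cols) at full concentration in one bin.
    Raises on empty input (the measure is undefined, not zero).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("spatial entropy undefined for empty positions")
    rows, cols = grid
    x = np.clip(positions[:, 0], 0, np.nextafter(pen.length, 0))
    y = np.clip(positions[:, 1], 0, np.nextafter(pen.width, 0))
    cx = (x / pen.length * cols).astype(int)
    ry = (y / pen.width * rows).astype(int)
    counts = np.bincount(ry * cols + cx, minlength=rows * cols).astype(float)
    p = counts / counts.sum()
    q = 1.0 / (rows * cols)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz] / q)))


# ---------------------------------------------------------------------------
# Standing totals + interval aggregation
# ---------------------------------------------------------------------------

def _clip_span(
    start: float, end: float, windows: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Subtract (merged, sorted) exclusion windows from a [start, end] span."""
    pieces = [(start, end)]
    for a, b in windows:
        nxt: list[tuple[float, float]] = []
        for s, e in pieces:
            if b <= s or a >= e:
                nxt.append((s, e))
                continue
            if s < a:
                nxt.append((s, a))
            if b < e:
                nxt.append((b, e))
        pieces = nxt
    return pieces


def count_standing(
    tracks: list[Track],
    standing_flags: dict[int, np.ndarray],
    interval: float = 300.0,
    t_origin: float | None = None,
    frame_period: float = 1.0 / 7.0,
    qc_windows: list[tuple[float, float]] | None = None,
) -> dict[float, float]:
    """Per-interval standing seconds summed over all tracked animals.

    Each standing-classified sample covers the gap to the next sample of its
    track (the final sample covers one nominal frame period), so totals are
    robust to dropped frames: the sample before a gap simply covers it.
    Samples inside a QC window contribute nothing, and coverage spans are
    clipped at window boundaries, so retained + excluded time is conserved.
    """
    org = t_origin if t_origin is not None else 0.0
    qc = _merge_windows(qc_windows or [])
    totals: dict[float, float] = {}
    for tr in tracks:
        flags = standing_flags.get(tr.track_id)
        if flags is None:
            continue
        times = np.asarray(tr.times)
        covers = np.empty(len(times))
        covers[:-1] = np.diff(times)
        covers[-1] = frame_period
        for t, cov, flag in zip(times, covers, flags):
            if not flag:
                continue
            if any(a <= t < b for a, b in qc):
                continue
            for s, e in _clip_span(t, t + cov, qc):
                for istart, length in _split_over_intervals(s, e, interval, org):
                    totals[istart] = totals.get(istart, 0.0) + length
    return totals


def aggregate_intervals(
    tracks: list[Track],
    standing_flags: dict[int, np.ndarray],
    pen: PenGeometry,
    params: BehaviourParams | None = None,
    qc_windows: list[tuple[float, float]] | None = None,
    t_origin: float | None = None,
    span: tuple[float, float] | None = None,
) -> list[BehaviourInterval]:
    """Aggregate all behaviour measures into interval records with QC.

    QC windows (epoch-second spans; overlaps are merged) exclude samples
    before aggregation; an interval fully covered by QC is emitted as
    missing (``qc_excluded`` with NaN measures), not as zero.
    """
    params = params or BehaviourParams()
    qc = _merge_windows(qc_windows or [])
    orig_flags = {
        k: np.asarray(v, dtype=bool) for k, v in standing_flags.items()
    }
    kept_tracks: list[Track] = []
    kept_flags: dict[int, np.ndarray] = {}
    for tr in tracks:
        sub, keep_idx = _exclude_qc(tr, qc)
        if len(sub.times) == 0:
            continue
        kept_tracks.append(sub)
        flags = orig_flags.get(tr.track_id)
        if flags is not None:
            kept_flags[tr.track_id] = flags[keep_idx]
    standing_flags = kept_flags

    raw_times = [t for tr in tracks for t in tr.times]
    if span is not None:
        t_min, t_max = span
    elif raw_times:
        t_min, t_max = min(raw_times), max(raw_times)
    else:
        return []
    org = t_origin if t_origin is not None else _interval_start(t_min, params.interval, 0.0)

    feeding = measure_area_visits(
        kept_tracks, standing_flags, pen, params, org, qc_windows=qc
    )
    standing = count_standing(
        tracks,
        {tr.track_id: orig_flags.get(tr.track_id) for tr in tracks},
        params.interval,
        org,
        1.0 / 7.0,
        qc_windows=qc,
    )
    loco: dict[float, dict[str, float]] = {}
    for tr in tracks:
        for istart, d in measure_locomotion(
            tr, params.speed_window, params.interval, org, qc_windows=qc
        ).items():
            agg = loco.setdefault(
                istart, {"distance": 0.0, "elapsed": 0.0}
            )
            agg["distance"] += d["distance"]
            agg["elapsed"] += d["elapsed"]

    out: list[BehaviourInterval] = []
    start = _interval_start(t_min, params.interval, org)
    while start <= t_max:
        end = start + params.interval
        fully_excluded = any(w0 <= start and end <= w1 for w0, w1 in qc)
        rec = BehaviourInterval(start=start, qc_excluded=fully_excluded)
        if fully_excluded:
            rec.standing_s = rec.feeding_s = rec.drinking_s = float("nan")
            rec.distance_m = rec.mean_speed_mps = float("nan")
            rec.spatial_entropy = None
        else:
            rec.standing_s = standing.get(start, 0.0)
            fd = feeding.get(start, {"feeding": 0.0, "drinking": 0.0})
            rec.feeding_s = fd["feeding"]
            rec.drinking_s = fd["drinking"]
            lc = loco.get(start)
            if lc:
                rec.distance_m = lc["distance"]
                rec.mean_speed_mps = (
                    lc["distance"] / lc["elapsed"] if lc["elapsed"] > 0 else 0.0
                )
            pos = [
                c[:2]
                for tr in kept_tracks
                for t, c in zip(tr.times, tr.centroids)
                if start <= t < end
            ]
            rec.n_tracks = sum(
                1 for tr in kept_tracks if any(start <= t < end for t in tr.times)
            )
            if pos:
                rec.spatial_entropy = spatial_entropy(np.asarray(pos), pen)
        out.append(rec)
        start = end
    return out


def _merge_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not windows:
        return []
    ws = sorted((min(a, b), max(a, b)) for a, b in windows)
    out = [list(ws[0])]
    for a, b in ws[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def _exclude_qc(
    tr: Track, qc: list[tuple[float, float]]
) -> tuple[Track, np.ndarray]:
    """Drop samples inside any QC window; returns the subtrack and the kept
    indices (for subsetting parallel per-sample arrays)."""
    if not qc:
        return tr, np.arange(len(tr.times))
    keep = np.asarray(
        [
            k
            for k, t in enumerate(tr.times)
            if not any(a <= t < b for a, b in qc)
        ],
        dtype=int,
    )
    return _subtrack(tr, keep), keep


def measure_behaviour(
    tracks: list[Track],
    pen: PenGeometry,
    params: BehaviourParams | None = None,
    model: StandingModel | None = None,
    qc_windows: list[tuple[float, float]] | None = None,
    seed: int = 0,
    t_origin: float | None = None,
) -> tuple[list[BehaviourInterval], StandingModel]:
    """Fit (or reuse) the standing model and aggregate behaviour intervals."""
    params = params or BehaviourParams()
    z = np.concatenate([tr.as_array()[:, 2] for tr in tracks]) if tracks else np.empty(0)
    if model is None:
        model = fit_standing_model(z, params, seed=seed)
    flags = {
        tr.track_id: classify_standing(model, tr.as_array()[:, 2]) for tr in tracks
    }
    intervals = aggregate_intervals(
        tracks, flags, pen, params, qc_windows, t_origin=t_origin
    )
    return intervals, model
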