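"""Tracking and behaviour validation metrics.

Tracking follows the CLEAR-MOT protocol: per frame, previously established
ground-truth/hypothesis correspondences persist while still within the
match threshold, remaining candidates are matched by minimum-total-distance
assignment, and the error events are accumulated into

    MOTA = 1 - (sum_t FN_t + FP_t + IDSW_t) / (sum_t GT_t)
    MOTP = (sum_{i,t} d_t^i) / (sum_t c_t)

with FN the missed ground-truth objects, FP the spurious hypotheses, IDSW
the identity switches, c_t the matched pairs at frame t and d their
ground-plane centroid distances (metres).  An oriented-box IoU distance is
available as an alternative MOTP metric.  Behaviour series are compared
with R^2, RMSE, an F-test against the intercept-only null, and trapezoidal
area under the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detect_track import Track, assign_detections
from .synthetic_scene import GroundTruthFrame

__all__ = [
    "MotResult",
    "ComparisonResult",
    "match_frame",
    "MotAccumulator",
    "compute_mota",
    "compute_motp",
    "evaluate_tracking",
    "track_duration_stats",
    "crossval_protocol",
    "compare_series",
    "tracks_to_hypotheses",
]


@dataclass
class MotResult:
    mota: float
    motp: float
    fn_rate: float
    fp_rate: float
    idsw_rate: float
    mean_track_duration: float | None
    fn: int
    fp: int
    idsw: int
    gt: int
    matches: int
    distance_sum: float

    def __post_init__(self) -> None:
        if self.mota > 1 + 1e-12:
            raise ValueError("MOTA cannot exceed 1")
        decomposed = 1.0 - (self.fn_rate + self.fp_rate + self.idsw_rate)
        if not math.isclose(self.mota, decomposed, rel_tol=0, abs_tol=1e-9):
            raise ValueError("MOTA must equal 1 - (fn+fp+idsw rates)")


@dataclass
class ComparisonResult:
    r2: float
    rmse: float
    f_stat: float
    f_p: float
    auc_automated: float
    auc_observed: float
    n: int
    alpha: float = 0.001  # recorded, not gated


# ---------------------------------------------------------------------------
# Oriented-box IoU (alternative MOTP distance)
# ---------------------------------------------------------------------------

def oriented_box_iou(
    a: tuple[float, float, float, float, float],
    b: tuple[float, float, float, float, float],
) -> float:
    """Intersection-over-union of two oriented boxes (cx, cy, len, wid, yaw)."""
    from shapely.geometry import Polygon

    def poly(box) -> Polygon:
        cx, cy, ln, wd, yaw = box
        c, s = math.cos(yaw), math.sin(yaw)
        corners = []
        for sx, sy in ((-1, -1), (1, -1), (1, 1), (-1, 1)):
            dx, dy = sx * ln / 2, sy * wd / 2
            corners.append((cx + c * dx - s * dy, cy + s * dx + c * dy))
        return Polygon(corners)

    pa, pb = poly(a), poly(b)
    union = pa.union(pb).area
    if union == 0:
        return 0.0
    return pa.intersection(pb).area / union


def iou_distance(a, b) -> float:
    """1 - IoU, usable as the MOTP distance when hypotheses carry boxes."""
    return 1.0 - oriented_box_iou(a, b)


def motp_from_box_pairs(
    pairs: list[tuple[tuple, tuple]],
) -> float:
    """Alternative MOTP on matched (gt_box, hyp_box) pairs: mean (1 - IoU).

    Use the id pairs returned by :func:`match_frame` to look up the boxes;
    the default metres-valued MOTP remains the centroid distance.
    """
    if not pairs:
        raise ValueError("MOTP undefined with no matches")
    return float(np.mean([iou_distance(a, b) for a, b in pairs]))


# ---------------------------------------------------------------------------
# CLEAR-MOT frame matching
# ---------------------------------------------------------------------------

def match_frame(
    gt_boxes: list,
    hyp_detections: list,
    prior: dict[int, int],
    threshold: float,
    last_match: dict[int, int] | None = None,
) -> tuple[list[tuple[int, int, float]], int, int, int, dict[int, int]]:
    """Match one frame's ground truth against tracker hypotheses.

    ``gt_boxes`` is a list of (gt_id, x, y); ``hyp_detections`` a list of
    (hyp_id, x, y).  ``prior`` maps gt_id -> hyp_id correspondences from the
    previous frame; ``last_match`` maps gt_id -> the hypothesis id it was
    last ever matched to (for identity-switch counting over gaps).

    Returns (matches [(gt_id, hyp_id, distance)], FN, FP, IDSW, new prior).
    """
    gt_pos = {g[0]: np.asarray(g[1:3], dtype=float) for g in gt_boxes}
    hyp_pos = {h[0]: np.asarray(h[1:3], dtype=float) for h in hyp_detections}
    last = last_match if last_match is not None else dict(prior)

    matches: list[tuple[int, int, float]] = []
    new_prior: dict[int, int] = {}

    # 1. persist correspondences still within the threshold
    for gid, hid in prior.items():
        if gid in gt_pos and hid in hyp_pos:
            d = float(np.hypot(*(gt_pos[gid] - hyp_pos[hid])))
            if d <= threshold:
                matches.append((gid, hid, d))
                new_prior[gid] = hid

    # 2. optimal assignment over the remainder
    free_gt = [g for g in gt_pos if g not in new_prior]
    used_hyp = set(new_prior.values())
    free_hyp = [h for h in hyp_pos if h not in used_hyp]
    if free_gt and free_hyp:
        a = np.asarray([gt_pos[g] for g in free_gt])
        b = np.asarray([hyp_pos[h] for h in free_hyp])
        assignment = assign_detections(a, b, threshold)
        for r, c in assignment.pairs:
            gid, hid = free_gt[r], free_hyp[c]
            d = float(np.hypot(*(gt_pos[gid] - hyp_pos[hid])))
            matches.append((gid, hid, d))
            new_prior[gid] = hid

    idsw = 0
    for gid, hid in new_prior.items():
        if gid in last and last[gid] != hid:
            idsw += 1
        last[gid] = hid

    fn = len(gt_pos) - len(new_prior)
    fp = len(hyp_pos) - len(new_prior)
    return matches, fn, fp, idsw, new_prior


class MotAccumulator:
    """Streams frames through :func:`match_frame` and totals the errors."""

    def __init__(self, threshold: float = 0.3):
        self.threshold = threshold
        self.prior: dict[int, int] = {}
        self.last_match: dict[int, int] = {}
        self.fn = self.fp = self.idsw = self.gt = self.matches = 0
        self.distance_sum = 0.0

    def update(self, gt_boxes: list, hyp_detections: list) -> None:
        matches, fn, fp, idsw, self.prior = match_frame(
            gt_boxes, hyp_detections, self.prior, self.threshold, self.last_match
        )
        self.fn += fn
        self.fp += fp
        self.idsw += idsw
        self.gt += len(gt_boxes)
        self.matches += len(matches)
        self.distance_sum += sum(d for _, _, d in matches)

    def result(self, tracks: list[Track] | None = None) -> MotResult:
        if self.gt == 0:
            raise ValueError("MOTA undefined: no ground-truth objects")
        if self.matches == 0:
            raise ValueError("MOTP undefined: no matches")
        mean_dur = track_duration_stats(tracks)[0] if tracks else None
        return MotResult(
            mota=compute_mota(self.fn, self.fp, self.idsw, self.gt),
            motp=compute_motp(self.distance_sum, self.matches),
            fn_rate=self.fn / self.gt,
            fp_rate=self.fp / self.gt,
            idsw_rate=self.idsw / self.gt,
            mean_track_duration=mean_dur,
            fn=self.fn,
            fp=self.fp,
            idsw=self.idsw,
            gt=self.gt,
            matches=self.matches,
            distance_sum=self.distance_sum,
        )


def compute_mota(fn: int | float, fp: int | float, idsw: int | float, gt: int | float) -> float:
    """MOTA = 1 - (FN + FP + IDSW) / GT; may be negative."""
    if gt <= 0:
        raise ValueError("MOTA undefined for sum of ground truth <= 0")
    return 1.0 - (fn + fp + idsw) / gt


def compute_motp(distance_sum: float, match_count: int) -> float:
    """MOTP = mean matched centroid distance (metres, ground plane)."""
    if match_count <= 0:
        raise ValueError("MOTP undefined with no matches")
    return distance_sum / match_count


def tracks_to_hypotheses(
    tracks: list[Track], times: list[float], atol: float = 1e-6
) -> list[list[tuple[int, float, float]]]:
    """Sample tracks at the ground-truth timestamps -> per-frame hypotheses."""
    out: list[list[tuple[int, float, float]]] = []
    track_times = [np.asarray(tr.times) for tr in tracks]
    for t in times:
        hyps = []
        for tr, tt in zip(tracks, track_times):
            if len(tt) == 0:
                continue
            k = int(np.argmin(np.abs(tt - t)))
            if abs(tt[k] - t) <= atol:
                c = tr.centroids[k]
                hyps.append((tr.track_id, float(c[0]), float(c[1])))
        out.append(hyps)
    return out


def evaluate_tracking(
    gt_frames: list[GroundTruthFrame],
    tracks: list[Track],
    threshold: float = 0.3,
) -> MotResult:
    """CLEAR-MOT evaluation of pen-frame tracks against ground-truth frames."""
    acc = MotAccumulator(threshold)
    times = [f.t for f in gt_frames]
    hyp_frames = tracks_to_hypotheses(tracks, times)
    for frame, hyps in zip(gt_frames, hyp_frames):
        gt_boxes = [(b.animal_id, b.cx, b.cy) for b in frame.boxes]
        acc.update(gt_boxes, hyps)
    return acc.result(tracks)


def track_duration_stats(tracks: list[Track]) -> tuple[float, float]:
    """Mean track duration (last t - first t) in seconds, with SEM."""
    if not tracks:
        raise ValueError("no tracks")
    durations = np.asarray([tr.duration for tr in tracks])
    sem = (
        float(durations.std(ddof=1) / math.sqrt(len(durations)))
        if len(durations) > 1
        else 0.0
    )
    return float(durations.mean()), sem


# ---------------------------------------------------------------------------
# Cross-validation protocol
# ---------------------------------------------------------------------------

def crossval_protocol(
    gt_frames: list[GroundTruthFrame],
    tracks: list[Track],
    k_folds: int = 10,
    fold_length_s: float = 30.0,
    threshold: float = 0.3,
) -> tuple[list[MotResult], dict[str, tuple[float, float]]]:
    """Contiguous-fold evaluation: k folds of ``fold_length_s`` seconds.

    Frame ordering stays intact within each fold; each fold is evaluated
    independently and the summary reports mean +/- SEM of MOTA and MOTP over
    folds.  (Parameter tuning on the held-in folds is the caller's concern;
    this routine performs the rotated evaluation.)
    """
    if not gt_frames:
        raise ValueError("no ground-truth frames")
    t0 = gt_frames[0].t
    t1 = gt_frames[-1].t
    if t1 - t0 + 1e-9 < k_folds * fold_length_s - fold_length_s:
        raise ValueError(
            f"sequence of {t1 - t0:.1f} s too short for "
            f"{k_folds} folds of {fold_length_s} s"
        )
    results: list[MotResult] = []
    for k in range(k_folds):
        lo = t0 + k * fold_length_s
        hi = lo + fold_length_s
        fold = [f for f in gt_frames if lo <= f.t < hi]
        if not fold:
            raise ValueError(f"fold {k} contains no frames")
        results.append(evaluate_tracking(fold, tracks, threshold))
    motas = np.asarray([r.mota for r in results])
    motps = np.asarray([r.motp for r in results])

    def _mean_sem(x: np.ndarray) -> tuple[float, float]:
        sem = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
        return float(x.mean()), sem

    return results, {"mota": _mean_sem(motas), "motp": _mean_sem(motps)}


# ---------------------------------------------------------------------------
# Behaviour series comparison
# ---------------------------------------------------------------------------

def compare_series(
    automated: np.ndarray,
    observed: np.ndarray,
    times: np.ndarray | None = None,
    alpha: float = 0.001,
) -> ComparisonResult:
    """Validate an automated behaviour series against observations.

    R^2 = 1 - SS_res/SS_tot of observed vs automated (may be negative),
    RMSE in series units, an F-test of the one-regressor fit against the
    intercept-only null, and trapezoidal AUC over time for both series.
    Pairs with a missing (NaN) entry are dropped.
    """
    a = np.asarray(automated, dtype=float)
    o = np.asarray(observed, dtype=float)
    if a.shape != o.shape:
        raise ValueError("series must have equal length")
    t = (
        np.asarray(times, dtype=float)
        if times is not None
        else np.arange(len(a), dtype=float)
    )
    keep = np.isfinite(a) & np.isfinite(o)
    a, o, t = a[keep], o[keep], t[keep]
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 paired intervals")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed series has zero variance; R^2 undefined")
    ss_res = float(np.sum((o - a) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / n)

    # F-test: observed ~ automated vs intercept-only
    if np.ptp(a) == 0:
        # a constant regressor explains nothing beyond the intercept
        f_stat, f_p = 0.0, 1.0
    else:
        slope, intercept = np.polyfit(a, o, 1)
        fitted = slope * a + intercept
        ss_reg_res = float(np.sum((o - fitted) ** 2))
        df1, df2 = 1, n - 2
        if ss_reg_res == 0:
            f_stat, f_p = float("inf"), 0.0
        else:
            f_stat = (ss_tot - ss_reg_res) / df1 / (ss_reg_res / df2)
            f_p = float(stats.f.sf(f_stat, df1, df2))
    return ComparisonResult(
        r2=r2,
        rmse=rmse,
        f_stat=float(f_stat),
        f_p=f_p,
        auc_automated=float(np.trapezoid(a, t)),
        auc_observed=float(np.trapezoid(o, t)),
        n=n,
        alpha=alpha,
    )
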