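"""Per-frame animal detection and frame-to-frame identity tracking.

Detection segments the normal-annotated cloud by region growing: regions
expand from low-curvature seeds through neighbours whose surface normals
are nearly parallel, so the smooth back of one animal forms one region
while the normal discontinuity in the crease between touching animals
separates them.  Detections are linked across frames by minimum-total-
distance assignment (Hungarian algorithm) with a distance gate, tracks from
the two pen cameras are merged into the shared pen frame by the camera
ceiling offsets, and track coordinates are median-smoothed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, cKDTree

from .cloud_pipeline import FilterParams, NormalCloud, preprocess
from .depth_geometry import CameraIntrinsics, DepthFrame, PointCloud, back_project
from .synthetic_scene import PenGeometry

log = logging.getLogger("depthherd.tracking")

__all__ = [
    "Detection",
    "Track",
    "TrackerParams",
    "segment_regions",
    "assign_detections",
    "update_tracks",
    "TrackManager",
    "merge_cameras",
    "smooth_track",
    "resample_to_fps",
    "minimum_area_box",
    "track_sequence",
]


@dataclass
class TrackerParams:
    smoothness_angle: float = 20.0  # degrees between neighbour normals
    curvature_max: float = 0.10  # seeds/expansion restricted below this
    min_cluster_size: int = 60  # points
    max_cluster_size: int = 6000
    gate_distance: float = 0.5  # m between frames at 7 fps
    max_coast: int = 3  # frames a track survives unmatched
    median_window: int = 5  # frames
    fps: float = 7.0
    fuse_distance: float = 0.3  # m, cross-camera duplicate gate

    def __post_init__(self) -> None:
        if self.median_window % 2 == 0:
            raise ValueError("median_window must be odd")
        if min(
            self.smoothness_angle,
            self.curvature_max,
            self.gate_distance,
            self.fps,
        ) <= 0 or self.min_cluster_size < 1:
            raise ValueError("tracker parameters must be positive")


@dataclass
class Detection:
    """One segmented animal in one frame (camera or pen coordinates)."""

    t: float
    camera_id: str | None
    centroid: np.ndarray  # (3,) XYZ
    box_center: tuple[float, float]
    box_extents: tuple[float, float]  # (len, wid), len >= wid
    box_yaw: float
    point_count: int
    member_indices: np.ndarray | None = None


@dataclass
class Track:
    """Identity-linked centroid sequence."""

    track_id: int
    times: list[float] = field(default_factory=list)
    centroids: list[np.ndarray] = field(default_factory=list)
    camera_ids: list[str | None] = field(default_factory=list)
    misses: int = 0  # consecutive unmatched frames (live tracks only)

    @property
    def birth(self) -> float:
        return self.times[0]

    @property
    def death(self) -> float:
        return self.times[-1]

    @property
    def duration(self) -> float:
        return self.times[-1] - self.times[0]

    def append(self, t: float, centroid: np.ndarray, camera_id: str | None) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("track timestamps must be strictly increasing")
        self.times.append(t)
        self.centroids.append(np.asarray(centroid, dtype=float))
        self.camera_ids.append(camera_id)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.centroids)


# ---------------------------------------------------------------------------
# Oriented bounding box (minimum-area rectangle via rotating calipers)
# ---------------------------------------------------------------------------

def minimum_area_box(
    xy: np.ndarray,
) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Minimum-area oriented rectangle of 2D points.

    Returns (center, (length, width), yaw) with length >= width and yaw in
    [0, pi) measured from the +x axis to the long edge.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) == 1:
        return (float(xy[0, 0]), float(xy[0, 1])), (0.0, 0.0), 0.0
    if len(xy) == 2 or np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
        # collinear: box degenerates to a segment
        d = xy.max(axis=0) - xy.min(axis=0)
        c = (xy.max(axis=0) + xy.min(axis=0)) / 2
        span = float(np.hypot(*(xy[np.argmax(np.linalg.norm(xy - xy[0], axis=1))] - xy[0])))
        yaw = math.atan2(d[1], d[0]) % math.pi if span > 0 else 0.0
        return (float(c[0]), float(c[1])), (span, 0.0), yaw
    hull = xy[ConvexHull(xy).vertices]
    edges = np.roll(hull, -1, axis=0) - hull
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), math.pi / 2))
    best = None
    for ang in angles:
        c, s = math.cos(ang), math.sin(ang)
        rot = hull @ np.array([[c, -s], [s, c]])
        lo, hi = rot.min(axis=0), rot.max(axis=0)
        area = float(np.prod(hi - lo))
        if best is None or area < best[0]:
            best = (area, ang, lo, hi)
    _, ang, lo, hi = best
    ext = hi - lo
    center_rot = (lo + hi) / 2
    c, s = math.cos(ang), math.sin(ang)
    center = center_rot @ np.array([[c, s], [-s, c]])
    length, width = float(ext[0]), float(ext[1])
    yaw = ang % math.pi
    if width > length:
        length, width = width, length
        yaw = (yaw + math.pi / 2) % math.pi
    return (float(center[0]), float(center[1])), (length, width), yaw


# ---------------------------------------------------------------------------
# Region growing
# ---------------------------------------------------------------------------

def segment_regions(
    cloud: PointCloud,
    normals: NormalCloud,
    params: TrackerParams,
    neighbour_radius: float | None = None,
) -> list[Detection]:
    """Segment a normal-annotated cloud into per-animal detections.

    Regions grow through pairs of neighbouring points whose normals differ
    by less than ``smoothness_angle``; only low-curvature points propagate
    growth (high-curvature points — crease points between touching animals —
    may join a region but never bridge two regions).  Regions outside the
    [min, max] cluster-size band are discarded.
    """
    n = len(cloud)
    if n == 0:
        return []
    radius = neighbour_radius if neighbour_radius is not None else 0.04
    p = cloud.points
    defined = normals.defined
    low_curv = defined & (normals.curvature < params.curvature_max)

    tree = cKDTree(p)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    cos_thresh = math.cos(math.radians(params.smoothness_angle))
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        ok = defined[i] & defined[j]
        dots = np.abs(np.einsum("ij,ij->i", normals.normals[i], normals.normals[j]))
        smooth = ok & (dots >= cos_thresh)
        i, j = i[smooth], j[smooth]
    else:
        i = j = np.empty(0, dtype=int)

    # components over low-curvature points only (growth propagation)
    if i.size:
        core = low_curv[i] & low_curv[j]
        ic, jc = i[core], j[core]
    else:
        ic, jc = i, j
    adj = csr_matrix(
        (np.ones(len(ic) * 2), (np.r_[ic, jc], np.r_[jc, ic])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    labels = labels.copy()
    labels[~low_curv] = -1

    # attach high-curvature (but defined) points to an adjacent region
    if i.size:
        boundary = low_curv[i] ^ low_curv[j]
        bi, bj = i[boundary], j[boundary]
        hi_pt = np.where(low_curv[bi], bj, bi)
        lo_pt = np.where(low_curv[bi], bi, bj)
        for h, l in zip(hi_pt, lo_pt):
            if labels[h] < 0:
                labels[h] = labels[l]

    detections: list[Detection] = []
    for lab in np.unique(labels[labels >= 0]):
        members = np.nonzero(labels == lab)[0]
        if not (params.min_cluster_size <= len(members) <= params.max_cluster_size):
            continue
        pts = p[members]
        centroid = pts.mean(axis=0)
        center, extents, yaw = minimum_area_box(pts[:, :2])
        detections.append(
            Detection(
                t=cloud.t if cloud.t is not None else 0.0,
                camera_id=cloud.camera_id,
                centroid=centroid,
                box_center=center,
                box_extents=extents,
                box_yaw=yaw,
                point_count=len(members),
                member_indices=members,
            )
        )
    return detections


# ---------------------------------------------------------------------------
# Frame-to-frame assignment
# ---------------------------------------------------------------------------

@dataclass
class Assignment:
    pairs: list[tuple[int, int]]  # (prev index, curr index)
    unmatched_prev: list[int]
    unmatched_curr: list[int]
    total_cost: float


def assign_detections(
    prev: list[Detection] | np.ndarray,
    curr: list[Detection] | np.ndarray,
    gate: float,
) -> Assignment:
    """Globally optimal gated matching of detections between two frames.

    Cost is the 2D ground-plane (XY) centroid distance; pairs further apart
    than ``gate`` are never matched.  Accepts detection lists or raw (N, 2+)
    centroid arrays.
    """
    a = _centroids_xy(prev)
    b = _centroids_xy(curr)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return Assignment([], list(range(na)), list(range(nb)), 0.0)
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    # large-cost padding keeps gated pairs out of the optimum
    big = gate * (na + nb + 1) + cost.max() + 1.0
    padded = np.where(cost <= gate, cost, big)
    rows, cols = linear_sum_assignment(padded)
    pairs, up, uc = [], set(range(na)), set(range(nb))
    total = 0.0
    for r, c in zip(rows, cols):
        if cost[r, c] <= gate:
            pairs.append((int(r), int(c)))
            up.discard(int(r))
            uc.discard(int(c))
            total += float(cost[r, c])
    return Assignment(pairs, sorted(up), sorted(uc), total)


def _track_point(det: Detection) -> np.ndarray:
    """Track coordinate of a detection: oriented-box centre + mean depth.

    The box centre comes from the silhouette extremes, so unlike the point
    mean it is not biased toward the camera side of an obliquely viewed
    body.
    """
    return np.array([det.box_center[0], det.box_center[1], det.centroid[2]])


def _centroids_xy(dets) -> np.ndarray:
    if isinstance(dets, np.ndarray):
        return dets[:, :2].astype(float) if len(dets) else dets.reshape(0, 2)
    return (
        np.asarray([_track_point(d)[:2] for d in dets])
        if dets
        else np.empty((0, 2))
    )


# ---------------------------------------------------------------------------
# Track life cycle
# ---------------------------------------------------------------------------

class TrackManager:
    """Maintains live tracks; ids are never reused.

    Birth is immediate (every unmatched detection opens a track); a track
    unmatched for more than ``max_coast`` consecutive frames is closed.
    """

    def __init__(self, params: TrackerParams):
        self.params = params
        self.live: list[Track] = []
        self.closed: list[Track] = []
        self._next_id = 0

    def step(self, detections: list[Detection], t: float) -> None:
        prev = np.asarray(
            [tr.centroids[-1][:2] for tr in self.live]
        ) if self.live else np.empty((0, 2))
        curr = _centroids_xy(detections)
        assignment = assign_detections(prev, curr, self.params.gate_distance)
        for r, c in assignment.pairs:
            self.live[r].append(t, _track_point(detections[c]), detections[c].camera_id)
            self.live[r].misses = 0
        for r in assignment.unmatched_prev:
            self.live[r].misses += 1
        for c in assignment.unmatched_curr:
            tr = Track(track_id=self._next_id)
            self._next_id += 1
            tr.append(t, _track_point(detections[c]), detections[c].camera_id)
            self.live.append(tr)
        still_live = []
        for tr in self.live:
            if tr.misses > self.params.max_coast:
                self.closed.append(tr)
            else:
                still_live.append(tr)
        self.live = still_live

    def finish(self) -> list[Track]:
        tracks = self.closed + self.live
        self.closed, self.live = [], []
        return sorted(tracks, key=lambda tr: tr.track_id)


def update_tracks(
    manager: TrackManager, detections: list[Detection], t: float
) -> TrackManager:
    """Functional wrapper over :meth:`TrackManager.step`."""
    manager.step(detections, t)
    return manager


# ---------------------------------------------------------------------------
# Camera merging, smoothing, resampling
# ---------------------------------------------------------------------------

def merge_cameras(
    tracks_by_camera: dict[str, list[Track]],
    pen: PenGeometry,
    fuse_distance: float = 0.3,
) -> list[Track]:
    """Combine per-camera tracks into the shared pen frame.

    Each camera's XY is translated by its ceiling offset; pairs of tracks
    from different cameras observing the same animal (simultaneous samples
    within ``fuse_distance``) are fused by averaging the matched centroids
    and concatenating the rest.  Z passes through unchanged.
    """
    shifted: list[Track] = []
    next_id = 0
    for cam_id, tracks in tracks_by_camera.items():
        ox, oy = pen.camera_offset(cam_id)  # raises on unknown camera
        for tr in tracks:
            nt = Track(track_id=next_id)
            next_id += 1
            for t, c, cid in zip(tr.times, tr.centroids, tr.camera_ids):
                nt.append(t, np.array([c[0] + ox, c[1] + oy, c[2]]), cam_id)
            shifted.append(nt)

    merged = True
    while merged:
        merged = False
        for ia in range(len(shifted)):
            for ib in range(ia + 1, len(shifted)):
                a, b = shifted[ia], shifted[ib]
                if set(a.camera_ids) & set(b.camera_ids):
                    continue  # same-camera tracks are distinct animals
                fused = _try_fuse(a, b, fuse_distance)
                if fused is not None:
                    fused.track_id = a.track_id
                    shifted[ia] = fused
                    del shifted[ib]
                    merged = True
                    break
            if merged:
                break
    return shifted


def _try_fuse(a: Track, b: Track, gate: float) -> Track | None:
    ta = {round(t, 6): k for k, t in enumerate(a.times)}
    tb = {round(t, 6): k for k, t in enumerate(b.times)}
    common = sorted(set(ta) & set(tb))
    if not common:
        return None
    d = [
        float(np.hypot(*(a.centroids[ta[t]][:2] - b.centroids[tb[t]][:2])))
        for t in common
    ]
    if np.mean(d) >= gate:
        return None
    out = Track(track_id=a.track_id)
    all_times = sorted(set(ta) | set(tb))
    for t in all_times:
        if t in ta and t in tb:
            c = (a.centroids[ta[t]] + b.centroids[tb[t]]) / 2.0
            cam = a.camera_ids[ta[t]]
        elif t in ta:
            c, cam = a.centroids[ta[t]], a.camera_ids[ta[t]]
        else:
            c, cam = b.centroids[tb[t]], b.camera_ids[tb[t]]
        out.append(t, c, cam)
    return out


def smooth_track(track: Track, window: int = 5) -> Track:
    """Per-coordinate running median; ends use a symmetrically shrunk window."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    arr = track.as_array()
    n = len(arr)
    half = window // 2
    out = Track(track_id=track.track_id)
    for k in range(n):
        h = min(half, k, n - 1 - k)
        med = np.median(arr[k - h : k + h + 1], axis=0)
        out.append(track.times[k], med, track.camera_ids[k])
    return out


def resample_to_fps(frames: list, fps: float) -> list:
    """Keep the frame nearest each 1/fps tick (one frame per tick).

    ``frames`` is any list of objects with a ``t`` attribute, time-ordered.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if not frames:
        return []
    times = np.asarray([f.t for f in frames])
    t0, t1 = times[0], times[-1]
    ticks = t0 + np.arange(0, math.floor((t1 - t0) * fps) + 1) / fps
    keep_idx = sorted(set(int(np.argmin(np.abs(times - tick))) for tick in ticks))
    return [frames[k] for k in keep_idx]


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------

def track_sequence(
    frames_by_camera: dict[str, list[DepthFrame]],
    intrinsics: CameraIntrinsics,
    pen: PenGeometry,
    filter_params: FilterParams | None = None,
    tracker_params: TrackerParams | None = None,
) -> list[Track]:
    """Depth frames -> clouds -> detections -> merged, smoothed pen tracks."""
    tparams = tracker_params or TrackerParams()
    tracks_by_camera: dict[str, list[Track]] = {}
    for cam_id, frames in frames_by_camera.items():
        fparams = filter_params or FilterParams()
        if fparams.pen_bounds is None:
            fparams = FilterParams(
                voxel_size=fparams.voxel_size,
                knn_k=fparams.knn_k,
                outlier_sd=fparams.outlier_sd,
                normal_radius=fparams.normal_radius,
                pen_bounds=camera_roi_bounds(pen, cam_id),
                two_sided_outliers=fparams.two_sided_outliers,
            )
        frames = resample_to_fps(frames, tparams.fps)
        manager = TrackManager(tparams)
        for frame in frames:
            cloud = back_project(frame, intrinsics)
            cloud, normals = preprocess(cloud, fparams)
            dets = segment_regions(cloud, normals, tparams)
            manager.step(dets, frame.t)
            log.debug(
                "camera=%s t=%.3f points=%d detections=%d live_tracks=%d",
                cam_id,
                frame.t,
                len(cloud),
                len(dets),
                len(manager.live),
            )
        tracks_by_camera[cam_id] = manager.finish()
        log.info(
            "camera=%s frames=%d tracks=%d",
            cam_id,
            len(frames),
            len(tracks_by_camera[cam_id]),
        )
    merged = merge_cameras(tracks_by_camera, pen, tparams.fuse_distance)
    return [smooth_track(tr, tparams.median_window) for tr in merged]


def camera_roi_bounds(
    pen: PenGeometry,
    camera_id: str,
    floor_margin: float = 0.05,
    wall_margin: float = 0.03,
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Camera-frame region of interest for a perpendicular ceiling camera.

    The depth cut ``Z < mount_height - floor_margin`` removes floor returns;
    the XY bounds, the pen rectangle inset by ``wall_margin`` and translated
    into the camera frame, remove wall and gate returns.
    """
    ox, oy = pen.camera_offset(camera_id)
    h = pen.camera_mount_height
    return (
        (wall_margin - ox, wall_margin - oy, 0.2),
        (pen.length - wall_margin - ox, pen.width - wall_margin - oy, h - floor_margin),
    )
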