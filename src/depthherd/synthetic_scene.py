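"""Synthetic pen scenes: trajectories, behaviour states, depth rendering.

Everything downstream (cloud filtering, detection, tracking, behaviour
measurement, evaluation) is exercised on scenes produced here: a group of
pigs moving in a rectangular pen under ceiling-mounted depth cameras.
Animals are modelled as half-ellipsoids resting on the floor whose
top-surface height encodes posture; a continuous-time Markov chain (or an
explicit deterministic schedule) drives the behaviour state of each animal.

The default pen reproduces the study geometry: 4.02 m x 2.36 m floor,
2.14 m walls, two cameras at 1.98 m above the floor.  With the camera at
1.98 m, standing pigs (top surface 0.68 m) return depths near 1.30 m and
lying pigs (top surface 0.13 m) near 1.85 m — the two depth clusters the
standing model separates.

Pig body dimensions are configurable defaults, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import expm, null_space

from .depth_geometry import CameraIntrinsics, DepthFrame

__all__ = [
    "PenGeometry",
    "BodyDims",
    "AnimalState",
    "GTBox",
    "GroundTruthFrame",
    "MarkovScript",
    "ScheduleScript",
    "DEFAULT_RATES",
    "simulate_group",
    "render_depth_sequence",
    "write_annotations",
    "read_annotations",
    "simulate_pen_day_z",
    "demo_schedule",
    "demo_scene",
    "scripted_standing_series",
]

STATES = ("lying", "sitting", "standing", "feeding", "drinking", "walking")

#: behaviour state -> posture label
POSTURE_OF = {
    "lying": "lying",
    "sitting": "sitting",
    "standing": "standing",
    "feeding": "standing",
    "drinking": "standing",
    "walking": "standing",
}

#: behaviour state -> activity label
ACTIVITY_OF = {s: "none" for s in STATES}
ACTIVITY_OF["feeding"] = "feeding"
ACTIVITY_OF["drinking"] = "drinking"


# ---------------------------------------------------------------------------
# Geometry types
# ---------------------------------------------------------------------------

def _default_feeders() -> list[tuple[float, float, float, float]]:
    # 4 trough areas along the y=0 wall: (xmin, ymin, xmax, ymax)
    return [(0.26 + i * 1.0, 0.0, 0.76 + i * 1.0, 0.30) for i in range(4)]


def _default_drinkers() -> list[tuple[float, float, float, float]]:
    # 4 nipple-drinker areas along the opposite wall
    return [(0.50 + i * 0.90, 2.11, 0.75 + i * 0.90, 2.36) for i in range(4)]


def _default_cameras() -> list[tuple[str, tuple[float, float]]]:
    return [("cam0", (1.06, 1.18)), ("cam1", (2.96, 1.18))]


@dataclass
class PenGeometry:
    """Rectangular pen with ceiling cameras and feeder/drinker areas.

    All lengths in metres.  The pen frame has origin at one floor corner,
    x along ``length``, y along ``width``, z up from the floor.  Camera
    offsets are the XY floor positions directly beneath each camera.
    """

    length: float = 4.02
    width: float = 2.36
    wall_height: float = 2.14
    camera_mount_height: float = 1.98
    camera_offsets: list[tuple[str, tuple[float, float]]] = field(
        default_factory=_default_cameras
    )
    feeder_areas: list[tuple[float, float, float, float]] = field(
        default_factory=_default_feeders
    )
    drinker_areas: list[tuple[float, float, float, float]] = field(
        default_factory=_default_drinkers
    )

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("pen length and width must be positive")
        if self.camera_mount_height <= 0:
            raise ValueError("camera mount height must be positive")
        for rect in list(self.feeder_areas) + list(self.drinker_areas):
            x0, y0, x1, y1 = rect
            if not (0 <= x0 < x1 <= self.length and 0 <= y0 < y1 <= self.width):
                raise ValueError(f"area rectangle {rect} outside pen or degenerate")

    def camera_offset(self, camera_id: str) -> tuple[float, float]:
        for cid, off in self.camera_offsets:
            if cid == camera_id:
                return off
        raise KeyError(f"unknown camera_id {camera_id!r}")

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.length and 0 <= y <= self.width


def point_in_rects(
    x: np.ndarray | float,
    y: np.ndarray | float,
    rects: list[tuple[float, float, float, float]],
) -> np.ndarray:
    """Membership of XY positions in any of a list of axis-aligned rectangles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    for x0, y0, x1, y1 in rects:
        inside |= (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    return inside


@dataclass(frozen=True)
class BodyDims:
    """Ellipsoidal torso body model.

    ``height`` is the standing top-surface height; lying and sitting scale
    it by the posture factors (the lying default places the lying depth
    cluster at 1.85 m under a 1.98 m camera).  The torso is rendered as an
    ellipsoid of vertical extent ``thickness`` whose top sits at the posture
    height: standing animals are a broad slab carried on (unrendered) legs
    rather than a ground-attached spike, which reproduces the smooth, wide
    back an overhead camera actually sees; lying bodies compress onto the
    floor.
    """

    length: float = 0.62
    width: float = 0.26
    height: float = 0.68
    lying_factor: float = 0.19
    sitting_factor: float = 0.45
    thickness: float = 0.30

    def vertical_semi_axis(self, posture: str) -> float:
        return min(self.thickness, self.top_height(posture)) / 2.0

    def top_height(self, posture: str) -> float:
        if posture == "standing":
            return self.height
        if posture == "sitting":
            return self.height * self.sitting_factor
        if posture == "lying":
            return self.height * self.lying_factor
        raise ValueError(f"unknown posture {posture!r}")


@dataclass
class AnimalState:
    """Pose + behaviour of one animal at one instant."""

    animal_id: int
    t: float
    position: tuple[float, float]
    heading: float
    posture: str
    activity: str
    body_dims: BodyDims

    @property
    def behaviour(self) -> str:
        if self.activity != "none":
            return self.activity
        return self.posture


@dataclass
class GTBox:
    """Oriented ground-truth box of one animal in the pen frame."""

    animal_id: int
    cx: float
    cy: float
    length: float
    width: float
    yaw: float
    z_top: float


@dataclass
class GroundTruthFrame:
    t: float
    boxes: list[GTBox]


# ---------------------------------------------------------------------------
# Behaviour scripts
# ---------------------------------------------------------------------------

#: default transition rates (events per second) of the behaviour chain
DEFAULT_RATES: dict[tuple[str, str], float] = {
    ("lying", "standing"): 0.020,
    ("lying", "sitting"): 0.005,
    ("sitting", "lying"): 0.050,
    ("sitting", "standing"): 0.050,
    ("standing", "walking"): 0.100,
    ("standing", "lying"): 0.030,
    ("standing", "sitting"): 0.010,
    ("standing", "feeding"): 0.020,
    ("standing", "drinking"): 0.010,
    ("walking", "standing"): 0.250,
    ("walking", "feeding"): 0.050,
    ("walking", "drinking"): 0.020,
    ("feeding", "standing"): 0.050,
    ("feeding", "walking"): 0.020,
    ("drinking", "standing"): 0.150,
    ("drinking", "walking"): 0.050,
}


@dataclass
class MarkovScript:
    """Continuous-time Markov chain over the behaviour states.

    ``rates[(a, b)]`` is the instantaneous transition rate a -> b in 1/s.
    Sampling at the capture clock uses the exact one-step kernel
    ``P = expm(Q * dt)``, which preserves the chain's stationary law.
    """

    rates: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )
    walk_speed: float = 0.30  # m/s
    initial_state: str | None = None  # None -> drawn from the stationary law

    def __post_init__(self) -> None:
        for (a, b), r in self.rates.items():
            if a not in STATES or b not in STATES:
                raise ValueError(f"unknown state in rate ({a!r}, {b!r})")
            if r < 0:
                raise ValueError("transition rates must be non-negative")

    def generator(self) -> np.ndarray:
        q = np.zeros((len(STATES), len(STATES)))
        idx = {s: i for i, s in enumerate(STATES)}
        for (a, b), r in self.rates.items():
            if a != b:
                q[idx[a], idx[b]] = r
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def step_kernel(self, dt: float) -> np.ndarray:
        return expm(self.generator() * dt)

    def stationary_distribution(self) -> np.ndarray:
        """Closed-form stationary law: the null space of Q^T, normalised.

        States not referenced by any rate get probability 0; raises if the
        stationary law over the active states is not unique (disconnected
        chain with two sinks).
        """
        q = self.generator()
        active = np.nonzero(np.abs(q).sum(axis=0) + np.abs(q).sum(axis=1))[0]
        if active.size == 0:
            raise ValueError("behaviour chain has no transitions")
        ns = null_space(q[np.ix_(active, active)].T)
        if ns.shape[1] != 1:
            raise ValueError("behaviour chain has no unique stationary law")
        sub = ns[:, 0] / ns[:, 0].sum()
        if np.any(sub < -1e-9):
            raise ValueError("invalid stationary distribution")
        sub = np.clip(sub, 0.0, None)
        pi = np.zeros(len(STATES))
        pi[active] = sub / sub.sum()
        return pi


@dataclass
class ScheduleScript:
    """Deterministic behaviour schedule: a list of (state, duration_s) segments.

    ``segments`` may be one shared list or one list per animal.
    """

    segments: list[tuple[str, float]] | list[list[tuple[str, float]]]
    walk_speed: float = 0.30

    def for_animal(self, i: int, n: int) -> list[tuple[str, float]]:
        segs = self.segments
        if segs and isinstance(segs[0], tuple):
            return list(segs)  # shared
        if len(segs) != n:
            raise ValueError("per-animal schedule count does not match n_animals")
        return list(segs[i])

    def state_at(self, i: int, n: int, t: float) -> str:
        acc = 0.0
        segs = self.for_animal(i, n)
        for state, dur in segs:
            acc += dur
            if t < acc - 1e-12:
                return state
        return segs[-1][0]


# ---------------------------------------------------------------------------
# Group simulation
# ---------------------------------------------------------------------------

def _home_grid(pen: PenGeometry, n: int, body: BodyDims) -> list[tuple[float, float]]:
    """Home anchor per animal on a regular grid covering the pen interior."""
    if n * body.length * body.width > 0.6 * pen.length * pen.width:
        raise ValueError(
            f"infeasible placement: {n} animals of {body.length}x{body.width} m "
            f"cannot fit in a {pen.length}x{pen.width} m pen"
        )
    cols = max(1, math.ceil(math.sqrt(n * pen.length / pen.width)))
    rows = max(1, math.ceil(n / cols))
    while rows * cols < n:
        cols += 1
    cx = pen.length / cols
    cy = pen.width / rows
    homes = []
    for i in range(n):
        r, c = divmod(i, cols)
        homes.append(((c + 0.5) * cx, (r + 0.5) * cy))
    return homes


def _area_slots(
    rects: list[tuple[float, float, float, float]],
    per_area: int,
    pen: PenGeometry,
) -> list[tuple[tuple[float, float], float]]:
    """Engagement points inside each area, each with the approach heading
    (animals face the pen wall the area is attached to, so side-by-side
    occupants stand parallel rather than crossing bodies)."""
    slots = []
    for x0, y0, x1, y1 in rects:
        wall_dists = [y0, pen.width - y1, x0, pen.length - x1]
        headings = [-math.pi / 2, math.pi / 2, math.pi, 0.0]
        heading = headings[int(np.argmin(wall_dists))]
        for j in range(per_area):
            fx = (j + 0.5) / per_area
            slots.append(((x0 + fx * (x1 - x0), (y0 + y1) / 2.0), heading))
    return slots


def simulate_group(
    pen: PenGeometry,
    n_animals: int,
    duration: float,
    behaviour_script: MarkovScript | ScheduleScript | None = None,
    seed: int = 0,
    fps: float = 7.0,
    body_dims: BodyDims | None = None,
) -> list[list[AnimalState]]:
    """Simulate a group of animals over ``duration`` seconds at ``fps``.

    Returns one time-ordered list of :class:`AnimalState` per animal, with
    timestamps k/fps for k = 0 .. floor(duration*fps)-1.  Deterministic given
    the seed.  Movement is bounded by the script's walking speed, and the
    behaviour labels always satisfy the state invariants (feeding/drinking
    only while standing inside the corresponding area: a sampled transition
    into feeding while away from the feeder becomes walking-toward until
    arrival).
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    body = body_dims or BodyDims()
    script = behaviour_script if behaviour_script is not None else MarkovScript()
    rng = np.random.default_rng(seed)
    homes = _home_grid(pen, n_animals, body)
    n_steps = int(math.floor(duration * fps))
    dt = 1.0 / fps

    feeder_slots = _area_slots(pen.feeder_areas, 2, pen) or None
    drinker_slots = _area_slots(pen.drinker_areas, 1, pen) or None

    markov = isinstance(script, MarkovScript)
    if markov:
        kernel = script.step_kernel(dt)
        pi = script.stationary_distribution()
        idx = {s: i for i, s in enumerate(STATES)}

    # per-animal state
    pos = np.array(homes, dtype=float)
    heading = rng.uniform(0, 2 * np.pi, size=n_animals)
    dims = [
        replace(
            body,
            length=body.length * (1 + 0.03 * rng.standard_normal()),
            width=body.width * (1 + 0.03 * rng.standard_normal()),
        )
        for _ in range(n_animals)
    ]
    if markov:
        if script.initial_state is not None:
            goal = [script.initial_state] * n_animals
        else:
            goal = [STATES[rng.choice(len(STATES), p=pi)] for _ in range(n_animals)]
    else:
        goal = [script.state_at(i, n_animals, 0.0) for i in range(n_animals)]

    # animals whose schedule starts engaged are placed at their slot
    slot_of = {}
    for i in range(n_animals):
        slot_of[i] = {
            "feeding": feeder_slots[i % len(feeder_slots)] if feeder_slots else None,
            "drinking": drinker_slots[i % len(drinker_slots)] if drinker_slots else None,
        }
        if goal[i] in ("feeding", "drinking"):
            slot = slot_of[i][goal[i]]
            if slot is None:
                goal[i] = "standing"
            else:
                pos[i] = slot[0]
                heading[i] = slot[1]

    occupied: dict[tuple[float, float], int] = {}
    out: list[list[AnimalState]] = [[] for _ in range(n_animals)]
    speed = script.walk_speed
    waypoint: list[tuple[float, float]] = [tuple(h) for h in homes]
    min_sep = 0.7 * body.length  # bodies may touch but not interpenetrate

    def blocked(i: int, newp: np.ndarray) -> bool:
        d = np.hypot(pos[:, 0] - newp[0], pos[:, 1] - newp[1])
        d[i] = np.inf
        d_now = np.hypot(pos[:, 0] - pos[i, 0], pos[:, 1] - pos[i, 1])
        d_now[i] = np.inf
        k = int(np.argmin(d))
        return d[k] < min_sep and d[k] < d_now[k]

    def move(i: int, target, max_step: float) -> None:
        newp = _step_toward(pos[i], target, max_step)
        if not blocked(i, newp):
            pos[i] = newp

    areas_of = {"feeding": pen.feeder_areas, "drinking": pen.drinker_areas}

    for k in range(n_steps):
        t = k * dt
        for i in range(n_animals):
            g = goal[i]
            label = g
            if g in ("feeding", "drinking"):
                slot = slot_of[i][g]
                in_area = (
                    bool(point_in_rects(pos[i, 0], pos[i, 1], areas_of[g]))
                    if areas_of[g]
                    else False
                )
                if slot is None:
                    label = "standing"
                elif not in_area:
                    holder = occupied.get(slot[0])
                    if holder is not None and holder != i:
                        label = "standing"  # slot busy: wait where it is
                    else:
                        label = "walking"
                        move(i, slot[0], speed * dt)
                        if bool(point_in_rects(pos[i, 0], pos[i, 1], areas_of[g])):
                            label = g
                            heading[i] = slot[1]
                            occupied[slot[0]] = i
                else:
                    heading[i] = slot[1]
                    occupied[slot[0]] = i
            elif g == "walking":
                move(i, waypoint[i], speed * dt)
                if np.hypot(*(pos[i] - np.asarray(waypoint[i]))) < 1e-9:
                    # pick a fresh waypoint in a small roam disc around home
                    ang = rng.uniform(0, 2 * np.pi)
                    r = rng.uniform(0, 0.15)
                    waypoint[i] = (
                        float(np.clip(homes[i][0] + r * np.cos(ang), 0.2, pen.length - 0.2)),
                        float(np.clip(homes[i][1] + r * np.sin(ang), 0.2, pen.width - 0.2)),
                    )
            # release slot when no longer engaged/heading there
            if g not in ("feeding", "drinking"):
                for s, holder in list(occupied.items()):
                    if holder == i:
                        del occupied[s]

            if label == "walking":
                target = (
                    slot_of[i][g][0]
                    if g in ("feeding", "drinking")
                    else waypoint[i]
                )
                d = np.asarray(target) - pos[i]
                if np.hypot(*d) > 1e-6:
                    heading[i] = math.atan2(d[1], d[0])

            out[i].append(
                AnimalState(
                    animal_id=i,
                    t=t,
                    position=(float(pos[i, 0]), float(pos[i, 1])),
                    heading=float(heading[i]),
                    posture=POSTURE_OF[label],
                    activity=ACTIVITY_OF[label],
                    body_dims=dims[i],
                )
            )

            # advance the behaviour chain / schedule
            if markov:
                row = kernel[idx[g]]
                goal[i] = STATES[rng.choice(len(STATES), p=row)]
            else:
                goal[i] = script.state_at(i, n_animals, (k + 1) * dt)
    return out


def _step_toward(p: np.ndarray, target, max_step: float) -> np.ndarray:
    d = np.asarray(target, dtype=float) - p
    dist = float(np.hypot(*d))
    if dist <= max_step or dist == 0:
        return np.asarray(target, dtype=float).copy()
    return p + d * (max_step / dist)


# ---------------------------------------------------------------------------
# Depth rendering
# ---------------------------------------------------------------------------

def _ray_grid(intr: CameraIntrinsics) -> tuple[np.ndarray, np.ndarray]:
    u = np.arange(intr.width, dtype=float)
    v = np.arange(intr.height, dtype=float)
    alpha = (u - intr.principal_x) / intr.focal_x
    beta = (v - intr.principal_y) / intr.focal_y
    return np.meshgrid(alpha, beta)  # (H, W) each


def render_background(
    pen: PenGeometry, intr: CameraIntrinsics, camera_id: str
) -> np.ndarray:
    """Depth map of the empty pen (floor + walls) for one camera; 0 = no hit."""
    ox, oy = pen.camera_offset(camera_id)
    h = pen.camera_mount_height
    alpha, beta = _ray_grid(intr)
    depth = np.full(alpha.shape, np.inf)

    # floor hit at t = h
    fx = ox + alpha * h
    fy = oy + beta * h
    on_floor = (fx >= 0) & (fx <= pen.length) & (fy >= 0) & (fy <= pen.width)
    depth[on_floor] = h

    # vertical wall planes at x=0, x=L, y=0, y=W
    for axis, coord, lo, hi in (
        (0, 0.0, 0.0, pen.width),
        (0, pen.length, 0.0, pen.width),
        (1, 0.0, 0.0, pen.length),
        (1, pen.width, 0.0, pen.length),
    ):
        dirc = alpha if axis == 0 else beta
        orig = ox if axis == 0 else oy
        with np.errstate(divide="ignore", invalid="ignore"):
            tw = (coord - orig) / dirc
            other = (oy + beta * tw) if axis == 0 else (ox + alpha * tw)
            zw = h - tw  # height above floor at the hit
        ok = (
            np.isfinite(tw)
            & (tw > 0)
            & (other >= lo)
            & (other <= hi)
            & (zw >= 0)
            & (zw <= pen.wall_height)
        )
        depth = np.where(ok & (tw < depth), tw, depth)

    depth[~np.isfinite(depth)] = 0.0
    return depth


def _render_animal(
    depth: np.ndarray,
    state: AnimalState,
    pen: PenGeometry,
    intr: CameraIntrinsics,
    camera_id: str,
) -> None:
    """Composite one half-ellipsoid animal into ``depth`` (in place)."""
    ox, oy = pen.camera_offset(camera_id)
    h = pen.camera_mount_height
    x0, y0 = state.position
    a = state.body_dims.length / 2.0
    b = state.body_dims.width / 2.0
    c = state.body_dims.top_height(state.posture)
    cv = state.body_dims.vertical_semi_axis(state.posture)
    z_center = c - cv  # ellipsoid centre height above the floor
    r = max(a, b)

    # pixel bounding box from the enclosing cylinder at near/far depth
    us, vs = [], []
    for t in (max(h - c, 1e-3), h):
        for sx in (-r, r):
            us.append((x0 + sx - ox) / t * intr.focal_x + intr.principal_x)
        for sy in (-r, r):
            vs.append((y0 + sy - oy) / t * intr.focal_y + intr.principal_y)
    u0 = max(0, int(math.floor(min(us))) - 2)
    u1 = min(intr.width, int(math.ceil(max(us))) + 3)
    v0 = max(0, int(math.floor(min(vs))) - 2)
    v1 = min(intr.height, int(math.ceil(max(vs))) + 3)
    if u0 >= u1 or v0 >= v1:
        return

    uu = np.arange(u0, u1, dtype=float)
    vv = np.arange(v0, v1, dtype=float)
    alpha = (uu - intr.principal_x) / intr.focal_x
    beta = (vv - intr.principal_y) / intr.focal_y
    A_, B_ = np.meshgrid(alpha, beta)

    cosy, siny = math.cos(state.heading), math.sin(state.heading)
    dx0, dy0 = ox - x0, oy - y0
    # body-frame ray components: x'(t) = p0 + p1 t, y'(t) = q0 + q1 t,
    # height relative to the ellipsoid centre: z(t) = (h - z_center) - t
    p0 = cosy * dx0 + siny * dy0
    q0 = -siny * dx0 + cosy * dy0
    p1 = cosy * A_ + siny * B_
    q1 = -siny * A_ + cosy * B_
    he = h - z_center

    Aq = (p1 / a) ** 2 + (q1 / b) ** 2 + 1.0 / cv**2
    Bq = 2.0 * (p0 * p1 / a**2 + q0 * q1 / b**2 - he / cv**2)
    Cq = (p0 / a) ** 2 + (q0 / b) ** 2 + (he / cv) ** 2 - 1.0
    disc = Bq**2 - 4.0 * Aq * Cq
    hit = disc >= 0
    if not np.any(hit):
        return
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t_hit = (-Bq - sq) / (2.0 * Aq)
    ok = hit & (t_hit > 0)

    sub = depth[v0:v1, u0:u1]
    closer = ok & ((t_hit < sub) | (sub <= 0))
    sub[closer] = t_hit[closer]


def render_depth_sequence(
    states: list[list[AnimalState]],
    pen: PenGeometry,
    intrinsics: CameraIntrinsics | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    frame_drop_rate: float = 0.0,
    t0: float = 0.0,
) -> tuple[dict[str, list[DepthFrame]], list[GroundTruthFrame]]:
    """Render animal trajectories into per-camera depth frames + ground truth.

    Each pixel holds the distance (along the optical axis) to the nearest
    surface — animal, floor, or wall — plus zero-mean Gaussian noise of
    ``noise_sd``; ``noise_sd=0`` gives the exact geometric render.  A
    ``frame_drop_rate`` > 0 randomly drops frames per camera, emulating
    capture hiccups.  ``t0`` offsets all timestamps (epoch seconds).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    intr = intrinsics or CameraIntrinsics.wide_demo()
    rng = np.random.default_rng(seed)
    cam_ids = [cid for cid, _ in pen.camera_offsets]
    backgrounds = {cid: render_background(pen, intr, cid) for cid in cam_ids}

    n_steps = len(states[0]) if states else 0
    frames: dict[str, list[DepthFrame]] = {cid: [] for cid in cam_ids}
    gt: list[GroundTruthFrame] = []
    for k in range(n_steps):
        t = states[0][k].t
        boxes = []
        for traj in states:
            s = traj[k]
            boxes.append(
                GTBox(
                    animal_id=s.animal_id,
                    cx=s.position[0],
                    cy=s.position[1],
                    length=s.body_dims.length,
                    width=s.body_dims.width,
                    yaw=s.heading,
                    z_top=s.body_dims.top_height(s.posture),
                )
            )
        gt.append(GroundTruthFrame(t=t0 + t, boxes=boxes))
        for cid in cam_ids:
            if frame_drop_rate > 0 and rng.random() < frame_drop_rate:
                continue
            depth = backgrounds[cid].copy()
            for traj in states:
                _render_animal(depth, traj[k], pen, intr, cid)
            if noise_sd > 0:
                valid = depth > 0
                depth[valid] = np.maximum(
                    depth[valid] + rng.normal(0.0, noise_sd, size=int(valid.sum())),
                    1e-3,
                )
            frames[cid].append(DepthFrame(camera_id=cid, t=t0 + t, depth=depth))
    return frames, gt


# ---------------------------------------------------------------------------
# Annotation files
# ---------------------------------------------------------------------------

_ANNOT_HEADER = "frame_ts,animal_id,cx,cy,len,wid,yaw,z_top"


def write_annotations(gt: list[GroundTruthFrame], path: str | Path) -> Path:
    """Write ground-truth boxes as CSV (pen frame, metres/radians).

    Floats are written with ``repr`` so that a read/write round trip is
    bit-exact.
    """
    if not gt:
        raise ValueError("ground truth is empty")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_ANNOT_HEADER + "\n")
        for frame in gt:
            for b in frame.boxes:
                fh.write(
                    f"{float(frame.t)!r},{b.animal_id},"
                    f"{float(b.cx)!r},{float(b.cy)!r},"
                    f"{float(b.length)!r},{float(b.width)!r},"
                    f"{float(b.yaw)!r},{float(b.z_top)!r}\n"
                )
    return path


def read_annotations(path: str | Path) -> list[GroundTruthFrame]:
    path = Path(path)
    frames: dict[float, GroundTruthFrame] = {}
    order: list[float] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _ANNOT_HEADER:
            raise ValueError(f"unexpected annotation header {header!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            ts, aid, cx, cy, ln, wd, yaw, zt = line.split(",")
            t = float(ts)
            if t not in frames:
                frames[t] = GroundTruthFrame(t=t, boxes=[])
                order.append(t)
            frames[t].boxes.append(
                GTBox(
                    animal_id=int(aid),
                    cx=float(cx),
                    cy=float(cy),
                    length=float(ln),
                    width=float(wd),
                    yaw=float(yaw),
                    z_top=float(zt),
                )
            )
    return [frames[t] for t in order]


# ---------------------------------------------------------------------------
# Bundled demo scene
# ---------------------------------------------------------------------------

def demo_schedule(
    n_animals: int, duration: float, seed: int
) -> ScheduleScript:
    """Disturbance-style behaviour schedule for the bundled demo scene.

    The group starts mostly lying, rises into a wave of standing, walking
    and feeding (as a pen does when disturbed), and settles again, with
    per-animal staggering.  The scripted standing series therefore spans
    nearly the whole 0..n_animals range, which is what behaviour validation
    against the script needs.
    """
    rng = np.random.default_rng(seed)
    per_animal: list[list[tuple[str, float]]] = []
    for i in range(n_animals):
        rest0 = duration * (0.25 + 0.15 * rng.random())
        active = duration * (0.35 + 0.15 * rng.random())
        engage = "feeding" if i % 3 == 0 else ("drinking" if i % 7 == 3 else "standing")
        segs = [
            ("lying", rest0),
            ("standing", duration * 0.05),
            ("walking", duration * 0.08),
            (engage, active),
            ("standing", duration * 0.05),
            ("lying", duration),  # remainder
        ]
        per_animal.append(segs)
    return ScheduleScript(segments=per_animal)


def demo_scene(
    seed: int,
    n_animals: int = 19,
    duration: float = 60.0,
    noise_sd: float = 0.01,
    pen: PenGeometry | None = None,
    intrinsics: CameraIntrinsics | None = None,
) -> tuple[
    list[list[AnimalState]], dict[str, list[DepthFrame]], list[GroundTruthFrame]
]:
    """The default synthetic pen: 19 animals, 60 s, 0.01 m depth noise.

    Returns (script truth, depth frames per camera, ground-truth frames).
    """
    pen = pen or PenGeometry()
    states = simulate_group(
        pen,
        n_animals,
        duration,
        demo_schedule(n_animals, duration, seed),
        seed=seed,
    )
    frames, gt = render_depth_sequence(
        states, pen, intrinsics, noise_sd=noise_sd, seed=seed + 1
    )
    return states, frames, gt


def scripted_standing_series(
    states: list[list[AnimalState]], interval: float, fps: float = 7.0
) -> dict[float, float]:
    """Ground-truth standing seconds per interval from simulated states."""
    out: dict[float, float] = {}
    for traj in states:
        for s in traj:
            if s.posture == "standing":
                k = interval * math.floor(s.t / interval)
                out[k] = out.get(k, 0.0) + 1.0 / fps
    return out


# ---------------------------------------------------------------------------
# Pen-day depth sampler (standing-model training data)
# ---------------------------------------------------------------------------

def simulate_pen_day_z(
    seed: int,
    n: int = 10_000,
    camera_mount_height: float = 1.98,
    body: BodyDims | None = None,
    standing_fraction: float | None = None,
    z_sd: float = 0.03,
) -> tuple[np.ndarray, dict]:
    """Draw centroid depth (Z) measurements for one synthetic pen-day.

    Standing centroids sit near ``mount_height - (2/3) body height`` (the
    mean surface height of a half-ellipsoid is 2/3 of its apex height),
    lying/sitting centroids proportionally lower, each blurred by ``z_sd``.
    Returns the samples and the generating parameters (the oracle for
    mixture-recovery tests).
    """
    rng = np.random.default_rng(seed)
    body = body or BodyDims()
    if standing_fraction is None:
        standing_fraction = float(rng.uniform(0.25, 0.6))
    mu_stand = camera_mount_height - (2.0 / 3.0) * body.height
    mu_other = camera_mount_height - (2.0 / 3.0) * body.top_height("lying")
    labels = rng.random(n) < standing_fraction
    z = np.where(
        labels,
        rng.normal(mu_stand, z_sd, size=n),
        rng.normal(mu_other, z_sd, size=n),
    )
    truth = {
        "mu_stand": mu_stand,
        "mu_other": mu_other,
        "sd": z_sd,
        "w_stand": standing_fraction,
    }
    return z, truth
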