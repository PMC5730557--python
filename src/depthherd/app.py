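"""Orchestration: YAML run configuration, logging, and the command-line
interface chaining simulate -> track -> behave -> evaluate.

The CLI is a thin shell over the library:

    depthherd simulate --config run.yaml
    depthherd track    --config run.yaml
    depthherd behave   --config run.yaml
    depthherd evaluate --config run.yaml

All scalar parameters live in one YAML file (sections ``pen``,
``intrinsics``, ``cloud``, ``tracker``, ``behaviour``, ``scene``, ``qc``,
``paths``, ``seed``) and any of them can be overridden on the command line
with ``--set section.key=value``.  Every command is deterministic given the
config and seeds, logs structured progress lines to stderr, and exits
non-zero with a named error on invalid input.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from .behaviour import BehaviourParams, measure_behaviour
from .cloud_pipeline import FilterParams
from .depth_geometry import CameraIntrinsics, read_depth_frame, write_depth_frame
from .detect_track import Track, TrackerParams, track_sequence
from .evaluation import evaluate_tracking, track_duration_stats
from .synthetic_scene import (
    BodyDims,
    MarkovScript,
    PenGeometry,
    read_annotations,
    render_depth_sequence,
    simulate_group,
    write_annotations,
)

log = logging.getLogger("depthherd")

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "cmd_simulate",
    "cmd_track",
    "cmd_behave",
    "cmd_evaluate",
    "main",
]


@dataclass
class SceneConfig:
    n_animals: int = 19
    duration: float = 60.0
    noise_sd: float = 0.01
    fps: float = 7.0
    frame_drop_rate: float = 0.0
    body_length: float = 0.62
    body_width: float = 0.26
    body_height: float = 0.68

    def body_dims(self) -> BodyDims:
        return BodyDims(
            length=self.body_length, width=self.body_width, height=self.body_height
        )


@dataclass
class PathsConfig:
    frames_dir: str = "frames"
    annotations: str = "annotations.csv"
    tracks: str = "tracks.csv"
    behaviour: str = "behaviour.csv"
    standing_model: str = "standing_model.json"
    mot_result: str = "mot_result.json"
    comparison: str = "comparison.csv"


@dataclass
class RunConfig:
    """Validated, round-trippable run configuration."""

    pen: PenGeometry = field(default_factory=PenGeometry)
    intrinsics: CameraIntrinsics = field(
        default_factory=CameraIntrinsics.wide_demo
    )
    cloud: FilterParams = field(default_factory=FilterParams)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    behaviour: BehaviourParams = field(default_factory=BehaviourParams)
    scene: SceneConfig = field(default_factory=SceneConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)
    qc_windows: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0
    workdir: str = "."

    def resolve(self, name: str) -> Path:
        return Path(self.workdir) / getattr(self.paths, name)


_SECTION_TYPES = {
    "pen": PenGeometry,
    "intrinsics": CameraIntrinsics,
    "cloud": FilterParams,
    "tracker": TrackerParams,
    "behaviour": BehaviourParams,
    "scene": SceneConfig,
    "paths": PathsConfig,
}


def _build_section(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    coerced = dict(data)
    # YAML gives lists where the dataclasses expect tuples
    tuple_fields = {"entropy_grid", "pen_bounds"}
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            v = coerced[f.name]
            if f.name in tuple_fields:
                coerced[f.name] = _deep_tuple(v)
            elif v and isinstance(v[0], list):
                coerced[f.name] = [_deep_tuple(item) for item in v]
    return cls(**coerced)


def _deep_tuple(x):
    if isinstance(x, list):
        return tuple(_deep_tuple(v) for v in x)
    return x


def load_config(path: str | Path, overrides: list[str] | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown sections or keys are rejected.  ``overrides`` are
    ``section.key=value`` strings applied before validation.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    for ov in overrides or []:
        if "=" not in ov or "." not in ov.split("=", 1)[0]:
            raise ValueError(f"override {ov!r} must look like section.key=value")
        key, value = ov.split("=", 1)
        section, name = key.split(".", 1)
        raw.setdefault(section, {})[name] = yaml.safe_load(value)
    known = set(_SECTION_TYPES) | {"qc_windows", "seed", "workdir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            data = raw[section]
            if section == "pen" and "camera_offsets" in data:
                data["camera_offsets"] = [
                    (cid, (float(x), float(y))) for cid, (x, y) in
                    ((c[0], c[1]) for c in data["camera_offsets"])
                ]
            if section == "pen":
                for key in ("feeder_areas", "drinker_areas"):
                    if key in data:
                        data[key] = [tuple(map(float, r)) for r in data[key]]
            kwargs[section] = _build_section(cls, data)
    if "qc_windows" in raw:
        kwargs["qc_windows"] = [
            (float(a), float(b)) for a, b in raw["qc_windows"]
        ]
    for scalar in ("seed", "workdir"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str | Path) -> Path:
    """Serialise a RunConfig back to YAML (load -> dump -> load is identity)."""
    out = {}
    for section, cls in _SECTION_TYPES.items():
        obj = getattr(config, section)
        out[section] = _to_plain(dataclasses.asdict(obj))
    out["qc_windows"] = [[a, b] for a, b in config.qc_windows]
    out["seed"] = config.seed
    out["workdir"] = config.workdir
    path = Path(path)
    path.write_text(yaml.safe_dump(out, sort_keys=True))
    return path


def _to_plain(x):
    if isinstance(x, dict):
        return {k: _to_plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_to_plain(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


# ---------------------------------------------------------------------------
# Commands
# ---------------------------------------------------------------------------

def cmd_simulate(config: RunConfig) -> tuple[Path, Path]:
    """Render the configured synthetic scene to depth PNGs + annotations."""
    sc = config.scene
    log.info("simulate: n=%d duration=%.0fs seed=%d", sc.n_animals, sc.duration, config.seed)
    states = simulate_group(
        config.pen,
        sc.n_animals,
        sc.duration,
        MarkovScript(),
        seed=config.seed,
        fps=sc.fps,
        body_dims=sc.body_dims(),
    )
    frames, gt = render_depth_sequence(
        states,
        config.pen,
        config.intrinsics,
        noise_sd=sc.noise_sd,
        seed=config.seed + 1,
        frame_drop_rate=sc.frame_drop_rate,
    )
    frames_dir = config.resolve("frames_dir")
    frames_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for cam_frames in frames.values():
        for frame in cam_frames:
            write_depth_frame(frame, frames_dir)
            n += 1
    annot = write_annotations(gt, config.resolve("annotations"))
    log.info("simulate: wrote %d frames to %s, annotations to %s", n, frames_dir, annot)
    return frames_dir, annot


def cmd_track(config: RunConfig) -> Path:
    """Depth frames -> merged, smoothed pen-frame tracks CSV."""
    frames_dir = config.resolve("frames_dir")
    if not frames_dir.is_dir():
        raise FileNotFoundError(f"frames directory {frames_dir} does not exist")
    by_camera: dict[str, list] = {}
    for png in sorted(frames_dir.glob("*.png")):
        frame = read_depth_frame(png)
        by_camera.setdefault(frame.camera_id, []).append(frame)
    if not by_camera:
        raise FileNotFoundError(f"no depth frames found in {frames_dir}")
    for frames in by_camera.values():
        frames.sort(key=lambda f: f.t)
    log.info(
        "track: %s frames from %d cameras",
        sum(len(v) for v in by_camera.values()),
        len(by_camera),
    )
    cloud = config.cloud if config.cloud.pen_bounds is not None else None
    tracks = track_sequence(
        by_camera, config.intrinsics, config.pen, cloud, config.tracker
    )
    path = config.resolve("tracks")
    write_tracks_csv(tracks, path)
    log.info("track: %d tracks -> %s", len(tracks), path)
    return path


def cmd_behave(config: RunConfig) -> tuple[Path, Path | None]:
    """Tracks CSV -> behaviour intervals CSV + standing-model JSON."""
    tracks = read_tracks_csv(config.resolve("tracks"))
    out_path = config.resolve("behaviour")
    if not tracks:
        log.warning("behave: empty track set; writing header-only output")
        _write_behaviour_csv([], out_path)
        return out_path, None
    intervals, model = measure_behaviour(
        tracks,
        config.pen,
        config.behaviour,
        qc_windows=config.qc_windows,
        seed=config.seed,
    )
    _write_behaviour_csv(intervals, out_path)
    model_path = config.resolve("standing_model")
    model.to_json(model_path)
    log.info("behave: %d intervals -> %s", len(intervals), out_path)
    return out_path, model_path


def cmd_evaluate(config: RunConfig) -> Path:
    """Tracks vs annotations -> CLEAR-MOT metrics JSON."""
    gt = read_annotations(config.resolve("annotations"))
    tracks = read_tracks_csv(config.resolve("tracks"))
    if not tracks:
        raise ValueError("no tracks to evaluate")
    result = evaluate_tracking(gt, tracks)
    mean_dur, sem_dur = track_duration_stats(tracks)
    payload = {
        "mota": result.mota,
        "motp": result.motp,
        "fn_rate": result.fn_rate,
        "fp_rate": result.fp_rate,
        "idsw_rate": result.idsw_rate,
        "fn": result.fn,
        "fp": result.fp,
        "idsw": result.idsw,
        "gt": result.gt,
        "matches": result.matches,
        "mean_track_duration_s": mean_dur,
        "track_duration_sem_s": sem_dur,
        "n_tracks": len(tracks),
    }
    path = config.resolve("mot_result")
    path.write_text(json.dumps(payload, indent=2))
    log.info("evaluate: MOTA=%.3f MOTP=%.3f -> %s", result.mota, result.motp, path)
    return path


# ---------------------------------------------------------------------------
# Track / behaviour CSV dialects
# ---------------------------------------------------------------------------

def write_tracks_csv(tracks: list[Track], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["track_id", "t", "x", "y", "z", "camera_id"])
        for tr in tracks:
            for t, c, cid in zip(tr.times, tr.centroids, tr.camera_ids):
                w.writerow(
                    [
                        tr.track_id,
                        repr(float(t)),
                        repr(float(c[0])),
                        repr(float(c[1])),
                        repr(float(c[2])),
                        cid or "",
                    ]
                )
    return path


def read_tracks_csv(path: str | Path) -> list[Track]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tracks file {path} does not exist")
    tracks: dict[int, Track] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["track_id", "t", "x", "y", "z", "camera_id"]:
            raise ValueError(f"unexpected tracks header {header}")
        for row in reader:
            tid = int(row[0])
            tr = tracks.setdefault(tid, Track(track_id=tid))
            tr.append(
                float(row[1]),
                np.array([float(row[2]), float(row[3]), float(row[4])]),
                row[5] or None,
            )
    return [tracks[k] for k in sorted(tracks)]


_BEHAVIOUR_HEADER = [
    "interval_start",
    "standing_s",
    "feeding_s",
    "drinking_s",
    "distance_m",
    "mean_speed_mps",
    "spatial_entropy",
    "n_tracks",
    "qc_excluded",
]


def _write_behaviour_csv(intervals, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_BEHAVIOUR_HEADER)
        for iv in intervals:
            w.writerow(
                [
                    repr(float(iv.start)),
                    repr(float(iv.standing_s)),
                    repr(float(iv.feeding_s)),
                    repr(float(iv.drinking_s)),
                    repr(float(iv.distance_m)),
                    repr(float(iv.mean_speed_mps)),
                    ""
                    if iv.spatial_entropy is None
                    else repr(float(iv.spatial_entropy)),
                    iv.n_tracks,
                    int(iv.qc_excluded),
                ]
            )
    return path


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _configure_logging(verbose: bool) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@click.group()
@click.option("--verbose", is_flag=True, help="Enable debug logging.")
def main(verbose: bool) -> None:
    """Overhead depth-video tracking and behaviour monitoring for pig pens."""
    _configure_logging(verbose)


def _common(func):
    func = click.option(
        "--set",
        "overrides",
        multiple=True,
        help="Override a config value: section.key=value.",
    )(func)
    func = click.option(
        "--config",
        "config_path",
        required=True,
        type=click.Path(exists=True, dir_okay=False),
        help="YAML run configuration.",
    )(func)
    return func


def _run(fn, config_path: str, overrides) -> None:
    try:
        config = load_config(config_path, list(overrides))
        fn(config)
    except (ValueError, FileNotFoundError, KeyError) as exc:
        log.error("%s: %s", type(exc).__name__, exc)
        raise SystemExit(1)


@main.command()
@_common
def simulate(config_path: str, overrides) -> None:
    """Render the configured synthetic scene."""
    _run(cmd_simulate, config_path, overrides)


@main.command()
@_common
def track(config_path: str, overrides) -> None:
    """Track animals in the rendered depth frames."""
    _run(cmd_track, config_path, overrides)


@main.command()
@_common
def behave(config_path: str, overrides) -> None:
    """Measure behaviour from the tracks."""
    _run(cmd_behave, config_path, overrides)


@main.command()
@_common
def evaluate(config_path: str, overrides) -> None:
    """Evaluate tracking against the ground-truth annotations."""
    _run(cmd_evaluate, config_path, overrides)


if __name__ == "__main__":
    main()
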