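"""Shared fixtures: pen geometry, rendered scenes, and the full demo run.

The expensive fixtures (rendered scenes, the 60 s demo pipeline) are
session-scoped so the suite renders each scene exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from depthherd import (
    CameraIntrinsics,
    PenGeometry,
    ScheduleScript,
    demo_scene,
    render_depth_sequence,
    simulate_group,
    track_sequence,
)


@pytest.fixture()
def pen() -> PenGeometry:
    return PenGeometry()


@pytest.fixture()
def intr() -> CameraIntrinsics:
    return CameraIntrinsics.wide_demo()


@pytest.fixture(scope="session")
def small_scene():
    """4 standing animals, 3 s, light noise: a cheap tracked scene."""
    pen = PenGeometry()
    intr = CameraIntrinsics.wide_demo()
    states = simulate_group(
        pen, 4, 3.0, ScheduleScript(segments=[("standing", 10.0)]), seed=1
    )
    frames, gt = render_depth_sequence(states, pen, intr, noise_sd=0.01, seed=2)
    return {"pen": pen, "intr": intr, "states": states, "frames": frames, "gt": gt}


@pytest.fixture(scope="session")
def small_scene_tracks(small_scene):
    return track_sequence(
        small_scene["frames"], small_scene["intr"], small_scene["pen"]
    )


@pytest.fixture(scope="session")
def demo_run():
    """The bundled 19-animal, 60 s demo scene, fully tracked (runs once)."""
    pen = PenGeometry()
    intr = CameraIntrinsics.wide_demo()
    states, frames, gt = demo_scene(101)
    tracks = track_sequence(frames, intr, pen)
    return {
        "pen": pen,
        "intr": intr,
        "states": states,
        "frames": frames,
        "gt": gt,
        "tracks": tracks,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
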