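"""Depth rasters and pinhole back projection.

Overhead time-of-flight cameras deliver 2D rasters of metric distance.  This
module defines the in-memory containers (:class:`DepthFrame`,
:class:`PointCloud`), the 16-bit millimetre PNG file dialect, and the
conversion from raster to 3D point cloud in camera coordinates.

Conventions
-----------
* Internal unit is metres everywhere; millimetres exist only inside the PNG
  file dialect (16-bit, 0 = invalid pixel).
* Pixel indices are 0-based, ``u`` rightward, ``v`` downward.
* Camera coordinates: X along ``u``, Y along ``v``, Z along the optical axis
  pointing down toward the pen floor, so a pixel ``(u, v)`` with depth ``d``
  back-projects to ``((u - cx) d / fx, (v - cy) d / fy, d)``.
* Timestamps are epoch seconds carried at millisecond resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CameraIntrinsics",
    "DepthFrame",
    "PointCloud",
    "read_depth_frame",
    "write_depth_frame",
    "back_project",
    "forward_project",
    "write_pcd",
    "write_ply",
]

#: maximum plausible depth (m); anything above is treated as malformed
MAX_DEPTH_M = 10.0


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of one depth camera.

    Defaults are Kinect-v2-like: 512 x 424 pixels, 365 px focal length,
    principal point at the image centre.
    """

    width: int = 512
    height: int = 424
    focal_x: float = 365.0
    focal_y: float = 365.0
    principal_x: float | None = None
    principal_y: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.focal_x <= 0 or self.focal_y <= 0:
            raise ValueError("focal lengths must be positive")
        if self.principal_x is None:
            object.__setattr__(self, "principal_x", (self.width - 1) / 2.0)
        if self.principal_y is None:
            object.__setattr__(self, "principal_y", (self.height - 1) / 2.0)

    @classmethod
    def half_resolution(cls) -> "CameraIntrinsics":
        """256 x 212 / focal 182.5: the default intrinsics scaled by 1/2."""
        return cls(width=256, height=212, focal_x=182.5, focal_y=182.5)

    @classmethod
    def wide_demo(cls) -> "CameraIntrinsics":
        """Wide-angle 256 x 212 / focal 140 used for the synthetic demo pen.

        With two ceiling cameras at 1.98 m this field of view covers the
        whole 4.02 x 2.36 m pen at standing-animal height, so tracking
        quality on synthetic scenes reflects the algorithms rather than
        geometric coverage gaps.
        """
        return cls(width=256, height=212, focal_x=140.0, focal_y=140.0)


@dataclass
class DepthFrame:
    """One timestamped depth raster from one camera.

    ``depth`` is a ``(height, width)`` float array in metres; 0 marks invalid
    pixels (no return from the sensor).
    """

    camera_id: str
    t: float
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.ndim != 2:
            raise ValueError("depth raster must be 2D")
        valid = self.depth > 0
        if np.any(self.depth[valid] > MAX_DEPTH_M):
            raise ValueError(f"depth values exceed {MAX_DEPTH_M} m")
        if np.any(~np.isfinite(self.depth)):
            raise ValueError("depth raster contains non-finite values")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.depth > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class PointCloud:
    """Unordered 3D points in camera coordinates (metres)."""

    points: np.ndarray
    camera_id: str | None = None
    t: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# File dialect: 16-bit single-channel PNG, millimetres, 0 = invalid.
# Filename pattern: <camera_id>_<epoch_ms>.png
# ---------------------------------------------------------------------------

_FILENAME_RE = re.compile(r"^(?P<camera_id>.+)_(?P<epoch_ms>\d+)\.png$")


def depth_frame_filename(frame: DepthFrame) -> str:
    return f"{frame.camera_id}_{int(round(frame.t * 1000))}.png"


def write_depth_frame(frame: DepthFrame, path: str | Path) -> Path:
    """Write a frame as 16-bit millimetre PNG.

    ``path`` may be a directory, in which case the canonical
    ``<camera_id>_<epoch_ms>.png`` name is used.
    """
    path = Path(path)
    if path.is_dir():
        path = path / depth_frame_filename(frame)
    mm = np.round(frame.depth * 1000.0)
    mm[frame.depth <= 0] = 0
    if np.any(mm > np.iinfo(np.uint16).max):
        raise ValueError("depth out of range for 16-bit millimetre encoding")
    img = Image.fromarray(mm.astype(np.uint16))
    img.save(path, format="PNG")
    return path


def read_depth_frame(
    path: str | Path,
    camera_id: str | None = None,
    t: float | None = None,
) -> DepthFrame:
    """Read a 16-bit millimetre PNG depth frame.

    Camera id and timestamp are parsed from the canonical filename when not
    given explicitly.
    """
    path = Path(path)
    if camera_id is None or t is None:
        m = _FILENAME_RE.match(path.name)
        if m is None:
            raise ValueError(
                f"cannot parse camera_id/timestamp from filename {path.name!r}; "
                "expected <camera_id>_<epoch_ms>.png"
            )
        camera_id = camera_id if camera_id is not None else m.group("camera_id")
        t = t if t is not None else int(m.group("epoch_ms")) / 1000.0
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"depth PNG must be single-channel, got shape {arr.shape}")
    if arr.dtype not in (np.uint16, np.int32, np.uint8):
        raise ValueError(f"depth PNG must be integer-typed, got dtype {arr.dtype}")
    depth = arr.astype(np.float64) / 1000.0
    return DepthFrame(camera_id=camera_id, t=t, depth=depth)


# ---------------------------------------------------------------------------
# Back projection
# ---------------------------------------------------------------------------

def back_project(frame: DepthFrame, intr: CameraIntrinsics) -> PointCloud:
    """Convert a depth raster to a 3D point cloud (one point per valid pixel).

    X = (u - cx) * d / fx,  Y = (v - cy) * d / fy,  Z = d.
    """
    h, w = frame.shape
    if (h, w) != (intr.height, intr.width):
        raise ValueError(
            f"raster shape {(h, w)} does not match intrinsics "
            f"{(intr.height, intr.width)}"
        )
    mask = frame.valid_mask
    v, u = np.nonzero(mask)
    d = frame.depth[v, u]
    x = (u - intr.principal_x) * d / intr.focal_x
    y = (v - intr.principal_y) * d / intr.focal_y
    pts = np.column_stack([x, y, d])
    return PointCloud(points=pts, camera_id=frame.camera_id, t=frame.t)


def forward_project(
    points: np.ndarray, intr: CameraIntrinsics
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project 3D camera-frame points to (u, v, depth) pixel coordinates.

    Inverse of :func:`back_project` on points in view; used for consistency
    checks and rendering.  Returns float pixel coordinates (not rounded).
    """
    pts = np.asarray(points, dtype=np.float64)
    z = pts[:, 2]
    if np.any(z <= 0):
        raise ValueError("points must have Z > 0 to project")
    u = pts[:, 0] * intr.focal_x / z + intr.principal_x
    v = pts[:, 1] * intr.focal_y / z + intr.principal_y
    return u, v, z


# ---------------------------------------------------------------------------
# Cloud export (ASCII PCD / PLY) for inspection
# ---------------------------------------------------------------------------

def write_pcd(cloud: PointCloud, path: str | Path) -> Path:
    path = Path(path)
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for x, y, z in cloud.points:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
    return path


def write_ply(cloud: PointCloud, path: str | Path) -> Path:
    path = Path(path)
    n = len(cloud)
    header = (
        "ply\nformat ascii 1.0\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\nend_header\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for x, y, z in cloud.points:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
    return path
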