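"""Point-cloud pre-processing: pen filtering, voxel downsampling, outlier
removal, and surface-normal estimation.

The four stages run in the order listed, each reducing (or preserving) the
point count.  Conventions are fixed so results reproduce bit-for-bit:

* Voxel cells are half-open ``[i*s, (i+1)*s)`` per axis, anchored at the
  coordinate origin; each occupied cell is replaced by the arithmetic
  centroid of its points.
* Outlier removal is a single pass: each point's mean distance to its k
  nearest neighbours (Euclidean, excluding itself) is compared with the
  grand mean and SD of these values; points above ``mean + sd_mult * sd``
  are dropped (one-sided by default, two-sided optionally).
* Normals come from the smallest-eigenvalue eigenvector of the
  radius-neighbourhood covariance, oriented toward the ceiling camera
  (nz <= 0); curvature is lambda_min / (lambda_0+lambda_1+lambda_2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .depth_geometry import PointCloud

__all__ = [
    "FilterParams",
    "NormalCloud",
    "filter_pen_region",
    "voxel_downsample",
    "remove_outliers",
    "estimate_normals",
    "preprocess",
]


@dataclass
class FilterParams:
    """Pre-processing parameters (defaults are the study's stated values)."""

    voxel_size: float = 0.02  # m
    knn_k: int = 50
    outlier_sd: float = 0.25  # SD multiplier
    normal_radius: float = 0.06  # m
    #: camera-frame axis-aligned region of interest (min_xyz, max_xyz)
    pen_bounds: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    two_sided_outliers: bool = False

    def __post_init__(self) -> None:
        if min(self.voxel_size, self.outlier_sd, self.normal_radius) <= 0:
            raise ValueError("filter parameters must be positive")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class NormalCloud:
    """Per-point unit surface normals + curvature, parallel to a PointCloud.

    ``defined`` flags points with at least 3 neighbours inside the radius;
    normals of undefined points are NaN.
    """

    normals: np.ndarray
    curvature: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.normals[self.defined], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("defined normals must be unit length")


def filter_pen_region(
    cloud: PointCloud,
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]],
) -> PointCloud:
    """Keep points strictly inside an axis-aligned camera-frame box.

    With a ceiling camera mounted perpendicular to the floor this removes
    floor, walls and gate returns by known coordinates, leaving only animal
    surfaces.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("bounds must satisfy min < max per axis")
    p = cloud.points
    keep = np.all((p > lo) & (p < hi), axis=1)
    return PointCloud(points=p[keep], camera_id=cloud.camera_id, t=cloud.t)


def voxel_downsample(cloud: PointCloud, voxel_size: float) -> PointCloud:
    """Replace the points of each occupied voxel by their centroid."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    p = cloud.points
    if len(p) == 0:
        return PointCloud(points=p, camera_id=cloud.camera_id, t=cloud.t)
    cells = np.floor(p / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(
        cells, axis=0, return_inverse=True, return_counts=True
    )
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inverse, p)
    centroids = sums / counts[:, None]
    return PointCloud(points=centroids, camera_id=cloud.camera_id, t=cloud.t)


def remove_outliers(cloud: PointCloud, k: int, sd_mult: float) -> PointCloud:
    """Statistical outlier removal by k-nearest-neighbour mean distance."""
    p = cloud.points
    if len(p) <= k:
        raise ValueError(f"cloud of {len(p)} points too small for k={k} neighbours")
    tree = cKDTree(p)
    # k+1 because the query point itself is its own nearest neighbour
    dists, _ = tree.query(p, k=k + 1)
    mean_dist = dists[:, 1:].mean(axis=1)
    mu = mean_dist.mean()
    sigma = mean_dist.std()
    keep = mean_dist <= mu + sd_mult * sigma
    return PointCloud(points=p[keep], camera_id=cloud.camera_id, t=cloud.t)


def remove_outliers_two_sided(cloud: PointCloud, k: int, sd_mult: float) -> PointCloud:
    """Variant removing both tails of the neighbour-distance distribution."""
    p = cloud.points
    if len(p) <= k:
        raise ValueError(f"cloud of {len(p)} points too small for k={k} neighbours")
    tree = cKDTree(p)
    dists, _ = tree.query(p, k=k + 1)
    mean_dist = dists[:, 1:].mean(axis=1)
    mu, sigma = mean_dist.mean(), mean_dist.std()
    keep = np.abs(mean_dist - mu) <= sd_mult * sigma
    return PointCloud(points=p[keep], camera_id=cloud.camera_id, t=cloud.t)


def estimate_normals(cloud: PointCloud, radius: float) -> NormalCloud:
    """Estimate unit surface normals and curvature in a fixed radius.

    Vectorised over the whole cloud: neighbour pairs within ``radius`` are
    accumulated into per-point first/second moments, the 3x3 covariances are
    eigendecomposed in batch, and the smallest-eigenvalue eigenvector is
    taken as the normal (flipped to nz <= 0, facing the overhead sensor).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    p = cloud.points
    n = len(p)
    normals = np.full((n, 3), np.nan)
    curvature = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    if n == 0:
        return NormalCloud(normals, curvature, defined)

    tree = cKDTree(p)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    # neighbourhood includes the point itself
    counts = np.ones(n)
    s1 = p.copy()  # sum of neighbour coordinates
    s2 = np.einsum("ni,nj->nij", p, p)  # sum of outer products
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(counts, i, 1.0)
        np.add.at(counts, j, 1.0)
        np.add.at(s1, i, p[j])
        np.add.at(s1, j, p[i])
        outer = np.einsum("ni,nj->nij", p, p)
        np.add.at(s2, i, outer[j])
        np.add.at(s2, j, outer[i])

    defined = counts >= 3
    if not np.any(defined):
        return NormalCloud(normals, curvature, defined)
    cnt = counts[defined][:, None, None]
    mean = s1[defined] / counts[defined][:, None]
    cov = s2[defined] / cnt - np.einsum("ni,nj->nij", mean, mean)
    # guard against tiny negative eigenvalues from cancellation
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    nrm = evecs[:, :, 0]  # eigenvector of the smallest eigenvalue
    flip = nrm[:, 2] > 0
    nrm[flip] *= -1.0
    lam_sum = evals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        curv = np.where(lam_sum > 0, evals[:, 0] / lam_sum, 0.0)
    # renormalise (eigh returns unit vectors, but be safe)
    nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
    normals[defined] = nrm
    curvature[defined] = curv
    return NormalCloud(normals, curvature, defined)


def preprocess(
    cloud: PointCloud, params: FilterParams
) -> tuple[PointCloud, NormalCloud]:
    """Run the four pre-processing stages in order."""
    if params.pen_bounds is not None:
        cloud = filter_pen_region(cloud, params.pen_bounds)
    cloud = voxel_downsample(cloud, params.voxel_size)
    if len(cloud) > params.knn_k:
        if params.two_sided_outliers:
            cloud = remove_outliers_two_sided(cloud, params.knn_k, params.outlier_sd)
        else:
            cloud = remove_outliers(cloud, params.knn_k, params.outlier_sd)
    normals = estimate_normals(cloud, params.normal_radius)
    return cloud, normals
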