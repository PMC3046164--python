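"""The occupancy-model family for numerosity estimation.

Occupancy models predict perceived numerosity from the area covered by the
union of disk-shaped "influence spheres" centred on the items — a combined
measure of spatial extent and density.  Implemented here are the
fixed-radius model (union area, one free parameter r), the density-adaptive
normalized variant, and the spatial-filtering route that computes occupancy
directly from a luminance frame.  The filtering route is the crux: on
contrast-defined (second-order) frames there are no luminance-defined items,
so it returns zero at every numerosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .geometry import BLACK, DisplayGeometry


@dataclass(frozen=True)
class PointSet:
    """Planar items (degrees), optionally with rectangular extents.

    ``points`` are item centres, shape (n, 2).  ``extents`` (optional,
    shape (n, 2)) gives each item's (width, height); point items have zero
    extent.  ``region`` is the (xmin, ymin, xmax, ymax) bounding area used
    for density; it defaults to the items' bounding box.
    """

    points: np.ndarray
    extents: np.ndarray | None = None
    region: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            raise ValueError("empty point set")
        if pts.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        object.__setattr__(self, "points", pts)
        if self.extents is not None:
            ext = np.atleast_2d(np.asarray(self.extents, dtype=float))
            if ext.shape != pts.shape:
                raise ValueError("extents must match points in shape")
            object.__setattr__(self, "extents", ext)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def half_extents(self) -> np.ndarray:
        if self.extents is None:
            return np.zeros_like(self.points)
        return self.extents / 2.0

    def region_bounds(self) -> tuple[float, float, float, float]:
        if self.region is not None:
            return self.region
        he = self.half_extents()
        lo = (self.points - he).min(axis=0)
        hi = (self.points + he).max(axis=0)
        return (float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1]))

    def region_area(self) -> float:
        x0, y0, x1, y1 = self.region_bounds()
        return (x1 - x0) * (y1 - y0)

    @classmethod
    def from_layout(cls, layout, region: tuple[float, float, float, float]
                    | None = None) -> "PointSet":
        """Bar centres and extents of a stimulus layout."""
        pts = np.array([b.center_deg for b in layout.bars])
        ext = np.array([[b.width_deg, b.height_deg] for b in layout.bars])
        return cls(points=pts, extents=ext, region=region)


@dataclass(frozen=True)
class OccupancyParams:
    """Fixed influence-sphere radius r (degrees) — the model's only free
    parameter."""

    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("influence-sphere radius must be positive")


def _default_radius_fn(r0: float, k: float) -> Callable[[float], float]:
    def radius(density: float) -> float:
        return r0 / (1.0 + k * density)
    return radius


@dataclass(frozen=True)
class DurginParams:
    """Density-adaptive variant: influence radius shrinks with item density
    and occupancy is normalized by the influence-sphere area, so n disjoint
    spheres score exactly n.

    ``radius_fn`` maps density (items/deg^2) to a radius; the default is
    r0 / (1 + k*d), monotone non-increasing and positive.
    """

    r0: float
    k: float = 1.0
    radius_fn: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("base radius must be positive")
        if self.radius_fn is None:
            object.__setattr__(self, "radius_fn",
                               _default_radius_fn(self.r0, self.k))

    def radius_at(self, density: float) -> float:
        r = self.radius_fn(density)
        if r <= 0:
            raise ValueError("radius_fn must stay positive")
        return r


# ---------------------------------------------------------------------------
# union area


def _coverage_mask(points: PointSet, r: float, xs: np.ndarray,
                   ys: np.ndarray) -> np.ndarray:
    """Boolean mask of grid points within distance r of any item.

    Items with extent use the distance to the rectangle (Minkowski sum of
    rectangle and disk), reducing to the disk for point items.
    """
    he = points.half_extents()
    covered = np.zeros((ys.size, xs.size), dtype=bool)
    X = xs[None, :]
    Y = ys[:, None]
    for (cx, cy), (hx, hy) in zip(points.points, he):
        dx = np.maximum(np.abs(X - cx) - hx, 0.0)
        dy = np.maximum(np.abs(Y - cy) - hy, 0.0)
        covered |= dx * dx + dy * dy <= r * r
    return covered


def union_disk_area(points: PointSet, r: float,
                    resolution: float = 0.02) -> float:
    """Area (deg^2) of the union of radius-r influence regions.

    Rasterizes the plane at ``resolution`` degrees per pixel (pixel-centre
    inclusion test) over the items' bounding box padded by r.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    he = points.half_extents()
    lo = (points.points - he).min(axis=0) - r - resolution
    hi = (points.points + he).max(axis=0) + r + resolution
    xs = np.arange(lo[0] + resolution / 2, hi[0], resolution)
    ys = np.arange(lo[1] + resolution / 2, hi[1], resolution)
    covered = _coverage_mask(points, r, xs, ys)
    return float(covered.sum()) * resolution ** 2


def union_disk_area_mc(points: PointSet, r: float,
                       n_samples: int = 1_000_000,
                       seed: int | np.random.Generator = 0) -> float:
    """Monte-Carlo estimate of the union area (independent of the raster
    route): uniform samples over the padded bounding box, hit fraction
    times box area."""
    if r <= 0:
        raise ValueError("radius must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    he = points.half_extents()
    lo = (points.points - he).min(axis=0) - r
    hi = (points.points + he).max(axis=0) + r
    samples = rng.uniform(lo, hi, size=(n_samples, 2))
    hit = np.zeros(n_samples, dtype=bool)
    for (cx, cy), (hx, hy) in zip(points.points, he):
        dx = np.maximum(np.abs(samples[:, 0] - cx) - hx, 0.0)
        dy = np.maximum(np.abs(samples[:, 1] - cy) - hy, 0.0)
        hit |= dx * dx + dy * dy <= r * r
    box_area = float(np.prod(hi - lo))
    return box_area * float(hit.mean())


def occupancy_estimate(points: PointSet, params: OccupancyParams,
                       resolution: float = 0.02) -> float:
    """Fixed-radius occupancy: the union area of the influence spheres."""
    return union_disk_area(points, params.r, resolution=resolution)


def density(points: PointSet) -> float:
    """Items per square degree over the point set's region."""
    area = points.region_area()
    if area <= 0:
        raise ValueError("region area must be positive for density")
    return points.n / area


def durgin_estimate(points: PointSet, params: DurginParams,
                    resolution: float = 0.02) -> float:
    """Density-adaptive normalized occupancy.

    Evaluates the influence radius at the set's density, computes the union
    area at that radius and divides by the single-sphere area pi*r^2; n
    disjoint spheres therefore score exactly n, n coincident ones score 1.
    """
    d = density(points)
    r = params.radius_at(d)
    return union_disk_area(points, r, resolution=resolution) / (np.pi * r * r)


# ---------------------------------------------------------------------------
# spatial-filtering route


def disk_kernel(radius_px: float) -> np.ndarray:
    """Binary disk of the given radius in pixels.

    Uses the pixel-extent convention (offsets with
    ``x^2 + y^2 <= (r + 1/2)^2``) so a coarse raster neither systematically
    under- nor over-covers the true disk.
    """
    k = int(np.ceil(radius_px))
    y, x = np.ogrid[-k:k + 1, -k:k + 1]
    return (x * x + y * y <= (radius_px + 0.5) ** 2).astype(float)


def filter_occupancy(frame: np.ndarray, params: OccupancyParams,
                     geometry: DisplayGeometry | None = None) -> float:
    """Occupancy of a luminance frame by spatial filtering (deg^2).

    Thresholds the frame at black to get the luminance-defined item mask,
    convolves it with a disk kernel of radius r and counts the strictly
    positive response area — equivalently, the area of the mask dilated by
    the disk.  An empty mask (e.g. any second-order frame, which contains
    no black texels) returns 0.
    """
    geometry = geometry or DisplayGeometry()
    mask = (np.asarray(frame) == BLACK)
    if not mask.any():
        return 0.0
    r_texels = params.r / geometry.texel_deg
    kernel = disk_kernel(r_texels)
    response = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    return float((response > 1e-9).sum()) * geometry.texel_area_deg2
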