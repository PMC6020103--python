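"""Per-crown structure metrics: maximum height H, projected crown area Ar
(2D convex hull of all crown points) and the equivalent crown radius
r = sqrt(Ar / pi).  These three numbers drive both the canopy-splitting
thresholds and the volume allometry.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import MultiPoint, Polygon

__all__ = ["crown_height", "crown_area", "crown_radius", "crown_hull"]


def crown_height(points) -> float:
    """Maximum point height H (m) of a crown point set (n x 3 or a z vector)."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point set has no height")
    z = pts[:, 2] if pts.ndim == 2 else pts
    return float(z.max())


def crown_hull(points):
    """2D convex hull (shapely geometry) of the xy projection of the crown.

    Degenerate sets (single point, collinear) yield a Point/LineString with
    zero area rather than an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("need an (n, >=2) point array")
    return MultiPoint(pts[:, :2]).convex_hull


def crown_area(points) -> float:
    """Projected crown area Ar (m^2): area of the 2D convex hull."""
    return float(crown_hull(points).area)


def crown_radius(Ar: float) -> float:
    """Equivalent crown radius r = sqrt(Ar / pi), in metres."""
    if Ar < 0:
        raise ValueError("crown area cannot be negative")
    return float(np.sqrt(Ar / np.pi))


def hull_polygon_coords(hull) -> list:
    """Exterior ring coordinates of a hull, or a degenerate ring for
    sub-2D hulls (used when serialising crowns to GeoJSON)."""
    if isinstance(hull, Polygon):
        return [list(c) for c in hull.exterior.coords]
    return [list(c) for c in hull.coords]
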