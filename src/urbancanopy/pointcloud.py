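"""Point-cloud container and the pre-clustering filters.

An airborne-LiDAR tile is held as flat numpy arrays.  Two pointwise filters
prepare a height-normalised cloud for crown clustering:

* drop low returns (``z <= z_min``, default 1 m), removing ground and street
  clutter;
* keep only returns whose emitting pulse produced more than one return.
  Vegetation is porous to the laser pulse and typically yields several
  returns per pulse, whereas buildings and other hard surfaces backscatter
  a single return, so this removes most built structure.

Both predicates act point-by-point, so they are idempotent and commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lasio

__all__ = ["PointCloud", "read_point_cloud", "write_point_cloud",
           "normalize_heights", "filter_low_points",
           "filter_single_return_points"]


@dataclass
class PointCloud:
    """LiDAR returns in a projected CRS, optionally height-normalised.

    Parameters
    ----------
    x, y : ndarray
        Easting/northing in metres.
    z : ndarray
        Elevation, or height above ground once ``normalized`` is set.
    number_of_returns : ndarray
        Returns recorded for the emitting pulse (>= 1).
    return_number : ndarray, optional
        Index of each return within its pulse.
    crs : str, optional
        Opaque CRS identifier; carried through, never interpreted.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    number_of_returns: np.ndarray
    return_number: np.ndarray | None = None
    classification: np.ndarray | None = None
    crs: str | None = None
    normalized: bool = False

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        self.number_of_returns = np.asarray(self.number_of_returns)
        if self.return_number is not None:
            self.return_number = np.asarray(self.return_number)
        if self.classification is not None:
            self.classification = np.asarray(self.classification)
        n = self.x.size
        for name in ("y", "z", "number_of_returns"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length {getattr(self, name).size} "
                                 f"!= x length {n}")
        if n:
            if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                    and np.isfinite(self.z).all()):
                raise ValueError("non-finite coordinates")
            if (self.number_of_returns < 1).any():
                raise ValueError("number_of_returns must be >= 1")
            if self.return_number is not None:
                rn = np.asarray(self.return_number)
                if ((rn < 1) | (rn > self.number_of_returns)).any():
                    raise ValueError("return_number out of [1, number_of_returns]")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) coordinate array."""
        return np.column_stack([self.x, self.y, self.z])

    def select(self, mask) -> "PointCloud":
        """New cloud containing the points where ``mask`` is true."""
        return PointCloud(
            self.x[mask], self.y[mask], self.z[mask],
            self.number_of_returns[mask],
            None if self.return_number is None else self.return_number[mask],
            None if self.classification is None else self.classification[mask],
            crs=self.crs, normalized=self.normalized)


def read_point_cloud(path, crs: str | None = None,
                     normalized: bool = False) -> PointCloud:
    """Load a .las tile (see :mod:`urbancanopy.lasio` for the dialect)."""
    arrays = lasio.read_las(path)
    return PointCloud(arrays["x"], arrays["y"], arrays["z"],
                      arrays["number_of_returns"], arrays["return_number"],
                      arrays["classification"], crs=crs, normalized=normalized)


def write_point_cloud(cloud: PointCloud, path, scale: float = 0.001) -> None:
    """Write ``cloud`` to LAS 1.2 / point format 0."""
    lasio.write_las(path, cloud.x, cloud.y, cloud.z, cloud.number_of_returns,
                    cloud.return_number, cloud.classification, scale=scale)


def normalize_heights(cloud: PointCloud, cell: float = 1.0) -> PointCloud:
    """Grid-minimum height normalisation.

    Subtracts, per ``cell`` x ``cell`` metre column, the minimum z from every
    point in that column.  A deliberately simple normaliser adequate for
    synthetic scenes and gently sloping ground; operational tiles are
    expected to arrive already normalised to height above ground.
    """
    if len(cloud) == 0:
        out = cloud.select(np.zeros(0, dtype=bool))
        out.normalized = True
        return out
    ix = np.floor(cloud.x / cell).astype(np.int64)
    iy = np.floor(cloud.y / cell).astype(np.int64)
    # dense per-cell minimum via lexicographic grouping
    keys = np.stack([ix, iy], axis=1)
    order = np.lexsort((iy, ix))
    sk = keys[order]
    new_group = np.ones(len(order), dtype=bool)
    new_group[1:] = (sk[1:] != sk[:-1]).any(axis=1)
    group_id = np.cumsum(new_group) - 1
    zmin = np.full(group_id[-1] + 1, np.inf)
    np.minimum.at(zmin, group_id, cloud.z[order])
    z_new = np.empty_like(cloud.z)
    z_new[order] = cloud.z[order] - zmin[group_id]
    out = PointCloud(cloud.x.copy(), cloud.y.copy(), z_new,
                     cloud.number_of_returns.copy(),
                     None if cloud.return_number is None else cloud.return_number.copy(),
                     None if cloud.classification is None else cloud.classification.copy(),
                     crs=cloud.crs, normalized=True)
    return out


def filter_low_points(cloud: PointCloud, z_min: float = 1.0) -> PointCloud:
    """Remove ground and low returns: keeps exactly the points with z > z_min."""
    if not cloud.normalized:
        raise ValueError("cloud must be height-normalised before low-point "
                         "filtering (z must mean height above ground)")
    return cloud.select(cloud.z > z_min)


def filter_single_return_points(cloud: PointCloud,
                                field: str = "number_of_returns"
                                ) -> PointCloud:
    """Keep only returns from pulses with more than one return.

    Hard surfaces (roofs, roads) backscatter a single return; vegetation
    usually produces several, so this discards most buildings.  The test
    targets the per-pulse return count ("Number of Returns"); because some
    datasets swap that field with "Return Number", ``field`` may be set to
    ``"return_number"`` to filter on the other dimension instead.
    """
    if field == "number_of_returns":
        values = cloud.number_of_returns
    elif field == "return_number":
        values = cloud.return_number
    else:
        raise ValueError(f"unknown return field {field!r}")
    if values is None:
        raise ValueError(f"{field} metafield missing")
    return cloud.select(np.asarray(values) > 1)
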