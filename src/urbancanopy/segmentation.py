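"""Two-stage individual tree detection from airborne LiDAR.

Stage one clusters the filtered point cloud with DBSCAN in 3D; each
density-connected component is a candidate crown or, where neighbouring
crowns touch, a merged canopy.  Stage two tests every cluster against an
allometric width bound — a crown whose equivalent radius exceeds the upper
95% prediction bound for its height (``beta + alpha*H < r``) is treated as a
canopy and split by radius-threshold hierarchical clustering (BIRCH) on the
xy plane, with the threshold ``B_t = beta + alpha*H`` taken from the mean
height->radius regression.  Splitting recurses until no subcluster exceeds
the width bound.  A final cleaning pass removes implausible and duplicate
crowns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point as ShapelyPoint
from sklearn.cluster import DBSCAN, Birch

from .allometry import ThresholdModel
from .metrics import crown_area, crown_height, crown_hull, crown_radius, \
    hull_polygon_coords
from .pointcloud import PointCloud, filter_low_points, \
    filter_single_return_points

__all__ = ["SegmentationParams", "Cluster", "CrownSet", "cluster_density",
           "needs_split", "split_canopy", "segment_trees", "clean_crowns",
           "crowns_to_geojson"]


@dataclass
class SegmentationParams:
    """Parameters of the two-stage ITD algorithm.

    ``eps`` (m) and ``min_samples`` control the DBSCAN stage; the defaults
    (3.5 m, 20 points) suit ~2 pulses m^-2 airborne capture, where the eps
    disc covers roughly 38 m^2.  ``split_model`` is the 95%-prediction-bound
    line deciding which clusters are merged canopies; ``bt_model`` the mean
    height->radius line supplying the BIRCH radius threshold.
    """

    split_model: ThresholdModel
    bt_model: ThresholdModel
    eps: float = 3.5
    min_samples: int = 20
    min_subcluster_points: int = 5
    max_iterations: int = 20
    min_polygon_area: float = 10.0
    max_crown_height: float = 50.0
    duplicate_iou: float = 0.7

    def __post_init__(self):
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.min_polygon_area < 0:
            raise ValueError("min_polygon_area must be >= 0")
        if not 0 < self.duplicate_iou <= 1:
            raise ValueError("duplicate_iou must be in (0, 1]")

    @classmethod
    def from_file(cls, path, split_model: ThresholdModel,
                  bt_model: ThresholdModel) -> "SegmentationParams":
        """Load numeric parameters from a flat ``key = value`` text file;
        the threshold lines are supplied separately (they are fitted
        models, not scalars)."""
        numeric = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                numeric[key.strip()] = float(value)
        ints = {"min_samples", "min_subcluster_points", "max_iterations"}
        kwargs = {k: (int(v) if k in ints else v) for k, v in numeric.items()}
        return cls(split_model=split_model, bt_model=bt_model, **kwargs)


class Cluster:
    """A detected crown (or canopy): member points plus derived metrics."""

    def __init__(self, points: np.ndarray, id: int | None = None,
                 non_convergent: bool = False):
        self.points = np.asarray(points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] < 3:
            raise ValueError("cluster points must be (n, 3)")
        self.id = id
        self.non_convergent = non_convergent
        self.H = crown_height(self.points)
        self.hull = crown_hull(self.points)
        self.Ar = float(self.hull.area)
        self.r = crown_radius(self.Ar)
        c = self.hull.centroid
        self.centroid = (float(c.x), float(c.y))
        # attached later by the biomass stage
        self.V: float | None = None
        self.agb: float | None = None
        self.agb_sd: float | None = None

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def __repr__(self):
        return (f"Cluster(n={self.n_points}, H={self.H:.1f} m, "
                f"Ar={self.Ar:.1f} m2)")


@dataclass
class CrownSet:
    """Final set of detected crowns plus processing provenance."""

    crowns: list
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.crowns)

    def __iter__(self):
        return iter(self.crowns)

    def total_points(self) -> int:
        return sum(c.n_points for c in self.crowns)


def cluster_density(cloud: PointCloud, eps: float = 3.5,
                    min_samples: int = 20):
    """DBSCAN over (x, y, z) in metres.

    Returns ``(clusters, noise)``: the density-connected components as
    :class:`Cluster` objects (each with at least ``min_samples`` members)
    and the unclustered points as a :class:`PointCloud`.
    """
    if len(cloud) == 0:
        return [], cloud.select(np.zeros(0, dtype=bool))
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(cloud.xyz)
    clusters = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        clusters.append(Cluster(cloud.xyz[labels == lab], id=int(lab)))
    noise = cloud.select(labels == -1)
    return clusters, noise


def needs_split(cluster: Cluster, split_model: ThresholdModel) -> bool:
    """True iff the crown is wider than the allometric bound for its height:
    ``beta + alpha*H < r`` (strict)."""
    return float(split_model.predict(cluster.H)) < cluster.r


def _birch_partition(xy: np.ndarray, threshold: float,
                     min_points: int) -> tuple[list[np.ndarray], np.ndarray]:
    """One double-run BIRCH pass: first unconstrained by cluster count to
    discover how many crowns the radius threshold supports, then re-run with
    that count fixed for a refined (centroid-merged) partition.

    Returns (index arrays per subcluster, dropped-point index array).
    """
    b1 = Birch(threshold=threshold, n_clusters=None).fit(xy)
    k = b1.subcluster_centers_.shape[0]
    if k <= 1:
        return [np.arange(len(xy))], np.array([], dtype=int)
    labels = Birch(threshold=threshold, n_clusters=k).fit_predict(xy)
    groups, dropped = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_points:
            dropped.append(idx)
        else:
            groups.append(idx)
    dropped = (np.concatenate(dropped) if dropped
               else np.array([], dtype=int))
    if not groups:       # everything sub-minimal: keep input intact
        return [np.arange(len(xy))], np.array([], dtype=int)
    return groups, dropped


def split_canopy(cluster: Cluster, bt_model: ThresholdModel,
                 split_model: ThresholdModel,
                 params: SegmentationParams):
    """Iteratively divide a merged canopy into individual crowns.

    Per iteration, every cluster still exceeding the width bound is
    partitioned by BIRCH on its xy coordinates with radius threshold
    ``B_t = beta + alpha*H`` recomputed from that cluster's height; height,
    area and radius are recomputed per subcluster and the bound re-applied.
    The loop ends when no subcluster exceeds the bound, or after
    ``max_iterations`` (survivors are flagged ``non_convergent``).
    Subclusters below ``min_subcluster_points`` are discarded.

    Returns ``(crowns, dropped_points)``; the crown point sets are disjoint
    subsets of the input.
    """
    if not needs_split(cluster, split_model):
        return [cluster], np.empty((0, 3))
    done: list[Cluster] = []
    active = [cluster]
    dropped_parts: list[np.ndarray] = []
    for _ in range(params.max_iterations):
        if not active:
            break
        next_active: list[Cluster] = []
        for c in active:
            bt = max(float(bt_model.predict(c.H)), 1e-6)
            groups, dropped = _birch_partition(
                c.points[:, :2], bt, params.min_subcluster_points)
            if len(groups) == 1 and dropped.size == 0:
                # radius threshold cannot divide this cluster further
                done.append(Cluster(c.points, id=c.id, non_convergent=True))
                continue
            if dropped.size:
                dropped_parts.append(c.points[dropped])
            for idx in groups:
                sub = Cluster(c.points[idx], id=c.id)
                if needs_split(sub, split_model):
                    next_active.append(sub)
                else:
                    done.append(sub)
        active = next_active
    if active:
        warnings.warn("canopy splitting hit max_iterations before all "
                      "subclusters satisfied the width bound")
        done.extend(Cluster(c.points, id=c.id, non_convergent=True)
                    for c in active)
    dropped_points = (np.concatenate(dropped_parts) if dropped_parts
                      else np.empty((0, 3)))
    return done, dropped_points


def clean_crowns(crown_set: CrownSet, params: SegmentationParams) -> CrownSet:
    """Remove implausible and duplicate crowns.

    Drops crowns with hull area below ``min_polygon_area`` (building-edge
    slivers), crowns taller than ``max_crown_height`` (cranes, aerials), and
    for pairs whose hull intersection-over-union reaches ``duplicate_iou``
    (vertically offset duplicates) keeps the crown with more points (ties:
    greater height).
    """
    crowns = [c for c in crown_set.crowns
              if c.Ar >= params.min_polygon_area
              and c.H <= params.max_crown_height]
    # duplicate suppression, better-supported crown first
    order = sorted(range(len(crowns)),
                   key=lambda i: (-crowns[i].n_points, -crowns[i].H))
    keep: list[int] = []
    for i in order:
        ci = crowns[i]
        dup = False
        for j in keep:
            cj = crowns[j]
            inter = ci.hull.intersection(cj.hull).area
            if inter <= 0:
                continue
            union = ci.hull.union(cj.hull).area
            if union > 0 and inter / union >= params.duplicate_iou:
                dup = True
                break
        if not dup:
            keep.append(i)
    kept = [crowns[i] for i in sorted(keep)]
    for new_id, c in enumerate(kept):
        c.id = new_id
    return CrownSet(kept, provenance=dict(crown_set.provenance))


def segment_trees(cloud: PointCloud, params: SegmentationParams) -> CrownSet:
    """Full ITD chain: return filter -> low filter -> DBSCAN -> canopy
    splitting -> cleaning.

    The input must be height-normalised.  Provenance records the parameters
    and the point bookkeeping (filtered, noise, dropped counts).
    """
    n_input = len(cloud)
    veg = filter_single_return_points(cloud)
    veg = filter_low_points(veg)
    clusters, noise = cluster_density(veg, params.eps, params.min_samples)
    crowns: list[Cluster] = []
    n_dropped = 0
    for c in clusters:
        subs, dropped = split_canopy(c, params.bt_model, params.split_model,
                                     params)
        crowns.extend(subs)
        n_dropped += len(dropped)
    raw = CrownSet(crowns, provenance={
        "eps": params.eps, "min_samples": params.min_samples,
        "split_model": params.split_model.to_dict(),
        "bt_model": params.bt_model.to_dict(),
        "n_input_points": n_input,
        "n_filtered_out": n_input - len(veg),
        "n_noise_points": len(noise),
        "n_dropped_subcluster_points": n_dropped,
    })
    cleaned = clean_crowns(raw, params)
    cleaned.provenance["n_crowns_before_cleaning"] = len(raw)
    return cleaned


def crowns_to_geojson(crown_set: CrownSet, path=None, crs: str | None = None
                      ) -> dict:
    """Serialize crowns as a GeoJSON FeatureCollection of 2D hull polygons
    with {id, H_m, Ar_m2, r_m, n_points} (+ V_m3/AGB_Mg when attached)."""
    import json
    features = []
    for c in crown_set:
        props = {"id": c.id, "H_m": round(c.H, 3), "Ar_m2": round(c.Ar, 3),
                 "r_m": round(c.r, 3), "n_points": c.n_points}
        if c.V is not None:
            props["V_m3"] = round(c.V, 4)
        if c.agb is not None:
            props["AGB_Mg"] = round(c.agb, 5)
        if c.agb_sd is not None:
            props["AGB_sd_Mg"] = round(c.agb_sd, 5)
        ring = hull_polygon_coords(c.hull)
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": props,
        })
    fc = {"type": "FeatureCollection", "features": features}
    if crs:
        fc["crs"] = {"type": "name", "properties": {"name": crs}}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
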