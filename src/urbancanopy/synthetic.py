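"""Synthetic urban scenes with known ground truth.

The generator emulates the situation the pipeline is built for: a
height-normalised airborne-LiDAR capture (~2 pulses m^-2) over a patchwork
of trees, buildings and open ground, plus TLS-style QSM-tree tables.  Trees
follow configurable allometric laws —

* crown radius  ``r = beta + alpha * H + N(0, radius_sd)``
* woody volume  ``V = k_Ar * (pi r^2) + k_exp * a * b**H``, with
  multiplicative lognormal noise of coefficient of variation ``noise_cv``

— so that segmentation thresholds and the volume allometry have a known
generating truth to recover.  Crown points are sampled on the crown
envelope (airborne LiDAR mostly sees the canopy surface), vegetation pulses
yield multiple returns, buildings return single echoes except for an
optional edge-noise fraction, and ground sits at z ~ 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pointcloud import PointCloud

__all__ = ["AllometricParams", "TreeSpec", "Building", "SceneSpec",
           "SceneTruth", "generate_tree_population", "layout_positions",
           "render_scene", "make_qsm_table", "match_crowns"]


@dataclass
class AllometricParams:
    """Generating laws for a synthetic tree population.

    Defaults give heights to ~35 m and crown areas to a few hundred m^2,
    the observed envelope of a mixed urban tree stock, with volumes of a
    few tens of m^3 for the largest trees.
    """

    alpha: float = 0.15        # radius slope (m per m height)
    beta: float = 1.0          # radius intercept (m)
    radius_sd: float = 2.0     # within-height radius scatter (m); urban
                               # crowns of similar height differ severalfold
                               # in area between street and woodland settings
    k_Ar: float = 0.05         # volume per crown area (m^3 per m^2)
    k_exp: float = 1.0         # weight of the exponential height term
    a: float = 0.08            # exponential scale (m^3)
    b: float = 1.17            # exponential base (per m height)
    noise_cv: float = 0.10     # multiplicative volume noise
    height_range: tuple = (5.0, 35.0)

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("exponential parameters must be positive")
        if self.radius_sd < 0 or self.noise_cv < 0:
            raise ValueError("noise levels must be >= 0")
        lo, hi = self.height_range
        if not 0 < lo < hi:
            raise ValueError("invalid height range")


@dataclass
class TreeSpec:
    id: int
    x: float
    y: float
    H: float
    crown_radius: float
    crown_base: float
    shape: str = "ellipsoid"
    species: str = "Platanus x acerifolia"
    wood_density: float = 560.0     # kg m^-3
    V_true: float = 1.0

    def __post_init__(self):
        if not (self.H > self.crown_base >= 0):
            raise ValueError("need H > crown_base >= 0")
        if self.crown_radius <= 0 or self.V_true <= 0:
            raise ValueError("crown_radius and V_true must be positive")

    @property
    def Ar_true(self) -> float:
        return float(np.pi * self.crown_radius ** 2)

    @property
    def agb_true(self) -> float:
        return self.V_true * self.wood_density / 1000.0


@dataclass
class Building:
    x0: float
    y0: float
    x1: float
    y1: float
    height: float


@dataclass
class SceneSpec:
    extent: tuple                     # (xmax, ymax) metres
    trees: list = field(default_factory=list)
    buildings: list = field(default_factory=list)
    pulse_density: float = 2.0        # pulses m^-2
    veg_multireturn_prob: float = 1.0
    edge_noise_prob: float = 0.0
    ground: bool = True
    volumetric_crowns: bool = False   # sample within crowns, not on surface
    seed: int | None = None

    def __post_init__(self):
        if self.pulse_density <= 0:
            raise ValueError("pulse_density must be positive")
        for p in (self.veg_multireturn_prob, self.edge_noise_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class SceneTruth:
    """Per-point provenance labels and per-tree truth.

    ``labels``: tree id >= 0, ``-1`` ground, ``-2`` building.
    ``trees``: DataFrame of id, x, y, H, Ar_true, V_true, agb_true.
    ``counts``: generator bookkeeping (points emitted per class).
    """

    labels: np.ndarray
    trees: pd.DataFrame
    counts: dict


def generate_tree_population(n: int, params: AllometricParams | None = None,
                             seed: int | None = None) -> list[TreeSpec]:
    """Draw ``n`` trees from the configured allometric laws.

    Positions are initialised at the origin; use :func:`layout_positions`
    or set them when building a :class:`SceneSpec`.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    params = params or AllometricParams()
    rng = np.random.default_rng(seed)
    lo, hi = params.height_range
    trees = []
    for i in range(n):
        H = float(rng.uniform(lo, hi))
        r = params.beta + params.alpha * H
        if params.radius_sd > 0:
            r += float(rng.normal(0.0, params.radius_sd))
        r = max(r, 0.5)
        Ar = np.pi * r * r
        V = params.k_Ar * Ar + params.k_exp * params.a * params.b ** H
        if params.noise_cv > 0:
            sigma = np.sqrt(np.log1p(params.noise_cv ** 2))
            V *= float(rng.lognormal(-0.5 * sigma ** 2, sigma))
        base = max(2.0, 0.25 * H)
        trees.append(TreeSpec(id=i, x=0.0, y=0.0, H=H, crown_radius=r,
                              crown_base=base, V_true=float(V)))
    return trees


def layout_positions(trees: list[TreeSpec], spacing: float,
                     jitter: float = 0.0, seed: int | None = None,
                     origin: tuple = (0.0, 0.0)) -> list[TreeSpec]:
    """Place trees on a square grid of the given stem ``spacing`` (m),
    optionally jittered; returns the same TreeSpec objects, repositioned."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(len(trees))))
    for k, t in enumerate(trees):
        i, j = divmod(k, side)
        t.x = origin[0] + spacing * (j + 0.5)
        t.y = origin[1] + spacing * (i + 0.5)
        if jitter > 0:
            t.x += float(rng.uniform(-jitter, jitter))
            t.y += float(rng.uniform(-jitter, jitter))
    return trees


def _sample_crown_surface(tree: TreeSpec, n: int,
                          rng: np.random.Generator,
                          volumetric: bool = False) -> np.ndarray:
    """Points on (or, with ``volumetric``, within) the crown envelope of a
    tree (ellipsoid or cone)."""
    if n == 0:
        return np.empty((0, 3))
    if volumetric and tree.shape != "cone":
        cz = 0.5 * (tree.crown_base + tree.H)
        sz = 0.5 * (tree.H - tree.crown_base)
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        d *= rng.uniform(0.0, 1.0, (n, 1)) ** (1.0 / 3.0)
        return np.column_stack([tree.x + tree.crown_radius * d[:, 0],
                                tree.y + tree.crown_radius * d[:, 1],
                                cz + sz * d[:, 2]])
    cz = 0.5 * (tree.crown_base + tree.H)
    sz = 0.5 * (tree.H - tree.crown_base)
    if tree.shape == "cone":
        # lateral surface of a cone, apex at H
        u = rng.uniform(0.0, 1.0, n)
        h = tree.crown_base + (tree.H - tree.crown_base) * (1 - np.sqrt(u))
        frac = (tree.H - h) / (tree.H - tree.crown_base)
        rad = tree.crown_radius * frac
        theta = rng.uniform(0.0, 2 * np.pi, n)
        return np.column_stack([tree.x + rad * np.cos(theta),
                                tree.y + rad * np.sin(theta), h])
    # ellipsoid: gaussian direction -> unit sphere -> scale semi-axes
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return np.column_stack([tree.x + tree.crown_radius * d[:, 0],
                            tree.y + tree.crown_radius * d[:, 1],
                            cz + sz * d[:, 2]])


def render_scene(spec: SceneSpec) -> tuple[PointCloud, SceneTruth]:
    """Simulate the airborne capture of a scene.

    Pulse counts per surface are Poisson at ``pulse_density`` times the
    footprint area.  Vegetation pulses produce two returns (surface echo
    plus a lower within-crown echo) with probability
    ``veg_multireturn_prob``, else one; building and ground pulses produce
    single returns, except an ``edge_noise_prob`` fraction of building
    points marked multi-return to emulate edge artefacts.
    """
    rng = np.random.default_rng(spec.seed)
    xs, ys, zs, nor, rn, labels = [], [], [], [], [], []
    counts = {"ground": 0, "building": 0}

    def emit(pts, n_returns, return_no, label):
        if len(pts) == 0:
            return
        xs.append(pts[:, 0]); ys.append(pts[:, 1]); zs.append(pts[:, 2])
        nor.append(n_returns); rn.append(return_no)
        labels.append(np.full(len(pts), label, dtype=np.int64))

    ex, ey = spec.extent
    if spec.ground:
        n_ground = rng.poisson(spec.pulse_density * ex * ey)
        pts = np.column_stack([rng.uniform(0, ex, n_ground),
                               rng.uniform(0, ey, n_ground),
                               np.abs(rng.normal(0.0, 0.03, n_ground))])
        emit(pts, np.ones(n_ground, dtype=np.int16),
             np.ones(n_ground, dtype=np.int16), -1)
        counts["ground"] = int(n_ground)

    for b in spec.buildings:
        area = max((b.x1 - b.x0) * (b.y1 - b.y0), 0.0)
        n_roof = rng.poisson(spec.pulse_density * area)
        pts = np.column_stack([rng.uniform(b.x0, b.x1, n_roof),
                               rng.uniform(b.y0, b.y1, n_roof),
                               b.height + rng.normal(0.0, 0.05, n_roof)])
        n_ret = np.ones(n_roof, dtype=np.int16)
        if spec.edge_noise_prob > 0:
            n_ret[rng.uniform(size=n_roof) < spec.edge_noise_prob] = 2
        emit(pts, n_ret, np.ones(n_roof, dtype=np.int16), -2)
        counts["building"] += int(n_roof)

    for t in spec.trees:
        n_pulses = rng.poisson(spec.pulse_density * t.Ar_true)
        first = _sample_crown_surface(t, n_pulses, rng,
                                      volumetric=spec.volumetric_crowns)
        multi = rng.uniform(size=n_pulses) < spec.veg_multireturn_prob
        n_ret = np.where(multi, 2, 1).astype(np.int16)
        emit(first, n_ret, np.ones(n_pulses, dtype=np.int16), t.id)
        # second (lower) return of multi-return pulses, inside the crown
        sec = first[multi].copy()
        if len(sec):
            sec[:, 2] = rng.uniform(t.crown_base, np.maximum(
                sec[:, 2], t.crown_base + 1e-6))
            emit(sec, np.full(len(sec), 2, dtype=np.int16),
                 np.full(len(sec), 2, dtype=np.int16), t.id)
        # sparse stem echoes below the crown
        n_stem = rng.poisson(1.0)
        if n_stem:
            stem = np.column_stack([
                t.x + rng.normal(0, 0.1, n_stem),
                t.y + rng.normal(0, 0.1, n_stem),
                rng.uniform(1.2, t.crown_base, n_stem)])
            emit(stem, np.full(n_stem, 2, dtype=np.int16),
                 np.full(n_stem, 2, dtype=np.int16), t.id)
        counts[t.id] = int(n_pulses + multi.sum() + n_stem)

    if xs:
        cloud = PointCloud(np.concatenate(xs), np.concatenate(ys),
                           np.concatenate(zs), np.concatenate(nor),
                           np.concatenate(rn), normalized=True)
        label_arr = np.concatenate(labels)
    else:
        cloud = PointCloud(np.empty(0), np.empty(0), np.empty(0),
                           np.empty(0, dtype=np.int16), normalized=True)
        label_arr = np.empty(0, dtype=np.int64)
    truth_df = pd.DataFrame([{
        "id": t.id, "x": t.x, "y": t.y, "H": t.H,
        "Ar_true": t.Ar_true, "V_true": t.V_true, "agb_true": t.agb_true,
    } for t in spec.trees])
    return cloud, SceneTruth(labels=label_arr, trees=truth_df, counts=counts)


def make_qsm_table(trees: list[TreeSpec], recon_cv: float = 0.03,
                   seed: int | None = None, site: str = "synthetic",
                   n_recon: int = 10) -> pd.DataFrame:
    """TLS-style QSM table: per tree, ``n_recon`` reconstruction volumes
    drawn Gaussian around the true volume with relative sd ``recon_cv``.

    dbh is synthesised from volume through a monotone power law
    (``dbh = 0.1 * V^0.4``), standing in for the stem-taper relation; it is
    reported but never used as a predictor.
    """
    if recon_cv < 0:
        raise ValueError("recon_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for t in trees:
        vols = t.V_true + rng.normal(0.0, recon_cv * t.V_true, n_recon)
        vols = np.maximum(vols, 1e-6)
        row = {"id": f"{site}-{t.id}", "site": site,
               "dbh_m": 0.1 * t.V_true ** 0.4, "h_m": t.H,
               "ar_m2": t.Ar_true}
        row.update({f"vol_{i+1}": vols[i] for i in range(n_recon)})
        row["species"] = t.species
        row["wood_density"] = t.wood_density
        rows.append(row)
    return pd.DataFrame(rows)


def calibration_thresholds(seed: int | None = None, n: int = 99,
                           params: AllometricParams | None = None):
    """Fit the canopy-splitting threshold lines the honest way: from a
    synthetic QSM-tree table drawn from the same allometric laws, exactly
    as TLS calibration would supply them.  Returns ``(split_95pi,
    bt_mean)`` threshold models."""
    from .allometry import fit_threshold_model, qsm_trees_from_dataframe
    trees = generate_tree_population(n, params, seed=seed)
    table = make_qsm_table(trees, seed=None if seed is None else seed + 1)
    qsm = qsm_trees_from_dataframe(table)
    return (fit_threshold_model(qsm, "split_95pi"),
            fit_threshold_model(qsm, "bt_mean"))


def well_separated_scene(n_trees: int = 50, spacing: float = 14.0,
                         seed: int = 0, height_range: tuple = (12.0, 18.0),
                         radius_sd: float = 0.25):
    """Benchmark scene of isolated trees on a jittered grid.

    Stem spacing (default 14 m) exceeds twice the largest crown radius plus
    the clustering neighbourhood, so every tree forms its own density
    cluster; the radius scatter is kept small (0.25 m) for the same
    reason.  Returns ``(cloud, truth)``.
    """
    params = AllometricParams(height_range=height_range, radius_sd=radius_sd)
    trees = generate_tree_population(n_trees, params, seed=seed)
    layout_positions(trees, spacing, jitter=0.5, seed=seed + 1)
    side = spacing * int(np.ceil(np.sqrt(max(n_trees, 1))))
    spec = SceneSpec(extent=(side, side), trees=trees, seed=seed + 2)
    return render_scene(spec)


def merged_pair_scene(seed: int = 0, separation: float = 8.0):
    """Scene of two equal-height trees close enough that their crowns
    density-connect into one canopy; ground truth for the splitting stage.
    Returns ``(cloud, truth)``."""
    rng = np.random.default_rng(seed)
    H = float(rng.uniform(13.0, 17.0))
    r = 1.0 + 0.15 * H
    base = max(2.0, 0.25 * H)
    trees = [TreeSpec(id=0, x=30.0, y=30.0, H=H, crown_radius=r,
                      crown_base=base, V_true=5.0),
             TreeSpec(id=1, x=30.0 + separation, y=30.0, H=H, crown_radius=r,
                      crown_base=base, V_true=5.0)]
    spec = SceneSpec(extent=(60.0 + separation, 60.0), trees=trees,
                     seed=seed + 500)
    return render_scene(spec)


def match_crowns(truth, detected, max_dist: float = 2.0) -> dict:
    """Greedy one-to-one matching of detected crowns to true stems.

    ``truth`` is a :class:`SceneTruth` or a DataFrame with columns
    x, y, H, Ar_true.  Returns precision, recall, f1, the detected/true
    crown-area ratio and the mean height bias over matches.  With no
    detections precision is reported as 0 with ``undefined_precision``
    flagged.
    """
    tdf = truth.trees if isinstance(truth, SceneTruth) else truth
    det = list(detected)
    n_truth, n_det = len(tdf), len(det)
    pairs = []
    for di, c in enumerate(det):
        dx = tdf["x"].to_numpy() - c.centroid[0]
        dy = tdf["y"].to_numpy() - c.centroid[1]
        dist = np.hypot(dx, dy)
        for ti in np.flatnonzero(dist <= max_dist):
            pairs.append((dist[ti], di, int(ti)))
    pairs.sort()
    used_d, used_t, matches = set(), set(), []
    for d, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di); used_t.add(ti)
        matches.append((di, ti))
    n_match = len(matches)
    precision = n_match / n_det if n_det else 0.0
    recall = n_match / n_truth if n_truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    area_ratio = (sum(c.Ar for c in det) / tdf["Ar_true"].sum()
                  if n_truth and tdf["Ar_true"].sum() > 0 else np.nan)
    height_bias = (float(np.mean([det[di].H - tdf["H"].iloc[ti]
                                  for di, ti in matches]))
                   if matches else np.nan)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_matched": n_match, "n_detected": n_det, "n_truth": n_truth,
            "area_ratio": float(area_ratio), "height_bias": height_bias,
            "undefined_precision": n_det == 0}
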