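"""Volume -> biomass -> carbon conversion and per-hectare mapping.

Woody volume converts to above-ground biomass through wood density
(AGB = V * rho / 1000, Mg) and to carbon through the 0.471 carbon fraction
for woody tissue.  Crowns are binned into grid cells (default 100 m, i.e.
1 ha, so cell sums read directly as Mg ha^-1) by hull centroid, yielding
AGB-density, tree-density and uncertainty layers; a height-class summary
table stratifies counts, crown area and AGB share by forest membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import shape as shapely_shape
from shapely.prepared import prep

__all__ = ["CARBON_FRACTION", "volume_to_agb", "agb_to_carbon",
           "attribute_biomass", "AGBRaster", "rasterize_crowns",
           "summarize_by_height_class"]

#: fraction of dry woody biomass that is carbon
CARBON_FRACTION = 0.471


def volume_to_agb(V, density):
    """AGB (Mg) from volume (m^3) and wood density (kg m^-3)."""
    V = np.asarray(V, dtype=float)
    density = np.asarray(density, dtype=float)
    if (V < 0).any() or (density < 0).any():
        raise ValueError("volume and density must be non-negative")
    out = V * density / 1000.0
    return float(out) if out.ndim == 0 else out


def agb_to_carbon(agb):
    """Carbon mass (Mg C) from AGB (Mg): multiply by the carbon fraction."""
    agb = np.asarray(agb, dtype=float)
    if (agb < 0).any():
        raise ValueError("AGB must be non-negative")
    out = CARBON_FRACTION * agb
    return float(out) if out.ndim == 0 else out


def attribute_biomass(crown_set, model, density: float) -> None:
    """Attach predicted volume and AGB to every crown in place.

    ``model`` is a fitted/frozen volume allometry; ``density`` a mean wood
    density (kg m^-3) applied to all crowns.
    """
    for c in crown_set:
        V, _ = model.predict(c.H, c.Ar)
        c.V = float(V)
        c.agb = volume_to_agb(c.V, density)


@dataclass
class AGBRaster:
    """Gridded biomass layers.

    Cell values are per-hectare densities; with the default 100 m cell the
    cell area is exactly 1 ha.  Layers: ``agb_density`` (Mg ha^-1),
    ``tree_density`` (trees ha^-1), ``agb_sd_abs`` (Mg ha^-1, per-cell
    quadrature sum of crown sds) and ``agb_sd_rel`` (fraction, 0 where the
    cell is empty).
    """

    origin: tuple            # (x0, y0) of the lower-left corner
    cell: float              # cell edge length (m)
    layers: dict             # name -> 2D array, row 0 = southernmost row
    crs: str | None = None

    @property
    def shape(self):
        return next(iter(self.layers.values())).shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell * self.cell / 10_000.0

    def total_agb(self) -> float:
        """Grand total AGB (Mg) implied by the density layer."""
        return float(self.layers["agb_density"].sum() * self.cell_area_ha)

    def write_ascii_grids(self, prefix) -> list:
        """Write each layer as an ESRI ASCII grid (plain text) named
        ``<prefix>_<layer>.asc``; returns the paths written."""
        paths = []
        ny, nx = self.shape
        for name, grid in self.layers.items():
            path = f"{prefix}_{name}.asc"
            with open(path, "w") as fh:
                fh.write(f"ncols {nx}\nnrows {ny}\n")
                fh.write(f"xllcorner {self.origin[0]}\n"
                         f"yllcorner {self.origin[1]}\n")
                fh.write(f"cellsize {self.cell}\nNODATA_value -9999\n")
                for row in grid[::-1]:      # ASCII grids run north to south
                    fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
            paths.append(path)
        return paths

    def plot(self, layer: str = "agb_density", ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ny, nx = self.shape
        extent = (self.origin[0], self.origin[0] + nx * self.cell,
                  self.origin[1], self.origin[1] + ny * self.cell)
        im = ax.imshow(self.layers[layer], origin="lower", extent=extent)
        ax.figure.colorbar(im, ax=ax, label=layer)
        return ax


def rasterize_crowns(crown_set, extent=None, cell: float = 100.0,
                     crs: str | None = None,
                     method: str = "centroid") -> AGBRaster:
    """Grid crowns into per-hectare AGB and tree-density layers.

    With ``method="centroid"`` (default) each crown is assigned wholly to
    the cell containing its hull centroid; ``method="area"`` apportions a
    crown's AGB (and a fractional tree count) across the cells its hull
    overlaps, in proportion to overlap area.  ``extent`` is
    ``(x0, y0, x1, y1)``; by default it is the centroid bounding box
    snapped outward to the cell size.  Crowns (or hull fractions) falling
    outside a user-supplied extent are dropped with a warning.
    """
    if method not in ("centroid", "area"):
        raise ValueError(f"unknown assignment method {method!r}")
    crowns = [c for c in crown_set]
    if any(c.agb is None for c in crowns):
        raise ValueError("crowns must carry AGB; run attribute_biomass first")
    xs = np.array([c.centroid[0] for c in crowns], dtype=float)
    ys = np.array([c.centroid[1] for c in crowns], dtype=float)
    if extent is None:
        if not crowns:
            extent = (0.0, 0.0, cell, cell)
        else:
            x0 = np.floor(xs.min() / cell) * cell
            y0 = np.floor(ys.min() / cell) * cell
            x1 = np.floor(xs.max() / cell) * cell + cell
            y1 = np.floor(ys.max() / cell) * cell + cell
            extent = (x0, y0, x1, y1)
    x0, y0, x1, y1 = map(float, extent)
    nx = max(int(np.ceil((x1 - x0) / cell)), 1)
    ny = max(int(np.ceil((y1 - y0) / cell)), 1)
    agb = np.zeros((ny, nx))
    count = np.zeros((ny, nx))
    var = np.zeros((ny, nx))
    dropped = 0
    for c, x, y in zip(crowns, xs, ys):
        if method == "area" and getattr(c, "hull", None) is not None \
                and c.hull.area > 0:
            from shapely.geometry import box
            minx, miny, maxx, maxy = c.hull.bounds
            lost = 1.0
            for iy in range(max(int((miny - y0) // cell), 0),
                            min(int((maxy - y0) // cell) + 1, ny)):
                for ix in range(max(int((minx - x0) // cell), 0),
                                min(int((maxx - x0) // cell) + 1, nx)):
                    cell_geom = box(x0 + ix * cell, y0 + iy * cell,
                                    x0 + (ix + 1) * cell,
                                    y0 + (iy + 1) * cell)
                    frac = c.hull.intersection(cell_geom).area / c.hull.area
                    if frac <= 0:
                        continue
                    lost -= frac
                    agb[iy, ix] += frac * c.agb
                    count[iy, ix] += frac
                    if c.agb_sd is not None:
                        var[iy, ix] += (frac * c.agb_sd) ** 2
            if lost > 1e-9:
                dropped += 1
            continue
        ix = int(np.floor((x - x0) / cell))
        iy = int(np.floor((y - y0) / cell))
        if not (0 <= ix < nx and 0 <= iy < ny):
            dropped += 1
            continue
        agb[iy, ix] += c.agb
        count[iy, ix] += 1
        if c.agb_sd is not None:
            var[iy, ix] += c.agb_sd ** 2
    if dropped:
        warnings.warn(f"{dropped} crowns fell outside the raster extent "
                      "and were dropped")
    area_ha = cell * cell / 10_000.0
    agb_density = agb / area_ha
    sd_abs = np.sqrt(var) / area_ha
    with np.errstate(divide="ignore", invalid="ignore"):
        sd_rel = np.where(agb_density > 0, sd_abs / agb_density, 0.0)
    return AGBRaster(origin=(x0, y0), cell=cell, crs=crs, layers={
        "agb_density": agb_density,
        "tree_density": count / area_ha,
        "agb_sd_abs": sd_abs,
        "agb_sd_rel": sd_rel,
    })


def _mask_predicate(forest_mask):
    """Return a point-in-forest predicate from a GeoJSON-like mapping,
    shapely geometry, or None."""
    if forest_mask is None:
        return None
    if hasattr(forest_mask, "contains"):
        geom = forest_mask
    else:
        gj = forest_mask
        if isinstance(gj, dict) and gj.get("type") == "FeatureCollection":
            from shapely.ops import unary_union
            geoms = [shapely_shape(f["geometry"]) for f in gj["features"]]
            if not geoms:
                return lambda p: False
            geom = unary_union(geoms)
        elif isinstance(gj, dict) and gj.get("type") == "Feature":
            geom = shapely_shape(gj["geometry"])
        else:
            geom = shapely_shape(gj)
    prepared = prep(geom)
    return lambda p: prepared.contains(p)


def summarize_by_height_class(crown_set, forest_mask=None,
                              bins=5.0) -> pd.DataFrame:
    """Height-class summary: tree count, summed crown area and AGB share.

    ``bins`` is either a bin width (m) or an explicit edge array.  Crowns
    are stratified by whether their centroid falls inside ``forest_mask``
    (GeoJSON mapping or shapely geometry); without a mask all crowns form a
    single ``all`` stratum.  AGB shares are fractions of the overall total,
    so they sum to 1 across the whole table.
    """
    crowns = [c for c in crown_set]
    H = np.array([c.H for c in crowns], dtype=float)
    Ar = np.array([c.Ar for c in crowns], dtype=float)
    agb = np.array([c.agb if c.agb is not None else 0.0 for c in crowns])
    if np.isscalar(bins):
        top = (np.ceil(H.max() / bins) * bins) if len(crowns) else bins
        edges = np.arange(0.0, top + bins, bins)
    else:
        edges = np.asarray(bins, dtype=float)
    pred = _mask_predicate(forest_mask)
    if pred is None:
        strata = np.array(["all"] * len(crowns))
    else:
        strata = np.array([
            "forest" if pred(ShapelyPoint(*c.centroid)) else "non-forest"
            for c in crowns])
    which = np.clip(np.digitize(H, edges) - 1, 0, len(edges) - 2) \
        if len(crowns) else np.array([], dtype=int)
    total_agb = agb.sum()
    rows = []
    for s in np.unique(strata):
        in_s = strata == s
        for b in range(len(edges) - 1):
            sel = in_s & (which == b)
            if not sel.any():
                continue
            rows.append({
                "stratum": s,
                "h_low": edges[b], "h_high": edges[b + 1],
                "n_trees": int(sel.sum()),
                "sum_ar_m2": float(Ar[sel].sum()),
                "agb_mg": float(agb[sel].sum()),
                "agb_share": float(agb[sel].sum() / total_agb)
                if total_agb > 0 else 0.0,
            })
    return pd.DataFrame(rows)
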