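"""Forest-structure predictors from LiDAR-derived rasters.

Canopy density is expressed as the proportion of LiDAR returns above 2 m
(PRA2m, percent), vegetation height as the median-aggregated DSM-DTM
difference, and tree-type cover as PRA2m split by the coniferous fraction
of the canopy. All are computed on the common 5-m grid and smoothed with
the same Gaussian bandwidths (10 m, 25 m) as the terrain predictors.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import terrain
from .raster import RasterGrid

__all__ = ["veg_height", "pra2m", "type_cover", "smooth_structure",
           "rasterize_crowns"]


def rasterize_crowns(polygons: list, template: RasterGrid,
                     conifer_flags: list[bool]) -> RasterGrid:
    """Coniferous canopy fraction from crown polygons, by cell-centre test.

    ``polygons`` are shapely geometries or GeoJSON-like mappings of tree
    crowns, flagged coniferous or deciduous. Each cell of the template grid
    is classified by its centre point: 1 under a coniferous crown, 0 under
    a deciduous crown, nodata outside any crown (no canopy to attribute).
    Overlaps resolve in favour of the first polygon listed.
    """
    from shapely.geometry import Point, shape
    from shapely.strtree import STRtree

    geoms = [p if hasattr(p, "geom_type") else shape(p) for p in polygons]
    if len(geoms) != len(conifer_flags):
        raise ValueError("one conifer flag per polygon required")
    out = np.full(template.shape, np.nan)
    if not geoms:
        return template.like(out)
    tree = STRtree(geoms)
    xs = template.x_centers()
    ys = template.y_centers()
    for i in range(template.nrows):
        for j in range(template.ncols):
            pt = Point(xs[j], ys[i])
            hits = sorted(tree.query(pt, predicate="intersects"))
            if len(hits):
                out[i, j] = 1.0 if conifer_flags[int(hits[0])] else 0.0
    return template.like(out)


def veg_height(dsm: RasterGrid, dtm: RasterGrid, target_cell: float = 5.0) -> RasterGrid:
    """Vegetation height: DSM minus DTM, median-aggregated to the target grid.

    Heights are floored at 0 (a DSM below the DTM is sensor noise); fine
    cells more than 0.5 m below the terrain trigger an alignment warning.
    The target cell must be an integer multiple of the fine cell.
    """
    if not dsm.aligned_with(dtm):
        raise ValueError("DSM and DTM must be co-registered")
    diff = dsm.values - dtm.values
    if np.nanmin(diff) < -0.5:
        warnings.warn("DSM below DTM by more than 0.5 m: check co-registration")
    h = np.maximum(diff, 0.0)
    factor = target_cell / dsm.cell_size
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("target cell must be an integer multiple of the fine cell")
    f = int(round(factor))
    nr = dsm.nrows // f
    nc = dsm.ncols // f
    blocks = h[: nr * f, : nc * f].reshape(nr, f, nc, f).transpose(0, 2, 1, 3).reshape(nr, nc, f * f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(blocks, axis=2)
    return RasterGrid(med, target_cell, dsm.origin, dsm.crs_tag)


def pra2m(returns_above2m: RasterGrid, returns_total: RasterGrid) -> RasterGrid:
    """Proportion of returns above 2 m, in percent; 0-return cells are nodata."""
    if not returns_above2m.aligned_with(returns_total):
        raise ValueError("return-count rasters must be aligned")
    above = returns_above2m.values
    total = returns_total.values
    both = np.isfinite(above) & np.isfinite(total)
    if np.any(above[both] > total[both]):
        raise ValueError("returns above 2 m exceed total returns: corrupt input")
    if np.any(above[both] < 0) or np.any(total[both] < 0):
        raise ValueError("negative return counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 100.0 * above / total, np.nan)
    return returns_total.like(out)


def type_cover(
    pra: RasterGrid, tree_type_fraction: RasterGrid
) -> tuple[RasterGrid, RasterGrid]:
    """Split canopy density into coniferous and deciduous cover (percent).

    ``tree_type_fraction`` is the coniferous share of the canopy in [0, 1];
    the two outputs always sum to PRA2m.
    """
    if not pra.aligned_with(tree_type_fraction):
        raise ValueError("rasters must be aligned")
    frac = tree_type_fraction.values
    fin = np.isfinite(frac)
    if np.any((frac[fin] < 0) | (frac[fin] > 1)):
        raise ValueError("tree-type fraction must lie in [0, 1]")
    conif = pra.values * frac
    decid = pra.values * (1.0 - frac)
    return pra.like(conif), pra.like(decid)


def smooth_structure(
    stack: dict[str, RasterGrid], sigmas: tuple[float, ...] = (10.0, 25.0)
) -> dict[str, RasterGrid]:
    """Add Gaussian-smoothed variants of each raster, named ``<name>_g<sigma>``."""
    out = dict(stack)
    for name, r in stack.items():
        for sigma in sigmas:
            out[f"{name}_g{sigma:g}"] = terrain.gaussian_smooth(r, sigma)
    return out
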