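"""Land-surface predictors from a digital terrain model.

Implements the topographic indices commonly used in forest microclimate
modelling, on 5-m grids:

* slope and aspect from an Evans-Young second-order polynomial fit,
* topographic position index (TPI) at configurable radii,
* Freeman multiple-flow-direction accumulation (convergence exponent 1.0),
* topographic wetness index TWI = ln(a / tan beta) with flow width equal
  to the grid resolution,
* the SAGA wetness index, a TWI variant whose iteratively "modified"
  catchment area lets flat valley floors inherit the catchment of their
  surroundings (a proxy for cold-air pooling), suction factor 10,
* diurnal anisotropic heating DAH = cos(202.5 deg - aspect) * slope(rad),
  a radiation-load proxy with its maximum on south-west slopes,
* Gaussian smoothing with metre-specified bandwidth, and B-spline
  resampling / distance-feathered mosaicking for DTM preparation.

Conventions (documented because the literature is not unanimous): aspect is
the downslope azimuth in degrees clockwise from north; flats have slope 0
and undefined (NaN) aspect; TPI windows are circular by cell-centre
inclusion and include the focal cell; depressions are filled to an epsilon
gradient before flow routing.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from scipy.signal import fftconvolve

from .raster import RasterGrid

__all__ = [
    "FlowField",
    "resample_bspline",
    "mosaic_blend",
    "slope_aspect",
    "tpi",
    "standardize_tpi",
    "fill_depressions",
    "freeman_accumulation",
    "twi",
    "saga_wetness_index",
    "dah",
    "gaussian_smooth",
]

DAH_MAX_ASPECT = 202.5  # azimuth of maximum diurnal heat surplus, degrees
TAN_BETA_FLOOR = 1e-3  # slope floor in wetness indices

# 8-neighbour offsets and centre distances in cell units
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_NDIST = np.array([math.sqrt(dr * dr + dc * dc) for dr, dc in _NEIGHBORS])


@dataclass
class FlowField:
    """Freeman multiple-flow routing result.

    ``fractions[i, j, k]`` is the share of cell (i, j)'s accumulated area
    routed to its k-th 8-neighbour (ordering of ``_NEIGHBORS``); rows of a
    non-outlet cell sum to 1. ``area`` is the contributing area in m**2,
    including the cell's own area. ``outlet`` marks cells with no lower
    neighbour (area leaves the raster or pools there).
    """

    fractions: np.ndarray
    area: np.ndarray
    outlet: np.ndarray
    cell_size: float


def _nearest_fill(values: np.ndarray) -> np.ndarray:
    """Replace NaNs with the nearest finite value (for spline fitting)."""
    mask = ~np.isfinite(values)
    if not mask.any():
        return values
    idx = ndimage.distance_transform_edt(mask, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def resample_bspline(r: RasterGrid, target_cell: float) -> RasterGrid:
    """Resample to a coarser grid by sampling a cubic B-spline surface.

    The spline interpolates the source cell centres; output cells are
    evaluated at their centres. Extents are preserved (the output covers
    ``floor(extent / target_cell)`` whole cells from the same origin).
    Cells whose footprint is nodata in the source stay nodata.
    """
    if target_cell < r.cell_size:
        raise ValueError("target cell must not be finer than the source")
    n_out_r = int(r.nrows * r.cell_size // target_cell)
    n_out_c = int(r.ncols * r.cell_size // target_cell)
    valid = r.valid_mask()
    out = np.full((n_out_r, n_out_c), np.nan)
    result = RasterGrid(out, target_cell, r.origin, r.crs_tag)
    if not valid.any():
        return result
    filled = _nearest_fill(r.values)
    # source centre coordinates in a local frame: rows top-down
    ys = (np.arange(r.nrows) + 0.5) * r.cell_size
    xs = (np.arange(r.ncols) + 0.5) * r.cell_size
    ky = 3 if r.nrows > 3 else r.nrows - 1
    kx = 3 if r.ncols > 3 else r.ncols - 1
    spl = RectBivariateSpline(ys, xs, filled, kx=kx, ky=ky, s=0)
    yt = (np.arange(n_out_r) + 0.5) * target_cell
    xt = (np.arange(n_out_c) + 0.5) * target_cell
    out[:] = spl(yt, xt)
    # mask where the nearest source cell is nodata
    src_r = np.clip((yt / r.cell_size - 0.5).round().astype(int), 0, r.nrows - 1)
    src_c = np.clip((xt / r.cell_size - 0.5).round().astype(int), 0, r.ncols - 1)
    out[~valid[np.ix_(src_r, src_c)]] = np.nan
    return result


def _place_on(canvas: RasterGrid, r: RasterGrid) -> np.ndarray:
    """Return r's values embedded on canvas geometry (NaN elsewhere)."""
    out = np.full(canvas.shape, np.nan)
    dr = round((canvas.origin[1] - r.origin[1]) / canvas.cell_size)
    dc = round((r.origin[0] - canvas.origin[0]) / canvas.cell_size)
    r0, c0 = -dr, dc
    rs, cs = max(0, r0), max(0, c0)
    re, ce = min(canvas.nrows, r0 + r.nrows), min(canvas.ncols, c0 + r.ncols)
    if re > rs and ce > cs:
        out[rs:re, cs:ce] = r.values[rs - r0 : re - r0, cs - c0 : ce - c0]
    return out


def mosaic_blend(rasters: list[RasterGrid], blend_width: float = 25.0) -> RasterGrid:
    """Merge co-aligned rasters from high to low priority with edge feathering.

    Where only one source covers a cell its value is used. In the strip of
    the overlap within ``blend_width`` of the higher-priority raster's edge,
    the two sources are combined with linear distance weights (pure
    secondary at the primary's edge, pure primary ``blend_width`` inside).
    """
    if not rasters:
        raise ValueError("no rasters to mosaic")
    cell = rasters[0].cell_size
    for r in rasters[1:]:
        if abs(r.cell_size - cell) > 1e-9:
            raise ValueError("mosaic inputs must share a cell size")
        if abs((r.origin[0] - rasters[0].origin[0]) % cell) > 1e-6 * cell and abs(
            cell - (r.origin[0] - rasters[0].origin[0]) % cell
        ) > 1e-6 * cell:
            raise ValueError("mosaic inputs must be grid-aligned")
    x0 = min(r.origin[0] for r in rasters)
    y0 = max(r.origin[1] for r in rasters)
    x1 = max(r.origin[0] + r.ncols * cell for r in rasters)
    y1 = min(r.origin[1] - r.nrows * cell for r in rasters)
    shape = (round((y0 - y1) / cell), round((x1 - x0) / cell))
    canvas = RasterGrid(np.full(shape, np.nan), cell, (x0, y0), rasters[0].crs_tag)
    acc = canvas.values
    for r in rasters:
        layer = _place_on(canvas, r)
        have = np.isfinite(acc)
        new = np.isfinite(layer)
        if not have.any():
            acc = layer
            continue
        # distance (m) of each cell centre into the existing mosaic's footprint
        depth = np.maximum(ndimage.distance_transform_edt(have) - 0.5, 0.0) * cell
        w = np.clip(depth / blend_width, 0.0, 1.0)
        both = have & new
        merged = np.where(new & ~have, layer, acc)
        merged[both] = w[both] * acc[both] + (1 - w[both]) * layer[both]
        acc = merged
    return canvas.like(acc)


def slope_aspect(dtm: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope (degrees) and downslope aspect (degrees CW from north).

    Gradients come from the Evans-Young second-order polynomial fit on the
    3x3 window: p = dz/dx averages the three east-west differences, q =
    dz/dy the three north-south differences. Edge cells and cells with an
    incomplete window are nodata; flats keep slope 0 and NaN aspect.
    """
    z = dtm.values
    h = dtm.cell_size
    p = np.full(z.shape, np.nan)
    q = np.full(z.shape, np.nan)
    c = z[1:-1, 1:-1]
    win = np.isfinite(z)
    ok = np.ones(c.shape, dtype=bool)
    for dr, dc in _NEIGHBORS:
        ok &= win[1 + dr : z.shape[0] - 1 + dr, 1 + dc : z.shape[1] - 1 + dc]
    ok &= np.isfinite(c)
    p_in = (
        z[0:-2, 2:] + z[1:-1, 2:] + z[2:, 2:] - z[0:-2, 0:-2] - z[1:-1, 0:-2] - z[2:, 0:-2]
    ) / (6 * h)
    # rows increase southwards, so north-south difference is top minus bottom
    q_in = (
        z[0:-2, 0:-2] + z[0:-2, 1:-1] + z[0:-2, 2:] - z[2:, 0:-2] - z[2:, 1:-1] - z[2:, 2:]
    ) / (6 * h)
    p[1:-1, 1:-1] = np.where(ok, p_in, np.nan)
    q[1:-1, 1:-1] = np.where(ok, q_in, np.nan)
    grad = np.hypot(p, q)
    slope = np.degrees(np.arctan(grad))
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-p, -q)) % 360.0
        aspect[~(grad > 0)] = np.nan
    return dtm.like(slope), dtm.like(aspect)


def tpi(dtm: RasterGrid, radius: float) -> RasterGrid:
    """Topographic position index: elevation minus the circular-window mean.

    Positive on ridges and knolls, negative in depressions. The window
    includes every cell whose centre lies within ``radius`` of the focal
    cell's centre, focal cell included.
    """
    if radius < dtm.cell_size:
        raise ValueError("radius must be at least one cell")
    rad_cells = radius / dtm.cell_size
    n = int(math.floor(rad_cells))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    kernel = ((yy * yy + xx * xx) <= rad_cells * rad_cells).astype(float)
    vals = dtm.values
    valid = np.isfinite(vals).astype(float)
    filled = np.where(np.isfinite(vals), vals, 0.0)
    # FFT convolution: the window easily exceeds 100x100 cells at 500 m radius
    num = fftconvolve(filled, kernel, mode="same")
    den = fftconvolve(valid, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(den > 0.5, num / den, np.nan)
    out = vals - mean
    return dtm.like(out)


def standardize_tpi(t: RasterGrid) -> RasterGrid:
    """Divide TPI values by their standard deviation (unit-SD surface)."""
    vals = t.values[np.isfinite(t.values)]
    if vals.size < 2:
        raise ValueError("standardization needs more than one valid cell")
    sd = float(vals.std())
    if sd == 0:
        raise ValueError("flat raster: zero standard deviation")
    return t.like(t.values / sd)


def fill_depressions(dtm: RasterGrid, epsilon: float = 1e-4) -> RasterGrid:
    """Fill closed depressions so every cell drains to the raster edge.

    Priority-flood fill: cells are raised to at least the spill elevation
    plus a tiny epsilon gradient, guaranteeing monotone flow paths without
    flats. Nodata cells act as drains.
    """
    z = dtm.values
    nr, nc = z.shape
    filled = np.full_like(z, np.inf)
    closed = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    finite = np.isfinite(z)
    for i in range(nr):
        for j in range(nc):
            if not finite[i, j]:
                closed[i, j] = True
                filled[i, j] = np.nan
                continue
            edge = i in (0, nr - 1) or j in (0, nc - 1)
            if not edge:
                # cells adjacent to nodata also drain outwards
                for dr, dc in _NEIGHBORS:
                    if not finite[i + dr, j + dc]:
                        edge = True
                        break
            if edge:
                filled[i, j] = z[i, j]
                heapq.heappush(heap, (z[i, j], i, j))
                closed[i, j] = True
    while heap:
        zv, i, j = heapq.heappop(heap)
        for dr, dc in _NEIGHBORS:
            r2, c2 = i + dr, j + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and not closed[r2, c2]:
                closed[r2, c2] = True
                filled[r2, c2] = max(z[r2, c2], zv + epsilon)
                heapq.heappush(heap, (filled[r2, c2], r2, c2))
    return dtm.like(filled)


def freeman_accumulation(
    dtm: RasterGrid, convergence: float = 1.0, fill: bool = True
) -> FlowField:
    """Multiple-flow-direction accumulation (Freeman).

    Each cell distributes its accumulated area among all lower 8-neighbours
    with weights proportional to (downhill slope)**convergence; cells are
    processed in decreasing elevation order so all inflow is known before a
    cell drains. Contributing area includes the cell's own area. With
    ``fill`` the DTM is depression-filled first so no interior cell pools.
    """
    work = fill_depressions(dtm) if fill else dtm
    z = work.values
    nr, nc = z.shape
    cell = dtm.cell_size
    area = np.where(np.isfinite(z), cell * cell, np.nan)
    fractions = np.zeros((nr, nc, 8))
    outlet = np.zeros((nr, nc), dtype=bool)
    finite = np.isfinite(z)
    flat = z[finite]
    order = np.argsort(-flat, kind="stable")
    coords = np.argwhere(finite)[order]
    for i, j in coords:
        zi = z[i, j]
        wsum = 0.0
        w = [0.0] * 8
        for k, (dr, dc) in enumerate(_NEIGHBORS):
            r2, c2 = i + dr, j + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and finite[r2, c2] and z[r2, c2] < zi:
                s = (zi - z[r2, c2]) / (_NDIST[k] * cell)
                wk = s**convergence
                w[k] = wk
                wsum += wk
        if wsum <= 0:
            outlet[i, j] = True
            continue
        a = area[i, j]
        for k, (dr, dc) in enumerate(_NEIGHBORS):
            if w[k] > 0:
                f = w[k] / wsum
                fractions[i, j, k] = f
                area[i + dr, j + dc] += a * f
    return FlowField(fractions, area, outlet, cell)


def _tan_beta(dtm: RasterGrid, floor: float = TAN_BETA_FLOOR) -> np.ndarray:
    slope_deg, _ = slope_aspect(dtm)
    return np.maximum(np.tan(np.radians(slope_deg.values)), floor)


def twi(dtm: RasterGrid, flow: FlowField | None = None) -> RasterGrid:
    """Topographic wetness index ln(a / tan beta).

    Specific catchment area a is the Freeman contributing area divided by a
    flow width equal to the grid resolution; tan beta is floored to keep
    flats finite.
    """
    if flow is None:
        flow = freeman_accumulation(dtm, convergence=1.0)
    a = flow.area / dtm.cell_size
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log(a / _tan_beta(dtm))
    return dtm.like(out)


def saga_wetness_index(
    dtm: RasterGrid,
    suction: float = 10.0,
    flow: FlowField | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> RasterGrid:
    """SAGA wetness index: TWI on an iteratively modified catchment area.

    Flat cells inherit (a damped share of) the largest modified catchment
    area in their 3x3 neighbourhood, so valley floors without an explicit
    channel still score wet — the behaviour that makes this index a proxy
    for cold-air pooling. The damping factor is (1/suction)**(suction *
    tan beta): ~1 on flats, vanishing on steep slopes, so SAGAWI converges
    to TWI where terrain is steep. Iterated to a relative tolerance.
    """
    if flow is None:
        flow = freeman_accumulation(dtm, convergence=1.0)
    a = flow.area.copy()
    tanb = _tan_beta(dtm)
    # tan beta is nodata on edges; treat as steep (no modification)
    tan_eff = np.where(np.isfinite(tanb), tanb, np.inf)
    with np.errstate(over="ignore"):
        damp = np.power(1.0 / suction, suction * tan_eff)
    a_mod = a.copy()
    footprint = np.ones((3, 3), dtype=bool)
    work = np.where(np.isfinite(a_mod), a_mod, -np.inf)
    for _ in range(max_iter):
        neigh_max = ndimage.maximum_filter(work, footprint=footprint, mode="nearest")
        cand = np.maximum(a, neigh_max * damp)
        prev = work
        work = np.where(np.isfinite(a), cand, -np.inf)
        num = np.abs(work[np.isfinite(a)] - prev[np.isfinite(a)])
        den = np.abs(work[np.isfinite(a)]) + 1e-12
        if np.max(num / den, initial=0.0) < tol:
            break
    a_mod = np.where(np.isfinite(a), work, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log((a_mod / dtm.cell_size) / tanb)
    return dtm.like(out)


def dah(slope: RasterGrid, aspect: RasterGrid) -> RasterGrid:
    """Diurnal anisotropic heating: cos(202.5 deg - aspect) * arctan(slope).

    Slope enters as its angle in radians (via arctan of the radian slope
    angle), aspect in degrees clockwise from north. Values are positive on
    south-west-facing slopes (maximum heat surplus at azimuth 202.5 deg),
    negative opposite, and exactly 0 on flats.
    """
    s_rad = np.radians(slope.values)
    delta = np.radians(DAH_MAX_ASPECT - aspect.values)
    out = np.cos(delta) * np.arctan(s_rad)
    out = np.where(np.isnan(aspect.values) & np.isfinite(slope.values), 0.0, out)
    return slope.like(out)


def gaussian_smooth(r: RasterGrid, sigma: float) -> RasterGrid:
    """Isotropic Gaussian smoothing with metre-specified bandwidth.

    The kernel is truncated at four standard deviations and renormalized;
    nodata cells are excluded by mask-weighted normalization, so smoothing
    preserves the mean of fully valid rasters.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sig_cells = sigma / r.cell_size
    vals = r.values
    valid = np.isfinite(vals)
    if valid.all():
        # reflecting boundary keeps the smoothing operator mean-preserving
        return r.like(ndimage.gaussian_filter(vals, sig_cells, truncate=4.0,
                                              mode="reflect"))
    filled = np.where(valid, vals, 0.0)
    num = ndimage.gaussian_filter(filled, sig_cells, truncate=4.0, mode="reflect")
    den = ndimage.gaussian_filter(valid.astype(float), sig_cells, truncate=4.0,
                                  mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(valid, num / den, np.nan)
    return r.like(out)
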