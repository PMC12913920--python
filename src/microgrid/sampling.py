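"""Stratified site selection for a microclimate logger network.

Candidate plots (e.g. a forest-inventory grid) are classified into strata
by Fisher-Jenks natural breaks on elevation (5 classes), a radiation proxy
(3 classes) and topographic wetness (3 classes) — 45 strata, or 90 when an
open/closed canopy split at the median canopy cover is added. A fixed
number of plots is then drawn at random from each non-empty stratum, plus
forced picks at the elevation extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

__all__ = [
    "fisher_jenks",
    "classify",
    "build_strata",
    "select_sites",
    "exclude_disturbed",
    "site_density",
]


def fisher_jenks(values, k: int) -> list[float]:
    """Exact Fisher-Jenks natural breaks.

    Dynamic programming over the sorted values minimizing the total
    within-class sum of squared deviations from class means. Returns the
    ``k + 1`` class edges ``[min, b_1, ..., b_{k-1}, max]``; classes are
    left-closed, right-open except the last. Ties in the optimum are broken
    toward the lowest first break.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k < 1:
        raise ValueError("k must be at least 1")
    if np.unique(x).size < k:
        raise ValueError("k exceeds the number of distinct values")
    # prefix sums for O(1) class SSD; the inner minimization is vectorized
    # over the split position, so the DP is O(k n^2) numpy work
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def ssd_vec(i: np.ndarray, j: int) -> np.ndarray:
        m = j - i
        s = cs[j] - cs[i]
        return np.maximum(0.0, (cs2[j] - cs2[i]) - s * s / m)

    # cost[c][j]: best total SSD for first j values in c+1 classes
    cost = np.full((k, n + 1), np.inf)
    split = np.zeros((k, n + 1), dtype=int)
    j_all = np.arange(1, n + 1)
    cost[0][1:] = np.maximum(0.0, cs2[1:] - cs[1:] ** 2 / j_all)
    for c in range(1, k):
        for j in range(c + 1, n + 1):
            i = np.arange(c, j)
            v = cost[c - 1][i] + ssd_vec(i, j)
            arg = int(np.argmin(v))  # first minimum -> lowest split index
            cost[c][j] = v[arg]
            split[c][j] = c + arg
    # recover split indices (tie-break: smallest split found first above)
    cuts = []
    j = n
    for c in range(k - 1, 0, -1):
        i = split[c][j]
        cuts.append(i)
        j = i
    cuts.reverse()
    edges = [float(x[0])] + [float(x[i]) for i in cuts] + [float(x[-1])]
    return edges


def classify(values, edges: list[float]) -> np.ndarray:
    """1-based class index per value given Fisher-Jenks edges.

    Intervals are left-closed, right-open except the last; values outside
    the edge range are clipped into the end classes.
    """
    x = np.asarray(values, dtype=float)
    k = len(edges) - 1
    idx = np.searchsorted(np.asarray(edges[1:-1]), x, side="right") + 1
    return np.clip(idx, 1, k)


def build_strata(
    plots: pd.DataFrame,
    n_elevation: int = 5,
    n_radiation: int = 3,
    n_twi: int = 3,
    canopy_split: bool = False,
) -> pd.DataFrame:
    """Assign each plot a stratum from class combinations of its covariates.

    Expects columns ``elevation``, ``radiation``, ``twi`` and, when
    ``canopy_split`` is on, ``canopy_cover`` (split open/closed at its
    median). Rows with missing covariates get no stratum and are reported
    in the ``assigned`` column. The ``stratum`` label concatenates the
    class indices, e.g. ``"E3_R1_W2"`` or ``"E3_R1_W2_open"``.
    """
    out = plots.copy()
    needed = ["elevation", "radiation", "twi"] + (["canopy_cover"] if canopy_split else [])
    complete = out[needed].notna().all(axis=1)
    e_edges = fisher_jenks(out.loc[complete, "elevation"], n_elevation)
    r_edges = fisher_jenks(out.loc[complete, "radiation"], n_radiation)
    w_edges = fisher_jenks(out.loc[complete, "twi"], n_twi)
    ec = classify(out.loc[complete, "elevation"], e_edges)
    rc = classify(out.loc[complete, "radiation"], r_edges)
    wc = classify(out.loc[complete, "twi"], w_edges)
    labels = pd.Series(
        [f"E{e}_R{r}_W{w}" for e, r, w in zip(ec, rc, wc)], index=out.index[complete]
    )
    if canopy_split:
        median_cover = float(out.loc[complete, "canopy_cover"].median())
        open_closed = np.where(
            out.loc[complete, "canopy_cover"] < median_cover, "open", "closed"
        )
        labels = labels + "_" + open_closed
    out["stratum"] = labels.reindex(out.index)
    out["assigned"] = complete
    out.attrs["n_strata_theoretical"] = (
        n_elevation * n_radiation * n_twi * (2 if canopy_split else 1)
    )
    return out


def select_sites(
    strata: pd.DataFrame,
    n_per_stratum: int = 2,
    extremes: int = 6,
    rng_seed: int = 0,
    id_col: str = "plot_id",
) -> pd.DataFrame:
    """Random draws per stratum plus forced elevation-extreme plots.

    Draws ``n_per_stratum`` plots without replacement from every non-empty
    stratum (all of them when the stratum is smaller), then adds the
    ``extremes`` plots nearest the top and bottom of the elevation gradient
    (half each) that are not already selected. Deterministic for a seed.
    """
    rng = np.random.default_rng(rng_seed)
    pool = strata[strata["stratum"].notna()].sort_values(id_col).reset_index(drop=True)
    chosen: list = []
    for _, grp in pool.groupby("stratum", sort=True):
        ids = grp[id_col].to_numpy()
        if len(ids) <= n_per_stratum:
            chosen.extend(ids)
        else:
            chosen.extend(rng.choice(ids, size=n_per_stratum, replace=False))
    chosen_set = set(chosen)
    if extremes > 0:
        by_elev = pool.sort_values(["elevation", id_col])
        lows = [i for i in by_elev[id_col] if i not in chosen_set][: extremes // 2]
        highs = [i for i in by_elev[id_col][::-1] if i not in chosen_set][
            : extremes - extremes // 2
        ]
        chosen.extend(lows)
        chosen.extend(highs)
        chosen_set.update(lows + highs)
    sel = pool[pool[id_col].isin(chosen_set)].copy()
    sel.attrs["rng_seed"] = rng_seed
    return sel


def exclude_disturbed(plots: pd.DataFrame, polygons: list) -> pd.DataFrame:
    """Drop plots lying inside (or on the boundary of) any disturbance polygon.

    ``polygons`` are shapely geometries or GeoJSON-like mappings. Boundary
    points count as inside (closed-polygon convention).
    """
    geoms = []
    for p in polygons:
        g = p if hasattr(p, "geom_type") else shape(p)
        if not g.is_valid:
            raise ValueError("invalid disturbance polygon")
        geoms.append(g)
    if not geoms:
        return plots.copy()
    keep = []
    for _, row in plots.iterrows():
        pt = Point(row["x"], row["y"])
        keep.append(not any(g.intersects(pt) for g in geoms))
    return plots[np.asarray(keep)].copy()


def site_density(n_sites: int, area_km2: float) -> float:
    """Mean site density in sites per km**2."""
    return n_sites / area_km2
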