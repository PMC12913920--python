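"""Hexagonal spatial blocking and block cross-validation.

Model skill for spatial prediction must be measured on sites that are
spatially separated from the training data, otherwise autocorrelation
inflates apparent accuracy. Sites are grouped into a regular lattice of
flat-topped hexagons (about 9 km flat-to-flat in the source study),
hexagons are packed into k folds with approximately balanced site counts
(longest-processing-time greedy), and the cross-validated RMSE is the
unweighted mean of the k held-out-fold RMSEs. A hexagon is never split
across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpatialFolds", "hex_assign", "allocate_folds", "make_spatial_folds",
           "spatial_cv", "hexagon_geojson"]


def hexagon_geojson(hex_ids, flat_to_flat: float,
                    origin: tuple[float, float] = (0.0, 0.0)) -> dict:
    """GeoJSON FeatureCollection of flat-topped hexagons, for inspection."""
    s = flat_to_flat / np.sqrt(3.0)
    feats = []
    seen = set()
    for q, r in (tuple(h) for h in np.asarray(hex_ids)):
        if (q, r) in seen:
            continue
        seen.add((q, r))
        cx = origin[0] + s * 1.5 * q
        cy = origin[1] + s * (np.sqrt(3.0) / 2.0 * q + np.sqrt(3.0) * r)
        ring = [
            [cx + s * np.cos(np.pi / 3.0 * k), cy + s * np.sin(np.pi / 3.0 * k)]
            for k in range(6)
        ]
        ring.append(ring[0])
        feats.append({
            "type": "Feature",
            "properties": {"q": int(q), "r": int(r)},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    return {"type": "FeatureCollection", "features": feats}


@dataclass
class SpatialFolds:
    """Per-site hexagon ids and fold labels (1..k)."""

    hexagon: np.ndarray
    fold: np.ndarray
    flat_to_flat: float

    def to_frame(self, site_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"hexagon_id": [f"{q}_{r}" for q, r in self.hexagon],
                           "fold": self.fold})
        if site_ids is not None:
            df.insert(0, "site_id", np.asarray(site_ids))
        return df


def hex_assign(x, y, flat_to_flat: float, origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Axial (q, r) coordinates of the flat-topped hexagon containing each point.

    Flat-topped orientation: hexagon width (corner to corner) is 2s for
    circumradius s, and the flat-to-flat height is sqrt(3) * s. Assignment
    uses fractional axial coordinates with cube rounding, which maps every
    point to its nearest hexagon centre — i.e. the containing hexagon.
    """
    if flat_to_flat <= 0:
        raise ValueError("flat_to_flat must be positive")
    s = flat_to_flat / np.sqrt(3.0)
    px = (np.asarray(x, dtype=float) - origin[0]) / s
    py = (np.asarray(y, dtype=float) - origin[1]) / s
    qf = (2.0 / 3.0) * px
    rf = (-1.0 / 3.0) * px + (np.sqrt(3.0) / 3.0) * py
    return _cube_round(qf, rf)


def _cube_round(qf, rf):
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return np.stack([q.astype(int), r.astype(int)], axis=1)


def allocate_folds(hex_ids: np.ndarray, k: int = 10, rng_seed: int = 0) -> np.ndarray:
    """Pack hexagons into k folds with balanced site counts (LPT greedy).

    Hexagons are sorted by decreasing site count (seeded shuffle breaks
    ties) and each is assigned to the currently smallest fold, so no
    hexagon is ever split and the max-min spread of fold sizes is kept
    small. Returns a per-site fold label in 1..k.
    """
    keys = [tuple(h) for h in np.asarray(hex_ids)]
    series = pd.Series(keys)
    tab = series.value_counts()
    hexes = list(tab.index)
    if len(hexes) < k:
        raise ValueError(f"only {len(hexes)} non-empty hexagons for {k} folds")
    rng = np.random.default_rng(rng_seed)
    order = list(rng.permutation(len(hexes)))
    hexes = [hexes[i] for i in order]
    hexes.sort(key=lambda h: -tab[h])
    fold_of: dict = {}
    sizes = np.zeros(k, dtype=int)
    for h in hexes:
        f = int(np.argmin(sizes))
        fold_of[h] = f + 1
        sizes[f] += tab[h]
    return np.array([fold_of[h] for h in keys], dtype=int)


def make_spatial_folds(
    x, y, flat_to_flat: float, k: int = 10, rng_seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> SpatialFolds:
    """Hexagon assignment followed by fold allocation."""
    hexes = hex_assign(x, y, flat_to_flat, origin)
    folds = allocate_folds(hexes, k, rng_seed)
    return SpatialFolds(hexes, folds, flat_to_flat)


def spatial_cv(
    fit_predict,
    table: pd.DataFrame,
    response: str,
    folds: np.ndarray,
) -> dict:
    """Blocked cross-validation of an arbitrary fit/predict pipeline.

    ``fit_predict(train_table) -> callable(test_table) -> predictions``
    runs the *entire* modelling pipeline (including variable selection) on
    the training folds. Returns per-fold RMSEs, their unweighted mean (the
    headline statistic), and the pooled RMSE over all held-out residuals.
    """
    folds = np.asarray(folds)
    labels = np.unique(folds)
    if len(labels) < 2:
        raise ValueError("need at least 2 folds")
    per_fold = {}
    sq_resid = []
    for f in labels:
        te_mask = folds == f
        if not te_mask.any():
            continue
        train = table[~te_mask].reset_index(drop=True)
        test = table[te_mask].reset_index(drop=True)
        predict = fit_predict(train)
        pred = np.asarray(predict(test), dtype=float)
        resid = pred - test[response].to_numpy(dtype=float)
        per_fold[int(f)] = float(np.sqrt(np.mean(resid**2)))
        sq_resid.extend((resid**2).tolist())
    rmses = np.array(list(per_fold.values()))
    return {
        "per_fold_rmse": per_fold,
        "mean_rmse": float(rmses.mean()),
        "pooled_rmse": float(np.sqrt(np.mean(sq_resid))),
    }
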