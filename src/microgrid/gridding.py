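"""Apply fitted models over raster stacks: grids, uncertainty, zonal stats.

The fitted additive model is evaluated cell-by-cell over a co-registered
predictor stack (chunked by rows so memory stays bounded; the output is
independent of the chunking). Alongside each microclimate grid an
extrapolation-uncertainty raster records, per cell, the fraction of the
model's predictors whose value falls strictly outside the range covered by
the training sites — the standard caveat map for users of the grids.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .gamboost import BoostedGAMModel
from .raster import RasterGrid

__all__ = [
    "predict_grid",
    "uncertainty_raster",
    "zonal_mean",
    "grid_difference",
    "error_stats",
    "run_pipeline",
]


def _stack_check(model: BoostedGAMModel, stack: dict[str, RasterGrid]) -> list[str]:
    names = sorted({p for t in model.terms for p in t.predictors
                    if t.kind != "spatial_tensor"})
    missing = [n for n in names if n not in stack]
    if missing:
        raise ValueError(f"predictor layers missing from stack: {missing}")
    return names


def predict_grid(
    model: BoostedGAMModel,
    stack: dict[str, RasterGrid],
    chunk_rows: int = 32,
) -> RasterGrid:
    """Model prediction for every cell of the stack.

    Cells where any required input is nodata are nodata. Spatial-tensor
    coordinates come from the raster georeference (cell centres).
    """
    names = _stack_check(model, stack)
    ref = next(iter(stack.values()))
    for n in names:
        if not stack[n].aligned_with(ref):
            raise ValueError(f"layer {n!r} is not co-registered with the stack")
    out = np.full(ref.shape, np.nan)
    xs = ref.x_centers()
    ys = ref.y_centers()
    for r0 in range(0, ref.nrows, chunk_rows):
        r1 = min(r0 + chunk_rows, ref.nrows)
        nr = r1 - r0
        cols = {}
        valid = np.ones((nr, ref.ncols), dtype=bool)
        for n in names:
            v = stack[n].values[r0:r1]
            valid &= np.isfinite(v)
            cols[n] = v
        if not valid.any():
            continue
        idx_r, idx_c = np.nonzero(valid)
        table = pd.DataFrame({n: cols[n][idx_r, idx_c] for n in names})
        table["x"] = xs[idx_c]
        table["y"] = ys[r0 + idx_r]
        out[r0 + idx_r, idx_c] = model.predict(table)
    return ref.like(out)


def uncertainty_raster(model: BoostedGAMModel, stack: dict[str, RasterGrid]
                       ) -> RasterGrid:
    """Per-cell fraction of model predictors outside their training range.

    Strict (exclusive) out-of-range test; values are quantized to multiples
    of 1/p for the p predictors the model uses. 0 marks cells fully inside
    the training envelope, 1 cells where every predictor extrapolates.
    """
    names = [n for n in _stack_check(model, stack) if n in model.training_ranges]
    if not names:
        raise ValueError("model carries no training ranges")
    ref = next(iter(stack.values()))
    count = np.zeros(ref.shape)
    any_nan = np.zeros(ref.shape, dtype=bool)
    for n in names:
        v = stack[n].values
        lo, hi = model.training_ranges[n]
        count += ((v < lo) | (v > hi)).astype(float)
        any_nan |= ~np.isfinite(v)
    out = count / len(names)
    out[any_nan] = np.nan
    return ref.like(out)


def zonal_mean(fine: RasterGrid, coarse_cell: float) -> RasterGrid:
    """Aggregate to a coarser grid by the mean of valid fine cells."""
    factor = coarse_cell / fine.cell_size
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("coarse cell must be an integer multiple of the fine cell")
    f = int(round(factor))
    nr = fine.nrows // f
    nc = fine.ncols // f
    v = fine.values[: nr * f, : nc * f]
    blocks = v.reshape(nr, f, nc, f).transpose(0, 2, 1, 3).reshape(nr, nc, f * f)
    cnt = np.isfinite(blocks).sum(axis=2)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(np.isfinite(blocks), blocks, 0.0), axis=2)
        mean = np.where(cnt > 0, mean / cnt, np.nan)
    return RasterGrid(mean, coarse_cell, fine.origin, fine.crs_tag)


def error_stats(residuals: np.ndarray) -> dict[str, float]:
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    return {
        "ME": float(r.mean()),
        "MAE": float(np.abs(r).mean()),
        "RMSE": float(np.sqrt((r**2).mean())),
    }


def grid_difference(a: RasterGrid, b: RasterGrid) -> tuple[RasterGrid, dict[str, float]]:
    """Cell-wise a - b plus ME/MAE/RMSE over jointly valid cells."""
    if not a.aligned_with(b):
        raise ValueError("grids are not aligned")
    diff = a.values - b.values
    return a.like(diff), error_stats(diff[np.isfinite(diff)])


def run_pipeline(config: dict, outdir=None) -> dict:
    """End-to-end synthetic demo: world -> loggers -> summaries -> models -> grids.

    ``config`` keys (all optional): seed, n_cells, n_sites, noise_sd,
    variables (summary abbreviations to model), cv_folds, hex_flat_to_flat,
    mstop_max, run_cv. Returns the artifact bundle in memory; when ``outdir`` is
    given, writes summaries/models/grids plus a provenance JSON with the
    config hash and seed.
    """
    from . import synth
    from .gamboost import BoostConfig, fit_boosted_gam
    from .raster import write_ascii_grid
    from .spatialcv import make_spatial_folds, spatial_cv
    from .timeseries import SUMMARY_VARIABLES, summaries_to_frame, summarize_site

    t0 = time.time()
    seed = int(config.get("seed", 0))
    scfg = synth.SynthConfig(
        n_cells=int(config.get("n_cells", 200)),
        n_sites=int(config.get("n_sites", 150)),
        noise_sd=float(config.get("noise_sd", 0.3)),
    )
    variables = config.get("variables", ["T.air_200_cm.mean"])
    world = synth.build_world(seed, scfg)
    levels = sorted({SUMMARY_VARIABLES[v][0] for v in variables})
    series = synth.simulate_loggers(world, seed=seed + 1, levels=tuple(levels))
    by_site: dict[str, list] = {}
    for s in series:
        by_site.setdefault(s.site_id, []).append(s)
    summaries = []
    for site_id, ss in by_site.items():
        summaries.extend(summarize_site(ss))
    summary_df = summaries_to_frame(summaries)
    wide = summary_df.pivot(index="site_id", columns="variable", values="value")
    table = world.sites.merge(wide, left_on="site_id", right_index=True)
    predictors = [n for n in world.stack if n != "Elevation"] + ["Elevation"]
    folds = make_spatial_folds(
        table["x"].to_numpy(), table["y"].to_numpy(),
        float(config.get("hex_flat_to_flat", 250.0)),
        k=int(config.get("cv_folds", 10)), rng_seed=seed,
    )
    bcfg = BoostConfig(mstop_grid=tuple(
        range(25, int(config.get("mstop_max", 1000)) + 1, 25)))
    models, cv_results, grids, unc = {}, {}, {}, {}
    for var in variables:
        rng = np.random.default_rng(seed + 17)
        models[var] = fit_boosted_gam(table, var, predictors, bcfg, rng)

        def fit_fn(train, var=var):
            m = fit_boosted_gam(train, var, predictors, bcfg,
                                np.random.default_rng(seed + 17))
            return m.predict

        if config.get("run_cv", True):
            cv_results[var] = spatial_cv(fit_fn, table, var, folds.fold)
        grids[var] = predict_grid(models[var], world.stack)
        unc[var] = uncertainty_raster(models[var], world.stack)
    bundle = {
        "world": world, "summaries": summary_df, "table": table,
        "models": models, "cv": cv_results, "grids": grids,
        "uncertainty": unc, "folds": folds,
        "runtime_s": time.time() - t0,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary_df.to_csv(outdir / "site_summaries.csv", index=False)
        folds.to_frame(table["site_id"]).to_csv(outdir / "cv_folds.csv", index=False)
        for var, m in models.items():
            safe = var.replace(".", "_")
            m.to_json(outdir / f"model_{safe}.json")
            write_ascii_grid(grids[var], outdir / f"grid_{safe}.asc")
            write_ascii_grid(unc[var], outdir / f"uncertainty_{safe}.asc")
        # recomputed study-area and site ranges for every predictor layer
        pred_ranges = {
            name: {
                "area_min": float(np.nanmin(r.values)),
                "area_max": float(np.nanmax(r.values)),
                "sites_min": float(table[name].min()),
                "sites_max": float(table[name].max()),
            }
            for name, r in world.stack.items()
        }
        prov = {
            "seed": seed,
            "config": {k: v for k, v in config.items()},
            "predictor_ranges": pred_ranges,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "cv": {v: r["mean_rmse"] for v, r in cv_results.items()},
            "runtime_s": bundle["runtime_s"],
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=1)
    return bundle
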