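"""Model-summary and validation tables.

Mirrors the reporting style customary for boosted spatial GAM studies: one
row per modelled variable, one column per predictor ever selected (ordered
by how many models selected it), cells showing the term's effective df and
a shape symbol, plus adjusted R^2 and spatially cross-validated RMSE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gamboost import SHAPE_SYMBOL, BoostedGAMModel

__all__ = ["build_table3", "validation_table"]


def build_table3(models: dict[str, BoostedGAMModel], cv_results: dict[str, dict]
                 ) -> pd.DataFrame:
    """Cross-model summary table.

    Predictor columns are sorted by decreasing selection count across
    models (alphabetical tie-break); cells are "edf<symbol>" strings, empty
    when the predictor was not selected for that response. Trailing columns
    carry the spatial tensor edf, adjusted R^2 and mean spatial-CV RMSE.
    """
    if not models:
        raise ValueError("no models to report")
    counts: dict[str, int] = {}
    for m in models.values():
        for name in m.predictor_names:
            counts[name] = counts.get(name, 0) + 1
    order = sorted(counts, key=lambda n: (-counts[n], n))
    rows = []
    for var, m in models.items():
        row: dict[str, object] = {"variable": var}
        terms = {t.name: t for t in m.terms}
        for name in order:
            t = terms.get(name)
            row[name] = f"{t.edf:.2f}{SHAPE_SYMBOL[t.shape]}" if t else ""
        sp = next((t for t in m.terms if t.kind == "spatial_tensor"), None)
        row["spatial_tensor_edf"] = round(sp.edf, 2) if sp else np.nan
        row["adj_r2"] = round(m.adj_r2, 2)
        cv = cv_results.get(var)
        row["cv_rmse"] = round(cv["mean_rmse"], 4) if cv else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def validation_table(predicted, observed) -> dict[str, float]:
    """ME / MAE / RMSE of paired values, sign convention grid minus station."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed lengths differ")
    r = p - o
    return {
        "ME": float(r.mean()),
        "MAE": float(np.abs(r).mean()),
        "RMSE": float(np.sqrt((r**2).mean())),
    }
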