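"""Shared fixtures: synthetic worlds and site tables are expensive, so the
canonical ones are built once per session."""

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from microgrid import synth
from microgrid.timeseries import Level, summarize_site


@pytest.fixture(scope="session")
def world1():
    """Default synthetic world, seed 1."""
    return synth.build_world(1)


@pytest.fixture(scope="session")
def site_table(world1):
    """World-1 sites with simulated annual air-temperature summaries."""
    series = synth.simulate_loggers(world1, seed=11, levels=(Level.air_200cm,))
    by = defaultdict(list)
    for s in series:
        by[s.site_id].append(s)
    vals = {sid: {m.variable: m.value for m in summarize_site(ss)}
            for sid, ss in by.items()}
    tab = world1.sites.copy()
    tab["T.air_200_cm.mean"] = [vals[s]["T.air_200_cm.mean"] for s in tab["site_id"]]
    return tab


@pytest.fixture(scope="session")
def fitted_model(world1, site_table):
    from microgrid.gamboost import fit_boosted_gam

    return fit_boosted_gam(
        site_table, "T.air_200_cm.mean", list(world1.stack),
        rng=np.random.default_rng(7),
    )
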