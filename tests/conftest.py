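"""Shared fixtures: one synthetic study system reused across the suite.

Everything is generated at test time from fixed seeds; no data files are
bundled.  The heavyweight fixtures (population, usage design) are session
scoped so simulation and covariate extraction run once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from roadecol import habitat as hb
from roadecol.homerange import LoCoH
from roadecol.simulate import (
    LandscapeConfig,
    MovementParams,
    make_landscape,
    make_traffic,
    simulate_population,
)


@pytest.fixture(scope="session")
def landscape():
    return make_landscape(LandscapeConfig(), seed=1)


@pytest.fixture(scope="session")
def traffic():
    # long enough to cover the 90-night recovery simulations
    return make_traffic(seed=1, days=95)


@pytest.fixture(scope="session")
def population(landscape, traffic):
    """Six barn owls tracked for 60 nights with telemetry error attached."""
    return simulate_population(
        landscape, traffic, MovementParams(), n_individuals=6, days=60, seed=3
    )


@pytest.fixture(scope="session")
def telemetry(population):
    return pd.concat([s.telemetry_frame() for s in population], ignore_index=True)


@pytest.fixture(scope="session")
def usage_design(population, landscape, traffic):
    """Used-vs-available design built from the session population."""
    used_parts, disc_parts, avail = [], [], {}
    for i, s in enumerate(population):
        obs = s.observed_telemetry.reset_index(drop=True)
        if len(obs) < 40:
            continue
        kept, dropped, _ = hb.thin_to_independence(obs[["x", "y"]].to_numpy())
        used = obs.iloc[kept].copy()
        used["individual"] = s.individual
        disc = obs.iloc[dropped].copy()
        disc["individual"] = s.individual
        used_parts.append(used)
        disc_parts.append(disc)
        est = LoCoH(k=min(20, len(kept))).fit(obs.iloc[kept][["x", "y"]].to_numpy())
        avail[s.individual] = hb.sample_available(
            est.isopleths_[100], len(kept), seed=100 + i
        )
    return hb.build_usage_design(
        pd.concat(used_parts, ignore_index=True),
        avail,
        landscape,
        traffic,
        "barn_owl",
        196.0,
        discarded=pd.concat(disc_parts, ignore_index=True),
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_glmm_data():
    """2 groups x 10 observations for quadrature-oracle comparisons."""
    rng = np.random.default_rng(7)
    g = np.repeat([0, 1], 10)
    x = rng.normal(size=20)
    u = np.array([0.8, -0.5])
    from scipy.special import expit

    y = rng.binomial(1, expit(0.3 + 0.6 * x + u[g]))
    return pd.DataFrame({"individual": g, "response": y, "x": x})
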