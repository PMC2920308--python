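import numpy as np
import pytest
from hypothesis import settings

import minsig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def weak_params():
    """Stochastic (type B) regime: base parameters with x0 = 50."""
    return minsig.preset("weak")


@pytest.fixture(scope="session")
def strong_params():
    """Deterministic (type A) regime: base parameters with x0 = 2e5."""
    return minsig.preset("strong")


@pytest.fixture(scope="session")
def weak_ensemble(weak_params):
    """100 SSA cells under the weak stimulus, fine grid over [0, 10]."""
    return minsig.simulate_population(
        weak_params, n_cells=100, t_max=10.0,
        record_times=np.linspace(0.0, 10.0, 201), master_seed=42,
    )


@pytest.fixture(scope="session")
def deep_b_params():
    """Deep type B regime: slow step at k_b2 = 1e-6 with x0 = 5, below the
    type B threshold (k_b2*x1*x2/(k_a*x3) = 10).  Here the aggregate slow-step
    rate (k_b2*x1*x2 = 0.01) is far below the fast per-molecule hazard (k_b3 =
    1), the separation that produces all-or-none activation."""
    import dataclasses

    return dataclasses.replace(minsig.preset("base"), k_b2=1e-6, x0=5.0)


@pytest.fixture(scope="session")
def deep_b_ensemble(deep_b_params):
    """100 SSA cells deep in the type B regime, grid over [0, 1000]."""
    return minsig.simulate_population(
        deep_b_params, n_cells=100, t_max=1000.0,
        record_times=np.linspace(0.0, 1000.0, 2001), master_seed=44,
    )


@pytest.fixture(scope="session")
def strong_ensemble(strong_params):
    """100 SSA cells under the strong stimulus over [0, 3]."""
    return minsig.simulate_population(
        strong_params, n_cells=100, t_max=3.0,
        record_times=np.linspace(0.0, 3.0, 151), master_seed=43,
    )
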