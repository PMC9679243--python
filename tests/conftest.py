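import numpy as np
import pytest

from ipmviability import census as cs
from ipmviability import kernel as kn
from ipmviability import simulate as sim
from ipmviability import vitals as vt


@pytest.fixture(scope="session")
def small_params():
    """Two small populations, study-shaped defaults otherwise."""
    return sim.SimulationParams(
        populations=("P1", "P2"),
        n_quadrats={"P1": 20, "P2": 10},
        initial_n={"P1": 400, "P2": 300},
    )


@pytest.fixture(scope="session")
def small_census(small_params):
    df, truth = sim.simulate_census(small_params, seed=7)
    return df, truth


@pytest.fixture(scope="session")
def small_histories(small_census):
    df, _ = small_census
    return cs.build_histories(df)


@pytest.fixture(scope="session")
def small_tables(small_histories):
    return vt.make_tables(small_histories)


@pytest.fixture(scope="session")
def small_rates(small_tables):
    return vt.fit_population_rates(small_tables, "P1")


@pytest.fixture(scope="session")
def small_mesh(small_census):
    df, _ = small_census
    return kn.build_mesh(float(np.nanmax(df["diameter_mm"])), n_points=60)


def constant_rateset(survival=0.8, growth_sd=3.0, **overrides):
    """RateSet with flat rates: handy for conservation/identity checks."""
    const = lambda c: (lambda z: np.full(np.shape(z), float(c)))
    kw = dict(
        surv_n=const(survival), surv_b=const(survival), surv_d=const(survival),
        growth_mean=lambda z: np.asarray(z, float), growth_sd=growth_sd,
        p_nb=const(0.0), p_nd=const(0.0), p_bn=const(0.0), p_bd=const(0.0),
        p_dn=const(0.0), p_db=const(0.0),
        fruits_n=const(0.0), fruits_b=const(0.0),
        recruit_rate=0.0, recruit_size_mean=5.0, recruit_size_sd=2.0,
    )
    kw.update(overrides)
    return kn.RateSet(**kw)
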