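"""Stochastic growth rate, transient projections, bootstrap summaries."""

import numpy as np
import pytest

from ipmviability import kernel as kn
from ipmviability import projection as pj

from conftest import constant_rateset


class _Wrap:
    """Bare matrix pretending to be a kernel (λ_S needs only .matrix)."""

    def __init__(self, m):
        self.matrix = np.asarray(m, dtype=float)


def test_single_2x2_kernel_lambda_equals_eigenvalue():
    M = np.array([[0.5, 0.2], [0.3, 0.4]])       # eigenvalues 0.7 and 0.2
    lam = pj.stochastic_lambda([_Wrap(M)], n_steps=20_000,
                               rng=np.random.default_rng(0))
    assert lam == pytest.approx(0.7, abs=1e-10)


def test_two_scalar_kernels_geometric_mean():
    ks = [_Wrap([[2.0]]), _Wrap([[0.5]])]
    n = 40_000
    lam = pj.stochastic_lambda(ks, n_steps=n, rng=np.random.default_rng(1))
    mcse = np.log(2.0) / np.sqrt(n)              # SD of log λ_t is log 2
    assert abs(np.log(lam)) < 3 * mcse


def test_zero_kernel_stops_at_zero():
    lam = pj.stochastic_lambda([_Wrap([[0.0]])], n_steps=100,
                               rng=np.random.default_rng(0))
    assert lam == 0.0


def test_lambda_s_never_exceeds_mean_kernel_growth():
    """Tuljapurkar dampening on seeded scalar-kernel families.

    Multiplicative year noise rescaled to preserve the arithmetic-mean
    kernel can only lower the stochastic growth rate.
    """
    rng = np.random.default_rng(1)
    for _ in range(6):
        base = rng.uniform(0.5, 1.5)
        sig = rng.uniform(0.2, 0.8)
        f = np.exp(rng.normal(0.0, sig, 7))
        f /= f.mean()                            # mean kernel = base exactly
        lam = pj.stochastic_lambda([_Wrap([[base * x]]) for x in f],
                                   n_steps=20_000,
                                   rng=np.random.default_rng(42))
        assert lam <= base + 1e-9
        # and λ_S equals the geometric mean of the family, within MC error
        gm = base * np.exp(np.mean(np.log(f)))
        assert lam == pytest.approx(gm, rel=0.02)


def test_entrywise_larger_kernels_dominate():
    rng = np.random.default_rng(5)
    A = rng.uniform(0.1, 0.5, (3, 3))
    B = A + rng.uniform(0.0, 0.2, (3, 3))        # entrywise >= A
    seed = 11
    lam_a = pj.stochastic_lambda([_Wrap(A)], 5000, np.random.default_rng(seed))
    lam_b = pj.stochastic_lambda([_Wrap(B)], 5000, np.random.default_rng(seed))
    assert lam_b >= lam_a


# ---------------------------------------------------------------------------
# transient projections
# ---------------------------------------------------------------------------

def _mesh_kernel(factor):
    mesh = kn.build_mesh(30.0, 10)
    rs = constant_rateset(survival=factor, growth_sd=3.0)
    return kn.build_kernel(rs, mesh)


def test_all_zero_kernel_extinct_at_first_step():
    K = _mesh_kernel(0.0)
    cfg = pj.StochasticRunConfig.desk(n_trajectories=50, horizon_years=5)
    sizes, extinct = pj.transient_project([K], 100, cfg,
                                          np.random.default_rng(0))
    assert extinct.all()
    assert np.all(sizes[:, 1:] == 0)


def test_supercritical_kernel_never_extinct():
    mesh = kn.build_mesh(30.0, 10)
    rs = constant_rateset(survival=1.0,
                          fruits_n=lambda z: np.full(np.shape(z), 10.0),
                          recruit_rate=0.2)
    K = kn.build_kernel(rs, mesh)      # survival 1 + 2 recruits/plant: λ = 3
    assert K.dominant_eigenvalue() == pytest.approx(3.0, rel=0.01)
    cfg = pj.StochasticRunConfig.desk(n_trajectories=200, horizon_years=22)
    sizes, extinct = pj.transient_project([K], 1000, cfg,
                                          np.random.default_rng(0))
    assert extinct.sum() == 0
    assert np.all(sizes[:, -1] > sizes[:, 0])


def test_projected_totals_are_integers():
    K = _mesh_kernel(0.6)
    cfg = pj.StochasticRunConfig.desk(n_trajectories=40, horizon_years=10)
    sizes, _ = pj.transient_project([K], 37, cfg, np.random.default_rng(2))
    assert np.allclose(sizes, np.rint(sizes))
    assert np.all(sizes >= 0)


def test_transient_monotone_in_kernel(small_rates, small_mesh):
    """Same random kernel sequence: a larger kernel yields larger sizes."""
    K = kn.build_kernel(small_rates.rateset(), small_mesh)
    K2 = kn.MultiMatrixKernel(mesh=small_mesh, blocks={
        k: 1.2 * v for k, v in K.blocks.items()})
    cfg = pj.StochasticRunConfig.desk(n_trajectories=50, horizon_years=8)
    s1, _ = pj.transient_project([K], 500, cfg, np.random.default_rng(9))
    s2, _ = pj.transient_project([K2], 500, cfg, np.random.default_rng(9))
    assert np.all(s2[:, -1] >= s1[:, -1])


# ---------------------------------------------------------------------------
# bootstrap summaries
# ---------------------------------------------------------------------------

def _draw(lam, pe, n, traj=None):
    return pj.BootstrapDraw(lambda_s=lam, pr_ext=pe, mean_n_final=n,
                            median_trajectory=np.zeros(3) if traj is None
                            else traj)


def test_summary_constant_draws():
    s = pj.summarize_bootstrap([_draw(0.5, 1.0, 7.0)] * 10)
    assert s.lambda_s_median == 0.5
    assert s.lambda_s_ci == (0.5, 0.5)
    assert s.pr_ext_mean == 1.0
    assert s.pr_ext_ci == (1.0, 1.0)
    assert s.pred_n_mean == 7.0


def test_summary_percentiles_match_order_statistics():
    draws = [_draw(float(k), 0.0, float(k)) for k in range(1, 101)]
    s = pj.summarize_bootstrap(draws)
    lo, hi = np.percentile(np.arange(1.0, 101.0), [2.5, 97.5])
    assert s.lambda_s_ci == pytest.approx((lo, hi))
    assert s.pred_n_median == pytest.approx(50.5)


def test_summary_requires_two_draws():
    with pytest.raises(ValueError):
        pj.summarize_bootstrap([_draw(1.0, 0.0, 1.0)])


def test_bootstrap_population_reproducible(small_rates, small_mesh):
    cfg = pj.StochasticRunConfig(n_steps=300, n_bootstrap=4,
                                 n_trajectories=20, horizon_years=6)
    s1 = pj.bootstrap_population(small_rates, small_mesh, 80, cfg,
                                 np.random.default_rng(3))
    s2 = pj.bootstrap_population(small_rates, small_mesh, 80, cfg,
                                 np.random.default_rng(3))
    assert np.array_equal(s1.lambda_s_draws, s2.lambda_s_draws)
    assert np.array_equal(s1.pr_ext_draws, s2.pr_ext_draws)
    assert s1.pr_ext_ci[0] <= s1.pr_ext_mean <= s1.pr_ext_ci[1] or \
        s1.pr_ext_mean in s1.pr_ext_ci
    d = s1.to_dict()
    assert set(d) >= {"lambda_s_median", "pr_ext_mean", "pred_n_mean",
                      "lambda_s_ci", "pr_ext_ci", "pred_n_ci"}


def test_run_config_validation():
    with pytest.raises(ValueError):
        pj.StochasticRunConfig(n_steps=0)
    with pytest.raises(ValueError):
        pj.StochasticRunConfig(extinction_threshold=-1)
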