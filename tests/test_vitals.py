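"""Vital-rate regressions, AICc selection, and bootstrap coefficient draws."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ipmviability import vitals as vt
from ipmviability.errors import FittingError


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table, chosen", [
    ({"size_size2": 100.0, "size": 101.5, "intercept": 108.0}, "size"),
    ({"size_size2": 100.0, "size": 105.0}, "size_size2"),
    ({"size_size2": 100.0, "size": 100.5, "intercept": 101.9}, "intercept"),
    ({"size": 50.0, "size2": 50.0}, "size"),       # equal-AICc tie: name order
])
def test_select_model_parsimony_rule(table, chosen):
    assert vt.select_model(table) == chosen


def test_select_model_order_invariant():
    table = {"intercept": 101.9, "size_size2": 100.0, "size": 100.5}
    shuffled = dict(reversed(list(table.items())))
    assert vt.select_model(table) == vt.select_model(shuffled)


def test_select_model_empty_or_nonfinite():
    with pytest.raises(FittingError):
        vt.select_model({})
    with pytest.raises(FittingError):
        vt.select_model({"size": np.inf})


# ---------------------------------------------------------------------------
# prediction / link inverses
# ---------------------------------------------------------------------------

def _manual_fit(name, family, beta, terms, cov=None, sigma_year=0.0,
                year_df=0, resid_sd=None):
    beta = np.asarray(beta, float)
    cov = np.zeros((len(beta), len(beta))) if cov is None else np.asarray(cov)
    return vt.FittedVitalRate(
        name=name, family=family, population="X", structure="manual",
        terms=terms, beta=beta, cov=cov, sigma_year=sigma_year,
        year_df=year_df, year_deltas={}, aicc_table={}, n_obs=0,
        resid_sd=resid_sd)


def test_predict_logit_identity_point():
    f = _manual_fit("s", "binomial", [0.0, 0.0, 0.0], ("size", "size2"))
    assert f.predict(17.3) == pytest.approx(0.5)


def test_predict_logit_hand_value():
    f = _manual_fit("s", "binomial", [-1.0, 0.2, -0.005], ("size", "size2"))
    # logistic(-1 + 2 - 0.5) = logistic(0.5)
    assert f.predict(10.0) == pytest.approx(expit(0.5), abs=1e-12)
    assert f.predict(10.0) == pytest.approx(0.6225, abs=1e-4)


def test_predict_poisson_constant_mean():
    f = _manual_fit("f", "poisson", [np.log(3.0), 0.0], ("size",))
    assert f.predict(0.0) == pytest.approx(3.0)
    assert f.predict(55.0) == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_constant_response_falls_back_to_intercept():
    df = pd.DataFrame({"y": np.ones(50), "size": np.linspace(1, 30, 50),
                       "year": np.repeat([1990, 1991], 25)})
    f = vt.fit_candidates(df, vt.VitalRateSpec("s", "binomial"), "X")
    assert f.structure == "intercept"
    assert "constant_response" in f.flags
    assert 0.9 < f.predict(10.0) < 1.0       # Jeffreys shrinkage, not 1.0


def test_quadratic_truth_is_selected_at_scale():
    rng = np.random.default_rng(0)
    n = 6000
    z = rng.uniform(0, 45, n)
    eta = -0.3 + 0.09 * z - 0.0011 * z * z
    y = (rng.random(n) < expit(eta)).astype(float)
    df = pd.DataFrame({"y": y, "size": z, "year": rng.integers(1990, 1997, n)})
    f = vt.fit_candidates(df, vt.RATE_SPECS["survival_normal"], "X")
    assert f.structure == "size_size2"
    assert np.abs(f.beta - [-0.3, 0.09, -0.0011]).max() < 3 * f.cov.diagonal().max() ** 0.5 + 0.05


def test_gaussian_zero_year_variance_detected():
    rng = np.random.default_rng(1)
    n = 4000
    z = rng.uniform(2, 40, n)
    y = np.clip(3.0 + 0.9 * z + rng.normal(0, 3.0, n), 1e-3, None)
    df = pd.DataFrame({"y": y, "size": z, "year": rng.integers(1990, 1997, n)})
    f = vt.fit_candidates(df, vt.RATE_SPECS["growth"], "X")
    assert f.family == "gaussian"
    assert f.sigma_year < 0.5                 # truth is exactly 0
    assert f.resid_sd == pytest.approx(3.0, rel=0.1)


def test_truncated_gaussian_mle_handles_boundary():
    """OLS is biased upward when the response is truncated at zero."""
    rng = np.random.default_rng(2)
    n = 20000
    z = rng.uniform(0.5, 6, n)
    mu = 1.0 + 0.9 * z
    from scipy.stats import truncnorm
    y = truncnorm.rvs(-mu / 3.0, np.inf, loc=mu, scale=3.0, random_state=rng)
    df = pd.DataFrame({"y": y, "size": z, "year": 0})
    spec = vt.VitalRateSpec("growth", "gaussian", candidates=("size",))
    f = vt.fit_candidates(df, spec, "X")
    assert f.beta[0] == pytest.approx(1.0, abs=0.15)
    assert f.beta[1] == pytest.approx(0.9, abs=0.05)
    assert f.resid_sd == pytest.approx(3.0, rel=0.05)


def test_recruit_size_truncnorm_mle():
    from scipy.stats import truncnorm
    rng = np.random.default_rng(3)
    x = truncnorm.rvs(-2.0, np.inf, loc=4.0, scale=2.0, size=20000,
                      random_state=rng)
    mu, sd = vt._fit_truncnorm(x)
    assert mu == pytest.approx(4.0, abs=0.1)
    assert sd == pytest.approx(2.0, abs=0.1)


# ---------------------------------------------------------------------------
# bootstrap draws
# ---------------------------------------------------------------------------

def test_draw_zero_covariance_returns_point_estimate():
    f = _manual_fit("s", "binomial", [0.5, -0.1], ("size",))
    d = vt.draw_coefficients(f, 7, np.random.default_rng(0))
    assert np.array_equal(d.beta, f.beta)
    assert np.all(d.deltas == 0.0)


def test_draw_mvn_sampling_matches_target():
    cov = np.array([[0.04, 0.01], [0.01, 0.02]])
    f = _manual_fit("s", "binomial", [1.0, -0.5], ("size",), cov=cov)
    rng = np.random.default_rng(42)
    draws = np.array([vt.draw_coefficients(f, 1, rng).beta for _ in range(10_000)])
    se_mean = np.sqrt(np.diag(cov) / len(draws))
    assert np.all(np.abs(draws.mean(axis=0) - f.beta) < 3 * se_mean)
    assert np.allclose(np.cov(draws.T), cov, rtol=0.10)


def test_draw_reproducible_and_year_variance_propagates():
    f = _manual_fit("s", "binomial", [0.0], (), sigma_year=0.4, year_df=6)
    d1 = vt.draw_coefficients(f, 7, np.random.default_rng(5))
    d2 = vt.draw_coefficients(f, 7, np.random.default_rng(5))
    assert np.array_equal(d1.deltas, d2.deltas)
    assert len(d1.deltas) == 7
    assert d1.sigma_year > 0
    # sigma itself is redrawn: long-run SD of deltas matches a scaled chi-square
    rng = np.random.default_rng(6)
    sds = [vt.draw_coefficients(f, 1, rng).sigma_year for _ in range(4000)]
    assert np.mean(np.square(sds)) == pytest.approx(0.16, rel=0.1)


def test_draw_requires_positive_intervals():
    f = _manual_fit("s", "binomial", [0.0], ())
    with pytest.raises(ValueError):
        vt.draw_coefficients(f, 0, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# tables and population-level fitting
# ---------------------------------------------------------------------------

def test_make_tables_latent_size_memory():
    """A bolter year carries the plant's last normal size as its size."""
    from ipmviability import census as cs
    df = pd.DataFrame({
        "population": "A", "transect": "T", "quadrat": "Q",
        "plant_id": "p1", "year": [1990, 1991, 1992],
        "diameter_mm": [10.0, np.nan, 12.0],
        "survival": [1, 1, 1], "fruits": [0, 3, 0]})
    tables = vt.make_tables(cs.build_histories(df))
    tr = tables["transitions"]
    bolter_row = tr[tr["src_state"] == "bolter"].iloc[0]
    assert bolter_row["size"] == 10.0
    rp = tables["reproduction"]
    assert rp[rp["state"] == "bolter"]["fruits"].iloc[0] == 3.0


def test_fit_population_rates_complete(small_rates):
    pr = small_rates
    assert set(pr.fits) == set(vt.RATE_SPECS)
    assert 0 <= pr.recruit_rate < 5
    assert pr.recruit_size_sd > 0
    assert len(pr.intervals) == 7
    for f in pr.fits.values():
        assert np.all(np.isfinite(f.beta))
        # covariance is symmetric positive semi-definite
        w = np.linalg.eigvalsh((f.cov + f.cov.T) / 2)
        assert w.min() > -1e-8


def test_population_rateset_builds_kernel(small_rates, small_mesh):
    from ipmviability import kernel as kn
    K = kn.build_kernel(small_rates.rateset(), small_mesh, population="P1")
    assert np.isfinite(K.matrix).all()
    assert (K.matrix >= 0).all()
    assert 0 < K.dominant_eigenvalue() < 3


def test_annual_kernels_one_per_interval(small_rates, small_mesh):
    ks = small_rates.annual_kernels(small_mesh,
                                    rng=np.random.default_rng(0))
    assert len(ks) == len(small_rates.intervals)
    # drawn kernels differ across intervals through the year deviations
    diffs = [np.abs(ks[0].matrix - k.matrix).max() for k in ks[1:]]
    assert max(diffs) > 0
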