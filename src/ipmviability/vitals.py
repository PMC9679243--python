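"""Vital-rate regressions with AICc model selection and bootstrap draws.

Each vital rate (survival, growth, reproduction, state transitions …) is fit
per population as a generalized linear model of rosette diameter with year
intercepts, comparing four nested fixed-effect structures —
``intercept + size + size²``, ``intercept + size``, ``intercept + size²``
and ``intercept-only`` — by small-sample AICc.  The model with the lowest
AICc wins unless competitors sit within 2 AICc units, in which case the most
parsimonious (fewest-effects) candidate is chosen.

Year-to-year variation is modeled with sum-coded year intercepts (every
candidate keeps the identical year structure); the between-year SD is
recovered by method of moments from the fitted yearly deviations and its
estimation uncertainty is propagated into bootstrap draws as a scaled
chi-square with ``n_years − 1`` degrees of freedom.  Parametric-bootstrap
coefficient sets are sampled from MVN(β̂, Σ̂_β).

Bolters and dormant plants have no measurable rosette, so their rates are
regressions on *latent size* — the plant's last recorded normal size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2, norm

from . import kernel as kn
from .census import BOLTER, DEAD, DORMANT, NORMAL, IndividualHistory
from .errors import FittingError
from .utils import linpred

#: candidate fixed-effect structures, ordered by parameter count
CANDIDATE_TERMS = {
    "intercept": (),
    "size": ("size",),
    "size2": ("size2",),
    "size_size2": ("size", "size2"),
}
CANDIDATE_NPARAMS = {k: 1 + len(v) for k, v in CANDIDATE_TERMS.items()}

FAMILIES = {
    "binomial": sm.families.Binomial,
    "gaussian": sm.families.Gaussian,
    "poisson": sm.families.Poisson,
}

#: below this many observations a state-specific rate falls back to a pooled
#: or degenerate estimate rather than an unstable regression
MIN_OBS = 10


@dataclass(frozen=True)
class VitalRateSpec:
    """Name, response family and candidate structures of one vital rate."""

    name: str
    family: str
    candidates: tuple = ("intercept", "size", "size2", "size_size2")

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        bad = [c for c in self.candidates if c not in CANDIDATE_TERMS]
        if bad:
            raise ValueError(f"unknown candidate structures {bad}")


@dataclass
class FittedVitalRate:
    """Selected regression for one vital rate × population."""

    name: str
    family: str
    population: str
    structure: str
    terms: tuple
    beta: np.ndarray
    cov: np.ndarray                    # fixed-effect variance-covariance
    sigma_year: float
    year_df: int                       # df for the year-variance chi-square
    year_deltas: dict                  # year -> estimated deviation
    aicc_table: dict
    n_obs: int
    resid_sd: float | None = None      # gaussian only
    flags: tuple = ()

    def linear_predictor(self, z, delta: float = 0.0, beta=None):
        b = self.beta if beta is None else beta
        return linpred(b, self.terms, z, delta=delta)

    def predict(self, z, delta: float = 0.0, beta=None):
        """Rate on the response scale at size ``z`` (mm)."""
        eta = self.linear_predictor(z, delta=delta, beta=beta)
        if self.family == "binomial":
            return expit(eta)
        if self.family == "poisson":
            # bootstrap draws of a weakly identified quadratic can run off at
            # extrapolated sizes; keep the mean finite
            return np.exp(np.clip(eta, -30.0, 30.0))
        return eta

    def rate_function(self, delta: float = 0.0, beta=None):
        b = np.array(self.beta if beta is None else beta, dtype=float)
        return lambda z: self.predict(z, delta=delta, beta=b)

    def to_dict(self) -> dict:
        return {
            "name": self.name, "family": self.family,
            "population": self.population, "structure": self.structure,
            "terms": list(self.terms), "beta": self.beta.tolist(),
            "cov": self.cov.tolist(), "sigma_year": self.sigma_year,
            "year_df": self.year_df,
            "year_deltas": {str(k): float(v) for k, v in self.year_deltas.items()},
            "aicc_table": {k: float(v) for k, v in self.aicc_table.items()},
            "n_obs": self.n_obs, "resid_sd": self.resid_sd,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedVitalRate":
        return cls(
            name=d["name"], family=d["family"], population=d["population"],
            structure=d["structure"], terms=tuple(d["terms"]),
            beta=np.asarray(d["beta"], float), cov=np.asarray(d["cov"], float),
            sigma_year=d["sigma_year"], year_df=d["year_df"],
            year_deltas={int(k): v for k, v in d["year_deltas"].items()},
            aicc_table=d["aicc_table"], n_obs=d["n_obs"],
            resid_sd=d.get("resid_sd"), flags=tuple(d.get("flags", ())),
        )


@dataclass
class CoefficientDraw:
    """One parametric-bootstrap sample of a vital rate's parameters."""

    beta: np.ndarray
    deltas: np.ndarray        # one annual deviation per intercensus interval
    sigma_year: float


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def select_model(aicc_table: dict) -> str:
    """Most parsimonious structure within 2 AICc units of the minimum.

    Ties in parameter count resolve to the lower AICc, then to canonical
    name order, so the choice is invariant to input ordering.
    """
    finite = {k: v for k, v in aicc_table.items() if np.isfinite(v)}
    if not finite:
        raise FittingError("no candidate with a finite AICc")
    best = min(finite.values())
    pool = [k for k, v in finite.items() if v - best < 2.0]
    return min(pool, key=lambda k: (CANDIDATE_NPARAMS[k], finite[k], k))


def _aicc(llf: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class _MLEResult:
    """Minimal fitted-model facade (mirrors the GLMResults API we use)."""

    params: np.ndarray
    _cov: np.ndarray
    llf: float

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self._cov))

    def cov_params(self) -> np.ndarray:
        return self._cov


def _fit_gaussian_truncated(y, X) -> _MLEResult:
    """Linear regression of a size response left-truncated at zero.

    Rosette diameters cannot be ≤ 0, so observed next-year sizes follow a
    zero-truncated Normal around the growth mean — the same density the
    discretized growth kernel uses after eviction renormalization.  Fitted
    by MLE with an analytic gradient; the last parameter is log(residual
    SD), and the covariance comes from the numerically differentiated score
    at the optimum.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)

    def nll_grad(theta):
        b, logs = theta[:-1], theta[-1]
        s = np.exp(logs)
        mu = X @ b
        r = y - mu
        a = mu / s
        logcdf = norm.logcdf(a)
        ll = (-0.5 * np.log(2 * np.pi) - logs - r * r / (2 * s * s) - logcdf)
        ratio = np.exp(norm.logpdf(a) - logcdf)          # hazard φ/Φ, stable
        dmu = r / (s * s) - ratio / s
        dlogs = -1.0 + r * r / (s * s) + ratio * a
        grad = np.append(X.T @ dmu, dlogs.sum())
        return -ll.sum(), -grad

    ols = sm.OLS(y, X).fit()
    start = np.append(ols.params, np.log(max(float(np.sqrt(ols.scale)), 1e-6)))
    opt = minimize(nll_grad, start, jac=True, method="BFGS",
                   options={"maxiter": 300, "gtol": 1e-6 * n})
    theta = opt.x

    # observed information by central differences of the analytic score
    p = len(theta)
    H = np.zeros((p, p))
    eps = 1e-5 * np.maximum(np.abs(theta), 1.0)
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps[j]
        tm[j] -= eps[j]
        H[:, j] = (nll_grad(tp)[1] - nll_grad(tm)[1]) / (2 * eps[j])
    H = (H + H.T) / 2.0
    cov = np.linalg.pinv(H)
    return _MLEResult(params=theta, _cov=cov, llf=-float(opt.fun))


def _year_design(years: np.ndarray):
    """Sum-coded year dummies; the intercept is the average-year intercept."""
    uy = np.sort(np.unique(years))
    if len(uy) < 2:
        return np.empty((len(years), 0)), uy
    D = np.zeros((len(years), len(uy) - 1))
    for j, y in enumerate(uy[:-1]):
        D[:, j] = (years == y).astype(float)
    D -= (years == uy[-1]).astype(float)[:, None]
    return D, uy


def _design(size: np.ndarray, years: np.ndarray, structure: str):
    terms = CANDIDATE_TERMS[structure]
    cols = [np.ones_like(size)]
    for t in terms:
        cols.append(size if t == "size" else size ** 2)
    D, uy = _year_design(years)
    X = np.column_stack(cols + ([D] if D.shape[1] else []))
    return X, terms, uy


def _degenerate_fit(y, family, name, population, n_obs, flag):
    """Intercept-only penalized estimate for constant/degenerate responses.

    Binomial uses the Jeffreys-style (k+½)/(n+1) shrinkage so complete
    separation still yields a finite logit.
    """
    y = np.asarray(y, float)
    n = len(y)
    if family == "binomial":
        p = (y.sum() + 0.5) / (n + 1.0)
        beta = np.array([logit(p)])
        cov = np.array([[1.0 / (n * p * (1 - p))]])
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    elif family == "poisson":
        mu = (y.sum() + 0.5) / (n + 1.0)
        beta = np.array([np.log(mu)])
        cov = np.array([[1.0 / (n * mu)]])
        llf = float(np.sum(y * np.log(mu) - mu))
    else:
        mu = float(y.mean())
        sd = float(y.std(ddof=1)) if n > 1 else 0.0
        beta = np.array([mu])
        cov = np.array([[sd ** 2 / max(n, 1)]])
        llf = float(np.sum(norm.logpdf(y, mu, max(sd, 1e-8))))
    return FittedVitalRate(
        name=name, family=family, population=population,
        structure="intercept", terms=(), beta=beta, cov=cov,
        sigma_year=0.0, year_df=0, year_deltas={},
        aicc_table={"intercept": _aicc(llf, 1, n)}, n_obs=n_obs,
        resid_sd=(float(np.std(y, ddof=1)) if family == "gaussian" and n > 1
                  else None),
        flags=(flag,),
    )


def fit_candidates(data: pd.DataFrame, spec: VitalRateSpec,
                   population: str = "", response: str = "y",
                   size: str = "size", year: str = "year") -> FittedVitalRate:
    """Fit all candidate size structures and select one by AICc.

    All candidates share the identical year-intercept structure and the
    identical observation set (rows with missing response or size are
    dropped up front), so AICc values are comparable.  A candidate that
    fails to converge is flagged and excluded; if every candidate fails a
    :class:`FittingError` is raised.
    """
    df = data.dropna(subset=[response, size])
    n = len(df)
    if n == 0:
        raise FittingError(f"{spec.name}/{population}: no usable observations")
    y = df[response].to_numpy(dtype=float)
    z = df[size].to_numpy(dtype=float)
    yrs = df[year].to_numpy() if year in df else np.zeros(n, dtype=int)

    if spec.family in ("binomial", "poisson") and np.all(y == y[0]):
        return _degenerate_fit(y, spec.family, spec.name, population, n,
                               "constant_response")

    fam = FAMILIES[spec.family]()

    def _run(yrs_used):
        results, aicc_table, flags = {}, {}, []
        for cand in spec.candidates:
            X, terms, uy = _design(z, yrs_used, cand)
            if n <= X.shape[1] + 1:
                aicc_table[cand] = np.inf
                continue
            try:
                if spec.family == "gaussian":
                    res = _fit_gaussian_truncated(y, X)
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = sm.GLM(y, X, family=fam).fit(maxiter=200)
                ok = (np.all(np.isfinite(res.params))
                      and np.all(np.isfinite(res.bse)))
                # quasi-separation: any coefficient (incl. a year dummy for a
                # year with a constant response) running off to the boundary
                if ok and spec.family in ("binomial", "poisson") and (
                        np.any(np.abs(res.params) > 15)
                        or np.any(res.bse > 30)):
                    ok = False
            except Exception:
                ok = False
                res = None
            if not ok:
                aicc_table[cand] = np.inf
                flags.append(f"candidate_failed:{cand}")
                continue
            # gaussian fits carry the residual-SD parameter in the model
            k = X.shape[1] + (1 if spec.family == "gaussian" else 0)
            aicc_table[cand] = _aicc(res.llf, k, n)
            results[cand] = (res, terms, uy)
        return results, aicc_table, flags

    results, aicc_table, flags = _run(yrs)
    if not results and len(np.unique(yrs)) > 1:
        # a year with a constant response separates the sum-coded dummies;
        # refit without year effects rather than lose the size structure
        results, aicc_table, flags = _run(np.zeros(n, dtype=int))
        flags.append("year_effects_dropped")

    if not results:
        if spec.family == "binomial":
            return _degenerate_fit(y, spec.family, spec.name, population, n,
                                   "separation_fallback")
        raise FittingError(f"{spec.name}/{population}: all candidates failed")

    chosen = select_model(aicc_table)
    res, terms, uy = results[chosen]
    p_fix = 1 + len(terms)
    n_extra = 1 if spec.family == "gaussian" else 0   # trailing log-SD param
    beta = np.asarray(res.params[:p_fix], float)
    cov = np.asarray(res.cov_params()[:p_fix, :p_fix], float)

    # year deviations and method-of-moments between-year variance
    year_deltas, sigma_year, year_df = {}, 0.0, 0
    if len(uy) >= 2:
        stop = len(res.params) - n_extra
        c = np.asarray(res.params[p_fix:stop], float)
        C = np.asarray(res.cov_params()[p_fix:stop, p_fix:stop], float)
        deltas = np.append(c, -c.sum())
        se2 = np.append(np.diag(C), float(np.ones(len(c)) @ C @ np.ones(len(c))))
        year_deltas = {int(yv): float(d) for yv, d in zip(uy, deltas)}
        year_df = len(uy) - 1
        var_mom = np.var(deltas, ddof=1) - se2.mean()
        sigma_year = float(np.sqrt(max(var_mom, 0.0)))

    resid_sd = (float(np.exp(res.params[-1]))
                if spec.family == "gaussian" else None)
    return FittedVitalRate(
        name=spec.name, family=spec.family, population=population,
        structure=chosen, terms=terms, beta=beta, cov=cov,
        sigma_year=sigma_year, year_df=year_df, year_deltas=year_deltas,
        aicc_table={k: float(v) for k, v in aicc_table.items()},
        n_obs=n, resid_sd=resid_sd, flags=tuple(flags),
    )


def draw_coefficients(fit: FittedVitalRate, n_intervals: int,
                      rng: np.random.Generator) -> CoefficientDraw:
    """Parametric-bootstrap draw: β* ~ MVN(β̂, Σ̂) plus annual deviations.

    The year variance is itself drawn from its sampling distribution
    (scaled chi-square, df = number of years − 1) before the per-interval
    deviations δ_t ~ N(0, σ*) are sampled.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    cov = np.asarray(fit.cov, float)
    if np.any(cov):
        w, V = np.linalg.eigh((cov + cov.T) / 2.0)
        if np.any(w < -1e-10):
            warnings.warn(f"{fit.name}: covariance repaired by eigenvalue clipping")
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)
        beta = fit.beta + L @ rng.standard_normal(len(fit.beta))
    else:
        beta = fit.beta.copy()
    if fit.sigma_year > 0 and fit.year_df > 0:
        var_star = fit.sigma_year ** 2 * chi2.rvs(fit.year_df, random_state=rng) / fit.year_df
        sigma_star = float(np.sqrt(var_star))
    else:
        sigma_star = 0.0
    deltas = (rng.normal(0.0, sigma_star, size=n_intervals)
              if sigma_star > 0 else np.zeros(n_intervals))
    return CoefficientDraw(beta=np.asarray(beta, float), deltas=deltas,
                           sigma_year=sigma_star)


# ---------------------------------------------------------------------------
# transition tables from histories
# ---------------------------------------------------------------------------

def make_tables(histories: Iterable[IndividualHistory]) -> dict:
    """Regression-ready tables derived from corrected histories.

    Returns ``transitions`` (one row per plant × intercensus interval while
    alive, with latent size for sizeless states), ``reproduction`` (one row
    per aboveground plant-year with a recorded fruit count), ``recruitment``
    (per-population, per-interval fruit totals and next-year recruit counts)
    and ``recruit_sizes`` (first-year sizes of new recruits).
    """
    trans, repro, rsizes = [], [], []
    fruit_tot: dict = {}
    recruit_tot: dict = {}
    for h in histories:
        if not h.ever_alive:
            continue
        years = h.years
        first_year = years[0]
        latent = np.nan
        for i, y in enumerate(years):
            st = h.states[i]
            if st not in (NORMAL, BOLTER, DORMANT):
                continue
            if st == NORMAL:
                latent = h.sizes[i]
            z = h.sizes[i] if st == NORMAL else latent
            f = h.fruits[i]
            if st in (NORMAL, BOLTER) and np.isfinite(f):
                repro.append((h.population, y, st, z, f, int(f > 0)))
                fruit_tot[(h.population, y)] = \
                    fruit_tot.get((h.population, y), 0.0) + f
            if y == h.recruitment_year and y > first_year:
                recruit_tot[(h.population, y)] = \
                    recruit_tot.get((h.population, y), 0) + 1
                if st == NORMAL:
                    rsizes.append((h.population, h.sizes[i]))
            if i < len(years) - 1:
                survived = h.corrected_survival[i + 1] == "1"
                dst = h.states[i + 1] if survived else DEAD
                dst_size = h.sizes[i + 1] if survived and \
                    h.states[i + 1] == NORMAL else np.nan
                trans.append((h.population, y, st, z, int(survived),
                              dst, dst_size))

    transitions = pd.DataFrame(
        trans, columns=["population", "year", "src_state", "size",
                        "survived", "dst_state", "dst_size"])
    reproduction = pd.DataFrame(
        repro, columns=["population", "year", "state", "size",
                        "fruits", "flowered"])
    rec_rows = []
    for (pop, y), fr in sorted(fruit_tot.items()):
        rec_rows.append((pop, y, fr, recruit_tot.get((pop, y + 1), 0)))
    recruitment = pd.DataFrame(
        rec_rows, columns=["population", "year", "fruits", "recruits_next"])
    recruit_sizes = pd.DataFrame(rsizes, columns=["population", "size"])
    return {"transitions": transitions, "reproduction": reproduction,
            "recruitment": recruitment, "recruit_sizes": recruit_sizes}


# ---------------------------------------------------------------------------
# population-level rate sets
# ---------------------------------------------------------------------------

RATE_SPECS = {
    "survival_normal": VitalRateSpec("survival_normal", "binomial"),
    "survival_bolter": VitalRateSpec("survival_bolter", "binomial"),
    "survival_dormant": VitalRateSpec("survival_dormant", "binomial"),
    "growth": VitalRateSpec("growth", "gaussian"),
    "prob_bolt": VitalRateSpec("prob_bolt", "binomial"),
    "trans_nd": VitalRateSpec("trans_nd", "binomial"),
    "trans_bn": VitalRateSpec("trans_bn", "binomial"),
    "trans_bd": VitalRateSpec("trans_bd", "binomial"),
    "trans_dn": VitalRateSpec("trans_dn", "binomial"),
    "trans_db": VitalRateSpec("trans_db", "binomial"),
    "prob_flower_normal": VitalRateSpec("prob_flower_normal", "binomial"),
    "prob_flower_bolter": VitalRateSpec("prob_flower_bolter", "binomial"),
    "fecundity_normal": VitalRateSpec("fecundity_normal", "poisson"),
    "fecundity_bolter": VitalRateSpec("fecundity_bolter", "poisson"),
}


def _fit_truncnorm(x: np.ndarray) -> tuple[float, float]:
    """MLE of a zero-left-truncated Normal (recruit sizes cannot be ≤ 0)."""
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return (float(x.mean()) if len(x) else np.nan, np.nan)
    m0, s0 = float(x.mean()), float(max(x.std(ddof=1), 1e-3))

    def nll(theta):
        mu, logsd = theta
        sd = np.exp(logsd)
        return -(np.sum(norm.logpdf(x, mu, sd))
                 - len(x) * norm.logsf(0.0, mu, sd))

    res = minimize(nll, x0=[m0, np.log(s0)], method="Nelder-Mead")
    mu, sd = float(res.x[0]), float(np.exp(res.x[1]))
    return mu, sd


@dataclass
class PopulationRates:
    """Every fitted vital rate of one population plus recruitment closure."""

    population: str
    fits: dict                      # rate name -> FittedVitalRate
    recruit_rate: float             # recruits per fruit
    recruit_size_mean: float
    recruit_size_sd: float
    intervals: tuple                # interval start years
    fruit_cap: float = np.inf       # ceiling on predicted per-plant fruits
    flags: tuple = ()

    def draw(self, rng: np.random.Generator) -> dict:
        """One bootstrap draw (β*, per-interval δ) for every rate."""
        return {name: draw_coefficients(f, len(self.intervals), rng)
                for name, f in self.fits.items()}

    def rateset(self, draws: dict | None = None,
                interval: int = 0) -> kn.RateSet:
        """Rate functions for one annual kernel.

        With ``draws=None`` the point estimates with zero year deviations
        are used (the "mean-environment" kernel).
        """
        def rf(name):
            f = self.fits[name]
            if draws is None:
                return f.rate_function()
            d = draws[name]
            return f.rate_function(delta=float(d.deltas[interval]), beta=d.beta)

        growth_fit = self.fits["growth"]
        pf_n, fe_n = rf("prob_flower_normal"), rf("fecundity_normal")
        pf_b, fe_b = rf("prob_flower_bolter"), rf("fecundity_bolter")
        cap = self.fruit_cap

        def fruits_fn(pf, fe):
            # expected fruits; capped so an ill-identified bootstrap draw
            # cannot extrapolate to absurd seed production
            return lambda z: np.minimum(pf(z) * (1.0 + fe(z)), cap)

        return kn.RateSet(
            surv_n=rf("survival_normal"), surv_b=rf("survival_bolter"),
            surv_d=rf("survival_dormant"),
            growth_mean=rf("growth"), growth_sd=growth_fit.resid_sd,
            p_nb=rf("prob_bolt"), p_nd=rf("trans_nd"),
            p_bn=rf("trans_bn"), p_bd=rf("trans_bd"),
            p_dn=rf("trans_dn"), p_db=rf("trans_db"),
            fruits_n=fruits_fn(pf_n, fe_n),
            fruits_b=fruits_fn(pf_b, fe_b),
            recruit_rate=self.recruit_rate,
            recruit_size_mean=self.recruit_size_mean,
            recruit_size_sd=self.recruit_size_sd,
        )

    def annual_kernels(self, mesh: kn.MeshGrid,
                       rng: np.random.Generator | None = None) -> list:
        """One kernel per intercensus interval.

        With an ``rng`` this is one parametric-bootstrap replicate
        (coefficients drawn once, a fresh year deviation per interval);
        without, every interval collapses to the mean-environment kernel.
        """
        draws = self.draw(rng) if rng is not None else None
        return [
            kn.build_kernel(self.rateset(draws, i), mesh,
                            population=self.population, label=i)
            for i in range(len(self.intervals))
        ]


def _zero_rate(name, population, flag) -> FittedVitalRate:
    """Placeholder for a transition never observed (probability ~ 0)."""
    return FittedVitalRate(
        name=name, family="binomial", population=population,
        structure="intercept", terms=(), beta=np.array([-12.0]),
        cov=np.zeros((1, 1)), sigma_year=0.0, year_df=0, year_deltas={},
        aicc_table={"intercept": np.nan}, n_obs=0, flags=(flag,),
    )


def fit_population_rates(tables: dict, population: str) -> PopulationRates:
    """Fit the full per-state rate list of one population.

    Sparse sizeless-state rates (dormant survival with almost no observed
    dormancy, say) fall back to a pooled or near-zero estimate with a flag
    rather than an unstable regression.
    """
    tr = tables["transitions"]
    tr = tr[tr["population"] == population]
    rp = tables["reproduction"]
    rp = rp[rp["population"] == population]
    if tr.empty:
        raise FittingError(f"no transitions for population {population!r}")
    flags = []
    last_interval = tr["year"].max()

    def sub_tr(state):
        d = tr[tr["src_state"] == state]
        if state == DORMANT:
            # dormancy in the final census year is unobservable, so final-
            # interval dormant rows exist only when the plant re-emerged —
            # a selected sample that would bias the rate upward
            d = d[d["year"] < last_interval]
        return pd.DataFrame({"y": d["survived"].to_numpy(dtype=float),
                             "size": d["size"].to_numpy(dtype=float),
                             "year": d["year"].to_numpy()})

    def sub_dst(state, dst):
        d = tr[(tr["src_state"] == state) & (tr["survived"] == 1)]
        if dst == DORMANT or state == DORMANT:
            # a transition into dormancy cannot be scored in the final
            # interval (see above); drop the structurally censored rows
            d = d[d["year"] < last_interval]
        return pd.DataFrame({"y": (d["dst_state"] == dst).to_numpy(dtype=float),
                             "size": d["size"].to_numpy(dtype=float),
                             "year": d["year"].to_numpy()})

    fits = {}

    def fit_or_fallback(name, df, fallback=None):
        usable = df.dropna(subset=["y", "size"])
        if len(usable) >= MIN_OBS:
            fits[name] = fit_candidates(df, RATE_SPECS[name], population)
        elif fallback is not None:
            fits[name] = fallback()
            flags.append(f"{name}:sparse_fallback")
        else:
            fits[name] = _zero_rate(name, population, "never_observed")
            flags.append(f"{name}:never_observed")

    fit_or_fallback("survival_normal", sub_tr(NORMAL))

    def norm_surv_intercept():
        # pooled intercept-only survival borrowed from normal plants
        d = sub_tr(NORMAL)
        return _degenerate_fit(d["y"].to_numpy(), "binomial",
                               "survival_fallback", population, len(d),
                               "borrowed_from_normal")

    fit_or_fallback("survival_bolter", sub_tr(BOLTER), norm_surv_intercept)
    fit_or_fallback("survival_dormant", sub_tr(DORMANT), norm_surv_intercept)

    g = tr[(tr["src_state"].isin([NORMAL, BOLTER, DORMANT]))
           & (tr["survived"] == 1)]
    growth_df = pd.DataFrame({"y": g["dst_size"].to_numpy(dtype=float),
                              "size": g["size"].to_numpy(dtype=float),
                              "year": g["year"].to_numpy()})
    fits["growth"] = fit_candidates(growth_df, RATE_SPECS["growth"], population)

    fit_or_fallback("prob_bolt", sub_dst(NORMAL, BOLTER))
    fit_or_fallback("trans_nd", sub_dst(NORMAL, DORMANT))
    fit_or_fallback("trans_bn", sub_dst(BOLTER, NORMAL))
    fit_or_fallback("trans_bd", sub_dst(BOLTER, DORMANT))
    fit_or_fallback("trans_dn", sub_dst(DORMANT, NORMAL))
    fit_or_fallback("trans_db", sub_dst(DORMANT, BOLTER))

    for st, pf_name, fe_name in ((NORMAL, "prob_flower_normal", "fecundity_normal"),
                                 (BOLTER, "prob_flower_bolter", "fecundity_bolter")):
        d = rp[rp["state"] == st]
        pf_df = pd.DataFrame({"y": d["flowered"].to_numpy(dtype=float),
                              "size": d["size"].to_numpy(dtype=float),
                              "year": d["year"].to_numpy()})
        fit_or_fallback(pf_name, pf_df)
        dd = d[d["fruits"] > 0]
        fe_df = pd.DataFrame({"y": dd["fruits"].to_numpy(dtype=float) - 1.0,
                              "size": dd["size"].to_numpy(dtype=float),
                              "year": dd["year"].to_numpy()})
        fit_or_fallback(fe_name, fe_df)

    rec = tables["recruitment"]
    rec = rec[rec["population"] == population]
    # final census year has no observable next-year recruits
    rec = rec[rec["year"] < rec["year"].max()] if len(rec) else rec
    total_fruits = float(rec["fruits"].sum()) if len(rec) else 0.0
    total_recruits = float(rec["recruits_next"].sum()) if len(rec) else 0.0
    recruit_rate = total_recruits / total_fruits if total_fruits > 0 else 0.0

    rs = tables["recruit_sizes"]
    rs = rs[rs["population"] == population]["size"].to_numpy(dtype=float)
    if len(rs) >= MIN_OBS:
        r_mean, r_sd = _fit_truncnorm(rs)
    else:
        # no recruits observed: nominal small-rosette prior keeps the kernel
        # assemblable; the recruitment rate is 0 so it carries no mass
        r_mean, r_sd = 4.0, 2.0
        flags.append("recruit_sizes:sparse_fallback")

    # a predicted *mean* fruit count above every observed count is pure
    # extrapolation; clamp bootstrap-draw predictions to the observed range
    max_fruits = float(np.nanmax(rp["fruits"])) if len(rp) else 0.0
    years = np.sort(tr["year"].unique())
    return PopulationRates(
        population=population, fits=fits, recruit_rate=recruit_rate,
        recruit_size_mean=r_mean, recruit_size_sd=r_sd,
        intervals=tuple(int(y) for y in years),
        fruit_cap=max(max_fruits, 1.0), flags=tuple(flags),
    )
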