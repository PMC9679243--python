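"""Stochastic growth rates, transient projections and extinction risk.

Environmental stochasticity is modeled by drawing one of the annual kernels
independently and uniformly at random at each time step (IID environments).
The stochastic growth rate λ_S is the geometric mean of the step-wise growth
ratios over a long kernel sequence, with the state vector renormalized to
total one after every step to avoid rounding error.  Transient projections
start from the last census size, run a fixed horizon (22 years by default),
round the projected total to the nearest integer after each step — so
absorption at zero is possible — and score a trajectory extinct when the
total reaches the extinction threshold (zero individuals by default; a
single selfing hermaphrodite can found a population, so no quasi-extinction
cushion is assumed).

Uncertainty comes from the parametric bootstrap: each bootstrap replicate
redraws every vital-rate coefficient set and year deviations, rebuilds the
annual kernels, and recomputes λ_S and the transient summaries.  Confidence
intervals are percentile intervals across replicates (linear-interpolation
quantile rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernel as kn

__all__ = [
    "StochasticRunConfig", "ProjectionSummary", "stochastic_lambda",
    "transient_project", "summarize_bootstrap", "bootstrap_population",
]


@dataclass
class StochasticRunConfig:
    """Sizes of the stochastic simulations.

    Defaults are the full-scale analysis (50,000 λ steps, 5000 bootstrap
    replicates of 1000 22-year trajectories); the ``desk()`` preset shrinks
    them for interactive runs at the cost of Monte-Carlo noise.
    """

    n_steps: int = 50_000
    n_bootstrap: int = 5000
    n_trajectories: int = 1000
    horizon_years: int = 22
    extinction_threshold: float = 0.0
    initial_mode: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_steps", "n_bootstrap", "n_trajectories", "horizon_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")

    @classmethod
    def desk(cls, **kw) -> "StochasticRunConfig":
        base = dict(n_steps=2000, n_bootstrap=60, n_trajectories=100)
        base.update(kw)
        return cls(**base)


def stochastic_lambda(kernels: list, n_steps: int = 50_000,
                      rng: np.random.Generator | None = None,
                      v0: np.ndarray | None = None) -> float:
    """Geometric-mean growth rate under IID random kernel draws.

    At each step one kernel is chosen uniformly at random, the annual λ is
    the ratio of vector totals before and after the step, and the vector is
    renormalized to sum one.  Returns exp(mean(log λ_t)); a vector that hits
    exactly zero yields λ_S = 0 with an early stop.
    """
    if not kernels:
        raise ValueError("need at least one kernel")
    rng = np.random.default_rng() if rng is None else rng
    mats = [K.matrix for K in kernels]
    if v0 is None:
        dim = mats[0].shape[0]
        v = np.full(dim, 1.0 / dim)
    else:
        v = np.asarray(v0, float) / np.sum(v0)
    picks = rng.integers(0, len(mats), size=n_steps)
    log_sum = 0.0
    for t in range(n_steps):
        v = mats[picks[t]] @ v
        tot = v.sum()
        if tot <= 0.0:
            return 0.0
        log_sum += np.log(tot)
        v /= tot
    return float(np.exp(log_sum / n_steps))


def transient_project(kernels: list, n0: float,
                      config: StochasticRunConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_trajectories`` population paths over the horizon.

    The initial vector is uniform over cells and states, scaled to the last
    census size ``n0``.  After every annual step the total is rounded to the
    nearest integer (the stage vector is rescaled to the rounded total);
    a trajectory is extinct once the total is at or below the threshold.

    Returns ``(sizes, extinct)`` with ``sizes`` of shape
    ``(n_trajectories, horizon_years + 1)`` including year 0.
    """
    if n0 < 0:
        raise ValueError("initial population size must be >= 0")
    mats = [K.matrix for K in kernels]
    nk = len(mats)
    T, R = config.horizon_years, config.n_trajectories
    dim = mats[0].shape[0]
    base = kn.state_vector(kernels[0].mesh, mode=config.initial_mode)
    n_start = float(np.rint(n0))
    V = np.tile(base[:, None] * n_start, (1, R))
    sizes = np.zeros((R, T + 1))
    sizes[:, 0] = n_start
    alive = np.full(R, n_start > config.extinction_threshold)
    if not alive.any():
        return sizes, ~alive
    picks = rng.integers(0, nk, size=(T, R))
    for t in range(T):
        cols = np.flatnonzero(alive)
        newV = np.zeros((dim, len(cols)))
        for k in range(nk):
            sel = picks[t, cols] == k
            if sel.any():
                newV[:, sel] = mats[k] @ V[:, cols[sel]]
        totals = newV.sum(axis=0)
        rounded = np.rint(totals)
        dead = rounded <= config.extinction_threshold
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(totals > 0, rounded / totals, 0.0)
        newV *= scale
        newV[:, dead] = 0.0
        V[:, cols] = newV
        sizes[cols, t + 1] = rounded * (~dead)
        alive[cols[dead]] = False
    return sizes, ~alive


@dataclass
class BootstrapDraw:
    """Outcome of one parametric-bootstrap replicate."""

    lambda_s: float
    pr_ext: float
    mean_n_final: float
    median_trajectory: np.ndarray


@dataclass
class ProjectionSummary:
    """Bootstrap distributions of λ_S, extinction risk and predicted size."""

    population: str
    lambda_s_draws: np.ndarray
    pr_ext_draws: np.ndarray
    pred_n_draws: np.ndarray
    median_trajectory: np.ndarray = field(default=None)

    @staticmethod
    def _ci(x) -> tuple[float, float]:
        lo, hi = np.percentile(x, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def lambda_s_median(self) -> float:
        return float(np.median(self.lambda_s_draws))

    @property
    def lambda_s_ci(self):
        return self._ci(self.lambda_s_draws)

    @property
    def pr_ext_mean(self) -> float:
        return float(np.mean(self.pr_ext_draws))

    @property
    def pr_ext_ci(self):
        return self._ci(self.pr_ext_draws)

    @property
    def pred_n_mean(self) -> float:
        return float(np.mean(self.pred_n_draws))

    @property
    def pred_n_median(self) -> float:
        return float(np.median(self.pred_n_draws))

    @property
    def pred_n_ci(self):
        return self._ci(self.pred_n_draws)

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "lambda_s_median": self.lambda_s_median,
            "lambda_s_ci": list(self.lambda_s_ci),
            "pr_ext_mean": self.pr_ext_mean,
            "pr_ext_ci": list(self.pr_ext_ci),
            "pred_n_mean": self.pred_n_mean,
            "pred_n_median": self.pred_n_median,
            "pred_n_ci": list(self.pred_n_ci),
            "n_bootstrap": int(len(self.lambda_s_draws)),
            "median_trajectory": (
                None if self.median_trajectory is None
                else [float(x) for x in self.median_trajectory]),
        }


def summarize_bootstrap(draws: list, population: str = "") -> ProjectionSummary:
    """Collapse per-replicate outputs into medians, means and percentile CIs.

    Within a replicate the trajectory summary is the *median* across
    trajectories (population size is strongly right-skewed); across
    replicates λ_S is summarized by its median and 2.5/97.5 percentiles,
    extinction risk and predicted size by their means and percentile CIs.
    """
    if len(draws) < 2:
        raise ValueError("need at least two bootstrap draws to summarize")
    return ProjectionSummary(
        population=population,
        lambda_s_draws=np.array([d.lambda_s for d in draws]),
        pr_ext_draws=np.array([d.pr_ext for d in draws]),
        pred_n_draws=np.array([d.mean_n_final for d in draws]),
        median_trajectory=np.median(
            np.vstack([d.median_trajectory for d in draws]), axis=0),
    )


def bootstrap_population(pop_rates, mesh, n0: float,
                         config: StochasticRunConfig,
                         rng: np.random.Generator | None = None,
                         progress=None) -> ProjectionSummary:
    """Full viability analysis of one population.

    For each bootstrap replicate: redraw every vital-rate coefficient set,
    rebuild the annual kernels (one per intercensus interval), estimate λ_S
    from a long IID kernel sequence, and run the transient projections from
    the final census size.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    draws = []
    for b in range(config.n_bootstrap):
        kernels = pop_rates.annual_kernels(mesh, rng=rng)
        lam = stochastic_lambda(kernels, n_steps=config.n_steps, rng=rng)
        sizes, extinct = transient_project(kernels, n0, config, rng)
        draws.append(BootstrapDraw(
            lambda_s=lam,
            pr_ext=float(extinct.mean()),
            mean_n_final=float(sizes[:, -1].mean()),
            median_trajectory=np.median(sizes, axis=0),
        ))
        if progress is not None:
            progress(b)
    return summarize_bootstrap(draws, population=pop_rates.population)
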