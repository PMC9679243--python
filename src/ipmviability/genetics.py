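"""Genetics–demography correlations, transformations and power analysis.

Population-genetic summaries (observed heterozygosity H_O, gene diversity
H_S, allelic richness R_S, the inbreeding coefficient F_IS, …) are compared
against demographic outcomes (stochastic growth rate λ_S, extinction
probability, predicted population size, contemporary density) with Pearson
correlations after variance-stabilizing transformations: natural log for
λ_S, predicted size and density; logit for proportions.  Values exactly at
the boundary of a transformation's domain are moved inward by a small,
reported constant.  Because demographic replication is the number of
*populations* (five here, four in the East genetic group), a bias-adjusted
Fisher-z power analysis quantifies how strong a true correlation must be to
be detectable at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, pearsonr

#: boundary shrinkage for probability-scale transforms
EPS_PROB = 0.001
#: additive constant for log-transforming a predicted size of 0 individuals
EPS_COUNT = 0.5


def _data(name: str) -> pd.DataFrame:
    with resources.files("ipmviability.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_genetics_table() -> pd.DataFrame:
    """Packaged per-population genetic summaries (with East/West group)."""
    return _data("table2_genetics.csv")


def load_demography_table() -> pd.DataFrame:
    """Packaged per-population demographic outcomes of the source analysis."""
    return _data("table3_demography.csv")


def load_recensus_table() -> pd.DataFrame:
    """Packaged contemporary (2019) mean population densities (m⁻²)."""
    return _data("recensus2019_density.csv")


def transform(x, kind: str, epsilon: float | None = None):
    """Natural-log or logit transform with boundary adjustment.

    ``ln``: log(x), with ``epsilon`` added only where x == 0.
    ``logit``: log(x̃/(1−x̃)) where x̃ is x pulled inward by ``epsilon`` only
    at the 0/1 boundaries.  Values outside the domain after adjustment raise.
    """
    x = np.asarray(x, dtype=float)
    if kind == "ln":
        eps = EPS_COUNT if epsilon is None else epsilon
        adj = np.where(x == 0.0, x + eps, x)
        if np.any(adj <= 0):
            raise ValueError("ln transform requires positive values (after eps)")
        return np.log(adj)
    if kind == "logit":
        eps = EPS_PROB if epsilon is None else epsilon
        if np.any((x < 0) | (x > 1)):
            raise ValueError("logit transform requires values in [0, 1]")
        adj = np.where(x == 0.0, eps, np.where(x == 1.0, 1.0 - eps, x))
        return np.log(adj / (1.0 - adj))
    raise ValueError(f"unknown transformation {kind!r}")


@dataclass(frozen=True)
class CorrelationResult:
    """One Pearson correlation between a transformed variable pair."""

    x_name: str
    y_name: str
    x_transform: str
    y_transform: str
    subset: str
    r: float
    p: float
    n: int


def pearson_with_p(x, y, x_name: str = "x", y_name: str = "y",
                   subset: str = "all", x_transform: str = "none",
                   y_transform: str = "none") -> CorrelationResult:
    """Pearson r with the two-sided p-value from the t distribution (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(
            f"zero variance in {'x' if np.std(x) == 0 else 'y'} "
            f"({x_name} vs {y_name}, subset={subset})")
    r, p = pearsonr(x, y)
    return CorrelationResult(x_name=x_name, y_name=y_name,
                             x_transform=x_transform, y_transform=y_transform,
                             subset=subset, r=float(r), p=float(p), n=len(x))


#: (column, transform) for each demographic outcome entering correlations
OUTCOME_TRANSFORMS = {
    "lambda_s_median": "ln",
    "pr_ext_mean": "logit",
    "pred_n2019_mean": "ln",
    "density_2019": "ln",
}
PREDICTOR_TRANSFORMS = {"H_O": "logit", "F_IS": "logit"}


def correlate_all(genetics: pd.DataFrame, demography: pd.DataFrame,
                  recensus: pd.DataFrame | None = None,
                  eps_prob: float = EPS_PROB,
                  eps_count: float = EPS_COUNT) -> pd.DataFrame:
    """All genetic-predictor × demographic-outcome correlations.

    Each {H_O, F_IS} × {λ_S, Pr_ext, Pred(N₂₀₁₉), density₂₀₁₉} pair is
    evaluated for the full population set and for the East genetic group
    alone (the single West population otherwise dominates the contrast).
    Subsets with fewer than 3 populations are flagged not computable.
    """
    df = genetics.merge(demography, on="population", how="inner")
    if recensus is not None:
        df = df.merge(recensus[["population", "density_2019"]],
                      on="population", how="left")
    rows = []
    subsets = {"all": df}
    if "group" in df.columns:
        subsets["East"] = df[df["group"] == "East"]
    for subset, d in subsets.items():
        for xcol, xtr in PREDICTOR_TRANSFORMS.items():
            for ycol, ytr in OUTCOME_TRANSFORMS.items():
                if ycol not in d.columns:
                    continue
                dd = d.dropna(subset=[xcol, ycol])
                if len(dd) < 3:
                    rows.append({"predictor": xcol, "outcome": ycol,
                                 "subset": subset, "r": np.nan, "p": np.nan,
                                 "n": len(dd), "note": "subset too small"})
                    continue
                eps_x = eps_prob
                eps_y = eps_count if ytr == "ln" else eps_prob
                res = pearson_with_p(
                    transform(dd[xcol], xtr, eps_x),
                    transform(dd[ycol], ytr, eps_y),
                    x_name=xcol, y_name=ycol, subset=subset,
                    x_transform=xtr, y_transform=ytr)
                rows.append({"predictor": xcol, "outcome": ycol,
                             "subset": subset, "r": res.r, "p": res.p,
                             "n": res.n, "note": ""})
    return pd.DataFrame(rows)


def genetic_redundancy(genetics: pd.DataFrame | None = None) -> pd.Series:
    """Raw Pearson correlations of H_O with the other diversity metrics.

    The diversity metrics are near-interchangeable across populations,
    which is why H_O stands in for all of them in the main analysis.
    """
    g = load_genetics_table() if genetics is None else genetics
    out = {}
    for col in ("P", "n_a", "n_e", "H_S", "R_S"):
        out[col] = pearson_with_p(g["H_O"], g[col], "H_O", col).r
    return pd.Series(out)


def critical_r_for_power(n: int, power: float, alpha: float) -> float:
    """Smallest true |r| detectable with the given power at two-sided α.

    Solves the bias-adjusted Fisher-z power equation

        atanh(r) + r / (2(n−1)) = (z_{1−α/2} + z_power) / sqrt(n−3)

    for r by bracketed root-finding (tolerance 1e-6).
    """
    if n < 4:
        raise ValueError("power analysis needs n >= 4")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    target = (norm.ppf(1 - alpha / 2) + norm.ppf(power)) / np.sqrt(n - 3)

    def f(r):
        return np.arctanh(r) + r / (2.0 * (n - 1)) - target

    if target <= 0:
        return 0.0
    return float(brentq(f, 1e-12, 1 - 1e-12, xtol=1e-9))
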