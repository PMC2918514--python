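"""Post-fit parameter diagnostics.

Once a niche model is fitted, the per-species parameter estimates form
distributions that can be compared with the generative assumptions of
the classic niche model: niche positions n uniform on [0, 1], the
scaled range x = r/n beta/exponential-like, and the relative diet
position c' = c/n uniform below 1 (hierarchical feeding).  This module
computes those derived ratios, Kolmogorov–Smirnov tests of the assumed
distributions, Spearman rank correlations among parameters and body
mass with Benjamini–Hochberg false-discovery-rate control, and a small
PCA of the standardized (n, c, r) triples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pnm_core import ParamSet

__all__ = [
    "N_EPS",
    "RatioSet",
    "derived_ratios",
    "correlation_table",
    "distribution_tests",
    "DistributionTests",
    "pca_variance",
]

#: Species with n below this are treated as sitting at the axis origin;
#: their ratios r/n and c/n are reported as missing.
N_EPS = 1e-6


@dataclass
class RatioSet:
    """Per-species derived ratios; NaN where n is at the axis origin."""

    x: np.ndarray        # r / n, the scaled feeding range
    c_prime: np.ndarray  # c / n, the relative diet position (c' < 1 = hierarchical)


@dataclass
class DistributionTests:
    """K-S tests of the classic niche-model distributional assumptions."""

    n_uniform_stat: float
    n_uniform_p: float
    r_exponential_scale: float   # beta-hat, the sample mean of r
    r_exponential_stat: float
    r_exponential_p: float
    cprime_uniform_stat: float
    cprime_uniform_p: float
    cprime_n_excluded: int       # species dropped by the c' > 1 rule


def derived_ratios(params: ParamSet, n_eps: float = N_EPS) -> RatioSet:
    """x = r/n and c' = c/n, missing where n <= n_eps."""
    defined = params.n > n_eps
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(defined, params.r / params.n, np.nan)
        c_prime = np.where(defined, params.c / params.n, np.nan)
    return RatioSet(x=x, c_prime=c_prime)


def _pairwise_complete(u: np.ndarray, v: np.ndarray):
    ok = np.isfinite(u) & np.isfinite(v)
    return u[ok], v[ok]


def correlation_table(
    params: ParamSet,
    ratios: RatioSet | None = None,
    body_mass: np.ndarray | None = None,
    alpha: float = 0.05,
    min_obs: int = 4,
) -> pd.DataFrame:
    """Spearman correlations among parameters, ratios and body mass.

    Computes the standard ten pairs — (n,c), (n,r), (c,r), the three
    parameter–mass pairs, (n,x), (x,mass), (n,c') and (c',mass) — with
    missing entries dropped pairwise and Benjamini–Hochberg control of
    the false discovery rate at ``alpha``.  Mass pairs use log mass,
    which leaves the rank correlation unchanged but mirrors how such
    tables are usually presented.  Mass pairs are omitted when no body
    masses are given.
    """
    if ratios is None:
        ratios = derived_ratios(params)
    columns: dict[str, np.ndarray] = {
        "n": params.n,
        "c": params.c,
        "r": params.r,
        "x": ratios.x,
        "c'": ratios.c_prime,
    }
    pairs = [("n", "c"), ("n", "r"), ("c", "r")]
    if body_mass is not None:
        columns["mass"] = np.log10(np.asarray(body_mass, dtype=float))
        pairs += [("n", "mass"), ("c", "mass"), ("r", "mass")]
    pairs += [("n", "x")]
    if body_mass is not None:
        pairs += [("x", "mass")]
    pairs += [("n", "c'")]
    if body_mass is not None:
        pairs += [("c'", "mass")]

    rows = []
    for u_name, v_name in pairs:
        u, v = _pairwise_complete(columns[u_name], columns[v_name])
        if u.shape[0] < min_obs:
            raise ValueError(
                f"pair ({u_name}, {v_name}) has only {u.shape[0]} complete "
                f"observations (need {min_obs})"
            )
        res = stats.spearmanr(u, v)
        rows.append((f"{u_name}, {v_name}", float(res.statistic), float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["pair", "rho", "p"])
    table["significant"] = multipletests(
        table["p"].to_numpy(), alpha=alpha, method="fdr_bh"
    )[0]
    return table


def distribution_tests(
    params: ParamSet,
    ratios: RatioSet | None = None,
    min_obs: int = 5,
    r_values: np.ndarray | None = None,
) -> DistributionTests:
    """K-S tests of n ~ U(0,1), r ~ Exponential, and c' ~ U(0,1).

    The exponential scale is estimated as the sample mean of r and the
    asymptotic K-S p-value is reported with the scale held fixed (no
    Lilliefors correction).  The c' test first excludes species with
    c' > 1, following the convention that only hierarchically feeding
    species are compared against the uniform-below-the-consumer rule.
    ``r_values`` optionally restricts the exponential test to a subset
    (e.g. free-range consumers, excluding pinned producer ranges).
    """
    if ratios is None:
        ratios = derived_ratios(params)
    n = params.n[np.isfinite(params.n)]
    r = params.r if r_values is None else np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r) & (r > 0)]
    cp = ratios.c_prime[np.isfinite(ratios.c_prime)]
    n_excluded = int((cp > 1).sum())
    cp = cp[cp <= 1]
    for label, v in (("n", n), ("r", r), ("c'", cp)):
        if v.shape[0] < min_obs:
            raise ValueError(
                f"too few observations for the {label} distribution test "
                f"({v.shape[0]} < {min_obs})"
            )
    ks_n = stats.kstest(n, "uniform")
    beta = float(r.mean())
    ks_r = stats.kstest(r, "expon", args=(0, beta))
    ks_cp = stats.kstest(cp, "uniform")
    return DistributionTests(
        n_uniform_stat=float(ks_n.statistic),
        n_uniform_p=float(ks_n.pvalue),
        r_exponential_scale=beta,
        r_exponential_stat=float(ks_r.statistic),
        r_exponential_p=float(ks_r.pvalue),
        cprime_uniform_stat=float(ks_cp.statistic),
        cprime_uniform_p=float(ks_cp.pvalue),
        cprime_n_excluded=n_excluded,
    )


def pca_variance(params: ParamSet) -> np.ndarray:
    """Variance-explained fractions of the standardized (n, c, r) triples.

    Principal axes of the correlation matrix of complete triples;
    fractions are returned in descending order and sum to 1.
    """
    X = np.column_stack([params.n, params.c, params.r])
    X = X[np.isfinite(X).all(axis=1)]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 species with complete (n, c, r)")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance parameter: PCA is degenerate")
    Z = (X - X.mean(axis=0)) / sd
    eigvals = np.linalg.eigvalsh(np.cov(Z, rowvar=False))[::-1]
    eigvals = np.maximum(eigvals, 0.0)
    return eigvals / eigvals.sum()
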