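"""Spearman rank correlation panels for wall-polymer vs sugar-yield traits.

A panel crosses wall-polymer features (cellulose; Ara, Xyl, X/A; ASL, AIL,
total lignin) with saccharification yields and flags each pair at the
conventional p < 0.05 (*) and p < 0.01 (**) levels.  Spearman's rho is
computed as the Pearson correlation of mean-ranked data (ties receive their
mean rank); with no ties this equals 1 - 6*sum(d²)/(n(n²-1)).  P-values use
the two-sided t approximation t = rho*sqrt((n-2)/(1-rho²)) on n-2 df by
default; a seeded permutation test is available for exactness at small n.
No multiple-testing correction is applied: significance is reported
per pair.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from nirscal.datasets import InputError

DEFAULT_FEATURES = ("cellulose", "ara", "xyl", "xa", "asl", "ail", "lignin_total")
DEFAULT_YIELDS = (
    "pent_pre", "hex_pre", "total_pre",
    "pent_enz", "hex_enz", "total_enz",
    "pent_total", "hex_total", "sugar_total",
    "ferm_hex",
)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rho: Pearson correlation of average-ranked data."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InputError("x and y lengths differ")
    if x.size < 3:
        raise InputError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("rank correlation undefined for a constant variable")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_pvalue(
    rho: float,
    n: int,
    method: str = "t_approx",
    seed: int = 0,
    n_permutations: int = 10000,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> float:
    """Two-sided p-value for an observed Spearman rho.

    ``t_approx`` uses ``t = rho*sqrt((n-2)/(1-rho²))`` on n-2 df.
    ``permutation`` shuffles the labels of ``y`` (``x``/``y`` required) with
    add-one smoothing: ``p = (1 + #{|rho_perm| >= |rho|}) / (1 + B)``.
    """
    if method == "t_approx":
        if n < 4:
            raise InputError("t approximation needs n >= 4")
        if abs(rho) >= 1:
            warnings.warn("|rho| = 1: p-value degenerate, returning 0",
                          RuntimeWarning, stacklevel=2)
            return 0.0
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        return float(2 * sps.t.sf(abs(t), df=n - 2))
    if method == "permutation":
        if x is None or y is None:
            raise InputError("permutation method needs the raw x and y samples")
        if n < 3:
            raise InputError("permutation test needs n >= 3")
        rng = np.random.default_rng(seed)
        # ranks are permutation-equivariant, so permuting y's ranks is
        # equivalent to ranking permuted y; rank once and shuffle ranks
        rx = sps.rankdata(np.asarray(x, dtype=float).ravel())
        ry = sps.rankdata(np.asarray(y, dtype=float).ravel())
        rx = rx - rx.mean()
        ry = ry - ry.mean()
        denom = np.sqrt((rx @ rx) * (ry @ ry))
        hits = 0
        chunk = 5000
        done = 0
        while done < n_permutations:
            b = min(chunk, n_permutations - done)
            perms = np.argsort(rng.random((b, ry.size)), axis=1)
            r = (ry[perms] @ rx) / denom
            hits += int(np.count_nonzero(np.abs(r) >= abs(rho) - 1e-12))
            done += b
        return (1 + hits) / (1 + n_permutations)
    raise InputError(f"unknown p-value method {method!r}")


def significance_tier(p: float) -> str:
    """'**' below 0.01, '*' below 0.05, else 'ns'."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclasses.dataclass
class CorrelationPanel:
    """rho / p / significance-tier grid for feature x yield pairs."""

    rho: pd.DataFrame    # features x yields
    p: pd.DataFrame
    tier: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for f in self.rho.index:
            for t in self.rho.columns:
                rows.append({"feature": f, "yield": t,
                             "rho": self.rho.loc[f, t],
                             "p": self.p.loc[f, t],
                             "tier": self.tier.loc[f, t]})
        return pd.DataFrame(rows)


def correlation_panel(
    traits: pd.DataFrame,
    features=DEFAULT_FEATURES,
    yields=DEFAULT_YIELDS,
    method: str = "t_approx",
    seed: int = 0,
) -> CorrelationPanel:
    """Spearman rho/p/tier grid between feature and yield columns of a trait table."""
    for col in tuple(features) + tuple(yields):
        if col not in traits.columns:
            raise InputError(f"trait table has no column {col!r}")
    if len(traits) < 10:
        raise InputError("correlation panel needs n >= 10")
    n = len(traits)
    rho = pd.DataFrame(index=list(features), columns=list(yields), dtype=float)
    p = rho.copy()
    tier = pd.DataFrame(index=list(features), columns=list(yields), dtype=object)
    for f in features:
        xv = traits[f].to_numpy(float)
        for t in yields:
            yv = traits[t].to_numpy(float)
            r = spearman(xv, yv)
            pv = spearman_pvalue(r, n, method=method, seed=seed, x=xv, y=yv)
            rho.loc[f, t] = r
            p.loc[f, t] = pv
            tier.loc[f, t] = significance_tier(pv)
    return CorrelationPanel(rho=rho, p=p, tier=tier)
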