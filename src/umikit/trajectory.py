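"""Statistics on pseudotime orderings.

Two orderings of the same cells (for example, trajectories inferred by two
independent algorithms) are compared by Spearman's rank correlation; its
significance is assessed against a permutation null built by shuffling one
ordering B times.  Both the empirical permutation p-value and a one-sample
Student's t-test of the observed coefficient against the null sample are
reported — the t-test is the historical convention this pipeline follows,
but it treats the null sample as data, so the empirical p-value is the
recommended one.  Because a trajectory's direction is arbitrary between
methods, significance is computed on |rho|; the signed rho is reported too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from scipy.stats import t as t_dist

__all__ = [
    "ConcordanceResult",
    "TrendResult",
    "ordering_concordance",
    "permutation_concordance_test",
    "pseudotime_trend",
]


@dataclass
class ConcordanceResult:
    """Spearman concordance of two orderings with its permutation null."""

    rho_signed: float
    rho_abs: float
    null_sample: np.ndarray
    p_empirical: float
    p_ttest: float
    B: int
    seed: int


@dataclass
class TrendResult:
    """Spearman trend of a per-cell quantity against pseudotime."""

    rho: float
    p_value: float
    degenerate: bool = False


def _align(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    a = pd.Series(a).astype(float)
    b = pd.Series(b).astype(float)
    if set(a.index) != set(b.index):
        raise ValueError("orderings must cover the same cell set")
    if len(a) < 3:
        raise ValueError("need at least 3 cells")
    b = b.reindex(a.index)
    return a.values, b.values


def ordering_concordance(a: pd.Series, b: pd.Series) -> float:
    """Spearman rho between two orderings (average-rank tie handling)."""
    av, bv = _align(a, b)
    return float(spearmanr(av, bv).statistic)


def permutation_concordance_test(
    a: pd.Series, b: pd.Series, B: int = 1000, seed: int = 0
) -> ConcordanceResult:
    """Permutation test of ordering concordance.

    Shuffles b's values ``B`` times to build the null distribution of rho.
    ``p_empirical`` = (1 + #{|null| >= |observed|}) / (1 + B);
    ``p_ttest`` standardizes |observed rho| against the null sample's mean
    and standard deviation and refers the statistic to a two-sided Student
    t with B - 1 degrees of freedom — the classical way of t-testing one
    observation's deviation from a reference sample.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    av, bv = _align(a, b)
    ra = rankdata(av)
    rb = rankdata(bv)
    # Spearman rho = Pearson on ranks; shuffling values permutes b's ranks
    ra_c = ra - ra.mean()
    rb_c = rb - rb.mean()
    denom = np.sqrt((ra_c**2).sum() * (rb_c**2).sum())
    if denom == 0:
        raise ValueError("an ordering is constant; rho is undefined")
    observed = float((ra_c * rb_c).sum() / denom)
    rng = np.random.default_rng([int(seed), 211])
    perms = np.array([rng.permutation(rb_c) for _ in range(B)])
    null = perms @ ra_c / denom
    p_emp = float((1 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (1 + B))
    null_sd = float(null.std(ddof=1))
    if null_sd == 0:
        p_t = 1.0 if abs(observed) == null.mean() else 0.0
    else:
        t_stat = (abs(observed) - null.mean()) / null_sd
        p_t = float(2.0 * t_dist.sf(abs(t_stat), B - 1))
    return ConcordanceResult(
        rho_signed=observed,
        rho_abs=abs(observed),
        null_sample=null,
        p_empirical=p_emp,
        p_ttest=p_t,
        B=int(B),
        seed=int(seed),
    )


def pseudotime_trend(values: pd.Series, order: pd.Series) -> TrendResult:
    """Spearman trend of a per-cell quantity (total UMI, detected genes,
    ...) against pseudotime, with the asymptotic p-value.

    Constant inputs make rho undefined; they return rho 0, p 1 and the
    ``degenerate`` flag set.
    """
    vv, ov = _align(values, order)
    if np.all(vv == vv[0]) or np.all(ov == ov[0]):
        return TrendResult(rho=0.0, p_value=1.0, degenerate=True)
    res = spearmanr(vv, ov)
    return TrendResult(rho=float(res.statistic), p_value=float(res.pvalue))
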