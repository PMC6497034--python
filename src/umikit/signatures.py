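"""Multi-set signature intersection statistics and co-expression modules.

The central question: is the overlap shared by m signature gene sets (for
example the four granzyme-B program sets of NK/NKT/CTL subtypes) larger
than expected for size-matched random gene pools?  The null resamples m
sets of the observed sizes uniformly without replacement from the gene
universe; the statistic is the size of the full m-way intersection.  Both
the one-sample t-test of the observed value against the null sample (the
historical convention) and the empirical enrichment p-value are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

__all__ = [
    "GeneSetCollection",
    "IntersectionTestResult",
    "CorrelationModules",
    "venn_decompose",
    "intersection_permutation_test",
    "coexpression_modules",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared gene universe."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("universe contains duplicate gene ids")
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"set {name!r} is empty")
            outside = set(genes) - uni
            if outside:
                raise ValueError(f"set {name!r} has genes outside the universe: {sorted(outside)[:5]}")

    @classmethod
    def from_mapping(
        cls, sets: Mapping[str, Sequence[str]], universe: Sequence[str] | None = None
    ) -> "GeneSetCollection":
        sets = {k: list(v) for k, v in sets.items()}
        if universe is None:
            universe = sorted(reduce(set.union, (set(v) for v in sets.values()), set()))
        return cls(sets, list(universe))

    def sizes(self) -> dict[str, int]:
        return {k: len(set(v)) for k, v in self.sets.items()}


@dataclass
class IntersectionTestResult:
    """Observed full-intersection size against a size-matched random null."""

    observed: int
    null_sample: np.ndarray
    null_mean: float
    null_sd: float
    p_ttest: float
    p_empirical: float
    B: int
    seed: int
    regions: dict[tuple, int] = field(default_factory=dict)


@dataclass
class CorrelationModules:
    """Gene-gene Pearson correlation with a hierarchical module cut."""

    correlation: pd.DataFrame
    modules: pd.Series
    zero_variance_genes: list[str]
    n_modules: int
    linkage_method: str = "average"


def venn_decompose(collection: GeneSetCollection) -> dict[tuple, int]:
    """Counts of all 2^m - 1 membership regions of m sets.

    Keys are tuples of the member set names (sorted); e.g. for sets A, B
    the key ("A",) counts genes in A only, ("A", "B") genes in both.
    Region counts sum to the size of the union.
    """
    names = sorted(collection.sets)
    m = len(names)
    if not 2 <= m <= 6:
        raise ValueError("venn decomposition supports 2 to 6 sets")
    membership: dict[str, set] = {n: set(collection.sets[n]) for n in names}
    union = reduce(set.union, membership.values(), set())
    regions: dict[tuple, int] = {}
    # initialise every non-empty membership pattern at zero
    for pattern in range(1, 2**m):
        key = tuple(names[i] for i in range(m) if pattern >> i & 1)
        regions[key] = 0
    for gene in union:
        key = tuple(n for n in names if gene in membership[n])
        regions[key] += 1
    return regions


def intersection_permutation_test(
    collection: GeneSetCollection, B: int = 1000, seed: int = 0
) -> IntersectionTestResult:
    """Significance of the full m-way intersection against size-matched
    random gene pools.

    Each of the ``B`` null draws samples, for every set, a random subset of
    the universe of the same size (without replacement, independently
    across sets and draws) and records the full-intersection size.
    ``p_ttest`` standardizes the observed size against the null sample's
    mean and standard deviation and refers the statistic to a two-sided
    Student t with B - 1 degrees of freedom; ``p_empirical`` =
    (1 + #{null >= observed}) / (1 + B), the enrichment direction.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    names = sorted(collection.sets)
    sizes = [len(set(collection.sets[n])) for n in names]
    U = len(collection.universe)
    if any(s > U for s in sizes):
        raise ValueError("a set is larger than the universe")
    observed = len(reduce(set.intersection, (set(collection.sets[n]) for n in names)))
    rng = np.random.default_rng([int(seed), 307])
    null = np.empty(B, dtype=np.int64)
    hits = np.zeros(U, dtype=np.int8)
    for b in range(B):
        hits[:] = 0
        for s in sizes:
            hits[rng.choice(U, s, replace=False)] += 1
        null[b] = int(np.sum(hits == len(sizes)))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0:
        p_t = 1.0 if observed == null_mean else 0.0
    else:
        t_stat = (observed - null_mean) / null_sd
        p_t = float(2.0 * t_dist.sf(abs(t_stat), B - 1))
    p_emp = float((1 + np.sum(null >= observed)) / (1 + B))
    return IntersectionTestResult(
        observed=observed,
        null_sample=null,
        null_mean=null_mean,
        null_sd=null_sd,
        p_ttest=p_t,
        p_empirical=p_emp,
        B=int(B),
        seed=int(seed),
        regions=venn_decompose(collection) if 2 <= len(names) <= 6 else {},
    )


def coexpression_modules(
    expr: pd.DataFrame,
    genes: Sequence[str] | None = None,
    cells: Sequence[str] | None = None,
    n_modules: int = 2,
) -> CorrelationModules:
    """Gene-gene Pearson correlation modules across a cell subset.

    Correlations are computed across the selected cells; genes with zero
    variance get correlation 0 with everything (flagged).  Modules come
    from average-linkage hierarchical clustering of distance 1 - r cut to
    ``n_modules`` clusters.
    """
    sub = expr
    if genes is not None:
        sub = sub.loc[list(genes)]
    if cells is not None:
        sub = sub[list(cells)]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    X = sub.values.astype(float)
    sd = X.std(axis=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_modules, criterion="maxclust")
    corr_df = pd.DataFrame(corr, index=sub.index, columns=sub.index)
    return CorrelationModules(
        correlation=corr_df,
        modules=pd.Series(labels, index=sub.index, name="module"),
        zero_variance_genes=list(sub.index[zero_var]),
        n_modules=int(n_modules),
    )
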