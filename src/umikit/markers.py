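"""Normalization, cluster marker detection, doublet-cluster flagging and
reference-correlation annotation.

Marker detection follows the convention of the upstream single-cell
toolkit: a gene is tested for a cluster iff it is expressed (count > 0) in
at least ``min_pct`` of cells in the cluster or in the rest, and the
absolute log fold change of mean normalized expression is at least
``logfc_min`` (both default 0.25).  Passing genes are tested cluster
versus rest with a two-sided Wilcoxon rank-sum test: exact (a dynamic
program over the tied-rank multiset, equivalent to enumerating every
assignment of cells to groups) when both groups have <= 20 cells, and the
tie-corrected normal approximation otherwise.  P-values are
Bonferroni-adjusted over the genes tested within each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "lognormalize",
    "find_markers",
    "flag_doublet_clusters",
    "annotate_by_reference",
    "exact_ranksum_pvalue",
]

_EXACT_MAX_PER_SIDE = 20


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x cells, with ids."""

    genes: pd.Index
    cells: pd.Index
    values: sp.csr_matrix = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.toarray(), index=self.genes, columns=self.cells)


def lognormalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """ln(1 + scale * count / cell_total); all-zero cells map to zeros."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    X = counts.counts.tocsc(copy=True).astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    inv = np.where(totals > 0, 1.0 / np.where(totals > 0, totals, 1.0), 0.0)
    X = X.multiply(sp.csr_matrix(inv[None, :] * scale)).tocsr()
    X.data = np.log1p(X.data)
    return NormalizedMatrix(counts.genes, counts.cells, sp.csr_matrix(X))


def _rank_sum_exact_distribution(ranks2: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the group-1 rank sum over all C(n, n1) splits.

    ``ranks2`` are doubled average ranks (integers even with ties).  Returns
    (support, counts) where counts[s] is the number of subsets of size n1
    whose doubled-rank sum equals s.
    """
    total = int(ranks2.sum())
    # dp[j, s] = number of size-j subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for j in range(n1, 0, -1):  # descending: each cell used at most once
            dp[j, r:] += dp[j - 1, 0 : total + 1 - r]
    support = np.arange(total + 1)
    return support, dp[n1]


def exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value, valid under ties.

    The p-value is P(|S - E S| >= |s_obs - E S|) where S is the group-x
    rank sum over all equally likely assignments of the pooled values to
    the two groups (the permutation null conditioned on the observed
    values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.round(2.0 * rankdata(pooled)).astype(np.int64)
    s_obs = int(ranks2[:n1].sum())
    support, counts = _rank_sum_exact_distribution(ranks2, n1)
    e2 = n1 * ranks2.mean()  # E[doubled rank sum]
    dist_obs = abs(s_obs - e2)
    tail = counts[np.abs(support - e2) >= dist_obs - 1e-9].sum()
    return float(tail / comb(n1 + n2, n1))


def _tie_term(row: np.ndarray) -> float:
    _, cnt = np.unique(row, return_counts=True)
    return float(np.sum(cnt**3 - cnt))


def _asymptotic_ranksum_pvalues(X: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Vectorized two-sided tie-corrected normal-approximation rank-sum test,
    one p-value per row of X (genes x cells)."""
    from scipy.stats import norm

    n = X.shape[1]
    n1 = int(in_mask.sum())
    n2 = n - n1
    ranks = rankdata(X, axis=1)
    r1 = ranks[:, in_mask].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    ties = np.array([_tie_term(row) for row in X])
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (r1 - mu) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    return np.where(var > 0, np.minimum(p, 1.0), 1.0)


def find_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    min_pct: float = 0.25,
    logfc_min: float = 0.25,
    min_pct_mode: str = "either",
    alpha_sort: bool = True,
) -> pd.DataFrame:
    """Cluster-versus-rest marker genes for every cluster.

    Returns a DataFrame with columns gene, cluster, p_value, p_adjusted
    (Bonferroni over genes tested per cluster), log_fc (natural log of
    (mean expm1 + 1) in cluster over rest), pct_in, pct_out; one row per
    (cluster, tested gene), sorted by cluster then p-value.

    ``min_pct_mode`` is ``"either"`` (gene passes if expressed in min_pct
    of the cluster or of the rest, the upstream-tool semantics) or
    ``"both"``.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=norm.cells)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("no contrast: need at least 2 clusters")
    sizes = labels.value_counts()
    if (sizes < 3).any():
        raise ValueError("every cluster needs at least 3 cells")
    if min_pct_mode not in ("either", "both"):
        raise ValueError("min_pct_mode must be 'either' or 'both'")

    X = norm.values.toarray()
    expressed = X > 0
    records = []
    for c in clusters:
        in_mask = (labels == c).values
        out_mask = ~in_mask
        n_in, n_out = in_mask.sum(), out_mask.sum()
        pct_in = expressed[:, in_mask].mean(axis=1)
        pct_out = expressed[:, out_mask].mean(axis=1)
        if min_pct_mode == "either":
            pct_ok = (pct_in >= min_pct) | (pct_out >= min_pct)
        else:
            pct_ok = (pct_in >= min_pct) & (pct_out >= min_pct)
        m_in = np.expm1(X[:, in_mask]).mean(axis=1)
        m_out = np.expm1(X[:, out_mask]).mean(axis=1)
        log_fc = np.log(m_in + 1.0) - np.log(m_out + 1.0)
        gate = pct_ok & (np.abs(log_fc) >= logfc_min)
        tested = np.flatnonzero(gate)
        if len(tested) == 0:
            continue
        if n_in <= _EXACT_MAX_PER_SIDE and n_out <= _EXACT_MAX_PER_SIDE:
            pvals = np.array(
                [exact_ranksum_pvalue(X[g, in_mask], X[g, out_mask]) for g in tested]
            )
        else:
            pvals = _asymptotic_ranksum_pvalues(X[tested], in_mask)
        padj = np.minimum(pvals * len(tested), 1.0)
        for j, g in enumerate(tested):
            records.append(
                {
                    "gene": norm.genes[g],
                    "cluster": c,
                    "p_value": pvals[j],
                    "p_adjusted": padj[j],
                    "log_fc": log_fc[g],
                    "pct_in": pct_in[g],
                    "pct_out": pct_out[g],
                }
            )
    out = pd.DataFrame.from_records(
        records, columns=["gene", "cluster", "p_value", "p_adjusted", "log_fc", "pct_in", "pct_out"]
    )
    if alpha_sort and len(out):
        out = out.sort_values(["cluster", "p_value", "gene"]).reset_index(drop=True)
    return out


def _marker_sets(markers: pd.DataFrame, alpha: float, n_top: int) -> dict[object, set]:
    sig = markers[(markers["p_value"] < alpha) & (markers["log_fc"] > 0)]
    sig = sig.sort_values(["cluster", "p_value", "gene"])
    return {c: set(g["gene"].head(n_top)) for c, g in sig.groupby("cluster")}


def flag_doublet_clusters(
    markers: pd.DataFrame,
    labels: pd.Series,
    max_frac: float = 0.05,
    jaccard_min: float = 0.15,
    alpha: float = 0.05,
    n_top: int = 30,
) -> list:
    """Small clusters whose markers are shared with two larger clusters.

    A cluster is flagged iff its size is at most ``max_frac`` of all cells
    (droplet doublets are rare, ~5% of loaded cells) and its marker set has
    Jaccard overlap >= ``jaccard_min`` with the marker sets of at least two
    distinct larger clusters — the hybrid expression profile expected of a
    droplet containing two cells.

    The default ``jaccard_min`` of 0.15 reflects the geometry of the rule:
    an ideal doublet's markers split evenly between its two parents, so its
    Jaccard with either parent cannot exceed ~1/3 even without noise, while
    unrelated clusters overlap near 0.

    A cluster's marker set is its positive-log-fold-change records at
    nominal ``p_value < alpha``, ranked by p-value and capped at ``n_top``
    genes.  The nominal threshold plus cap (rather than the Bonferroni
    column) keeps the sets of the small candidate clusters, whose adjusted
    significance is power-limited, comparable in size to those of their
    putative parents.
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    sizes = labels.value_counts()
    total = len(labels)
    sets = _marker_sets(markers, alpha, n_top)
    flagged = []
    for c in sizes.index:
        if sizes[c] > max_frac * total:
            continue
        mine = sets.get(c, set())
        if not mine:
            continue
        n_parents = 0
        for d in sizes.index:
            if d == c or sizes[d] <= sizes[c]:
                continue
            other = sets.get(d, set())
            if not other:
                continue
            jac = len(mine & other) / len(mine | other)
            if jac >= jaccard_min:
                n_parents += 1
        if n_parents >= 2:
            flagged.append(c)
    return sorted(flagged)


def annotate_by_reference(
    cluster_means: pd.DataFrame, reference_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Annotate clusters by Pearson correlation against bulk reference
    profiles over the shared gene universe.

    Both inputs are genes x columns tables (clusters, reference labels).
    Returns a DataFrame indexed by cluster with one correlation column per
    reference label plus ``best_label`` (ties broken lexicographically).
    """
    shared = cluster_means.index.intersection(reference_profiles.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    cm = cluster_means.loc[shared].astype(float)
    ref = reference_profiles.loc[shared].astype(float)
    ref_labels = sorted(ref.columns)
    corr = pd.DataFrame(index=cm.columns, columns=ref_labels, dtype=float)
    for c in cm.columns:
        for r in ref_labels:
            corr.loc[c, r] = float(np.corrcoef(cm[c], ref[r])[0, 1])
    best = corr.astype(float).apply(
        lambda row: min(r for r in ref_labels if row[r] == row.max()), axis=1
    )
    corr["best_label"] = best
    corr.index.name = "cluster"
    return corr
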