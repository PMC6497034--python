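"""Cell and gene quality filtration for UMI-count datasets.

Implements the published filtration scheme for the cord-blood atlas:
per-dataset detected-gene definition (a gene must carry UMI >= 1 in at
least 30 cells), removal of cells by detected-gene number and
mitochondrial fraction, flagging of hemoglobin-high (erythroblast-like)
clusters, and the stricter mitochondrial cutoff applied to trajectory
cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "QCThresholds",
    "DATASET_THRESHOLDS",
    "detected_gene_mask",
    "compute_cell_qc",
    "filter_cells",
    "flag_hemoglobin_clusters",
    "trajectory_mito_exclusion",
]


@dataclass(frozen=True)
class QCThresholds:
    """Per-dataset cell filtration cutoffs.

    A cell is removed iff detected genes < ``min_genes`` OR detected genes
    > ``max_genes`` OR mitochondrial fraction > ``max_mito``.
    """

    min_genes: int = 400
    max_genes: int = 2000
    max_mito: float = 0.08
    min_cells_per_gene: int = 30

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 < self.max_mito <= 1.0:
            raise ValueError("max_mito must lie in (0, 1]")
        if self.min_cells_per_gene < 1:
            raise ValueError("min_cells_per_gene must be >= 1")


#: The four dataset-specific threshold sets used for the cord-blood atlas.
DATASET_THRESHOLDS: dict[str, QCThresholds] = {
    "PB1": QCThresholds(400, 2000, 0.08),
    "PB2": QCThresholds(400, 2000, 0.08),
    "UCB1": QCThresholds(400, 3500, 0.06),
    "UCB2": QCThresholds(400, 3000, 0.07),
}


def detected_gene_mask(counts: CountMatrix, min_cells_per_gene: int = 30) -> np.ndarray:
    """Boolean mask over genes: True iff the gene has UMI >= 1 in at least
    ``min_cells_per_gene`` cells of this dataset."""
    if min_cells_per_gene < 1:
        raise ValueError("min_cells_per_gene must be >= 1")
    n_expressing = np.asarray((counts.counts > 0).sum(axis=1)).ravel()
    return n_expressing >= min_cells_per_gene


def compute_cell_qc(
    counts: CountMatrix, mito_prefix: str = "MT-", mito_mode: str = "umi"
) -> pd.DataFrame:
    """Per-cell QC statistics: ``detected_genes``, ``total_umi``,
    ``mito_fraction``.

    Mitochondrial genes are identified by a case-insensitive id prefix.
    ``mito_mode`` chooses the denominator of the mitochondrial fraction:
    ``"umi"`` (mito UMI / total UMI, the downstream-tool convention,
    default) or ``"gene"`` (mito detected genes / detected genes).  Both
    fractions are 0 for cells with a zero denominator.
    """
    if mito_mode not in ("umi", "gene"):
        raise ValueError("mito_mode must be 'umi' or 'gene'")
    X = counts.counts
    is_mito = np.array([g.upper().startswith(mito_prefix.upper()) for g in counts.genes])
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    total = np.asarray(X.sum(axis=0)).ravel()
    if mito_mode == "umi":
        num = np.asarray(X[is_mito, :].sum(axis=0)).ravel() if is_mito.any() else np.zeros_like(total)
        den = total
    else:
        num = (
            np.asarray((X[is_mito, :] > 0).sum(axis=0)).ravel()
            if is_mito.any()
            else np.zeros_like(detected)
        )
        den = detected
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    return pd.DataFrame(
        {
            "detected_genes": detected.astype(int),
            "total_umi": total.astype(int),
            "mito_fraction": mito_frac,
        },
        index=counts.cells,
    )


def filter_cells(qc: pd.DataFrame, thresholds: QCThresholds) -> pd.Index:
    """Ids of cells surviving the three removal criteria."""
    keep = (
        (qc["detected_genes"] >= thresholds.min_genes)
        & (qc["detected_genes"] <= thresholds.max_genes)
        & (qc["mito_fraction"] <= thresholds.max_mito)
    )
    return qc.index[keep]


def flag_hemoglobin_clusters(
    norm_expr: pd.DataFrame,
    clusters: pd.Series,
    hb_genes: list[str],
    z_min: float = 2.0,
) -> list:
    """Clusters whose mean hemoglobin score is an outlier across clusters.

    ``norm_expr`` is a genes x cells table of normalized expression.  Each
    cell's hemoglobin score is its mean expression over ``hb_genes``; a
    cluster is flagged iff its mean score exceeds the across-cluster mean
    by more than ``z_min`` across-cluster standard deviations.
    """
    if not hb_genes:
        raise ValueError("hb_genes must be non-empty")
    missing = [g for g in hb_genes if g not in norm_expr.index]
    if missing:
        raise KeyError(f"hemoglobin genes not in expression table: {missing[:5]}")
    clusters = pd.Series(clusters)
    if clusters.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    score = norm_expr.loc[hb_genes].mean(axis=0)
    cluster_means = score.groupby(clusters.values).mean()
    sd = cluster_means.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return []
    z = (cluster_means - cluster_means.mean()) / sd
    return sorted(cluster_means.index[z > z_min].tolist())


def trajectory_mito_exclusion(qc: pd.DataFrame, max_mito: float = 0.025) -> pd.Index:
    """Ids of trajectory cells with mitochondrial fraction <= ``max_mito``
    (default 2.5%, the stricter cutoff used for erythroblast ordering)."""
    return qc.index[qc["mito_fraction"] <= max_mito]
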