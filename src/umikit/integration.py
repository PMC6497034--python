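"""Batch-mixing evaluation of a low-dimensional embedding.

The alignment score asks how well batches are locally mixed: after
subsampling every batch to the size of the smallest one, each sampled
cell's k nearest neighbors (Euclidean, self excluded) are inspected and
x_bar is the mean number of same-batch cells among them.  The score is

    score = 1 - (x_bar - k/N) / (k - k/N),   clamped to [0, 1],

so fully segregated batches (x_bar = k) score 0 and perfectly mixed
batches (x_bar = k/N, the expectation under random mixing of N equal
batches) score 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Embedding", "AlignmentScore", "alignment_score", "k_sweep", "compare_methods", "score_from_xbar"]


@dataclass
class Embedding:
    """Cells with finite d-dimensional coordinates and a batch label each."""

    cells: pd.Index
    coords: np.ndarray
    batch: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.cells = pd.Index(self.cells, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.cells):
            raise ValueError("coords must be (n_cells, d)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        self.batch = pd.Series(np.asarray(self.batch, dtype=object), index=self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class AlignmentScore:
    """Result of one alignment-score evaluation."""

    k: int
    n_batches: int
    x_bar: float
    score: float
    n_sampled_per_batch: int
    seed: int
    n_repeats: int = 1


def score_from_xbar(x_bar: float, k: int, n_batches: int) -> float:
    """Normalized mixing score for a mean same-batch neighbor count."""
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    raw = 1.0 - (x_bar - k / n_batches) / (k - k / n_batches)
    return float(np.clip(raw, 0.0, 1.0))


def _subsample_indices(
    batch: np.ndarray, rng: np.random.Generator, exclude: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Equal-size per-batch subsample (without replacement), sorted for
    deterministic downstream tie-breaking."""
    keep = np.ones(len(batch), dtype=bool)
    if exclude is not None:
        keep &= ~exclude
    labels = np.unique(batch[keep])
    if len(labels) < 2:
        raise ValueError("need at least 2 batches with cells after exclusion")
    per_batch = [np.flatnonzero(keep & (batch == b)) for b in labels]
    m = min(len(ix) for ix in per_batch)
    chosen = np.concatenate([rng.choice(ix, m, replace=False) for ix in per_batch])
    return np.sort(chosen), m


def _same_batch_counts(coords: np.ndarray, codes: np.ndarray, k_max: int) -> np.ndarray:
    """(n, k_max) boolean array: neighbor j of cell i shares i's batch.

    Exact kNN from the full Euclidean distance matrix; ties broken by cell
    index (stable argsort); self excluded.
    """
    d2 = np.sum(coords**2, axis=1)
    dist = d2[:, None] + d2[None, :] - 2.0 * coords @ coords.T
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k_max]
    return codes[order] == codes[:, None]


def alignment_score(
    embedding: Embedding,
    k: int,
    seed: int = 0,
    n_repeats: int = 1,
    exclude_cells=None,
) -> AlignmentScore:
    """Alignment score of one embedding.

    Parameters
    ----------
    k
        Neighborhood size; must be smaller than the subsample total.
    n_repeats
        Number of independent subsampling repeats to average (the score and
        x_bar are means over repeats); 1 by default.
    exclude_cells
        Optional cell ids to mask before subsampling (e.g. populations
        present in only one batch).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    batch = embedding.batch.values
    exclude = None
    if exclude_cells is not None:
        exclude = embedding.cells.isin(pd.Index(exclude_cells))
    rng = np.random.default_rng([int(seed), 101])
    xbars = []
    m = 0
    n_batches = 0
    for _ in range(n_repeats):
        idx, m = _subsample_indices(batch, rng, exclude)
        codes, labels = pd.factorize(pd.Series(batch[idx]))
        n_batches = len(labels)
        if k >= len(idx):
            raise ValueError(f"k={k} must be smaller than the subsample total {len(idx)}")
        same = _same_batch_counts(embedding.coords[idx], codes, k)
        xbars.append(float(same.sum(axis=1).mean()))
    x_bar = float(np.mean(xbars))
    return AlignmentScore(
        k=int(k),
        n_batches=n_batches,
        x_bar=x_bar,
        score=float(np.mean([score_from_xbar(x, k, n_batches) for x in xbars])),
        n_sampled_per_batch=m,
        seed=int(seed),
        n_repeats=int(n_repeats),
    )


def k_sweep(
    embedding: Embedding, k_values, seed: int = 0, exclude_cells=None
) -> list[AlignmentScore]:
    """Alignment scores over a list of k, sharing one subsample and one
    neighbor ordering for comparability across k."""
    k_values = [int(k) for k in k_values]
    if not k_values:
        raise ValueError("k_values must be non-empty")
    batch = embedding.batch.values
    exclude = None
    if exclude_cells is not None:
        exclude = embedding.cells.isin(pd.Index(exclude_cells))
    rng = np.random.default_rng([int(seed), 101])
    idx, m = _subsample_indices(batch, rng, exclude)
    codes, labels = pd.factorize(pd.Series(batch[idx]))
    n_batches = len(labels)
    k_max = max(k_values)
    if k_max >= len(idx):
        raise ValueError(f"k={k_max} must be smaller than the subsample total {len(idx)}")
    same = _same_batch_counts(embedding.coords[idx], codes, k_max)
    csum = np.cumsum(same, axis=1)
    out = []
    for k in k_values:
        x_bar = float(csum[:, k - 1].mean())
        out.append(
            AlignmentScore(
                k=k,
                n_batches=n_batches,
                x_bar=x_bar,
                score=score_from_xbar(x_bar, k, n_batches),
                n_sampled_per_batch=m,
                seed=int(seed),
            )
        )
    return out


def compare_methods(
    embeddings: dict[str, Embedding], k: int, seed: int = 0, exclude_cells=None
) -> pd.DataFrame:
    """Score several embeddings of the same cells with a common subsample.

    Returns a DataFrame (method, score, x_bar, k, n_sampled_per_batch)
    sorted by descending score — the best-mixed embedding first.
    """
    items = list(embeddings.items())
    if not items:
        raise ValueError("no embeddings given")
    ref_name, ref = items[0]
    for name, emb in items[1:]:
        if not ref.cells.equals(emb.cells) or not ref.batch.equals(emb.batch):
            raise ValueError(f"embedding {name!r} does not share cells/batches with {ref_name!r}")
    batch = ref.batch.values
    exclude = None
    if exclude_cells is not None:
        exclude = ref.cells.isin(pd.Index(exclude_cells))
    rng = np.random.default_rng([int(seed), 101])
    idx, m = _subsample_indices(batch, rng, exclude)
    codes, _ = pd.factorize(pd.Series(batch[idx]))
    n_batches = int(codes.max()) + 1
    if k >= len(idx):
        raise ValueError(f"k={k} must be smaller than the subsample total {len(idx)}")
    rows = []
    for name, emb in items:
        same = _same_batch_counts(emb.coords[idx], codes, k)
        x_bar = float(same.sum(axis=1).mean())
        rows.append(
            {
                "method": name,
                "score": score_from_xbar(x_bar, k, n_batches),
                "x_bar": x_bar,
                "k": int(k),
                "n_sampled_per_batch": m,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["score", "method"], ascending=[False, True])
        .reset_index(drop=True)
    )
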