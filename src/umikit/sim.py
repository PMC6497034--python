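"""Seeded synthetic UMI-count cohorts with planted ground truth.

The generator emulates the statistical structure each downstream stage
assumes: negative-binomial counts over discrete cell types spread across
batches, a hemoglobin-high erythroblast-like subpopulation, doublet cells
summing two parent profiles at half depth, a linear maturation trajectory
with early/intermediate/late gene waves and declining library size, and
granzyme-style signature gene sets built around a planted shared core.

Counts follow NB(mean mu, dispersion theta) with variance mu + mu^2/theta.
Batch effects are per-gene log-normal multiplicative factors on the mean.
One integer seed is propagated to named substreams so each stage can be
regenerated independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix
from .integration import Embedding

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "generate_cohort",
    "generate_embedding",
    "generate_trajectory",
    "generate_program_sets",
    "generate_coexpression",
]

_HB_GENES = ["HBG1", "HBM", "HBA1", "HBA2", "HBB", "HBD", "HBG2", "HBQ1"]
_N_MITO = 10

# substream tags keep the per-stage RNGs independent of one another
_STREAMS = {
    "profiles": 11,
    "assign": 13,
    "counts": 17,
    "batch": 19,
    "embedding": 23,
    "trajectory": 29,
    "programs": 31,
    "coexpr": 37,
}


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study conditions: four batches (two cord-blood and
    two peripheral-blood libraries), a 3.92% hemoglobin-high fraction,
    signature-set sizes drawn in [116, 144] with planted shared cores of
    31 (GZMB-type) and 22 (GZMK-type) genes, and a maturation trajectory
    whose expected library size drops along pseudotime.
    """

    n_batches: int = 4
    cells_per_batch: int = 500
    n_genes: int = 2000
    n_cell_types: int = 5
    nb_mean_range: tuple[float, float] = (0.05, 2.0)
    nb_dispersion: float = 2.0
    batch_logfc_sd: float = 0.1
    hb_fraction: float = 0.0392
    marker_genes_per_type: int = 25
    marker_fold: float = 8.0
    hb_fold: float = 50.0
    traj_n_cells: int = 667
    traj_stage_genes: tuple[int, int, int] = (40, 40, 40)
    libsize_decay: float = 0.6
    program_size_range: tuple[int, int] = (116, 144)
    program_set_sizes: tuple[int, int, int, int] | None = None
    core_sizes: tuple[int, int] = (31, 22)
    doublet_fraction: float = 0.03
    n_doublet_pairs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_batches", "cells_per_batch", "n_genes", "n_cell_types", "traj_n_cells"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive count")
        for name in ("hb_fraction", "doublet_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        lo, hi = self.nb_mean_range
        if not (0 < lo <= hi):
            raise ConfigError("nb_mean_range must be positive reals with lo <= hi")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be a positive real")
        if self.batch_logfc_sd < 0:
            raise ConfigError("batch_logfc_sd must be non-negative")
        if not 0.0 <= self.libsize_decay < 1.0:
            raise ConfigError("libsize_decay must lie in [0, 1)")
        if any(int(g) < 1 for g in self.traj_stage_genes) or len(self.traj_stage_genes) != 3:
            raise ConfigError("traj_stage_genes must be three positive counts")
        slo, shi = self.program_size_range
        if not (1 <= slo <= shi):
            raise ConfigError("program_size_range must be positive with lo <= hi")
        if self.program_set_sizes is not None and (
            len(self.program_set_sizes) != 4 or any(int(s) < 1 for s in self.program_set_sizes)
        ):
            raise ConfigError("program_set_sizes must be four positive counts")
        if len(self.core_sizes) != 2 or any(int(c) < 0 for c in self.core_sizes):
            raise ConfigError("core_sizes must be two non-negative counts")
        if self.n_doublet_pairs < 1:
            raise ConfigError("n_doublet_pairs must be a positive count")
        min_size = min(self.program_set_sizes) if self.program_set_sizes else self.program_size_range[0]
        if max(self.core_sizes) > min_size:
            raise ConfigError("core_sizes cannot exceed the smallest program set size")


@dataclass
class GroundTruth:
    """Planted per-cell and global truth for a simulated dataset.

    ``cells`` has one row per cell with columns ``batch``, ``cell_type``,
    ``is_hb`` (hemoglobin-high), ``is_doublet``, ``parent_a``/``parent_b``
    (doublet parents, NA otherwise) and ``pseudotime`` (NA off-trajectory).
    ``gene_sets`` maps named planted gene lists (per-type marker blocks,
    trajectory stage waves, signature programs and their cores) to gene ids.
    """

    cells: pd.DataFrame
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dbl = self.cells["is_doublet"].astype(bool)
        pa, pb = self.cells["parent_a"], self.cells["parent_b"]
        if dbl.any() and (pa[dbl].isna().any() or (pa[dbl] == pb[dbl]).any()):
            raise ValueError("doublets must record two distinct parents")


def _gene_names(n_genes: int) -> list[str]:
    if n_genes < _N_MITO + len(_HB_GENES) + 1:
        raise ConfigError("n_genes too small for the mitochondrial and hemoglobin blocks")
    mito = [f"MT-G{i:02d}" for i in range(_N_MITO)]
    rest = [f"G{i:05d}" for i in range(n_genes - _N_MITO - len(_HB_GENES))]
    return mito + _HB_GENES + rest


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB(mean, dispersion) with variance mean + mean^2/theta."""
    mean = np.clip(mean, 1e-12, None)
    return rng.negative_binomial(theta, theta / (theta + mean), size=mean.shape)


def generate_cohort(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a multi-batch cohort of NB-distributed UMI counts.

    Cell types get mutually exclusive elevated marker-gene blocks; a
    ``hb_fraction`` of cells form a hemoglobin-high population; a
    ``doublet_fraction`` of cells are sums of two distinct parent-type
    draws thinned to half depth each.  Identical (config, seed) pairs give
    bit-identical outputs.
    """
    genes = _gene_names(config.n_genes)
    n_genes = len(genes)
    theta = config.nb_dispersion

    prof_rng = _rng(config.seed, "profiles")
    lo, hi = config.nb_mean_range
    base = np.exp(prof_rng.uniform(np.log(lo), np.log(hi), n_genes))

    types = [f"T{i:02d}" for i in range(config.n_cell_types)]
    hb_name = "HB_HIGH"
    hb_idx = np.array([genes.index(g) for g in _HB_GENES])
    pool = np.arange(_N_MITO + len(_HB_GENES), n_genes)
    marker_blocks: dict[str, np.ndarray] = {}
    profiles: dict[str, np.ndarray] = {}
    for t in types:
        block = prof_rng.choice(pool, size=min(config.marker_genes_per_type, len(pool)), replace=False)
        pool = np.setdiff1d(pool, block)
        marker_blocks[t] = block
        p = base.copy()
        p[block] *= config.marker_fold
        profiles[t] = p
    hb_profile = base.copy()
    hb_profile[hb_idx] *= config.hb_fold
    profiles[hb_name] = hb_profile

    assign_rng = _rng(config.seed, "assign")
    n_total = config.n_batches * config.cells_per_batch
    batches = np.repeat([f"B{i}" for i in range(config.n_batches)], config.cells_per_batch)
    is_hb = assign_rng.random(n_total) < config.hb_fraction
    is_dbl = (~is_hb) & (assign_rng.random(n_total) < config.doublet_fraction)
    cell_type = np.array(assign_rng.choice(types, n_total), dtype=object)
    cell_type[is_hb] = hb_name
    parent_a = np.full(n_total, None, dtype=object)
    parent_b = np.full(n_total, None, dtype=object)
    if config.n_cell_types >= 2:
        # doublets concentrate in a few parent pairs, forming small hybrid
        # clusters rather than a diffuse scatter of singleton profiles
        all_pairs = [(i, j) for i in range(config.n_cell_types) for j in range(i + 1, config.n_cell_types)]
        n_pairs = min(config.n_doublet_pairs, len(all_pairs))
        pair_ids = assign_rng.choice(len(all_pairs), n_pairs, replace=False)
        pairs = [all_pairs[p] for p in pair_ids]
        for i in np.flatnonzero(is_dbl):
            pa, pb = pairs[assign_rng.integers(n_pairs)]
            parent_a[i], parent_b[i] = types[pa], types[pb]
            cell_type[i] = f"DBL_{types[pa]}_{types[pb]}"
    else:
        is_dbl[:] = False

    batch_rng = _rng(config.seed, "batch")
    batch_factor = np.exp(
        batch_rng.normal(0.0, config.batch_logfc_sd, (config.n_batches, n_genes))
    )

    count_rng = _rng(config.seed, "counts")
    X = np.zeros((n_genes, n_total), dtype=np.int64)
    batch_codes = np.repeat(np.arange(config.n_batches), config.cells_per_batch)
    for i in range(n_total):
        bf = batch_factor[batch_codes[i]]
        if is_dbl[i]:
            d1 = _nb_draw(count_rng, profiles[parent_a[i]] * bf, theta)
            d2 = _nb_draw(count_rng, profiles[parent_b[i]] * bf, theta)
            X[:, i] = count_rng.binomial(d1, 0.5) + count_rng.binomial(d2, 0.5)
        else:
            X[:, i] = _nb_draw(count_rng, profiles[cell_type[i]] * bf, theta)

    cells = pd.Index([f"{batches[i]}-C{i:06d}" for i in range(n_total)])
    truth_cells = pd.DataFrame(
        {
            "batch": batches,
            "cell_type": cell_type,
            "is_hb": is_hb,
            "is_doublet": is_dbl,
            "parent_a": parent_a,
            "parent_b": parent_b,
            "pseudotime": np.nan,
        },
        index=cells,
    )
    gene_sets = {f"markers_{t}": [genes[j] for j in blk] for t, blk in marker_blocks.items()}
    gene_sets["hb_genes"] = list(_HB_GENES)
    gene_sets["mito_genes"] = [g for g in genes if g.startswith("MT-")]
    matrix = CountMatrix(pd.Index(genes), cells, sp.csr_matrix(X), pd.Series(batches, index=cells))
    return matrix, GroundTruth(truth_cells, gene_sets)


def generate_embedding(truth: GroundTruth, batch_shift: float, seed: int) -> Embedding:
    """2-D embedding with one Gaussian center per cell type plus a per-batch
    offset of magnitude ``batch_shift``.

    ``batch_shift = 0`` models a perfectly batch-corrected embedding; large
    values model uncorrected, batch-segregated data.
    """
    if batch_shift < 0:
        raise ValueError("batch_shift must be non-negative")
    if len(truth.cells) == 0:
        raise ValueError("truth is empty")
    rng = _rng(seed, "embedding")
    types = sorted(truth.cells["cell_type"].unique())
    batches = sorted(truth.cells["batch"].unique())
    centers = {t: rng.normal(0.0, 6.0, 2) for t in types}
    offsets = {}
    for b in batches:
        v = rng.normal(0.0, 1.0, 2)
        offsets[b] = batch_shift * v / np.linalg.norm(v)
    coords = np.empty((len(truth.cells), 2))
    for i, (t, b) in enumerate(zip(truth.cells["cell_type"], truth.cells["batch"])):
        coords[i] = centers[t] + offsets[b] + rng.normal(0.0, 1.0, 2)
    return Embedding(
        cells=pd.Index(truth.cells.index),
        coords=coords,
        batch=pd.Series(truth.cells["batch"].values, index=truth.cells.index),
    )


def generate_trajectory(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a linear maturation trajectory of NB counts.

    Three gene waves peak at pseudotime 0, 0.5 and 1 (primitive,
    intermediate, mature stages) and the expected library size declines by
    a factor of ``1 - libsize_decay`` from pseudotime 0 to 1.
    """
    if config.traj_n_cells < 10:
        raise ConfigError("traj_n_cells must be at least 10")
    rng = _rng(config.seed, "trajectory")
    n_cells = config.traj_n_cells
    t = np.sort(rng.uniform(0.0, 1.0, n_cells))

    n_e, n_i, n_l = (int(g) for g in config.traj_stage_genes)
    n_wave = n_e + n_i + n_l
    mito = [f"MT-G{i:02d}" for i in range(_N_MITO)]
    stage_genes = (
        [f"EARLY{i:04d}" for i in range(n_e)]
        + [f"INTER{i:04d}" for i in range(n_i)]
        + [f"LATE{i:04d}" for i in range(n_l)]
    )
    n_bg = max(config.n_genes - n_wave - _N_MITO, 20)
    genes = mito + stage_genes + [f"BG{i:05d}" for i in range(n_bg)]
    n_genes = len(genes)

    lo, hi = config.nb_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    amp = 6.0  # peak fold-change of a wave over its floor
    centers = np.concatenate([np.zeros(n_e), np.full(n_i, 0.5), np.ones(n_l)])
    width = 0.25

    mean = np.tile(base[:, None], (1, n_cells)).astype(float)
    wave_rows = slice(_N_MITO, _N_MITO + n_wave)
    bump = np.exp(-((t[None, :] - centers[:, None]) / width) ** 2)
    mean[wave_rows, :] *= 0.2 + amp * bump
    mean *= 1.0 - config.libsize_decay * t[None, :]

    X = _nb_draw(rng, mean, config.nb_dispersion)
    cells = pd.Index([f"TRAJ-C{i:05d}" for i in range(n_cells)])
    truth_cells = pd.DataFrame(
        {
            "batch": "B0",
            "cell_type": "NRBC",
            "is_hb": True,
            "is_doublet": False,
            "parent_a": None,
            "parent_b": None,
            "pseudotime": t,
        },
        index=cells,
    )
    gene_sets = {
        "stage_early": [g for g in genes if g.startswith("EARLY")],
        "stage_intermediate": [g for g in genes if g.startswith("INTER")],
        "stage_late": [g for g in genes if g.startswith("LATE")],
        "mito_genes": mito,
    }
    matrix = CountMatrix(
        pd.Index(genes), cells, sp.csr_matrix(X), pd.Series("B0", index=cells)
    )
    return matrix, GroundTruth(truth_cells, gene_sets)


def _program_family(
    rng: np.random.Generator,
    universe: np.ndarray,
    names: Sequence[str],
    sizes: Sequence[int],
    core_size: int,
) -> tuple[dict[str, list[str]], list[str]]:
    core = list(rng.choice(universe, core_size, replace=False)) if core_size else []
    rest = np.setdiff1d(universe, core)
    sets = {}
    for name, s in zip(names, sizes):
        if core_size > s:
            raise ConfigError("core_sizes cannot exceed the smallest program set size")
        private = rng.choice(rest, s - core_size, replace=False)
        sets[name] = sorted(set(core) | set(private))
    return sets, sorted(core)


def generate_program_sets(
    config: SimConfig,
) -> tuple[dict[str, list[str]], dict[str, list[str]], GroundTruth]:
    """Build two families of four signature gene sets with planted cores.

    Each family (GZMB-type and GZMK-type) has four sets — one per cytotoxic
    subtype — each containing the family's planted shared core plus
    independently sampled private genes from the gene universe.  Set sizes
    are the configured ``program_set_sizes`` or drawn uniformly from
    ``program_size_range``.
    """
    rng = _rng(config.seed, "programs")
    universe = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    if config.program_set_sizes is not None:
        sizes_b = sizes_k = list(config.program_set_sizes)
    else:
        lo, hi = config.program_size_range
        sizes_b = list(rng.integers(lo, hi + 1, 4))
        sizes_k = list(rng.integers(lo, hi + 1, 4))
    subtype_names = ["NK_UCB", "NKT_UCB", "CTL_PB", "NK_PB"]
    gzmb, core_b = _program_family(
        rng, universe, [f"GZMB_{s}" for s in subtype_names], sizes_b, int(config.core_sizes[0])
    )
    gzmk, core_k = _program_family(
        rng, universe, [f"GZMK_{s}" for s in subtype_names], sizes_k, int(config.core_sizes[1])
    )
    empty = pd.DataFrame(
        {
            "batch": pd.Series(dtype=object),
            "cell_type": pd.Series(dtype=object),
            "is_hb": pd.Series(dtype=bool),
            "is_doublet": pd.Series(dtype=bool),
            "parent_a": pd.Series(dtype=object),
            "parent_b": pd.Series(dtype=object),
            "pseudotime": pd.Series(dtype=float),
        }
    )
    truth = GroundTruth(
        empty,
        {
            **{k: list(v) for k, v in gzmb.items()},
            **{k: list(v) for k, v in gzmk.items()},
            "core_gzmb": core_b,
            "core_gzmk": core_k,
            "universe": list(universe),
        },
    )
    return gzmb, gzmk, truth


def generate_coexpression(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    n_cells: int,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression table (genes x cells) with two anti-correlated modules.

    A single latent activation per cell drives module A up and module B
    down, emulating mutually exclusive co-expression programs; ``noise_sd``
    is the independent per-gene Gaussian noise on top of the latent signal.
    """
    if n_cells < 3:
        raise ValueError("n_cells must be at least 3")
    rng = _rng(seed, "coexpr")
    latent = rng.normal(0.0, 1.0, n_cells)
    rows = []
    for _ in genes_a:
        rows.append(latent + rng.normal(0.0, noise_sd, n_cells))
    for _ in genes_b:
        rows.append(-latent + rng.normal(0.0, noise_sd, n_cells))
    index = pd.Index(list(genes_a) + list(genes_b))
    if not index.is_unique:
        raise ValueError("module gene lists overlap")
    return pd.DataFrame(np.array(rows), index=index, columns=[f"C{i:05d}" for i in range(n_cells)])
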