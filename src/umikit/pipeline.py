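"""End-to-end orchestration of the pipeline stages on synthetic data.

Stage order mirrors the analysis flow: simulate -> qc -> markers ->
integration -> trajectory -> signatures.  Every stage writes plain-text
artifacts (MTX triplet, TSV, JSON) under the output directory and the run
ends with a manifest echoing the configuration, seeds and per-stage record
counts.  The manifest contains no timestamps, so a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import CountMatrix, read_counts, write_counts
from .integration import k_sweep
from .markers import find_markers, flag_doublet_clusters, annotate_by_reference, lognormalize
from .qc import QCThresholds, compute_cell_qc, detected_gene_mask, filter_cells, flag_hemoglobin_clusters
from .sim import (
    SimConfig,
    generate_cohort,
    generate_coexpression,
    generate_embedding,
    generate_program_sets,
    generate_trajectory,
)
from .signatures import GeneSetCollection, coexpression_modules, intersection_permutation_test
from .trajectory import permutation_concordance_test, pseudotime_trend

__all__ = ["PipelineConfig", "PipelineError", "run_all", "read_counts", "write_counts"]

STAGES = ("simulate", "qc", "markers", "integration", "trajectory", "signatures")
_DEPENDS = {
    "qc": "simulate",
    "markers": "qc",
    "integration": "simulate",
    "trajectory": "simulate",
    "signatures": "simulate",
}

logger = logging.getLogger("umikit")
if not logger.handlers:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("[umikit:%(stage)s] %(message)s"))
    logger.addHandler(h)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    """Missing stage dependency or invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic run.

    ``stages`` lists enabled stages in any order; dependencies are checked
    (e.g. markers needs the qc stage's filtered matrix).  Per-stage
    parameters have study-scale defaults.
    """

    outdir: str = "umikit_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    sim: dict = field(default_factory=dict)
    qc_thresholds: dict = field(
        default_factory=lambda: {"min_genes": 25, "max_genes": 100000, "max_mito": 0.5,
                                 "min_cells_per_gene": 30}
    )
    hb_z_min: float = 2.0
    min_pct: float = 0.25
    logfc_min: float = 0.25
    k_values: tuple[int, ...] = (100,)
    batch_shifts: tuple[float, ...] = (0.0, 4.0)
    trajectory_B: int = 1000
    trajectory_noise_sd: float = 0.1
    signatures_B: int = 1000

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "k_values", "batch_shifts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=True)

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        sim.setdefault("seed", self.seed)
        for key in ("nb_mean_range", "traj_stage_genes", "program_size_range",
                    "program_set_sizes", "core_sizes"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        return SimConfig(**sim)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


def run_all(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order and write a manifest.

    Returns the manifest dict (also written to ``manifest.json``).  Raises
    :class:`PipelineError` if an enabled stage's upstream stage is absent.
    """
    enabled = [s for s in STAGES if s in config.stages]
    for s in enabled:
        dep = _DEPENDS.get(s)
        if dep and dep not in enabled:
            raise PipelineError(f"stage {s!r} requires artifacts of stage {dep!r}, which is not enabled")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"package_version": __version__, "seed": config.seed, "stages": []}
    state: dict = {}

    for stage in enabled:
        record = _RUNNERS[stage](config, out, state)
        record["name"] = stage
        manifest["stages"].append(record)
        _log(stage, f"done ({record})")

    manifest["config"] = _jsonable(asdict(config))
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
    return manifest


def _run_simulate(config: PipelineConfig, out: Path, state: dict) -> dict:
    matrix, truth = generate_cohort(config.sim_config())
    write_counts(matrix, out / "counts")
    truth.cells.to_csv(out / "truth_cells.tsv", sep="\t")
    with open(out / "truth_gene_sets.json", "w") as fh:
        json.dump(_jsonable(truth.gene_sets), fh, indent=2, sort_keys=True)
    state["matrix"], state["truth"] = matrix, truth
    return {"n_cells": matrix.n_cells, "n_genes": matrix.n_genes,
            "outputs": ["counts/", "truth_cells.tsv", "truth_gene_sets.json"]}


def _run_qc(config: PipelineConfig, out: Path, state: dict) -> dict:
    matrix: CountMatrix = state["matrix"]
    thr = QCThresholds(**config.qc_thresholds)
    mask = detected_gene_mask(matrix, thr.min_cells_per_gene)
    detected = matrix.subset_genes(mask)
    qc = compute_cell_qc(detected)
    kept = filter_cells(qc, thr)
    filtered = detected.subset_cells(kept)
    truth = state["truth"]
    norm = lognormalize(filtered)
    hb_flagged = flag_hemoglobin_clusters(
        norm.to_frame(),
        truth.cells.loc[kept, "cell_type"],
        [g for g in truth.gene_sets["hb_genes"] if g in filtered.genes],
        z_min=config.hb_z_min,
    )
    qc.to_csv(out / "cell_qc.tsv", sep="\t")
    pd.Series(kept).to_csv(out / "kept_barcodes.txt", index=False, header=False)
    with open(out / "hb_flagged_clusters.json", "w") as fh:
        json.dump(hb_flagged, fh)
    state["filtered"], state["qc"], state["norm"] = filtered, qc, norm
    state["hb_flagged"] = hb_flagged
    return {"n_detected_genes": int(mask.sum()), "n_kept_cells": len(kept),
            "hb_flagged_clusters": hb_flagged,
            "outputs": ["cell_qc.tsv", "kept_barcodes.txt", "hb_flagged_clusters.json"]}


def _run_markers(config: PipelineConfig, out: Path, state: dict) -> dict:
    filtered: CountMatrix = state["filtered"]
    truth = state["truth"]
    labels = truth.cells.loc[filtered.cells, "cell_type"]
    norm = state["norm"]
    mk = find_markers(norm, labels, min_pct=config.min_pct, logfc_min=config.logfc_min)
    doublets = flag_doublet_clusters(mk, labels)
    expr = norm.to_frame()
    cluster_means = expr.T.groupby(labels).mean().T
    # self-annotation sanity check: references = the cluster mean profiles
    annot = annotate_by_reference(cluster_means, cluster_means)
    mk.to_csv(out / "markers.tsv", sep="\t", index=False)
    annot.to_csv(out / "annotation.tsv", sep="\t")
    with open(out / "doublet_flagged_clusters.json", "w") as fh:
        json.dump(list(doublets), fh)
    state["markers"] = mk
    return {"n_marker_records": len(mk), "doublet_flagged": list(doublets),
            "outputs": ["markers.tsv", "annotation.tsv", "doublet_flagged_clusters.json"]}


def _run_integration(config: PipelineConfig, out: Path, state: dict) -> dict:
    truth = state["truth"]
    report = {}
    for shift in config.batch_shifts:
        emb = generate_embedding(truth, batch_shift=float(shift), seed=config.seed)
        scores = k_sweep(emb, list(config.k_values), seed=config.seed)
        report[f"batch_shift_{shift:g}"] = [
            {"k": s.k, "score": s.score, "x_bar": s.x_bar,
             "n_batches": s.n_batches, "n_sampled_per_batch": s.n_sampled_per_batch}
            for s in scores
        ]
    with open(out / "alignment_scores.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return {"n_embeddings": len(config.batch_shifts), "k_values": list(config.k_values),
            "outputs": ["alignment_scores.json"]}


def _run_trajectory(config: PipelineConfig, out: Path, state: dict) -> dict:
    matrix, truth = generate_trajectory(config.sim_config())
    qc = compute_cell_qc(matrix)
    t_true = truth.cells["pseudotime"]
    rng = np.random.default_rng([int(config.seed), 401])
    observed = pd.Series(
        t_true.values + rng.normal(0.0, config.trajectory_noise_sd, len(t_true)),
        index=t_true.index,
    )
    conc = permutation_concordance_test(t_true, observed, B=config.trajectory_B, seed=config.seed)
    umi_trend = pseudotime_trend(qc["total_umi"], t_true)
    gene_trend = pseudotime_trend(qc["detected_genes"], t_true)
    result = {
        "concordance": {"rho_signed": conc.rho_signed, "p_empirical": conc.p_empirical,
                        "p_ttest": conc.p_ttest, "B": conc.B},
        "umi_trend": {"rho": umi_trend.rho, "p_value": umi_trend.p_value},
        "detected_genes_trend": {"rho": gene_trend.rho, "p_value": gene_trend.p_value},
    }
    with open(out / "trajectory_stats.json", "w") as fh:
        json.dump(_jsonable(result), fh, indent=2, sort_keys=True)
    return {"n_trajectory_cells": matrix.n_cells, "outputs": ["trajectory_stats.json"]}


def _run_signatures(config: PipelineConfig, out: Path, state: dict) -> dict:
    sim_cfg = config.sim_config()
    gzmb, gzmk, truth = generate_program_sets(sim_cfg)
    universe = truth.gene_sets["universe"]
    results = {}
    for name, fam in (("gzmb", gzmb), ("gzmk", gzmk)):
        coll = GeneSetCollection.from_mapping(fam, universe)
        res = intersection_permutation_test(coll, B=config.signatures_B, seed=config.seed)
        results[name] = {
            "observed_intersection": res.observed,
            "null_mean": res.null_mean, "null_sd": res.null_sd,
            "p_ttest": res.p_ttest, "p_empirical": res.p_empirical, "B": res.B,
            "regions": {"|".join(k): v for k, v in res.regions.items()},
        }
    core_b, core_k = truth.gene_sets["core_gzmb"], truth.gene_sets["core_gzmk"]
    expr = generate_coexpression(core_b, core_k, n_cells=300, seed=config.seed)
    modules = coexpression_modules(expr, n_modules=2)
    modules.modules.to_csv(out / "coexpression_modules.tsv", sep="\t")
    modules.correlation.to_csv(out / "coexpression_correlation.tsv", sep="\t")
    with open(out / "signature_tests.json", "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
    return {"observed_gzmb": results["gzmb"]["observed_intersection"],
            "observed_gzmk": results["gzmk"]["observed_intersection"],
            "outputs": ["signature_tests.json", "coexpression_modules.tsv",
                        "coexpression_correlation.tsv"]}


_RUNNERS = {
    "simulate": _run_simulate,
    "qc": _run_qc,
    "markers": _run_markers,
    "integration": _run_integration,
    "trajectory": _run_trajectory,
    "signatures": _run_signatures,
}
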