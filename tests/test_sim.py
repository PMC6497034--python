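"""Generator tests: determinism, planted marginals and planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from umikit import (
    ConfigError,
    SimConfig,
    alignment_score,
    generate_cohort,
    generate_embedding,
    generate_program_sets,
    generate_trajectory,
)


def test_identical_config_and_seed_give_bit_identical_outputs():
    cfg = SimConfig(n_batches=2, cells_per_batch=50, n_genes=100, seed=11)
    m1, t1 = generate_cohort(cfg)
    m2, t2 = generate_cohort(cfg)
    assert (m1.counts != m2.counts).nnz == 0
    pd.testing.assert_frame_equal(t1.cells, t2.cells)
    assert t1.gene_sets == t2.gene_sets


@pytest.mark.parametrize(
    "kwargs, field",
    [
        ({"n_batches": 0}, "n_batches"),
        ({"hb_fraction": 1.5}, "hb_fraction"),
        ({"nb_dispersion": -1.0}, "nb_dispersion"),
        ({"batch_logfc_sd": -0.1}, "batch_logfc_sd"),
        ({"libsize_decay": 1.0}, "libsize_decay"),
        ({"core_sizes": (200, 22)}, "core_sizes"),
        ({"n_doublet_pairs": 0}, "n_doublet_pairs"),
    ],
)
def test_invalid_config_errors_name_the_field(kwargs, field):
    with pytest.raises(ConfigError, match=field):
        SimConfig(**kwargs)


def test_hemoglobin_high_fraction_matches_binomial_expectation():
    # 10,000 cells at the study's 3.92% hemoglobin-high fraction
    cfg = SimConfig(
        n_batches=4, cells_per_batch=2500, n_genes=60, n_cell_types=3,
        hb_fraction=0.0392, doublet_fraction=0.0, seed=5,
    )
    _, truth = generate_cohort(cfg)
    n_hb = int(truth.cells["is_hb"].sum())
    sd = np.sqrt(10_000 * 0.0392 * (1 - 0.0392))
    assert abs(n_hb - 392) <= 3 * sd


def test_no_batch_effect_gives_nominal_rank_test_rejection_rate():
    # one cell type, batch_logfc_sd = 0: the two batches are draws from one
    # distribution, so per-gene two-sided rank tests should reject ~ alpha
    cfg = SimConfig(
        n_batches=2, cells_per_batch=150, n_genes=300, n_cell_types=1,
        batch_logfc_sd=0.0, hb_fraction=0.0, doublet_fraction=0.0,
        marker_genes_per_type=1, seed=13,
    )
    matrix, truth = generate_cohort(cfg)
    X = matrix.counts.toarray()
    in_b0 = (truth.cells["batch"] == "B0").values
    pvals = np.array(
        [mannwhitneyu(row[in_b0], row[~in_b0], method="asymptotic").pvalue
         for row in X if row.std() > 0]
    )
    assert len(pvals) >= 200
    rate = float((pvals < 0.05).mean())
    assert 0.02 <= rate <= 0.09


def test_count_marginals_match_nb_mean_and_variance():
    # homogeneous population: per-gene sample mean within 3 SE of the NB
    # mean, and sample variance consistent with mu + mu^2/theta
    theta = 2.0
    cfg = SimConfig(
        n_batches=1, cells_per_batch=2000, n_genes=220, n_cell_types=1,
        nb_dispersion=theta, batch_logfc_sd=0.0, hb_fraction=0.0,
        doublet_fraction=0.0, marker_genes_per_type=1, seed=17,
    )
    matrix, _ = generate_cohort(cfg)
    X = matrix.counts.toarray().astype(float)
    # recover each gene's configured mean from the empirical mean's CI and
    # compare the variance law; use the empirical mean as the NB mu estimate
    mu_hat = X.mean(axis=1)
    var_expected = mu_hat + mu_hat**2 / theta
    var_hat = X.var(axis=1, ddof=1)
    # SE of the sample variance for NB via 4th central moment, estimated
    m4 = ((X - mu_hat[:, None]) ** 4).mean(axis=1)
    se_var = np.sqrt(np.clip(m4 - var_hat**2, 0, None) / X.shape[1])
    ok = np.abs(var_hat - var_expected) <= 3 * se_var + 1e-9
    assert ok.mean() >= 0.95


def test_trajectory_library_size_decay_and_gene_waves():
    cfg = SimConfig(traj_n_cells=600, n_genes=200, libsize_decay=0.6, seed=23)
    matrix, truth = generate_trajectory(cfg)
    t = truth.cells["pseudotime"].values
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    res = spearmanr(totals, t)
    assert res.statistic < -0.5 and res.pvalue < 1e-6

    X = matrix.counts.toarray()
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    early = [gene_pos[g] for g in truth.gene_sets["stage_early"]]
    late = [gene_pos[g] for g in truth.gene_sets["stage_late"]]
    first_third, last_third = t < 1 / 3, t > 2 / 3
    assert X[early][:, first_third].mean() > 2 * X[early][:, last_third].mean()
    assert X[late][:, last_third].mean() > 2 * X[late][:, first_third].mean()


def test_trajectory_without_decay_has_no_library_size_trend():
    cfg = SimConfig(traj_n_cells=600, n_genes=200, libsize_decay=0.0,
                    traj_stage_genes=(5, 5, 5), seed=29)
    matrix, truth = generate_trajectory(cfg)
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    rho = spearmanr(totals, truth.cells["pseudotime"].values).statistic
    assert abs(rho) < 0.15


def test_trajectory_rejects_decay_of_one_or_more():
    with pytest.raises(ConfigError):
        SimConfig(libsize_decay=1.2)


def test_program_sets_contain_planted_cores_at_study_sizes():
    cfg = SimConfig(n_genes=12_000, core_sizes=(31, 22), seed=31)
    gzmb, gzmk, truth = generate_program_sets(cfg)
    for fam, core_key in ((gzmb, "core_gzmb"), (gzmk, "core_gzmk")):
        core = set(truth.gene_sets[core_key])
        inter = set.intersection(*(set(v) for v in fam.values()))
        assert core <= inter
        assert all(116 <= len(v) <= 144 for v in fam.values())
    assert len(truth.gene_sets["core_gzmb"]) == 31
    assert len(truth.gene_sets["core_gzmk"]) == 22


def test_coreless_program_sets_overlap_matches_product_expectation():
    # with no planted core the 4-way overlap is hypergeometric-independent:
    # E = U * prod(s_i / U)
    U, s = 200, 50
    sizes = (s, s, s, s)
    expected = U * (s / U) ** 4
    draws = []
    for seed in range(1000):
        cfg = SimConfig(n_genes=U, core_sizes=(0, 0), program_set_sizes=sizes, seed=seed)
        gzmb, _, _ = generate_program_sets(cfg)
        draws.append(len(set.intersection(*(set(v) for v in gzmb.values()))))
    draws = np.asarray(draws, dtype=float)
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - expected) <= 3 * se + 1e-9


def test_sets_equal_to_universe_intersect_fully():
    U = 30
    cfg = SimConfig(n_genes=U, core_sizes=(0, 0), program_set_sizes=(U, U, U, U), seed=3)
    gzmb, _, _ = generate_program_sets(cfg)
    assert len(set.intersection(*(set(v) for v in gzmb.values()))) == U


def test_embedding_batch_shift_zero_is_mixed_and_large_shift_segregates(small_cohort):
    _, _, truth = small_cohort
    mixed = generate_embedding(truth, batch_shift=0.0, seed=1)
    segregated = generate_embedding(truth, batch_shift=200.0, seed=1)
    assert alignment_score(mixed, k=50, seed=2).score > 0.9
    assert alignment_score(segregated, k=50, seed=2).score == 0.0


def test_embedding_rejects_negative_shift(small_cohort):
    _, _, truth = small_cohort
    with pytest.raises(ValueError):
        generate_embedding(truth, batch_shift=-1.0, seed=0)
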