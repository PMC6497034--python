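"""Marker detection: normalization identities, exact rank-sum oracle,
type-I calibration, doublet flagging and reference annotation."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from umikit import (
    SimConfig,
    annotate_by_reference,
    find_markers,
    flag_doublet_clusters,
    generate_cohort,
    lognormalize,
)
from umikit.markers import exact_ranksum_pvalue
from conftest import make_counts


# --- normalization -----------------------------------------------------------

def test_lognormalize_closed_forms():
    cm = make_counts([[0, 7, 1], [0, 0, 0]])
    norm = lognormalize(cm, scale=1e4).to_frame()
    assert norm.loc["G0", "C0"] == 0.0           # zero count
    assert norm.loc["G0", "C2"] == pytest.approx(np.log(10001))  # single-gene cell
    assert (norm["C0"] == 0).all()               # all-zero cell maps to zeros


def test_lognormalize_column_identity():
    rng = np.random.default_rng(2)
    cm = make_counts(rng.integers(0, 20, (30, 8)))
    norm = lognormalize(cm, scale=1e4).to_frame()
    colsums = np.expm1(norm).sum(axis=0)
    assert np.allclose(colsums, 1e4)


# --- exact rank-sum test -----------------------------------------------------

def _enumeration_pvalue(x, y):
    """Brute-force two-sided rank-sum p over all C(n, n1) group assignments."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, n1 = len(pooled), len(x)
    e = n1 * ranks.mean()
    s_obs = ranks[:n1].sum()
    hits = sum(
        abs(ranks[list(idx)].sum() - e) >= abs(s_obs - e) - 1e-9
        for idx in itertools.combinations(range(n), n1)
    )
    return hits / comb(n, n1)


@pytest.mark.parametrize(
    "x, y",
    [
        ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),
        ([1.0, 5.0, 2.0], [3.0, 4.0, 6.0]),
        ([0.0, 0.0, 1.0], [0.0, 2.0, 2.0]),      # heavy ties
        ([1.0, 1.0, 1.0, 2.0], [1.0, 3.0, 3.0]),  # unequal sizes with ties
        ([0.0] * 4, [0.0, 0.0, 1.0, 1.0]),
    ],
)
def test_exact_pvalue_equals_full_enumeration(x, y):
    got = exact_ranksum_pvalue(np.array(x), np.array(y))
    want = _enumeration_pvalue(np.array(x), np.array(y))
    assert got == pytest.approx(want, abs=1e-12)


def test_exact_pvalue_matches_scipy_on_tie_free_data():
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        ours = exact_ranksum_pvalue(x, y)
        ref = mannwhitneyu(x, y, method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


# --- find_markers ------------------------------------------------------------

def _two_cluster_matrix():
    # gene 0 on in cluster A only, gene 3 on in B only (so totals match and
    # gene 1 stays identical after depth normalization)
    X = np.zeros((4, 12), dtype=int)
    X[0, :6] = 10
    X[1, :] = 5
    X[2, :] = [0, 1, 2, 3, 4, 5] * 2
    X[3, 6:] = 10
    labels = pd.Series(["A"] * 6 + ["B"] * 6, index=[f"C{j}" for j in range(12)])
    return make_counts(X), labels


def test_exclusive_gene_is_top_marker_with_full_pct_split():
    cm, labels = _two_cluster_matrix()
    mk = find_markers(lognormalize(cm), labels, min_pct=0.25, logfc_min=0.25)
    rec = mk[(mk["gene"] == "G0") & (mk["cluster"] == "A")].iloc[0]
    assert rec["pct_in"] == 1.0 and rec["pct_out"] == 0.0
    assert rec["p_value"] == mk[mk["cluster"] == "A"]["p_value"].min()
    assert rec["p_adjusted"] >= rec["p_value"]


def test_identically_distributed_gene_is_not_reported_significant():
    cm, labels = _two_cluster_matrix()
    mk = find_markers(lognormalize(cm), labels)
    g1 = mk[mk["gene"] == "G1"]
    assert g1.empty or (g1["p_adjusted"] > 0.05).all()


def test_single_cluster_raises_no_contrast():
    cm, _ = _two_cluster_matrix()
    labels = pd.Series(["A"] * 12, index=cm.cells)
    with pytest.raises(ValueError, match="contrast"):
        find_markers(lognormalize(cm), labels)


def test_three_vs_three_pvalues_equal_exhaustive_enumeration():
    rng = np.random.default_rng(4)
    X = rng.integers(0, 6, (10, 6))
    X[0] = [5, 6, 7, 0, 0, 0]  # one clean marker so something passes the gates
    cm = make_counts(X)
    labels = pd.Series(["A"] * 3 + ["B"] * 3, index=cm.cells)
    norm = lognormalize(cm)
    mk = find_markers(norm, labels, min_pct=0.0, logfc_min=0.0)
    dense = norm.to_frame()
    for _, rec in mk.iterrows():
        row = dense.loc[rec["gene"]].values
        in_mask = (labels == rec["cluster"]).values
        want = _enumeration_pvalue(row[in_mask], row[~in_mask])
        assert rec["p_value"] == pytest.approx(want, abs=1e-12)


def test_markers_invariant_to_cell_order_and_cluster_relabeling(small_cohort):
    _, matrix, truth = small_cohort
    pure = ~truth.cells["is_doublet"].values
    sub = matrix.subset_cells(np.flatnonzero(pure)[::3])
    labels = truth.cells.loc[sub.cells, "cell_type"]
    base = find_markers(lognormalize(sub), labels)

    perm = np.random.default_rng(8).permutation(sub.n_cells)
    shuffled = sub.subset_cells(perm)
    mk_perm = find_markers(lognormalize(shuffled), labels.iloc[perm])
    pd.testing.assert_frame_equal(base, mk_perm)

    renamed = labels.map(lambda c: f"x_{c}")
    mk_renamed = find_markers(lognormalize(sub), renamed)
    assert len(mk_renamed) == len(base)
    got = mk_renamed.assign(cluster=mk_renamed["cluster"].str.replace("x_", "", regex=False))
    got = got.sort_values(["cluster", "p_value", "gene"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(base, got)


def test_type_one_error_calibrated_on_random_split():
    # one homogeneous population split at random: p < alpha for at most
    # alpha + 3 SE of the tested genes
    rng = np.random.default_rng(6)
    X = rng.negative_binomial(2, 0.4, (400, 100))
    cm = make_counts(X)
    labels = pd.Series(rng.permutation(["A"] * 50 + ["B"] * 50), index=cm.cells)
    mk = find_markers(lognormalize(cm), labels, min_pct=0.0, logfc_min=0.0)
    alpha = 0.05
    rate = float((mk["p_value"] < alpha).mean())
    se = np.sqrt(alpha * (1 - alpha) / len(mk))
    assert rate <= alpha + 3 * se


# --- doublet flagging --------------------------------------------------------

def test_doublet_clusters_flagged_and_pure_clusters_untouched(small_cohort):
    _, matrix, truth = small_cohort
    labels = truth.cells["cell_type"]
    mk = find_markers(lognormalize(matrix), labels)
    flagged = flag_doublet_clusters(mk, labels, max_frac=0.05)
    doublet_clusters = set(labels[truth.cells["is_doublet"]].unique())
    pure = set(labels.unique()) - doublet_clusters
    assert set(flagged) <= doublet_clusters
    assert doublet_clusters <= set(flagged)
    assert not (set(flagged) & pure)


def test_large_clusters_exempt_from_doublet_rule():
    mk = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g1", "g2", "g1", "g2"],
            "cluster": ["A", "A", "B", "B", "C", "C"],
            "p_value": [1e-10] * 6,
            "p_adjusted": [1e-8] * 6,
            "log_fc": [1.0] * 6,
            "pct_in": [1.0] * 6,
            "pct_out": [0.0] * 6,
        }
    )
    # identical marker sets, but every cluster holds >5% of cells
    labels = pd.Series(["A"] * 40 + ["B"] * 40 + ["C"] * 20)
    assert flag_doublet_clusters(mk, labels, max_frac=0.05) == []
    # shrink C below 5%: now it shares markers with two larger clusters
    labels_small_c = pd.Series(["A"] * 50 + ["B"] * 48 + ["C"] * 2)
    assert flag_doublet_clusters(mk, labels_small_c, max_frac=0.05) == ["C"]


# --- annotation --------------------------------------------------------------

def test_annotation_exact_and_affine_matches():
    genes = [f"g{i}" for i in range(10)]
    rng = np.random.default_rng(7)
    ref = pd.DataFrame(rng.uniform(0, 5, (10, 3)), index=genes, columns=["B", "A", "C"])
    clusters = pd.DataFrame(
        {"c1": ref["A"], "c2": 2.0 * ref["B"] + 5.0}, index=genes
    )
    result = annotate_by_reference(clusters, ref)
    assert result.loc["c1", "best_label"] == "A"
    assert result.loc["c1", "A"] == pytest.approx(1.0)
    assert result.loc["c2", "best_label"] == "B"
    assert result.loc["c2", "B"] == pytest.approx(1.0)


def test_annotation_requires_three_shared_genes():
    a = pd.DataFrame({"c": [1.0, 2.0]}, index=["g1", "g2"])
    b = pd.DataFrame({"r": [1.0, 2.0]}, index=["g1", "g3"])
    with pytest.raises(ValueError, match="shared genes"):
        annotate_by_reference(a, b)


def test_cross_batch_annotation_recovers_cell_types(small_cohort):
    _, matrix, truth = small_cohort
    norm = lognormalize(matrix).to_frame()
    labels = truth.cells["cell_type"]
    in_b0 = (truth.cells["batch"] == "B0").values
    pure = ~truth.cells["is_doublet"].values
    ref = norm.loc[:, in_b0 & pure].T.groupby(labels[in_b0 & pure]).mean().T
    query = norm.loc[:, ~in_b0 & pure].T.groupby(labels[~in_b0 & pure]).mean().T
    shared = sorted(set(ref.columns) & set(query.columns))
    result = annotate_by_reference(query[shared], ref[shared])
    accuracy = (result["best_label"] == result.index).mean()
    assert accuracy >= 0.95
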