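"""Single-cell QC, normalization, embedding, clustering, markers."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcmregnet import (GeneSetCollection, annotate_clusters, batch_center,
                       bh_adjust, cluster_graph, cluster_means, composition,
                       find_markers, normalize_lognorm, qc_filter,
                       scale_and_pca, select_hvg)
from dcmregnet.scqc import EmptySelectionError, detected_genes, rank_sum_pvalue

from conftest import make_cell_matrix


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def _cells_with_detected(counts_per_cell):
    """One gene per unit: cell j expresses exactly counts_per_cell[j] genes."""
    n = max(counts_per_cell)
    mat = np.zeros((n, len(counts_per_cell)), dtype=int)
    for j, k in enumerate(counts_per_cell):
        mat[:k, j] = 1
    return make_cell_matrix(mat)


def test_qc_filter_boundaries_inclusive():
    cells = _cells_with_detected([199, 200, 300, 5000, 5001])
    kept = qc_filter(cells, min_genes=200, max_genes=5000)
    g = detected_genes(kept)
    assert sorted(g) == [200, 300, 5000]


def test_qc_filter_matches_brute_force_scan(rng):
    counts = (rng.random((300, 80)) < 0.5) * rng.integers(1, 5, (300, 80))
    cells = make_cell_matrix(counts)
    kept = qc_filter(cells, min_genes=120, max_genes=180)
    expected = [cells.cell_ids[j] for j in range(80)
                if 120 <= (counts[:, j] > 0).sum() <= 180]
    assert kept.cell_ids == expected


def test_qc_filter_idempotent(rng):
    counts = (rng.random((300, 60)) < 0.5) * rng.integers(1, 5, (300, 60))
    cells = make_cell_matrix(counts)
    once = qc_filter(cells, min_genes=120, max_genes=200)
    twice = qc_filter(once, min_genes=120, max_genes=200)
    assert once.cell_ids == twice.cell_ids


def test_qc_filter_all_removed_reports_tally():
    cells = _cells_with_detected([5, 6, 7])
    with pytest.raises(EmptySelectionError, match="below"):
        qc_filter(cells, min_genes=100, max_genes=200)


# ---------------------------------------------------------------------------
# Log normalization
# ---------------------------------------------------------------------------

def test_lognorm_closed_form():
    mat = np.zeros((100, 1), dtype=int)
    mat[0, 0] = 10
    mat[1, 0] = 9990
    cells = make_cell_matrix(mat)
    ln = normalize_lognorm(cells, scale=10000)
    assert ln.dense()[0, 0] == pytest.approx(np.log(11.0), abs=1e-12)


def test_lognorm_scale_invariance(rng):
    counts = rng.integers(0, 20, (50, 1))
    counts[0] = 1
    a = make_cell_matrix(counts)
    b = make_cell_matrix(counts * 2)
    assert np.allclose(normalize_lognorm(a).dense(),
                       normalize_lognorm(b).dense())


def test_lognorm_matches_formula(rng):
    counts = (rng.random((100, 30)) < 0.4) * rng.integers(1, 30, (100, 30))
    counts[0, :] = 1                    # no zero-total cells
    cells = make_cell_matrix(counts)
    ln = normalize_lognorm(cells, scale=1e4).dense()
    totals = counts.sum(axis=0)
    expected = np.log1p(1e4 * counts / totals)
    assert np.allclose(ln, expected, atol=1e-12)


def test_lognorm_zero_total_cell_errors():
    counts = np.zeros((10, 2), dtype=int)
    counts[0, 0] = 5
    with pytest.raises(EmptySelectionError, match="zero total"):
        normalize_lognorm(make_cell_matrix(counts))


# ---------------------------------------------------------------------------
# Highly variable genes
# ---------------------------------------------------------------------------

def test_hvg_constant_genes_never_beat_variable(rng):
    # lognorm-layer input: rows 10+ identically constant across cells
    expr = np.ones((50, 40)) * 1.7
    expr[:10] = rng.gamma(2.0, 1.0, (10, 40))
    cells = make_cell_matrix(expr, layer_tag="lognorm")
    top = select_hvg(cells, n_top=10)
    assert set(top) == {f"g{i:04d}" for i in range(10)}


def test_hvg_recovers_planted_high_dispersion_genes(rng):
    n_genes, n_cells = 400, 300
    mean = rng.uniform(3, 20, n_genes)   # counts where overdispersion shows
    phi = np.full(n_genes, 0.05)
    hot = rng.choice(n_genes, 40, replace=False)
    phi[hot] = 0.5                                     # 10x dispersion
    lam = rng.gamma(1 / phi[:, None], (mean[:, None] * phi[:, None]),
                    (n_genes, n_cells))
    counts = rng.poisson(lam)
    cells = make_cell_matrix(counts)
    ln = normalize_lognorm(cells)
    top = select_hvg(ln, n_top=40)
    hits = len(set(top) & {f"g{i:04d}" for i in hot})
    assert hits / 40 > 0.9


def test_hvg_n_equal_to_gene_count_returns_all(rng):
    counts = rng.integers(0, 6, (30, 20))
    counts[0] = 1
    ln = normalize_lognorm(make_cell_matrix(counts))
    assert sorted(select_hvg(ln, n_top=30)) == sorted(ln.gene_ids)
    with pytest.raises(ValueError):
        select_hvg(ln, n_top=31)


# ---------------------------------------------------------------------------
# Scaling + PCA
# ---------------------------------------------------------------------------

def _lognorm_random(rng, n_genes=40, n_cells=60):
    counts = (rng.random((n_genes, n_cells)) < 0.6) * \
        rng.integers(1, 30, (n_genes, n_cells))
    counts[0] = 1
    return normalize_lognorm(make_cell_matrix(counts))


def test_pca_rank_two_matrix_has_two_components(rng):
    u = rng.normal(size=(30, 2))
    v = rng.normal(size=(2, 15))
    x = (u @ v)
    cells = make_cell_matrix(x.T - x.T.min() + 0.1, layer_tag="lognorm")
    scores = scale_and_pca(cells, cells.gene_ids, n_pcs=10, clip=50)
    variances = scores.var(axis=0, ddof=1).to_numpy()
    assert variances[2:].max() < 1e-16 * variances[0] + 1e-18
    assert np.all(np.diff(variances) <= 1e-12)


def test_pca_full_reconstruction(rng):
    ln = _lognorm_random(rng)
    n_pcs = min(ln.n_genes, ln.n_cells)
    # reconstruct via the orthogonality identity: total variance preserved
    scores = scale_and_pca(ln, ln.gene_ids, n_pcs=n_pcs, clip=10)
    x = ln.dense().T
    z = (x - x.mean(0)) / np.where(x.std(0) == 0, 1, x.std(0))
    z = np.clip(z, -10, 10)
    z = z - z.mean(0)
    assert np.isclose(scores.to_numpy().var(ddof=0) * scores.shape[1],
                      z.var(ddof=0) * z.shape[1], atol=1e-8)


def test_pca_too_many_components_errors(rng):
    ln = _lognorm_random(rng, n_genes=10, n_cells=8)
    with pytest.raises(ValueError, match="n_pcs"):
        scale_and_pca(ln, ln.gene_ids, n_pcs=20)


# ---------------------------------------------------------------------------
# Batch centering
# ---------------------------------------------------------------------------

def test_batch_center_single_batch_is_identity(rng):
    pcs = pd.DataFrame(rng.normal(size=(20, 3)),
                       index=[f"c{i}" for i in range(20)])
    batches = pd.Series("b0", index=pcs.index)
    out = batch_center(pcs, batches)
    pd.testing.assert_frame_equal(out, pcs)


def test_batch_center_removes_constant_offset(rng):
    base = rng.normal(size=(30, 4))
    pcs = np.vstack([base, base + np.array([5.0, -3.0, 2.0, 0.0])])
    idx = [f"c{i}" for i in range(60)]
    df = pd.DataFrame(pcs, index=idx)
    batches = pd.Series(["a"] * 30 + ["b"] * 30, index=idx)
    out = batch_center(df, batches)
    assert np.allclose(out.iloc[:30].to_numpy(), out.iloc[30:].to_numpy())


def test_batch_center_kills_planted_batch_separation(rng):
    from sklearn.metrics import silhouette_score
    base = rng.normal(size=(100, 5))
    offset = rng.normal(size=5) * 4
    pcs = np.vstack([base[:50], base[50:] + offset])
    idx = [f"c{i}" for i in range(100)]
    df = pd.DataFrame(pcs, index=idx)
    batches = pd.Series(["a"] * 50 + ["b"] * 50, index=idx)
    before = silhouette_score(df, batches)
    after = silhouette_score(batch_center(df, batches), batches)
    assert before > 0.2
    assert abs(after) < 0.05


# ---------------------------------------------------------------------------
# Graph clustering
# ---------------------------------------------------------------------------

def _two_blobs(seed=77, n=150, sep=10.0):
    r = np.random.default_rng(seed)
    a = r.normal(size=(n, 5))
    b = r.normal(size=(n, 5))
    b[:, 0] += sep
    idx = [f"c{i}" for i in range(2 * n)]
    return pd.DataFrame(np.vstack([a, b]), index=idx)


def test_cluster_graph_two_separated_blobs():
    pcs = _two_blobs()
    assign = cluster_graph(pcs, k_neighbors=15, resolution=0.7, seed=0)
    assert assign.n_clusters == 2
    first, second = assign.labels.iloc[:150], assign.labels.iloc[150:]
    assert first.nunique() == 1 and second.nunique() == 1


def test_cluster_graph_tiny_resolution_single_cluster():
    pcs = _two_blobs(sep=3.0)
    assign = cluster_graph(pcs, k_neighbors=15, resolution=1e-4, seed=0)
    assert assign.n_clusters == 1


def test_cluster_graph_permutation_invariant_partition():
    from sklearn.metrics import adjusted_rand_score
    pcs = _two_blobs()
    perm = np.random.default_rng(78).permutation(len(pcs))
    a = cluster_graph(pcs, k_neighbors=15, resolution=0.7, seed=0)
    b = cluster_graph(pcs.iloc[perm], k_neighbors=15, resolution=0.7, seed=0)
    joined = pd.concat([a.labels.rename("a"), b.labels.rename("b")], axis=1)
    assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0


def test_cluster_graph_seed_deterministic():
    pcs = _two_blobs(sep=2.0)
    a = cluster_graph(pcs, resolution=0.7, seed=3)
    b = cluster_graph(pcs, resolution=0.7, seed=3)
    assert (a.labels == b.labels).all()


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

def test_rank_sum_pvalue_matches_reference_formula(rng):
    """Dual route: scipy-backed p vs a hand-rolled tie-corrected normal
    approximation with continuity correction, 100 random instances."""
    for _ in range(100):
        n1, n2 = rng.integers(8, 30), rng.integers(8, 30)
        pool = rng.integers(0, 6, n1 + n2).astype(float)  # heavy ties
        x, y = pool[:n1], pool[n1:]
        p = rank_sum_pvalue(x, y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        n = n1 + n2
        _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        var_u = n1 * n2 / 12 * ((n + 1) - tie_term)
        mu_u = n1 * n2 / 2
        z = (u - mu_u - np.sign(u - mu_u) * 0.5) / np.sqrt(var_u)
        expected = 2 * stats.norm.sf(abs(z))
        assert p == pytest.approx(min(expected, 1.0), abs=1e-8)


def test_find_markers_null_p_values_uniform(rng):
    counts = rng.poisson(5.0, size=(1000, 120))
    labels = pd.Series(["A"] * 60 + ["B"] * 60,
                       index=[f"c{i:04d}" for i in range(120)])
    ln = normalize_lognorm(make_cell_matrix(counts))
    table = find_markers(ln, labels, logfc_threshold=0.0, min_pct=0.0,
                         mode="two-group")
    frac = (table["p_value"] < 0.05).mean()
    lo, hi = stats.binom.ppf([0.001, 0.999], len(table), 0.05) / len(table)
    assert lo <= frac <= hi


def test_find_markers_exclusive_gene_tops_table(rng):
    counts = rng.poisson(2.0, size=(50, 80))
    counts[0, :40] = 30
    counts[0, 40:] = 0                   # exclusive to cluster A
    labels = pd.Series(["A"] * 40 + ["B"] * 40,
                       index=[f"c{i:04d}" for i in range(80)])
    ln = normalize_lognorm(make_cell_matrix(counts))
    table = find_markers(ln, labels, mode="one-vs-rest")
    a = table[table["cluster"] == "A"]
    assert a.loc[a["p_value"].idxmin(), "gene"] == "g0000"
    assert a.loc[a["gene"] == "g0000", "pct_out"].iloc[0] == 0.0


def test_bh_step_up_hand_case():
    adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_find_markers_empty_side_errors(rng):
    counts = rng.poisson(2.0, size=(20, 10))
    ln = normalize_lognorm(make_cell_matrix(counts + 1))
    labels = pd.Series(["A"] * 10, index=ln.cell_ids)
    with pytest.raises(ValueError):
        find_markers(ln, labels, mode="one-vs-rest")


# ---------------------------------------------------------------------------
# Annotation and composition
# ---------------------------------------------------------------------------

def test_annotate_marker_overexpression_wins():
    means = pd.DataFrame(
        {0: [5.0, 5.0, 0.1, 0.1], 1: [0.1, 0.1, 5.0, 0.2]},
        index=["TTN", "MYH6", "VWF", "DCN"])
    ref = GeneSetCollection({"cardiomyocyte": ["TTN", "MYH6"],
                             "endothelial": ["VWF"]})
    out = annotate_clusters(means, ref)
    assert out.loc[0, "cell_type"] == "cardiomyocyte"
    assert out.loc[1, "cell_type"] == "endothelial"
    assert (out["margin"] > 0).all()


def test_annotate_identical_marker_sets_tie_break_warns():
    means = pd.DataFrame({0: [5.0, 0.1], 1: [0.1, 5.0]}, index=["A", "B"])
    ref = GeneSetCollection({"t1": ["A", "B"], "t2": ["A", "B"]})
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        out = annotate_clusters(means, ref)
    assert (out["cell_type"] == "t1").all()      # declared order
    assert any("tie" in str(w.message) for w in rec)


def test_annotate_all_markers_absent_errors():
    means = pd.DataFrame({0: [1.0], 1: [2.0]}, index=["A"])
    ref = GeneSetCollection({"t1": ["missing1", "missing2"]})
    with pytest.raises(ValueError, match="absent"):
        annotate_clusters(means, ref)


def test_annotation_recovers_planted_types(small_truth, small_cells):
    cells, _ = small_cells
    ln = normalize_lognorm(qc_filter(cells, min_genes=1))
    labels = ln.cell_meta["true_cell_type"]
    means = cluster_means(ln, labels)
    ref = GeneSetCollection(small_truth.marker_sets)
    out = annotate_clusters(means, ref)
    assert all(out.loc[t, "cell_type"] == t for t in out.index)


def test_composition_proportions_sum_to_one():
    meta = pd.DataFrame({
        "group": ["Normal"] * 4 + ["DCM"] * 6,
        "cell_type": ["a", "a", "b", "c", "a", "b", "b", "b", "c", "c"],
    })
    table = composition(meta)
    sums = table.groupby("group")["proportion"].sum()
    assert np.allclose(sums, 1.0)
    one = composition(pd.DataFrame({"group": ["DCM"], "cell_type": ["a"]}))
    assert one["proportion"].iloc[0] == 1.0
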