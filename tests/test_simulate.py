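"""Synthetic-data generators: determinism, planted structure, calibration."""

import json

import numpy as np
import pytest
from scipy import stats

from dcmregnet import (simulate_bulk, simulate_motif_table,
                       simulate_single_cell, simulate_truth)
from dcmregnet.scqc import normalize_lognorm, qc_filter


def test_truth_is_seed_deterministic(tmp_path):
    a = simulate_truth(n_celltypes=4, n_genes=300, n_tfs=6, targets_per_tf=10,
                       n_responsive=2, markers_per_type=8, seed=5)
    b = simulate_truth(n_celltypes=4, n_genes=300, n_tfs=6, targets_per_tf=10,
                       n_responsive=2, markers_per_type=8, seed=5)
    a.to_json(tmp_path / "a.json")
    b.to_json(tmp_path / "b.json")
    assert (tmp_path / "a.json").read_text() == (tmp_path / "b.json").read_text()


def test_truth_no_responsive_gives_empty_set():
    t = simulate_truth(n_celltypes=4, n_genes=300, n_tfs=6, targets_per_tf=10,
                       n_responsive=0, markers_per_type=8, seed=1)
    assert t.responsive == []
    assert t.group_effects == {}


def test_truth_stores_reported_composition():
    t = simulate_truth(seed=0)
    assert t.group_composition["Normal"][0] == pytest.approx(0.592, abs=1e-9)
    assert t.group_composition["DCM"][0] == pytest.approx(0.363, abs=1e-9)


def test_truth_infeasible_target_draw_errors():
    with pytest.raises(ValueError, match="targets_per_tf"):
        simulate_truth(n_genes=50, n_tfs=10, targets_per_tf=45, seed=0)


def test_truth_regulons_are_activating_and_tf_free():
    t = simulate_truth(n_celltypes=4, n_genes=400, n_tfs=8, targets_per_tf=12,
                       markers_per_type=8, seed=2)
    for reg in t.regulons:
        assert reg.tf not in reg.targets
        assert all(w > 0 for w in reg.loadings.values())
        assert len(set(reg.targets)) == len(reg.targets)


def test_single_cell_counts_bit_identical(small_truth):
    a, _ = simulate_single_cell(small_truth, n_cells_per_group=60,
                                n_samples_per_group=2, seed=4)
    b, _ = simulate_single_cell(small_truth, n_cells_per_group=60,
                                n_samples_per_group=2, seed=4)
    assert (a.values != b.values).nnz == 0
    assert a.cell_ids == b.cell_ids


def test_single_cell_null_group_effect_balances_activity():
    t = simulate_truth(n_celltypes=4, n_genes=300, n_tfs=6, targets_per_tf=10,
                       n_responsive=2, group_effect=0.0, markers_per_type=8,
                       seed=3)
    cells, act = simulate_single_cell(t, n_cells_per_group=400, seed=5)
    grp = cells.cell_meta["group"]
    for name in t.responsive:
        d = act.loc[(grp == "DCM").values, name]
        n = act.loc[(grp == "Normal").values, name]
        se = np.sqrt(d.var() / len(d) + n.var() / len(n))
        assert abs(d.mean() - n.mean()) < 3 * se


def test_single_cell_group_effect_moves_pseudobulk():
    """A shifted regulon's targets gain positive pseudobulk log-FC in DCM."""
    t = simulate_truth(n_celltypes=4, n_genes=300, n_tfs=6, targets_per_tf=10,
                       n_responsive=1, group_effect=2.0, markers_per_type=8,
                       shared_fraction=0.0, seed=6)
    cells, _ = simulate_single_cell(t, n_cells_per_group=1000, seed=7)
    grp = (cells.cell_meta["group"] == "DCM").to_numpy()
    dense = cells.dense().astype(float)
    totals = dense.sum(axis=0)
    cpm = dense / totals * 1e4
    reg = next(r for r in t.regulons if r.name in t.responsive)
    idx = [t.gene_ids.index(g) for g in reg.targets]
    lfc = np.log2((cpm[np.ix_(idx, np.flatnonzero(grp))].mean(axis=1) + 1)
                  / (cpm[np.ix_(idx, np.flatnonzero(~grp))].mean(axis=1) + 1))
    assert lfc.mean() > 0
    assert (lfc > 0).mean() > 0.9


def test_lognorm_removes_planted_library_size(small_cells):
    cells, _ = small_cells
    ln = normalize_lognorm(qc_filter(cells, min_genes=1))
    totals = np.asarray(ln.values.sum(axis=0)).ravel()
    lib = ln.cell_meta["true_libsize"].to_numpy(dtype=float)
    raw_totals = np.asarray(cells.values.sum(axis=0)).ravel()
    r_raw = np.corrcoef(raw_totals, cells.cell_meta["true_libsize"])[0, 1]
    r_norm = np.corrcoef(totals, lib)[0, 1]
    assert r_raw > 0.9              # library size dominates raw totals
    assert abs(r_norm) < 0.3        # and is gone after normalization


def test_bulk_null_settings_identical_group_means():
    t = simulate_truth(n_celltypes=4, n_genes=200, n_tfs=4, targets_per_tf=8,
                       n_responsive=2, group_effect=0.0,
                       composition_normal=[0.25] * 4,
                       composition_dcm=[0.25] * 4,
                       markers_per_type=5, seed=8)
    bulk = simulate_bulk(t, n_per_group=(5, 5), noise_sd=0.0, seed=9)
    groups = bulk.groups()
    mn = bulk.values.loc[:, (groups == "Normal").to_numpy()].mean(axis=1)
    md = bulk.values.loc[:, (groups == "DCM").to_numpy()].mean(axis=1)
    assert np.allclose(mn, md)


def test_bulk_requested_cohort_shape():
    t = simulate_truth(n_celltypes=4, n_genes=200, n_tfs=4, targets_per_tf=8,
                       n_responsive=2, markers_per_type=5, seed=1)
    bulk = simulate_bulk(t, n_per_group=(16, 86), seed=2)
    assert bulk.values.shape[1] == 102
    assert (bulk.groups() == "Normal").sum() == 16
    assert (bulk.groups() == "DCM").sum() == 86


def test_bulk_responsive_targets_exceed_fold_change_threshold():
    """Default effect size clears the |log2FC| > 0.5 screening threshold."""
    t = simulate_truth(seed=3)
    bulk = simulate_bulk(t, n_per_group=(20, 20), noise_sd=0.0, seed=4)
    groups = bulk.groups()
    lfc = (bulk.values.loc[:, (groups == "DCM").to_numpy()].mean(axis=1)
           - bulk.values.loc[:, (groups == "Normal").to_numpy()].mean(axis=1))
    resp_targets = {g for r in t.regulons if r.name in t.responsive
                    for g in r.targets}
    assert (lfc.loc[sorted(resp_targets)].abs() > 0.5).mean() > 0.95


def test_motif_table_extreme_rates(small_truth):
    planted = {(r.tf, g) for r in small_truth.regulons for g in r.targets}
    perfect = simulate_motif_table(small_truth, 1.0, 0.0, seed=0)
    flagged = {(r.tf, r.target) for r in perfect.itertuples(index=False)
               if r.motif_supported}
    assert flagged == planted
    none = simulate_motif_table(small_truth, 0.0, 0.0, seed=0)
    assert not none["motif_supported"].any()


def test_motif_table_rates_within_binomial_bounds(small_truth):
    table = simulate_motif_table(small_truth, 0.9, 0.1, seed=11)
    planted = {(r.tf, g) for r in small_truth.regulons for g in r.targets}
    is_planted = np.array([(tf, tg) in planted for tf, tg in
                           zip(table["tf"], table["target"])])
    for mask, rate in ((is_planted, 0.9), (~is_planted, 0.1)):
        k = int(table.loc[mask, "motif_supported"].sum())
        n = int(mask.sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, rate)
        assert lo <= k <= hi


def test_motif_table_invalid_rate_errors(small_truth):
    with pytest.raises(ValueError, match="rates"):
        simulate_motif_table(small_truth, 1.5, 0.0, seed=0)


def test_truth_json_round_trip(tmp_path, small_truth):
    from dcmregnet.simulate import SyntheticTruth
    small_truth.to_json(tmp_path / "t.json")
    back = SyntheticTruth.from_json(tmp_path / "t.json")
    assert back.gene_ids == small_truth.gene_ids
    assert back.responsive == small_truth.responsive
    assert back.group_effects == small_truth.group_effects
    assert np.allclose(back.baseline_log, small_truth.baseline_log)
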