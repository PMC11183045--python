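"""Moderated-t differential expression, ssGSEA, and group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcmregnet import (BulkMatrix, GeneSetCollection, compare_scores,
                       de_moderated, estimate_variance_prior, ssgsea)
from dcmregnet.bulkval import _ssgsea_sample, _stars
from dcmregnet.scqc import bh_adjust


def _bulk(values: np.ndarray, n_normal: int, n_dcm: int, genes=None):
    genes = genes or [f"g{i:04d}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame({"group": ["Normal"] * n_normal + ["DCM"] * n_dcm},
                        index=samples)
    return BulkMatrix(values=pd.DataFrame(values, index=genes,
                                          columns=samples),
                      sample_meta=meta, log_scale=True)


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

def test_moderated_t_reduces_to_ordinary_t_as_prior_vanishes(rng):
    x = rng.normal(size=(200, 20))
    bulk = _bulk(x, 10, 10)
    table = de_moderated(bulk, d0=1e-8)
    ok = table["t_ordinary"].notna()
    assert np.allclose(table.loc[ok, "t_moderated"],
                       table.loc[ok, "t_ordinary"], atol=1e-4)


def test_moderated_t_null_fdr_control(rng):
    x = rng.normal(scale=0.5, size=(2000, 30))
    bulk = _bulk(x, 15, 15)
    table = de_moderated(bulk)
    frac = (table["fdr"] < 0.05).mean()
    # BH keeps the null discovery fraction at or below alpha + slack
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000)


def test_moderated_t_power_at_study_cohort_shape(rng):
    """Planted log2FC=1, sd=0.5, 16 vs 86 samples: power above 0.9."""
    n_genes = 1000
    x = rng.normal(scale=0.5, size=(n_genes, 102))
    de_genes = rng.choice(n_genes, 200, replace=False)
    x[np.ix_(de_genes, np.arange(16, 102))] += 1.0
    bulk = _bulk(x, 16, 86)
    table = de_moderated(bulk)
    power = table.iloc[de_genes]["passes_filter"].mean()
    assert power > 0.9


def test_moderated_t_zero_variance_gene_missing_p(rng):
    x = rng.normal(size=(50, 10))
    x[7] = 3.14
    bulk = _bulk(x, 5, 5)
    with pytest.warns(UserWarning, match="zero variance"):
        table = de_moderated(bulk)
    assert np.isnan(table.iloc[7]["p"])
    assert not table.iloc[7]["passes_filter"]


def test_variance_prior_recovers_known_hyperparameters(rng):
    """Method-of-moments on variances drawn from the scaled-F model."""
    d0_true, s0_true, df = 8.0, 0.25, 18
    s2 = s0_true * d0_true / rng.chisquare(d0_true, 5000) \
        * rng.chisquare(df, 5000) / df
    d0, s0 = estimate_variance_prior(s2, df)
    assert d0 == pytest.approx(d0_true, rel=0.25)
    assert s0 == pytest.approx(s0_true, rel=0.1)


def test_de_orientation_positive_means_higher_in_dcm(rng):
    x = rng.normal(size=(10, 12))
    x[0, 6:] += 2.0                     # higher in DCM samples
    table = de_moderated(_bulk(x, 6, 6))
    assert table.iloc[0]["log2FC"] > 0


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def test_ssgsea_identical_rankings_give_identical_scores(rng):
    base = rng.random(50)
    x = np.column_stack([base, 2 * base + 5])       # same ranking
    genes = [f"g{i:03d}" for i in range(50)]
    bulk = _bulk(x, 1, 1, genes=genes)
    sets = GeneSetCollection({"S": list(rng.choice(genes, 8, replace=False))})
    scores = ssgsea(bulk, sets, normalize=False)
    assert scores.iloc[0, 0] == pytest.approx(scores.iloc[0, 1], abs=1e-12)


def test_ssgsea_hand_computed_five_gene_example():
    """Set {g1} with g1 ranked top, alpha=0.25: running sum accumulates
    P_hit = 1 from position 1 and P_miss = i/4, so ES = 2.5."""
    expr = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    member = np.array([True, False, False, False, False])
    es = _ssgsea_sample(expr, member, alpha=0.25)
    assert es == pytest.approx(2.5, abs=1e-10)
    # set {g2}: weight ratio 1 from position 2; ES = 0 + 3*(1 - i/4) terms
    member2 = np.array([False, True, False, False, False])
    expected = (0 - 1 / 4) + (1 - 1 / 4) + (1 - 2 / 4) + (1 - 3 / 4) + 0
    assert _ssgsea_sample(expr, member2, 0.25) == pytest.approx(expected,
                                                               abs=1e-10)


def test_ssgsea_invariant_to_monotone_sample_transform(rng):
    x = rng.random((40, 3))
    genes = [f"g{i:03d}" for i in range(40)]
    sets = GeneSetCollection({"S": list(rng.choice(genes, 6, replace=False))})
    a = ssgsea(_bulk(x, 2, 1, genes=genes), sets, normalize=False)
    b = ssgsea(_bulk(np.exp(4 * x), 2, 1, genes=genes), sets,
               normalize=False)
    pd.testing.assert_frame_equal(a, b)


def test_ssgsea_set_covering_all_genes_errors(rng):
    genes = [f"g{i}" for i in range(10)]
    bulk = _bulk(rng.random((10, 4)), 2, 2, genes=genes)
    sets = GeneSetCollection({"ALL": genes})
    with pytest.raises(ValueError, match="every gene"):
        ssgsea(bulk, sets)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def test_compare_scores_identical_groups_near_one(rng):
    # DCM scores duplicate the Normal scores exactly: the rank-sum
    # statistic sits at its center and p is ~1
    half = rng.random((3, 10))
    scores = pd.DataFrame(np.hstack([half, half]), index=["a", "b", "c"],
                          columns=[f"s{i}" for i in range(20)])
    groups = pd.Series(["Normal"] * 10 + ["DCM"] * 10, index=scores.columns)
    out = compare_scores(scores, groups)
    assert (out["p"] > 0.9).all()
    const = pd.DataFrame(np.ones((1, 20)), index=["flat"],
                         columns=scores.columns)
    assert compare_scores(const, groups)["p"].iloc[0] == 1.0


def test_compare_scores_detects_two_sd_shift(rng):
    base = rng.normal(size=60)
    shifted = np.concatenate([base[:30], base[30:] + 2 * base.std()])
    scores = pd.DataFrame(shifted[None, :], index=["S"],
                          columns=[f"s{i}" for i in range(60)])
    groups = pd.Series(["Normal"] * 30 + ["DCM"] * 30, index=scores.columns)
    out = compare_scores(scores, groups)
    assert out.loc["S", "p"] < 0.001
    assert out.loc["S", "direction"] == "up"


def test_star_thresholds():
    assert _stars(0.049) == "*"
    assert _stars(0.009) == "**"
    assert _stars(0.0009) == "***"
    assert _stars(0.05) == "ns"


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def test_bh_matches_statsmodels_oracle(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(50):
        p = rng.random(rng.integers(5, 400))
        ours = bh_adjust(p)
        _, oracle, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, oracle, atol=1e-12)
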