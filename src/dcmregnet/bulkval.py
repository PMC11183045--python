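"""Bulk-cohort validation: moderated-t differential expression, ssGSEA
scoring of regulon target sets, and per-set group comparison.

Differential expression uses an empirical-Bayes moderated t-statistic:
gene-wise pooled variances are shrunk toward a prior (d0, s0^2) estimated
by the method of moments on the log sample variances, and the moderated t
gets d0 + d_g degrees of freedom.  ssGSEA follows the integral running-sum
form with exponent alpha on the expression ranks.  The DCM-vs-Normal
orientation is fixed: positive log2FC means higher in DCM.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import special, stats

from .io import BulkMatrix, GeneSetCollection
from .scqc import bh_adjust


# ---------------------------------------------------------------------------
# Moderated-t differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for gene variances.

    Matches the scaled-F model for sample variances: with
    ``e = log(s2) - digamma(df/2) + log(df/2)``, solve
    ``trigamma(d0/2) = var(e) - trigamma(df/2)`` and recover ``s0^2`` from
    the mean.  When the observed spread is no larger than the sampling
    spread, d0 is effectively infinite (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need at least 2 positive variances")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def de_moderated(bulk: BulkMatrix, log2fc_threshold: float = 0.5,
                 fdr_threshold: float = 0.05,
                 d0: float | None = None,
                 s0_sq: float | None = None) -> pd.DataFrame:
    """Per-gene moderated-t differential table, DCM vs Normal.

    The matrix must be on log2 scale.  ``d0``/``s0_sq`` override the
    estimated prior (useful to reproduce the ordinary-t limit at d0->0).
    Genes with zero variance in both groups get a missing p with a
    warning and are excluded from the BH correction.
    """
    if not bulk.log_scale:
        raise ValueError("differential testing requires a log2-scale matrix")
    groups = bulk.groups()
    mask_d = (groups == "DCM").to_numpy()
    mask_n = (groups == "Normal").to_numpy()
    n1, n2 = int(mask_n.sum()), int(mask_d.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    x = bulk.values.to_numpy(dtype=float)
    xn, xd = x[:, mask_n], x[:, mask_d]
    log2fc = xd.mean(axis=1) - xn.mean(axis=1)
    v1 = xn.var(axis=1, ddof=1)
    v2 = xd.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    zero_var = s2 == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} genes with zero variance in "
                      "both groups; p set to missing")
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_variance_prior(s2[~zero_var], df)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    se_ord = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / se
        t_ord = np.where(se_ord > 0, log2fc / se_ord, np.nan)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where(zero_var, np.nan, p)
    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    fdr[ok] = bh_adjust(p[ok])
    out = pd.DataFrame({
        "log2FC": log2fc,
        "mean_expr": x.mean(axis=1),
        "t_ordinary": t_ord,
        "t_moderated": t_mod,
        "p": p,
        "fdr": fdr,
    }, index=bulk.values.index)
    out["passes_filter"] = ((np.abs(out["log2FC"]) > log2fc_threshold)
                            & (out["fdr"] < fdr_threshold)).fillna(False)
    out.attrs["d0"] = float(d0)
    out.attrs["s0_sq"] = float(s0_sq)
    return out


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ssgsea_sample(expr: np.ndarray, member_mask: np.ndarray,
                   alpha: float) -> float:
    """Integral-form ssGSEA enrichment score for one sample.

    Genes are ranked by decreasing expression with average ranks for ties;
    the running sum accumulates rank-weight^alpha (normalized over the
    set) at member positions minus 1/(G - |S|) at non-member positions,
    and the ES is the sum of the running difference over all positions.
    """
    n = expr.size
    n_in = int(member_mask.sum())
    if n_in == n:
        raise ValueError("gene set covers every gene; out-set empty")
    # ascending average ranks; highest expression -> largest weight
    ranks = stats.rankdata(expr, method="average")
    order = np.lexsort((np.arange(n), -expr))       # walk decreasing expr
    w = np.abs(ranks[order]) ** alpha
    members = member_mask[order]
    w_in = np.where(members, w, 0.0)
    sum_in = w_in.sum()
    p_hit = np.cumsum(w_in) / sum_in
    p_miss = np.cumsum(~members) / (n - n_in)
    return float(np.sum(p_hit - p_miss))


def ssgsea(bulk: BulkMatrix, gene_sets: GeneSetCollection,
           alpha: float = 0.25, normalize: bool = True) -> pd.DataFrame:
    """Gene-set x sample ssGSEA score matrix.

    With ``normalize`` the whole matrix is divided by its (max - min)
    range.  Warns when a set's coverage in the matrix is below 50%.
    """
    genes = list(bulk.values.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    x = bulk.values.to_numpy(dtype=float)
    masks = {}
    for name in gene_sets:
        members = gene_sets[name]
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if len(idx) < 0.5 * len(members):
            warnings.warn(f"{name}: only {len(idx)}/{len(members)} members "
                          "present in the bulk matrix")
        if not idx:
            raise ValueError(f"{name}: no member present in the bulk matrix")
        mask = np.zeros(len(genes), dtype=bool)
        mask[idx] = True
        masks[name] = mask
    scores = np.zeros((len(masks), x.shape[1]))
    for j in range(x.shape[1]):
        col = x[:, j]
        for i, name in enumerate(masks):
            scores[i, j] = _ssgsea_sample(col, masks[name], alpha)
    out = pd.DataFrame(scores, index=list(masks), columns=bulk.sample_ids)
    if normalize:
        rng_ = scores.max() - scores.min()
        if rng_ > 0:
            out = out / rng_
    return out


# ---------------------------------------------------------------------------
# Per-set group comparison
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_scores(scores: pd.DataFrame, groups: pd.Series,
                   fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene set, BH across sets.

    Direction is the sign of the median difference (DCM - Normal).
    Returns a frame indexed by set with p, fdr, direction, stars and a
    ``significant`` flag at ``fdr_threshold``.
    """
    groups = groups.loc[scores.columns]
    mask_d = (groups == "DCM").to_numpy()
    mask_n = (groups == "Normal").to_numpy()
    if mask_d.sum() == 0 or mask_n.sum() == 0:
        raise ValueError("both groups must be present")
    rows = {}
    for name in scores.index:
        v = scores.loc[name].to_numpy(dtype=float)
        vd, vn = v[mask_d], v[mask_n]
        if np.ptp(v) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(vd, vn, alternative="two-sided",
                                         method="asymptotic").pvalue)
        diff = float(np.median(vd) - np.median(vn))
        rows[name] = {"p": p, "median_diff": diff,
                      "direction": "up" if diff > 0 else
                                   "down" if diff < 0 else "none"}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["stars"] = [_stars(p) for p in out["p"]]
    out["significant"] = out["fdr"] < fdr_threshold
    return out
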