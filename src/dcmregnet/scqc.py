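"""Single-cell QC, normalization, PCA, graph clustering and annotation.

The stage mirrors a standard droplet-RNA workflow: filter cells by
detected-gene count, library-size log-normalize, pick highly variable
genes from a polynomial mean-variance trend, z-score + PCA, align batches
by centroid matching in PC space, cluster a shared-nearest-neighbor graph
with seeded Leiden modularity optimization, test markers with Wilcoxon
rank-sum + Benjamini-Hochberg, and annotate clusters against reference
marker sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CellMatrix, GeneSetCollection

logger = logging.getLogger("dcmregnet")


class EmptySelectionError(ValueError):
    """A filter removed every cell (or every gene)."""


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels from seeded SNN-Leiden clustering."""

    labels: pd.Series            # cell_id -> int cluster, contiguous from 0
    resolution: float
    k_neighbors: int
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def detected_genes(cells: CellMatrix) -> np.ndarray:
    """Number of genes with nonzero counts per cell."""
    v = cells.values
    if sp.issparse(v):
        return np.asarray((v > 0).sum(axis=0)).ravel()
    return (np.asarray(v) > 0).sum(axis=0)


def qc_filter(cells: CellMatrix, min_genes: int = 200,
              max_genes: int = 5000) -> CellMatrix:
    """Keep cells with ``min_genes <= detected genes <= max_genes``.

    Boundary cells are retained: the removal rule is "< min or > max".
    """
    if cells.layer_tag != "counts":
        raise ValueError("qc_filter requires the counts layer")
    g = detected_genes(cells)
    keep = (g >= min_genes) & (g <= max_genes)
    if not keep.any():
        raise EmptySelectionError(
            f"all {cells.n_cells} cells removed "
            f"({int((g < min_genes).sum())} below {min_genes}, "
            f"{int((g > max_genes).sum())} above {max_genes})")
    idx = np.flatnonzero(keep)
    kept_ids = [cells.cell_ids[i] for i in idx]
    return cells.copy_with(values=cells.values[:, idx], cell_ids=kept_ids,
                           cell_meta=cells.cell_meta.iloc[idx])


def normalize_lognorm(cells: CellMatrix, scale: float = 10000.0) -> CellMatrix:
    """x -> ln(1 + scale * x / total_counts(cell))."""
    if cells.layer_tag != "counts":
        raise ValueError("normalize_lognorm requires the counts layer")
    v = sp.csc_matrix(cells.values, dtype=float)
    totals = np.asarray(v.sum(axis=0)).ravel()
    if np.any(totals == 0):
        raise EmptySelectionError("cell with zero total counts; run qc_filter first")
    v = v.multiply(scale / totals[None, :]).tocsr()
    v.data = np.log1p(v.data)
    return cells.copy_with(values=v, layer_tag="lognorm")


# ---------------------------------------------------------------------------
# Highly variable genes
# ---------------------------------------------------------------------------

def select_hvg(cells: CellMatrix, n_top: int = 2000) -> list[str]:
    """Top-n genes by standardized variance around a mean-variance trend.

    A degree-2 polynomial is fit to log10(variance) vs log10(mean) over
    genes with positive mean; the score is observed/trend variance.
    Ties break deterministically by gene id.
    """
    if n_top > cells.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {cells.n_genes} genes")
    x = cells.dense().astype(float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    score = np.zeros(cells.n_genes)
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 3:
        lm, lv = np.log10(mean[ok]), np.log10(var[ok])
        coef = np.polyfit(lm, lv, deg=2)
        trend = 10 ** np.polyval(coef, lm)
        score[ok] = var[ok] / trend
    order = sorted(range(cells.n_genes),
                   key=lambda i: (-score[i], cells.gene_ids[i]))
    return [cells.gene_ids[i] for i in order[:n_top]]


# ---------------------------------------------------------------------------
# Scaling, PCA, batch centering
# ---------------------------------------------------------------------------

def scale_and_pca(cells: CellMatrix, hvg: list[str], n_pcs: int = 30,
                  clip: float = 10.0) -> pd.DataFrame:
    """Per-gene z-score (clipped) on the HVG submatrix, then exact PCA.

    Components are ordered by decreasing explained variance with the sign
    fixed so the largest-magnitude loading is positive.  Returns a cells x
    PCs score frame.
    """
    if not hvg:
        raise ValueError("hvg list is empty")
    gene_pos = {g: i for i, g in enumerate(cells.gene_ids)}
    idx = [gene_pos[g] for g in hvg]
    x = cells.dense()[idx].astype(float).T          # cells x hvg
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = np.clip((x - mu) / sd, -clip, clip)
    max_pcs = min(z.shape)
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(cells, genes)={max_pcs}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(z)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(n_pcs):
        load = pca.components_[j]
        k = np.argmax(np.abs(load))
        if load[k] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(scores, index=cells.cell_ids,
                        columns=[f"PC{j + 1}" for j in range(n_pcs)])


def batch_center(pc_scores: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Subtract each batch's PC-space centroid, add back the global centroid.

    A linear stand-in for iterative batch integration: exactly removes a
    constant per-batch offset while preserving within-batch geometry.
    """
    batches = batches.loc[pc_scores.index]
    global_centroid = pc_scores.mean(axis=0)
    out = pc_scores.copy()
    for b, idx in pc_scores.groupby(batches).groups.items():
        if len(idx) == 1:
            warnings.warn(f"batch {b!r} has a single cell; centered on itself")
        centroid = pc_scores.loc[idx].mean(axis=0)
        out.loc[idx] = pc_scores.loc[idx] - centroid + global_centroid
    return out


# ---------------------------------------------------------------------------
# SNN graph + Leiden clustering
# ---------------------------------------------------------------------------

def snn_graph(pc_scores: np.ndarray, k_neighbors: int = 20):
    """Shared-nearest-neighbor graph: kNN (Euclidean) with Jaccard weights.

    Returns (edge array, weight array) over cell indices; edges with zero
    Jaccard overlap are dropped.
    """
    n = pc_scores.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pc_scores)
    _, ind = nn.kneighbors(pc_scores)                 # includes self
    neigh_sets = [set(row) for row in ind]
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in ind[i]:
            j = int(j)
            if j == i:
                continue
            key = (i, j) if i < j else (j, i)
            if key in seen:
                continue
            seen.add(key)
            inter = len(neigh_sets[i] & neigh_sets[j])
            union = len(neigh_sets[i] | neigh_sets[j])
            w = inter / union
            if w > 0:
                edges.append(key)
                weights.append(w)
    return edges, weights


def cluster_graph(pc_scores: pd.DataFrame, k_neighbors: int = 20,
                  resolution: float = 0.7, seed: int = 0) -> ClusterAssignment:
    """Seeded Leiden modularity clustering of the SNN graph.

    Cluster labels are contiguous integers from 0, ordered by decreasing
    cluster size (ties by smallest member index) so the labeling is
    deterministic for a fixed input and seed.
    """
    x = pc_scores.to_numpy()
    if x.shape[0] < k_neighbors + 1:
        raise ValueError(f"need at least {k_neighbors + 1} cells")
    edges, _weights = snn_graph(x, k_neighbors)
    g = ig.Graph(n=x.shape[0], edges=edges)
    # Jaccard weights prune spurious kNN edges (zero-overlap links are
    # dropped in snn_graph); modularity itself is maximized unweighted —
    # weighted modularity over-fragments homogeneous neighborhoods
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed))
    raw = np.asarray(part.membership)
    labels = _relabel_by_size(raw)
    return ClusterAssignment(
        labels=pd.Series(labels, index=pc_scores.index, name="cluster"),
        resolution=resolution, k_neighbors=k_neighbors, seed=seed)


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    order = sorted(set(raw), key=lambda c: (-(raw == c).sum(),
                                            int(np.flatnonzero(raw == c)[0])))
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw])


# ---------------------------------------------------------------------------
# Marker detection
# ---------------------------------------------------------------------------

def rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p (normal approximation, tie-corrected)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _log2fc(mean_in: np.ndarray, mean_out: np.ndarray) -> np.ndarray:
    # stable at zeros: ratio of (mean expm1 + 1)
    return np.log2((mean_in + 1.0) / (mean_out + 1.0))


def find_markers(cells: CellMatrix, labels: pd.Series,
                 logfc_threshold: float = 0.25, min_pct: float = 0.1,
                 mode: str = "one-vs-rest") -> pd.DataFrame:
    """Wilcoxon rank-sum marker table with BH correction per comparison.

    Genes enter the test only if |log2FC| >= ``logfc_threshold`` (log2FC of
    mean expm1 + 1 ratios) and detection fraction >= ``min_pct`` on at
    least one side.  ``mode='two-group'`` runs a single comparison of
    exactly two labels; ``'one-vs-rest'`` runs one per cluster.
    """
    if cells.layer_tag != "lognorm":
        raise ValueError("find_markers expects lognorm expression")
    labels = labels.loc[cells.cell_ids]
    uniq = sorted(labels.unique(), key=str)
    if mode == "two-group" and len(uniq) != 2:
        raise ValueError("two-group mode requires exactly 2 labels")
    if len(uniq) < 2:
        raise ValueError("need at least 2 labels")
    x = cells.dense().astype(float)                  # genes x cells
    expm1 = np.expm1(x)
    detected = x > 0

    comparisons = ([(uniq[0], uniq[1])] if mode == "two-group"
                   else [(c, None) for c in uniq])
    rows = []
    for cl, other in comparisons:
        in_mask = (labels == cl).to_numpy()
        out_mask = ((labels == other).to_numpy() if other is not None
                    else ~in_mask)
        if in_mask.sum() == 0 or out_mask.sum() == 0:
            raise ValueError(f"empty side in comparison for label {cl!r}")
        mean_in = expm1[:, in_mask].mean(axis=1)
        mean_out = expm1[:, out_mask].mean(axis=1)
        lfc = _log2fc(mean_in, mean_out)
        pct_in = detected[:, in_mask].mean(axis=1)
        pct_out = detected[:, out_mask].mean(axis=1)
        test = ((np.abs(lfc) >= logfc_threshold)
                & (np.maximum(pct_in, pct_out) >= min_pct))
        gidx = np.flatnonzero(test)
        pvals = np.array([rank_sum_pvalue(x[g, in_mask], x[g, out_mask])
                          for g in gidx])
        fdr = bh_adjust(pvals) if len(pvals) else pvals
        for g, p, q in zip(gidx, pvals, fdr):
            rows.append({"cluster": cl, "gene": cells.gene_ids[g],
                         "log2FC": lfc[g], "pct_in": pct_in[g],
                         "pct_out": pct_out[g], "p_value": p, "fdr": q})
    return pd.DataFrame(rows, columns=["cluster", "gene", "log2FC", "pct_in",
                                       "pct_out", "p_value", "fdr"])


# ---------------------------------------------------------------------------
# Annotation and composition
# ---------------------------------------------------------------------------

def cluster_means(cells: CellMatrix, labels: pd.Series) -> pd.DataFrame:
    """Mean expression per cluster (genes x clusters)."""
    labels = labels.loc[cells.cell_ids]
    x = cells.dense().astype(float)
    cols = {}
    for cl in sorted(labels.unique(), key=str):
        cols[cl] = x[:, (labels == cl).to_numpy()].mean(axis=1)
    return pd.DataFrame(cols, index=cells.gene_ids)


def annotate_clusters(marker_means: pd.DataFrame,
                      reference_markers: GeneSetCollection) -> pd.DataFrame:
    """Assign each cluster the reference type with highest mean marker z.

    Genes are z-scored across clusters; a cluster's score for a type is
    the mean z of the type's markers present in the matrix.  Ties break by
    the declared type order.  Returns a frame indexed by cluster with
    ``cell_type``, ``score`` and ``margin`` (best minus runner-up).
    """
    mu = marker_means.mean(axis=1)
    sd = marker_means.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = marker_means.sub(mu, axis=0).div(sd, axis=0)
    type_order = reference_markers.names()
    scores = {}
    for tname in type_order:
        markers = reference_markers[tname]
        present = [m for m in markers if m in z.index]
        absent = set(markers) - set(present)
        if absent:
            warnings.warn(f"{tname}: {len(absent)} marker genes absent, dropped")
        if not present:
            raise ValueError(f"all markers of type {tname!r} absent from matrix")
        scores[tname] = z.loc[present].mean(axis=0)
    score_df = pd.DataFrame(scores)[type_order]
    rows = []
    for cl in score_df.index:
        s = score_df.loc[cl]
        ranked = sorted(type_order, key=lambda t: (-s[t], type_order.index(t)))
        best, second = ranked[0], ranked[1] if len(ranked) > 1 else ranked[0]
        if len(ranked) > 1 and s[best] == s[second]:
            warnings.warn(f"cluster {cl}: tie between {best} and {second}; "
                          "declared order breaks the tie")
        rows.append({"cluster": cl, "cell_type": best,
                     "score": s[best], "margin": s[best] - s[second]})
    return pd.DataFrame(rows).set_index("cluster")


def composition(cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Counts and within-group proportions of cell types per group."""
    if cell_meta["cell_type"].isna().any():
        raise ValueError("every cell needs a cell_type")
    counts = (cell_meta.groupby(["group", "cell_type"], observed=True)
              .size().rename("count").reset_index())
    counts["proportion"] = counts.groupby("group")["count"].transform(
        lambda c: c / c.sum())
    return counts
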