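"""Metacell construction: group-pure over-clustering and aggregation.

Cells are over-clustered at a high resolution separately within each group
(Normal / DCM) so every micro-cluster is group-pure, then each retained
micro-cluster is collapsed into one metacell by summing raw counts and
log-normalizing the sum.  Metacells with too few member cells are
discarded — the denoising step applied before network inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellMatrix
from .scqc import cluster_graph

logger = logging.getLogger("dcmregnet")


@dataclass
class MetacellMatrix:
    """Genes x metacells profiles with per-metacell provenance.

    ``counts`` holds the summed raw counts, ``values`` the log-normalized
    profiles.  ``meta`` is indexed by metacell id with columns ``group``,
    ``dominant_cell_type``, ``n_cells`` and ``member_cells``.
    """

    counts: np.ndarray
    values: np.ndarray
    gene_ids: list[str]
    metacell_ids: list[str]
    meta: pd.DataFrame

    @property
    def n_metacells(self) -> int:
        return len(self.metacell_ids)

    def lognorm_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.metacell_ids)


def overcluster(pc_scores: pd.DataFrame, groups: pd.Series,
                resolution: float = 50.0, k_neighbors: int = 20,
                seed: int = 0) -> pd.Series:
    """High-resolution clustering within each group; labels namespaced.

    Returns a cell -> label Series with labels like ``"Normal:12"`` so no
    micro-cluster can span groups.
    """
    groups = groups.loc[pc_scores.index]
    labels = pd.Series(index=pc_scores.index, dtype=object, name="microcluster")
    for gi, g in enumerate(sorted(groups.unique())):
        idx = groups.index[groups == g]
        if len(idx) < k_neighbors + 1:
            raise ValueError(f"group {g!r} has only {len(idx)} cells "
                             f"(< k_neighbors+1 = {k_neighbors + 1})")
        assign = cluster_graph(pc_scores.loc[idx], k_neighbors=k_neighbors,
                               resolution=resolution, seed=seed + gi)
        labels.loc[idx] = [f"{g}:{c}" for c in assign.labels]
    return labels


def aggregate_metacells(cells: CellMatrix, micro_labels: pd.Series,
                        min_cells: int = 10, strict: bool = True,
                        scale: float = 10000.0,
                        aggregate: str = "sum") -> MetacellMatrix:
    """Collapse micro-clusters into metacells.

    ``aggregate='sum'`` sums member raw counts and log-normalizes the sum
    (the default; preserves count sufficiency); ``'mean-lognorm'`` averages
    member log-normalized profiles instead.  Metacells with
    ``n_cells <= min_cells`` (strict) or ``< min_cells`` are discarded.
    """
    if cells.layer_tag != "counts":
        raise ValueError("aggregate_metacells requires the counts layer")
    micro_labels = micro_labels.loc[cells.cell_ids]
    counts = sp.csc_matrix(cells.values, dtype=float)
    meta_rows, profiles = [], []
    kept, discarded = 0, 0
    for label in sorted(micro_labels.unique()):
        members = np.flatnonzero((micro_labels == label).to_numpy())
        n = len(members)
        keep = n > min_cells if strict else n >= min_cells
        if not keep:
            discarded += 1
            continue
        kept += 1
        member_ids = [cells.cell_ids[i] for i in members]
        sub_meta = cells.cell_meta.iloc[members]
        group_vals = sub_meta["group"].unique()
        if len(group_vals) != 1:
            raise ValueError(f"micro-cluster {label!r} spans groups {group_vals}")
        if aggregate == "sum":
            prof = np.asarray(counts[:, members].sum(axis=1)).ravel()
        elif aggregate == "mean-lognorm":
            sub = counts[:, members].toarray()
            totals = sub.sum(axis=0)
            prof = np.log1p(scale * sub / totals).mean(axis=1)
        else:
            raise ValueError(f"unknown aggregate mode {aggregate!r}")
        type_col = ("cell_type" if "cell_type" in sub_meta.columns
                    else "true_cell_type" if "true_cell_type" in sub_meta.columns
                    else None)
        dominant = (sub_meta[type_col].mode().iloc[0]
                    if type_col is not None else "unknown")
        meta_rows.append({"metacell_id": f"mc_{label}",
                          "group": group_vals[0],
                          "dominant_cell_type": dominant,
                          "n_cells": n,
                          "member_cells": ",".join(member_ids)})
        profiles.append(prof)
    if not meta_rows:
        raise ValueError(
            f"all {discarded} metacells discarded at min_cells={min_cells}")
    logger.info("aggregated %d metacells (%d discarded)", kept, discarded)
    raw = np.column_stack(profiles)
    if aggregate == "sum":
        totals = raw.sum(axis=0)
        values = np.log1p(scale * raw / totals)
    else:
        values = raw
    meta = pd.DataFrame(meta_rows).set_index("metacell_id")
    return MetacellMatrix(counts=raw if aggregate == "sum" else raw,
                          values=values, gene_ids=list(cells.gene_ids),
                          metacell_ids=list(meta.index), meta=meta)
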