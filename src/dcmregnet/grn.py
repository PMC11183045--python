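"""Regulon inference: TF->target importances and motif-supported assembly.

Importances come from a deterministic ridge regression of every target
gene on all candidate TFs (standardized variables), replacing stochastic
gradient-boosting co-expression inference with an estimator that has the
same interface and is exactly reproducible.  Assembly keeps each TF's
top-ranked edges, prunes those without motif support (the stand-in for
motif-ranking enrichment), and drops TFs left with too few targets.
Only activating "(+)" regulons are modeled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .metacell import MetacellMatrix

logger = logging.getLogger("dcmregnet")


class RegulonAssemblyError(ValueError):
    """No regulon survived assembly; message carries per-TF attrition."""


@dataclass
class Regulon:
    """A TF with its inferred activating target set."""

    tf: str
    targets: list[str]                       # ordered by decreasing importance
    importances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError(f"{self.tf} cannot target itself")
        if any(v <= 0 for v in self.importances.values()):
            raise ValueError("importances must be positive")

    @property
    def name(self) -> str:
        return self.tf + "(+)"

    @property
    def size(self) -> int:
        return len(self.targets)


def infer_importance(metacells: MetacellMatrix | pd.DataFrame,
                     tf_list: list[str], ridge_lambda: float = 1.0,
                     importance_floor: float = 0.01) -> pd.DataFrame:
    """Ridge-regression TF importances for every non-TF gene.

    Expression (genes x units, log-normalized) is standardized per gene;
    for each target the importance of a TF is the magnitude of its ridge
    coefficient.  Importances below ``importance_floor`` are zeroed and
    omitted.  Returns a tidy frame with columns ``tf, target, importance``.
    """
    expr = (metacells.lognorm_frame()
            if isinstance(metacells, MetacellMatrix) else metacells)
    genes = list(expr.index)
    missing = [t for t in tf_list if t not in set(genes)]
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {missing[:5]}")
    n_units = expr.shape[1]
    if n_units < 30:
        warnings.warn(f"only {n_units} units; importance estimates will be noisy")

    x = expr.to_numpy().T                      # units x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    z = (x - mu) / sd_safe
    gene_pos = {g: i for i, g in enumerate(genes)}
    tf_idx = np.array([gene_pos[t] for t in tf_list])
    zt = z[:, tf_idx]                          # units x TFs
    zt[:, constant[tf_idx]] = 0.0
    if constant.any():
        n_const = int(constant.sum())
        warnings.warn(f"{n_const} constant genes; importances set to 0")

    a = zt.T @ zt + ridge_lambda * np.eye(len(tf_list))
    coefs = np.linalg.solve(a, zt.T @ z)       # TFs x genes
    imp = np.abs(coefs)
    imp[:, constant] = 0.0

    records = []
    for ti, tf in enumerate(tf_list):
        row = imp[ti]
        keep = np.flatnonzero(row >= importance_floor)
        for gi in keep:
            g = genes[gi]
            if g == tf:
                continue
            records.append((tf, g, float(row[gi])))
    out = pd.DataFrame(records, columns=["tf", "target", "importance"])
    return out.sort_values(["tf", "importance", "target"],
                           ascending=[True, False, True],
                           kind="mergesort").reset_index(drop=True)


def assemble_regulons(edges: pd.DataFrame, motif_table: pd.DataFrame,
                      top_n_per_tf: int = 50,
                      min_regulon_size: int = 10) -> list[Regulon]:
    """Truncate per-TF edge lists, prune unsupported edges, drop small TFs.

    ``motif_table`` is a regulon-edge table whose ``motif_supported``
    column flags (tf, target) pairs; pairs absent from the table count as
    unsupported.  Raises :class:`RegulonAssemblyError` with a per-TF
    attrition summary if nothing survives.
    """
    support = {(r.tf, r.target): bool(r.motif_supported)
               for r in motif_table.itertuples(index=False)}
    regulons: list[Regulon] = []
    attrition = []
    for tf, sub in edges.groupby("tf", sort=True):
        ranked = sub.sort_values(["importance", "target"],
                                 ascending=[False, True], kind="mergesort")
        top = ranked.head(top_n_per_tf)
        kept = top[[support.get((tf, t), False) for t in top["target"]]]
        attrition.append(f"{tf}: {len(sub)} edges -> top {len(top)} "
                         f"-> {len(kept)} supported")
        if len(kept) < min_regulon_size:
            continue
        regulons.append(Regulon(
            tf=tf, targets=list(kept["target"]),
            importances=dict(zip(kept["target"], kept["importance"]))))
    if not regulons:
        raise RegulonAssemblyError(
            "no regulon met min_regulon_size; attrition per TF:\n  "
            + "\n  ".join(attrition))
    logger.info("assembled %d regulons", len(regulons))
    return regulons


def regulons_to_genesets(regulons: list[Regulon],
                         include_tf: bool = False) -> GeneSetCollection:
    """One gene set per regulon (TF excluded by default)."""
    coll = GeneSetCollection()
    for reg in regulons:
        members = ([reg.tf] + reg.targets) if include_tf else reg.targets
        coll.add(reg.name, members, f"targets of {reg.tf}")
    return coll
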