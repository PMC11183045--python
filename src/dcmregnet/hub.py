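"""Hub-target discovery: cross-cohort regulon intersection, multi-regulon
target counting, DEG intersection, ROC diagnostics and over-representation.

The logic mirrors the validation cascade: regulons significant in every
bulk cohort (with a consistent direction) are intersected, their targets
counted, targets appearing in at least two shared regulons kept, and
those in turn intersected with each cohort's differentially expressed
genes; survivors in every cohort are the hub targets.  Diagnostic value
is scored by ROC AUC with a stratified bootstrap percentile CI.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .grn import Regulon
from .scqc import bh_adjust


@dataclass
class RocResult:
    """AUC with a stratified-bootstrap percentile confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


@dataclass
class HubTargetReport:
    """Full provenance of the hub-target cascade."""

    shared_regulons: pd.DataFrame        # regulon x (per-dataset direction, consistent)
    consistent_regulons: list[str]
    target_counts: dict[str, int]
    multi_targets: list[str]
    differential_targets: dict[str, list[str]]   # per dataset
    hub_targets: list[str]
    hub_provenance: dict[str, list[str]]         # hub -> shared regulons containing it
    roc: dict[str, dict[str, RocResult]] = field(default_factory=dict)


def intersect_regulons(diff_sets: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Intersect per-dataset {regulon -> direction} maps.

    Returns a frame indexed by the shared regulon names with one direction
    column per dataset and a ``consistent`` flag (identical direction in
    every dataset).
    """
    if len(diff_sets) < 2:
        raise ValueError("need at least 2 datasets to intersect")
    names = None
    for d in diff_sets.values():
        names = set(d) if names is None else names & set(d)
    rows = {}
    for reg in sorted(names):
        dirs = {ds: diff_sets[ds][reg] for ds in diff_sets}
        rows[reg] = {**dirs, "consistent": len(set(dirs.values())) == 1}
    cols = [*diff_sets, "consistent"]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  dtype=object)[cols] if rows else \
        pd.DataFrame(columns=cols)


def count_multi_targets(regulons: list[Regulon] | dict[str, list[str]],
                        min_occurrence: int = 2):
    """Occurrence counts of targets across regulons; multi-target subset.

    Returns ``(counts, multi_targets, membership)`` where ``membership``
    is a target x regulon boolean co-membership frame (the upset-style
    summary).
    """
    if isinstance(regulons, dict):
        sets = {name: set(t) for name, t in regulons.items()}
    else:
        sets = {r.name: set(r.targets) for r in regulons}
    if len(sets) < 2:
        raise ValueError("need at least 2 regulons")
    counts = Counter()
    for members in sets.values():
        counts.update(members)
    counts = dict(counts)
    multi = sorted(t for t, c in counts.items() if c >= min_occurrence)
    membership = pd.DataFrame(
        {name: [t in sets[name] for t in sorted(counts)] for name in sets},
        index=sorted(counts))
    return counts, multi, membership


def hub_targets(multi_targets: list[str],
                deg_tables: dict[str, pd.DataFrame],
                regulon_sets: dict[str, list[str]] | None = None):
    """Intersect multi-regulon targets with every cohort's DEGs.

    ``deg_tables`` map dataset -> differential table carrying a
    ``passes_filter`` column indexed by gene.  Returns
    ``(per_dataset_differential_targets, final_hubs, provenance)`` where
    provenance lists, per hub, the shared regulons containing it (when
    ``regulon_sets`` is given).
    """
    per_dataset: dict[str, list[str]] = {}
    final = set(multi_targets)
    for ds, table in deg_tables.items():
        degs = set(table.index[table["passes_filter"]])
        hits = sorted(set(multi_targets) & degs)
        per_dataset[ds] = hits
        final &= set(hits)
    provenance = {}
    if regulon_sets is not None:
        for t in sorted(final):
            provenance[t] = sorted(name for name, members in
                                   regulon_sets.items() if t in members)
    return per_dataset, sorted(final), provenance


# ---------------------------------------------------------------------------
# ROC diagnostics
# ---------------------------------------------------------------------------

def roc_auc(values: np.ndarray, labels: np.ndarray,
            positive: str | int = 1) -> float:
    """ROC AUC with the convention that higher values predict ``positive``.

    Equivalent to the normalized Mann-Whitney U with half-credit for ties.
    """
    labels = np.asarray(labels)
    y = (labels == positive).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(values, dtype=float)))


def roc_bootstrap_ci(values: np.ndarray, labels: np.ndarray,
                     positive: str | int = 1, n_boot: int = 2000,
                     seed: int = 0) -> RocResult:
    """Stratified bootstrap percentile 95% CI for the ROC AUC."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    point = roc_auc(values, labels, positive=positive)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == positive)
    neg_idx = np.flatnonzero(labels != positive)
    n_pos, n_neg = len(pos_idx), len(neg_idx)
    vp = values[rng.choice(pos_idx, size=(n_boot, n_pos), replace=True)]
    vn = values[rng.choice(neg_idx, size=(n_boot, n_neg), replace=True)]
    # Mann-Whitney identity on average ranks (half credit for ties)
    ranks = stats.rankdata(np.concatenate([vp, vn], axis=1),
                           method="average", axis=1)
    u = ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    aucs = u / (n_pos * n_neg)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return RocResult(auc=point, ci_low=float(lo), ci_high=float(hi),
                     n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora(hits: set[str] | list[str], universe: set[str] | list[str],
        gene_sets) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set + BH.

    ``gene_sets`` is a GeneSetCollection or mapping name -> members; sets
    are intersected with the universe.  Returns a frame with overlap
    sizes, fold enrichment, p and fdr.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    m = len(universe)
    n_hits = len(hits)
    names = list(gene_sets) if not isinstance(gene_sets, dict) else list(gene_sets)
    rows = {}
    for name in names:
        members = set(gene_sets[name]) & universe
        k = len(hits & members)
        expected = n_hits * len(members) / m if m else 0.0
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_hits)) \
            if members else 1.0
        rows[name] = {"set_size": len(members), "overlap": k,
                      "fold_enrichment": (k / expected) if expected else np.nan,
                      "p": p}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
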