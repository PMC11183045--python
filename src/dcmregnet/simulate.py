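"""Synthetic single-cell and bulk myocardium with planted regulatory truth.

The generator emulates the structure the downstream analysis assumes: a
UMI-count matrix over ~8 myocardial cell types in two groups (Normal vs
DCM) across several samples, a set of planted activating TF->target
regulons whose latent activity shifts in the DCM group, a composition
shift between groups (cardiomyocyte fraction dropping as in diseased
myocardium), and bulk matrices formed as noisy log2 pseudobulk mixtures
that inherit the planted group effects.

Generative model per cell
-------------------------
1. Draw the cell type from its group's composition vector.
2. For every regulon r draw a latent activity
   ``a_r = celltype_offset[r, type] + group_shift * 1[DCM & responsive] + N(0, 1)``.
3. The log mean of each gene is the cell type's baseline log expression
   plus ``loading[r, g] * a_r`` summed over regulons targeting g (the TF
   gene itself carries a self-loading so its expression tracks its
   regulon's activity), plus a small per-batch offset.
4. Counts are Gamma-Poisson (negative binomial) with gene-level
   dispersion, with the mean vector scaled to a log-normal library size.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (BulkMatrix, CellMatrix, GeneSetCollection,
                 _validate_regulon_table)

# Composition vectors follow the reported myocardial proportions:
# cardiomyocytes 59.2% -> 36.3%, endothelial 20.7% -> 30.1%,
# fibroblasts 7.3% -> 10.9%; the remainder is spread over the minor types.
DEFAULT_CELLTYPES = (
    "cardiomyocyte", "endothelial", "fibroblast", "pericyte",
    "smooth_muscle", "macrophage", "t_cell", "epithelial",
)
DEFAULT_COMPOSITION_NORMAL = (0.592, 0.207, 0.073, 0.047,
                              0.025, 0.024, 0.018, 0.014)
DEFAULT_COMPOSITION_DCM = (0.363, 0.301, 0.109, 0.060,
                           0.058, 0.049, 0.034, 0.026)


@dataclass
class PlantedRegulon:
    """One planted activating regulon: a TF, its targets and loadings."""

    tf: str
    targets: list[str]
    loadings: dict[str, float]          # target gene -> positive loading
    tf_loading: float                   # loading of the TF's own gene

    @property
    def name(self) -> str:
        return self.tf + "(+)"


@dataclass
class SyntheticTruth:
    """Planted ground truth shared by the single-cell and bulk generators."""

    gene_ids: list[str]
    cell_types: list[str]
    baseline_log: np.ndarray            # types x genes, natural-log means
    group_composition: dict[str, np.ndarray]
    regulons: list[PlantedRegulon]
    responsive: list[str]               # regulon names with a group shift
    group_effect: float                 # activity-SD shift scale in DCM
    group_effects: dict[str, float]     # per-responsive-regulon realized shift
    celltype_effect: np.ndarray         # regulons x types activity offsets
    dispersion: np.ndarray              # per-gene NB dispersion (phi > 0)
    libsize_log_mu: float
    libsize_log_sigma: float
    batch_sd: float
    marker_sets: dict[str, list[str]]   # per-type marker genes
    seed: int

    def __post_init__(self) -> None:
        for g, comp in self.group_composition.items():
            comp = np.asarray(comp, dtype=float)
            if comp.min() < 0 or abs(comp.sum() - 1.0) > 1e-8:
                raise ValueError(f"composition for {g} is not a simplex")
            self.group_composition[g] = comp
        names = {r.name for r in self.regulons}
        if not set(self.responsive) <= names:
            raise ValueError("responsive_set must be a subset of regulons")
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersions must be positive")

    @property
    def tf_ids(self) -> list[str]:
        return [r.tf for r in self.regulons]

    def regulon_genesets(self) -> GeneSetCollection:
        coll = GeneSetCollection()
        for r in self.regulons:
            coll.add(r.name, r.targets, f"planted regulon of {r.tf}")
        return coll

    def loading_matrix(self) -> sp.csr_matrix:
        """Regulons x genes sparse loading matrix (incl. TF self-loading)."""
        gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        rows, cols, vals = [], [], []
        for ri, reg in enumerate(self.regulons):
            for g, w in reg.loadings.items():
                rows.append(ri)
                cols.append(gene_index[g])
                vals.append(w)
            rows.append(ri)
            cols.append(gene_index[reg.tf])
            vals.append(reg.tf_loading)
        return sp.csr_matrix((vals, (rows, cols)),
                             shape=(len(self.regulons), len(self.gene_ids)))

    def to_json(self, path: str | Path) -> None:
        record = {
            "gene_ids": self.gene_ids,
            "cell_types": self.cell_types,
            "baseline_log": self.baseline_log.tolist(),
            "group_composition": {k: v.tolist()
                                  for k, v in self.group_composition.items()},
            "regulons": [{"tf": r.tf, "targets": r.targets,
                          "loadings": r.loadings, "tf_loading": r.tf_loading}
                         for r in self.regulons],
            "responsive": self.responsive,
            "group_effect": self.group_effect,
            "group_effects": self.group_effects,
            "celltype_effect": self.celltype_effect.tolist(),
            "dispersion": self.dispersion.tolist(),
            "libsize_log_mu": self.libsize_log_mu,
            "libsize_log_sigma": self.libsize_log_sigma,
            "batch_sd": self.batch_sd,
            "marker_sets": self.marker_sets,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(record) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        regs = [PlantedRegulon(tf=r["tf"], targets=r["targets"],
                               loadings=r["loadings"],
                               tf_loading=r["tf_loading"])
                for r in d["regulons"]]
        return cls(
            gene_ids=d["gene_ids"], cell_types=d["cell_types"],
            baseline_log=np.asarray(d["baseline_log"]),
            group_composition={k: np.asarray(v)
                               for k, v in d["group_composition"].items()},
            regulons=regs, responsive=d["responsive"],
            group_effect=d["group_effect"],
            group_effects=d["group_effects"],
            celltype_effect=np.asarray(d["celltype_effect"]),
            dispersion=np.asarray(d["dispersion"]),
            libsize_log_mu=d["libsize_log_mu"],
            libsize_log_sigma=d["libsize_log_sigma"],
            batch_sd=d["batch_sd"], marker_sets=d["marker_sets"],
            seed=d["seed"])


def simulate_truth(n_celltypes: int = 8, n_genes: int = 2000, n_tfs: int = 40,
                   targets_per_tf: int = 25, n_responsive: int = 5,
                   group_effect: float = 2.0,
                   composition_normal=None, composition_dcm=None,
                   celltype_effect_sd: float = 2.0,
                   markers_per_type: int = 20,
                   shared_pool_size: int = 40, shared_fraction: float = 0.4,
                   dispersion_mean: float = 0.3,
                   libsize_log_mu: float = np.log(5000.0),
                   libsize_log_sigma: float = 0.35,
                   batch_sd: float = 0.05,
                   seed: int = 0) -> SyntheticTruth:
    """Draw a reproducible planted truth.

    Responsive regulons draw ``shared_fraction`` of their targets from a
    small common pool so that some targets are shared by two or more
    responsive regulons — the synthetic analogue of co-regulated hub
    targets under a TF family.  Loadings are positive throughout: only
    activating "(+)" regulons are modeled.
    """
    if n_responsive > n_tfs:
        raise ValueError("n_responsive must not exceed n_tfs")
    if targets_per_tf > n_genes - n_tfs:
        raise ValueError("targets_per_tf exceeds available non-TF genes")
    rng = np.random.default_rng(seed)

    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    other = [f"G{i + 1:04d}" for i in range(n_genes - n_tfs)]
    gene_ids = tf_ids + other

    if n_celltypes == len(DEFAULT_CELLTYPES):
        cell_types = list(DEFAULT_CELLTYPES)
    else:
        cell_types = [f"type{i + 1}" for i in range(n_celltypes)]
    if composition_normal is None:
        composition_normal = (DEFAULT_COMPOSITION_NORMAL
                              if n_celltypes == 8 else
                              np.full(n_celltypes, 1.0 / n_celltypes))
    if composition_dcm is None:
        composition_dcm = (DEFAULT_COMPOSITION_DCM
                           if n_celltypes == 8 else
                           np.full(n_celltypes, 1.0 / n_celltypes))
    comp_n = np.asarray(composition_normal, dtype=float)
    comp_d = np.asarray(composition_dcm, dtype=float)
    comp_n = comp_n / comp_n.sum()
    comp_d = comp_d / comp_d.sum()

    # Baseline per-type profiles: shared log-normal means plus boosted,
    # type-exclusive marker genes drawn from the non-TF pool.  TF genes get
    # a moderate, reliably detectable baseline: expression-based network
    # inference has no signal path through a TF whose transcript drops out.
    base = rng.normal(loc=0.0, scale=1.0, size=n_genes)
    base[:n_tfs] = rng.normal(loc=1.0, scale=0.5, size=n_tfs)
    baseline_log = np.tile(base, (n_celltypes, 1))
    marker_pool = rng.permutation(other)
    marker_sets: dict[str, list[str]] = {}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    pos = 0
    for t, tname in enumerate(cell_types):
        markers = list(marker_pool[pos:pos + markers_per_type])
        pos += markers_per_type
        marker_sets[tname] = markers
        idx = [gene_index[m] for m in markers]
        baseline_log[t, idx] += np.log(8.0)

    # Target pools: markers and TFs excluded so annotation and regulon
    # signal stay unconfounded; responsive regulons share a small pool.
    # Target pools: markers and TFs excluded; responsive regulons draw from
    # a reserved pool (shared sub-pool + private remainder) disjoint from
    # the decoy regulons' pool, so every planted bulk group difference is
    # attributable to the responsive family.
    used_markers = set(marker_pool[:pos])
    free = [g for g in other if g not in used_markers]
    free = list(rng.permutation(free))
    shared_pool = free[:shared_pool_size]
    responsive_pool = free[shared_pool_size:
                           shared_pool_size + 10 * targets_per_tf]
    general_pool = free[shared_pool_size + 10 * targets_per_tf:]

    responsive_idx = rng.choice(n_tfs, size=n_responsive, replace=False)
    responsive_idx = sorted(int(i) for i in responsive_idx)
    regulons: list[PlantedRegulon] = []
    for i, tf in enumerate(tf_ids):
        if i in responsive_idx:
            n_shared = int(round(shared_fraction * targets_per_tf))
            shared = list(rng.choice(shared_pool, size=n_shared, replace=False))
            rest = list(rng.choice(responsive_pool,
                                   size=targets_per_tf - n_shared,
                                   replace=False))
            targets = shared + rest
        else:
            targets = list(rng.choice(general_pool, size=targets_per_tf,
                                      replace=False))
        targets = [str(g) for g in targets]
        loadings = {g: float(rng.uniform(0.25, 0.6)) for g in targets}
        regulons.append(PlantedRegulon(tf=tf, targets=targets,
                                       loadings=loadings, tf_loading=1.2))
    responsive = [regulons[i].name for i in responsive_idx]
    # responsive regulons differ in realized effect size, as disease
    # responses do; multipliers spread the group-variance fractions apart
    group_effects = {name: float(group_effect * rng.uniform(0.7, 1.3))
                     for name in responsive}

    celltype_effect = rng.normal(0.0, celltype_effect_sd,
                                 size=(n_tfs, n_celltypes))
    dispersion = np.exp(rng.normal(np.log(dispersion_mean), 0.3, size=n_genes))

    return SyntheticTruth(
        gene_ids=gene_ids, cell_types=cell_types, baseline_log=baseline_log,
        group_composition={"Normal": comp_n, "DCM": comp_d},
        regulons=regulons, responsive=responsive, group_effect=group_effect,
        group_effects=group_effects,
        celltype_effect=celltype_effect, dispersion=dispersion,
        libsize_log_mu=libsize_log_mu, libsize_log_sigma=libsize_log_sigma,
        batch_sd=batch_sd, marker_sets=marker_sets, seed=seed)


def simulate_single_cell(truth: SyntheticTruth, n_cells_per_group: int = 1500,
                         n_samples_per_group: int = 3,
                         seed: int = 0) -> tuple[CellMatrix, pd.DataFrame]:
    """Draw UMI counts plus the latent per-cell regulon activities.

    Returns ``(cells, activities)`` where ``activities`` is a cells x
    regulons DataFrame of the latent Gaussian activities that generated
    the counts (the recovery target for activity scoring).
    """
    rng = np.random.default_rng(seed)
    n_genes = len(truth.gene_ids)
    n_regs = len(truth.regulons)
    shift = np.array([truth.group_effects.get(r.name, 0.0)
                      for r in truth.regulons])
    loadings = truth.loading_matrix()          # regulons x genes

    all_counts = []
    meta_rows = []
    activity_rows = []
    cell_ids = []
    cell_no = 0
    for group in ("Normal", "DCM"):
        comp = truth.group_composition[group]
        # per-sample (= batch) additive offsets on log-means
        batch_offsets = rng.normal(0.0, truth.batch_sd,
                                   size=(n_samples_per_group, n_genes))
        types = rng.choice(len(truth.cell_types), size=n_cells_per_group,
                           p=comp)
        samples = rng.integers(0, n_samples_per_group,
                               size=n_cells_per_group)
        act = (truth.celltype_effect.T[types]          # cells x regulons
               + rng.normal(0.0, 1.0, size=(n_cells_per_group, n_regs)))
        if group == "DCM":
            act += shift[None, :]
        log_mu = (truth.baseline_log[types]
                  + act @ loadings
                  + batch_offsets[samples])
        mu = np.exp(log_mu)
        lib = np.exp(rng.normal(truth.libsize_log_mu, truth.libsize_log_sigma,
                                size=n_cells_per_group))
        mu *= (lib / mu.sum(axis=1))[:, None]
        shape = 1.0 / truth.dispersion                 # per-gene shape
        lam = rng.gamma(shape[None, :], mu / shape[None, :])
        counts = rng.poisson(lam)
        all_counts.append(counts)
        for i in range(n_cells_per_group):
            cid = f"{group}_{samples[i]}_{cell_no:05d}"
            cell_ids.append(cid)
            meta_rows.append({
                "cell_id": cid,
                "sample_id": f"{group}_s{samples[i]}",
                "group": group,
                "batch": f"{group}_s{samples[i]}",
                "true_cell_type": truth.cell_types[types[i]],
                "true_libsize": lib[i],
            })
            cell_no += 1
        activity_rows.append(act)

    counts = np.vstack(all_counts)                      # cells x genes
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    activities = pd.DataFrame(np.vstack(activity_rows), index=cell_ids,
                              columns=[r.name for r in truth.regulons])
    cells = CellMatrix(values=sp.csr_matrix(counts.T.astype(np.int64)),
                       gene_ids=list(truth.gene_ids), cell_ids=cell_ids,
                       cell_meta=meta, layer_tag="counts")
    return cells, activities


def simulate_bulk(truth: SyntheticTruth, n_per_group=(16, 86),
                  noise_sd: float = 0.3, seed: int = 0,
                  dataset_id: str = "bulk") -> BulkMatrix:
    """Noisy log2 pseudobulk mixtures with the planted group effect.

    Each sample is the log2 of its group's composition-weighted mixture of
    cell-type mean profiles; in the DCM group every target of a responsive
    regulon is amplified by ``exp(loading * group_effect)`` before mixing.
    Gaussian noise of ``noise_sd`` is added per gene and sample.
    """
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    n_genes = len(truth.gene_ids)

    effect = np.zeros(n_genes)
    for reg in truth.regulons:
        shift = truth.group_effects.get(reg.name, 0.0)
        if shift:
            for g, w in reg.loadings.items():
                effect[gene_index[g]] += w * shift
            effect[gene_index[reg.tf]] += reg.tf_loading * shift

    profiles = np.exp(truth.baseline_log)               # types x genes
    columns, sample_ids, groups = [], [], []
    for group, n_samples in zip(("Normal", "DCM"), n_per_group):
        comp = truth.group_composition[group]
        mix = comp @ profiles
        if group == "DCM":
            mix = mix * np.exp(effect)
        log2_mix = np.log2(mix)
        for s in range(n_samples):
            columns.append(log2_mix + rng.normal(0.0, noise_sd, size=n_genes))
            sample_ids.append(f"{dataset_id}_{group}_{s + 1}")
            groups.append(group)
    values = pd.DataFrame(np.column_stack(columns), index=truth.gene_ids,
                          columns=sample_ids)
    meta = pd.DataFrame({"group": groups}, index=sample_ids)
    return BulkMatrix(values=values, sample_meta=meta, log_scale=True)


def simulate_motif_table(truth: SyntheticTruth, true_support_rate: float = 1.0,
                         false_support_rate: float = 0.1,
                         seed: int = 0) -> pd.DataFrame:
    """Motif-support flags over all TF x gene candidate edges.

    Planted edges are flagged supported with probability
    ``true_support_rate``, every other (decoy) edge with probability
    ``false_support_rate`` — the stand-in for motif-ranking databases.
    """
    if not (0 <= true_support_rate <= 1 and 0 <= false_support_rate <= 1):
        raise ValueError("support rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = {(r.tf, t) for r in truth.regulons for t in r.targets}
    rows = []
    for reg in truth.regulons:
        tf = reg.tf
        for g in truth.gene_ids:
            if g == tf:
                continue
            rate = (true_support_rate if (tf, g) in planted
                    else false_support_rate)
            rows.append((tf, g, 0.0, bool(rng.random() < rate)))
    df = pd.DataFrame(rows, columns=["tf", "target", "importance",
                                     "motif_supported"])
    return _validate_regulon_table(df)


# ---------------------------------------------------------------------------
# Direct activity-matrix generators for the variance-decomposition benchmarks
# ---------------------------------------------------------------------------

def simulate_lmm_activity(fractions=(0.3, 0.4, 0.3), n_units: int = 500,
                          n_celltypes: int = 8, seed: int = 0):
    """One regulon-activity vector with exact realized variance fractions.

    Cell-type and group labels are assigned balanced and crossed.  The
    realized level effects are rescaled so that their between-level sample
    variance (ddof=1) equals the requested component exactly — the
    quantity a balanced-design REML fit estimates — making the generator a
    calibration-free recovery target.  Returns ``(y, celltype, group)``.
    """
    f_ct, f_grp, f_res = fractions
    if min(fractions) < 0 or f_res <= 0:
        raise ValueError("fractions must be non-negative with positive residual")
    rng = np.random.default_rng(seed)
    celltype = np.arange(n_units) % n_celltypes
    group = np.where((np.arange(n_units) // n_celltypes) % 2 == 0,
                     "Normal", "DCM")
    ct_eff = rng.normal(0.0, 1.0, size=n_celltypes)
    ct_eff -= ct_eff.mean()
    sv = ct_eff.var(ddof=1)
    ct_eff *= np.sqrt(f_ct / sv) if sv > 0 and f_ct > 0 else 0.0
    # two groups at +/- d have between-level sample variance 2 d^2
    d = np.sqrt(f_grp / 2.0)
    grp_eff = np.where(group == "DCM", d, -d)
    y = (ct_eff[celltype] + grp_eff
         + rng.normal(0.0, np.sqrt(f_res), size=n_units))
    return y, np.array([f"type{t}" for t in celltype]), group


def simulate_regulon_activity(n_regulons: int = 50, n_responsive: int = 5,
                              n_units: int = 500, n_celltypes: int = 8,
                              group_effect: float = 2.0,
                              celltype_effect_sd: float = 2.0,
                              seed: int = 0):
    """A units x regulons activity matrix with planted responsive regulons.

    Uses the same latent model as :func:`simulate_single_cell` but skips
    the count layer: activity = cell-type offset + group shift (responsive
    regulons, DCM units) + unit noise.  Returns
    ``(activity_df, celltype_labels, group_labels, responsive_names)``.
    """
    rng = np.random.default_rng(seed)
    names = [f"TF{i + 1:03d}(+)" for i in range(n_regulons)]
    responsive = sorted(rng.choice(n_regulons, size=n_responsive,
                                   replace=False)) if n_responsive else []
    celltype = rng.integers(0, n_celltypes, size=n_units)
    group = np.where(np.arange(n_units) < n_units // 2, "Normal", "DCM")
    offsets = rng.normal(0.0, celltype_effect_sd, size=(n_regulons, n_celltypes))
    act = offsets.T[celltype] + rng.normal(0.0, 1.0, size=(n_units, n_regulons))
    for r in responsive:
        act[group == "DCM", r] += group_effect
    df = pd.DataFrame(act, columns=names,
                      index=[f"u{i:04d}" for i in range(n_units)])
    return (df, np.array([f"type{t}" for t in celltype]), group,
            [names[r] for r in responsive])
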