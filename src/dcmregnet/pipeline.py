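"""End-to-end orchestration of the regulon-discovery pipeline.

Stage order: simulate (optional) -> single-cell QC/normalization ->
HVG/PCA/batch centering -> clustering + annotation + composition ->
metacells -> regulon inference + motif pruning -> AUCell activity ->
CSI modules -> variance decomposition + knee selection -> bulk
differential expression and ssGSEA on two cohorts -> hub-target
intersection and ROC diagnostics.  Every stage draws its seed from the
single config seed, and a manifest records parameters, per-stage sizes
and timings.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activity as activity_mod
from . import bulkval, csi, grn, hub, metacell, scqc, simulate
from .io import GeneSetCollection, PipelineConfig, load_config

logger = logging.getLogger("dcmregnet")


@dataclass
class RunManifest:
    """Parameter snapshot plus per-stage sizes and timings for one run."""

    params: dict
    seed: int
    stages: list[str] = field(default_factory=list)
    sizes: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def record(self, stage: str, t0: float, **sizes) -> None:
        self.stages.append(stage)
        self.timings_s[stage] = round(time.perf_counter() - t0, 3)
        self.sizes.update(sizes)


@dataclass
class PipelineResult:
    manifest: RunManifest
    truth: simulate.SyntheticTruth | None
    composition: pd.DataFrame
    regulons: list
    ras: pd.DataFrame
    modules: pd.Series
    vardecomp_table: pd.DataFrame
    selections: dict
    responsive: list[str]
    ssgsea_comparisons: dict[str, pd.DataFrame]
    deg_tables: dict[str, pd.DataFrame]
    report: hub.HubTargetReport


def run_full_pipeline(config: PipelineConfig | None = None,
                      seed: int | None = None) -> PipelineResult:
    """Run every stage on synthetic data with planted ground truth.

    ``seed`` overrides the config seed.  Inputs are generated by the
    simulation stage; file-based runs compose the same stage functions
    through the CLI instead.
    """
    cfg = config if config is not None else load_config()
    if seed is not None:
        cfg = PipelineConfig(params={**cfg.as_dict(), "seed": int(seed)})
    seed = cfg.seed
    manifest = RunManifest(params=cfg.as_dict(), seed=seed)
    sim = cfg["simulate"]

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    truth = simulate.simulate_truth(
        n_celltypes=sim["n_celltypes"], n_genes=sim["n_genes"],
        n_tfs=sim["n_tfs"], targets_per_tf=sim["targets_per_tf"],
        n_responsive=sim["n_responsive"], group_effect=sim["group_effect"],
        celltype_effect_sd=sim["celltype_effect_sd"],
        markers_per_type=sim["markers_per_type"],
        shared_pool_size=sim["shared_pool_size"],
        shared_fraction=sim["shared_fraction"], seed=seed)
    cells, _latent = simulate.simulate_single_cell(
        truth, n_cells_per_group=sim["n_cells_per_group"],
        n_samples_per_group=sim["n_samples_per_group"], seed=seed + 1)
    motif_table = simulate.simulate_motif_table(
        truth, true_support_rate=sim["true_support_rate"],
        false_support_rate=sim["false_support_rate"], seed=seed + 2)
    bulks = {}
    for i, shape in enumerate(sim["bulk_shapes"]):
        name = f"bulk{i + 1}"
        bulks[name] = simulate.simulate_bulk(
            truth, n_per_group=tuple(shape), noise_sd=sim["bulk_noise_sd"],
            seed=seed + 10 + i, dataset_id=name)
    manifest.record("simulate", t0, n_cells_simulated=cells.n_cells,
                    n_genes=cells.n_genes)

    # --- single-cell QC & embedding --------------------------------------
    t0 = time.perf_counter()
    cells = scqc.qc_filter(cells, **cfg["qc"])
    lognorm = scqc.normalize_lognorm(cells, scale=cfg["normalize"]["scale"])
    hvg = scqc.select_hvg(lognorm, n_top=min(cfg["hvg"]["n_top"],
                                             lognorm.n_genes))
    pcs = scqc.scale_and_pca(lognorm, hvg, n_pcs=cfg["pca"]["n_pcs"],
                             clip=cfg["pca"]["clip"])
    pcs = scqc.batch_center(pcs, cells.cell_meta["batch"])
    manifest.record("scqc", t0, n_cells_post_qc=cells.n_cells)

    # --- clustering, annotation, composition ------------------------------
    t0 = time.perf_counter()
    assign = scqc.cluster_graph(pcs, k_neighbors=cfg["cluster"]["k_neighbors"],
                                resolution=cfg["cluster"]["resolution"],
                                seed=seed)
    reference = GeneSetCollection(
        {t: truth.marker_sets[t] for t in truth.cell_types})
    means = scqc.cluster_means(lognorm, assign.labels)
    annotation = scqc.annotate_clusters(means, reference)
    cell_types = assign.labels.map(annotation["cell_type"])
    meta = cells.cell_meta.copy()
    meta["cell_type"] = cell_types
    cells = cells.copy_with(cell_meta=meta)
    lognorm = lognorm.copy_with(cell_meta=meta)
    comp = scqc.composition(meta)
    manifest.record("annotate", t0, n_clusters=assign.n_clusters)

    # --- metacells ---------------------------------------------------------
    t0 = time.perf_counter()
    micro = metacell.overcluster(pcs, meta["group"],
                                 resolution=cfg["metacell"]["resolution"],
                                 k_neighbors=cfg["metacell"]["k_neighbors"],
                                 seed=seed)
    mc = metacell.aggregate_metacells(cells, micro,
                                      min_cells=cfg["metacell"]["min_cells"],
                                      strict=cfg["metacell"]["strict"],
                                      scale=cfg["normalize"]["scale"],
                                      aggregate=cfg["metacell"]["aggregate"])
    counts_by_group = mc.meta["group"].value_counts().to_dict()
    manifest.record("metacell", t0, n_metacells=mc.n_metacells,
                    n_metacells_by_group=counts_by_group)

    # --- regulon inference -------------------------------------------------
    t0 = time.perf_counter()
    edges = grn.infer_importance(mc, truth.tf_ids,
                                 ridge_lambda=cfg["grn"]["ridge_lambda"],
                                 importance_floor=cfg["grn"]["importance_floor"])
    regulons = grn.assemble_regulons(edges, motif_table,
                                     top_n_per_tf=cfg["grn"]["top_n_per_tf"],
                                     min_regulon_size=cfg["grn"]["min_regulon_size"])
    manifest.record("grn", t0, n_regulons=len(regulons))

    # --- activity, CSI modules --------------------------------------------
    t0 = time.perf_counter()
    ras = activity_mod.ras_matrix(mc.lognorm_frame(), regulons,
                                  top_fraction=cfg["activity"]["top_fraction"])
    pcc = csi.pcc_matrix(ras)
    csi_m = csi.csi_matrix(pcc, strict=cfg["csi"]["strict"])
    n_modules = min(cfg["csi"]["n_modules"], csi_m.shape[0])
    modules = csi.cluster_modules(csi_m, n_modules=n_modules,
                                  method=cfg["csi"]["linkage"])
    manifest.record("csi", t0, n_modules=int(modules.nunique()))

    # --- variance decomposition -------------------------------------------
    t0 = time.perf_counter()
    vd_table, selections, responsive = decompose_stage(cfg, ras, modules, mc)
    manifest.record("vardecomp", t0, n_selected=len(responsive))

    # --- bulk validation ---------------------------------------------------
    t0 = time.perf_counter()
    selected_regs = [r for r in regulons if r.name in responsive]
    deg_tables, comparisons, diff_sets = {}, {}, {}
    if selected_regs:
        genesets = grn.regulons_to_genesets(
            selected_regs, include_tf=cfg["grn"]["include_tf_in_geneset"])
        for name, bulk in bulks.items():
            deg = bulkval.de_moderated(
                bulk, log2fc_threshold=cfg["bulk_de"]["log2fc_threshold"],
                fdr_threshold=cfg["bulk_de"]["fdr_threshold"])
            deg_tables[name] = deg
            scores = bulkval.ssgsea(bulk, genesets,
                                    alpha=cfg["ssgsea"]["alpha"],
                                    normalize=cfg["ssgsea"]["normalize"])
            cmp_ = bulkval.compare_scores(scores, bulk.groups())
            comparisons[name] = cmp_
            diff_sets[name] = {reg: cmp_.loc[reg, "direction"]
                               for reg in cmp_.index[cmp_["significant"]]}
    manifest.record("bulkval", t0,
                    n_differentiated={k: len(v) for k, v in diff_sets.items()})

    # --- hub targets -------------------------------------------------------
    t0 = time.perf_counter()
    report = hub_stage(cfg, selected_regs, diff_sets, deg_tables, bulks, seed)
    manifest.record("hub", t0, n_multi_targets=len(report.multi_targets),
                    n_hub_targets=len(report.hub_targets))
    return PipelineResult(
        manifest=manifest, truth=truth, composition=comp, regulons=regulons,
        ras=ras, modules=modules, vardecomp_table=vd_table,
        selections=selections, responsive=responsive,
        ssgsea_comparisons=comparisons, deg_tables=deg_tables, report=report)


def decompose_stage(cfg: PipelineConfig, ras: pd.DataFrame,
                    modules: pd.Series, mc: metacell.MetacellMatrix):
    from . import vardecomp as vd
    return vd.decompose_all(
        ras, modules,
        celltype=mc.meta["dominant_cell_type"].to_numpy(),
        group=mc.meta["group"].to_numpy(),
        min_group_fraction=cfg["vardecomp"]["min_group_fraction"],
        slope_threshold=cfg["vardecomp"]["slope_threshold"])


def hub_stage(cfg: PipelineConfig, selected_regs, diff_sets, deg_tables,
              bulks, seed: int) -> hub.HubTargetReport:
    """Regulon intersection -> multi targets -> DEG intersection -> ROC."""
    empty = hub.HubTargetReport(
        shared_regulons=pd.DataFrame(), consistent_regulons=[],
        target_counts={}, multi_targets=[], differential_targets={},
        hub_targets=[], hub_provenance={})
    if len(diff_sets) < 2:
        return empty
    shared = hub.intersect_regulons(diff_sets)
    consistent = (list(shared.index[shared["consistent"].astype(bool)])
                  if len(shared) else [])
    use = consistent if cfg["hub"]["consistent_only"] else list(shared.index)
    reg_sets = {r.name: r.targets for r in selected_regs if r.name in use}
    if len(reg_sets) < 2:
        empty.shared_regulons = shared
        empty.consistent_regulons = consistent
        return empty
    counts, multi, _membership = hub.count_multi_targets(
        reg_sets, min_occurrence=cfg["hub"]["min_occurrence"])
    per_ds, final, provenance = hub.hub_targets(multi, deg_tables, reg_sets)
    roc: dict[str, dict[str, hub.RocResult]] = {}
    for name, bulk in bulks.items():
        roc[name] = {}
        labels = bulk.groups().to_numpy()
        for t in final:
            values = bulk.values.loc[t].to_numpy(dtype=float)
            # orient by the cohort's observed direction so the marker's
            # disease-ward tail predicts DCM
            if float(deg_tables[name].loc[t, "log2FC"]) < 0:
                values = -values
            roc[name][t] = hub.roc_bootstrap_ci(
                values, labels, positive="DCM",
                n_boot=cfg["hub"]["n_boot"], seed=seed)
    return hub.HubTargetReport(
        shared_regulons=shared, consistent_regulons=consistent,
        target_counts=counts, multi_targets=multi,
        differential_targets=per_ds, hub_targets=final,
        hub_provenance=provenance, roc=roc)


def planted_hub_targets(truth: simulate.SyntheticTruth,
                        min_occurrence: int = 2) -> list[str]:
    """Ground-truth hub targets implied by the planted regulons.

    Targets carried by at least ``min_occurrence`` of the planted
    responsive regulons — the set the pipeline should recover when every
    stage works (responsive targets are differential in bulk by
    construction).
    """
    counts: dict[str, int] = {}
    for reg in truth.regulons:
        if reg.name in truth.responsive:
            for t in reg.targets:
                counts[str(t)] = counts.get(str(t), 0) + 1
    return sorted(t for t, c in counts.items() if c >= min_occurrence)
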