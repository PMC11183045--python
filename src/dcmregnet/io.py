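"""Readers, writers, configuration and logging for every on-disk format.

Every pipeline stage is file-in/file-out reproducible through this module:
MatrixMarket triplets for sparse count matrices, dense TSV for bulk
expression, GMT for gene sets, a TSV edge table for regulons, and a strict
YAML configuration.  All writers can emit a sidecar provenance record
(`<path>.prov.json`) carrying the parameters and seed that produced a file.

Conventions
-----------
* MatrixMarket files are 1-based on disk (per the standard); everything in
  memory is 0-based.  Conversion happens only at the I/O boundary.
* Gene and cell identifiers are opaque, case-sensitive strings; no
  symbol/alias mapping is attempted.
* Matrices are oriented genes x cells (single cell) and genes x samples
  (bulk) throughout.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("dcmregnet")

VALID_GROUPS = ("Normal", "DCM")
VALID_LAYERS = ("counts", "lognorm", "scaled")


class FormatError(ValueError):
    """A file violated the declared on-disk format."""


class ConfigError(ValueError):
    """Configuration file contained unknown or invalid keys."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class CellMatrix:
    """Genes x cells expression matrix with per-cell metadata.

    ``values`` is a scipy sparse matrix or dense ndarray of shape
    ``(len(gene_ids), len(cell_ids))``.  ``cell_meta`` is indexed by cell id
    and carries at least ``sample_id``, ``group`` and ``batch`` columns; a
    ``cell_type`` column is added by annotation.  ``layer_tag`` records the
    processing state: raw ``counts``, library-size ``lognorm``, or per-gene
    z-scored ``scaled``.
    """

    values: object
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell identifiers")
        if self.layer_tag not in VALID_LAYERS:
            raise ValueError(f"layer_tag must be one of {VALID_LAYERS}")
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        missing = set(self.cell_ids) - set(self.cell_meta.index.astype(str))
        if missing:
            raise FormatError(f"cell_meta missing {len(missing)} cells")
        self.cell_meta = self.cell_meta.loc[self.cell_ids]
        if self.layer_tag == "counts":
            data = self.values.data if sp.issparse(self.values) else np.asarray(self.values)
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise FormatError("counts layer must hold non-negative integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def copy_with(self, *, values=None, layer_tag=None, gene_ids=None,
                  cell_ids=None, cell_meta=None) -> "CellMatrix":
        return CellMatrix(
            values=self.values if values is None else values,
            gene_ids=list(self.gene_ids) if gene_ids is None else list(gene_ids),
            cell_ids=list(self.cell_ids) if cell_ids is None else list(cell_ids),
            cell_meta=(self.cell_meta if cell_meta is None else cell_meta).copy(),
            layer_tag=self.layer_tag if layer_tag is None else layer_tag,
        )


@dataclass
class BulkMatrix:
    """Genes x samples real-valued bulk expression with group labels.

    The expression scale (log2 intensities vs linear) is the caller's
    declaration via ``log_scale``; differential testing requires log2.
    """

    values: pd.DataFrame          # genes x samples
    sample_meta: pd.DataFrame     # indexed by sample id, column "group"
    log_scale: bool = True

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise FormatError("duplicate gene identifiers in bulk matrix")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample identifiers in bulk matrix")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise FormatError(f"sample_meta missing {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[self.values.columns]
        bad = set(self.sample_meta["group"]) - set(VALID_GROUPS)
        if bad:
            raise FormatError(f"unknown group labels {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> pd.Series:
        return self.sample_meta["group"]


class GeneSetCollection:
    """Ordered mapping of unique set names to non-empty gene-id sets."""

    def __init__(self, sets: Mapping[str, Iterable[str]] | None = None,
                 descriptions: Mapping[str, str] | None = None) -> None:
        self._sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        if sets:
            for name, members in sets.items():
                self.add(name, members,
                         (descriptions or {}).get(name, ""))

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        members = list(dict.fromkeys(str(m) for m in members))
        if name in self._sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        if not members:
            raise FormatError(f"gene set {name!r} has no members")
        self._sets[name] = members
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def names(self) -> list[str]:
        return list(self._sets)

    def as_dict(self) -> dict[str, list[str]]:
        return {k: list(v) for k, v in self._sets.items()}

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.as_dict() == other.as_dict()


REGULON_TABLE_COLUMNS = ["tf", "target", "importance", "motif_supported"]


def _validate_regulon_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REGULON_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"regulon table missing columns {missing}")
    df = df[REGULON_TABLE_COLUMNS].copy()
    df["tf"] = df["tf"].astype(str)
    df["target"] = df["target"].astype(str)
    imp = pd.to_numeric(df["importance"], errors="coerce")
    if imp.isna().any() or not np.isfinite(imp).all():
        bad = df.loc[imp.isna() | ~np.isfinite(imp), "importance"].iloc[0]
        raise FormatError(f"unparseable importance value {bad!r}")
    df["importance"] = imp.astype(float)
    df["motif_supported"] = df["motif_supported"].map(_parse_bool)
    if df.duplicated(subset=["tf", "target"]).any():
        dup = df[df.duplicated(subset=["tf", "target"])].iloc[0]
        raise FormatError(f"repeated edge ({dup['tf']}, {dup['target']})")
    return df.reset_index(drop=True)


def _parse_bool(x) -> bool:
    s = str(x).strip().lower()
    if s in ("1", "true"):
        return True
    if s in ("0", "false"):
        return False
    raise FormatError(f"unparseable boolean {x!r}")


# ---------------------------------------------------------------------------
# MatrixMarket single-cell I/O
# ---------------------------------------------------------------------------

def _read_id_file(path: str | Path) -> list[str]:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def read_mtx(matrix_path: str | Path, genes_path: str | Path,
             barcodes_path: str | Path,
             meta_path: str | Path | None = None) -> CellMatrix:
    """Read a MatrixMarket count triplet into a :class:`CellMatrix`.

    ``meta_path`` optionally points at a TSV (indexed by cell id) with
    ``sample_id``, ``group`` and ``batch`` columns; without it a
    single-sample placeholder metadata frame is attached.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending file
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise FormatError(f"non-integer entries in {matrix_path}")
    genes = _read_id_file(genes_path)
    barcodes = _read_id_file(barcodes_path)
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{genes_path}: {len(genes)} ids but matrix has {mat.shape[0]} rows")
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} ids but matrix has {mat.shape[1]} columns")
    if len(set(genes)) != len(genes):
        raise FormatError(f"{genes_path}: duplicated gene id")
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{barcodes_path}: duplicated barcode")
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    else:
        meta = pd.DataFrame(
            {"sample_id": "sample0", "group": "Normal", "batch": "batch0"},
            index=pd.Index(barcodes, name="cell_id"),
        )
    return CellMatrix(values=mat.astype(np.int64), gene_ids=genes,
                      cell_ids=barcodes, cell_meta=meta, layer_tag="counts")


def write_mtx(cells: CellMatrix, matrix_path: str | Path,
              genes_path: str | Path, barcodes_path: str | Path,
              meta_path: str | Path | None = None,
              provenance: Mapping | None = None) -> None:
    mat = sp.coo_matrix(cells.values)
    scipy.io.mmwrite(str(matrix_path), mat, field="integer"
                     if cells.layer_tag == "counts" else "real")
    Path(genes_path).write_text("".join(g + "\n" for g in cells.gene_ids))
    Path(barcodes_path).write_text("".join(c + "\n" for c in cells.cell_ids))
    if meta_path is not None:
        cells.cell_meta.to_csv(meta_path, sep="\t", index_label="cell_id")
    _write_provenance(matrix_path, provenance)


# ---------------------------------------------------------------------------
# Bulk TSV
# ---------------------------------------------------------------------------

def read_bulk_tsv(values_path: str | Path, meta_path: str | Path,
                  log_scale: bool = True) -> BulkMatrix:
    """Read a genes x samples TSV plus a sample-metadata TSV.

    The caller must declare whether the matrix is on log scale; the study's
    array platforms differ and the file cannot say.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    if "group" not in meta.columns:
        raise FormatError(f"{meta_path}: missing 'group' column")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta.index = meta.index.astype(str)
    return BulkMatrix(values=values, sample_meta=meta, log_scale=log_scale)


def write_bulk_tsv(bulk: BulkMatrix, values_path: str | Path,
                   meta_path: str | Path,
                   provenance: Mapping | None = None) -> None:
    bulk.values.to_csv(values_path, sep="\t", index_label="gene_id")
    bulk.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    _write_provenance(values_path, provenance)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file: ``name<TAB>description<TAB>members...``."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: gene set with zero members")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set with zero members")
            coll.add(name, members, desc)
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path,
              provenance: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")
    _write_provenance(path, provenance)


# ---------------------------------------------------------------------------
# Regulon edge table
# ---------------------------------------------------------------------------

def read_regulon_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with header ``tf  target  importance  motif_supported``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _validate_regulon_table(df)


def write_regulon_table(table: pd.DataFrame, path: str | Path,
                        provenance: Mapping | None = None) -> None:
    df = _validate_regulon_table(table)
    out = df.copy()
    out["motif_supported"] = out["motif_supported"].astype(int)
    out.to_csv(path, sep="\t", index=False)
    _write_provenance(path, provenance)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_config() -> dict:
    """Stage parameters with defaults mirroring the study's settings."""
    return {
        "seed": 0,
        "qc": {"min_genes": 200, "max_genes": 5000},
        "normalize": {"scale": 10000.0},
        "hvg": {"n_top": 2000},
        "pca": {"n_pcs": 30, "clip": 10.0},
        "cluster": {"k_neighbors": 20, "resolution": 0.7},
        "markers": {"logfc_threshold": 0.25, "min_pct": 0.1},
        "metacell": {"resolution": 10.0, "k_neighbors": 20, "min_cells": 10,
                     "strict": True, "aggregate": "sum"},
        "grn": {"ridge_lambda": 1.0, "importance_floor": 0.01,
                "top_n_per_tf": 2000, "min_regulon_size": 10,
                "include_tf_in_geneset": False},
        "activity": {"top_fraction": 0.05},
        "csi": {"n_modules": 8, "linkage": "average", "strict": False},
        "vardecomp": {"units": "metacells", "min_group_fraction": 0.05,
                      "slope_threshold": -1.0},
        "bulk_de": {"log2fc_threshold": 0.5, "fdr_threshold": 0.05},
        "ssgsea": {"alpha": 0.25, "normalize": True},
        "hub": {"min_occurrence": 2, "consistent_only": True,
                "n_boot": 2000},
        "simulate": {
            "n_celltypes": 8, "n_genes": 2000, "n_tfs": 40,
            "targets_per_tf": 25, "n_responsive": 5, "group_effect": 2.0,
            "celltype_effect_sd": 2.0, "markers_per_type": 20,
            "shared_pool_size": 40, "shared_fraction": 0.4,
            "n_cells_per_group": 1500, "n_samples_per_group": 3,
            "bulk_shapes": [[16, 86], [136, 82]], "bulk_noise_sd": 0.3,
            "true_support_rate": 1.0, "false_support_rate": 0.0,
        },
    }


@dataclass
class PipelineConfig:
    """Fully materialized parameter record for one pipeline run."""

    params: dict = field(default_factory=_default_config)

    def __getitem__(self, key):
        return self.params[key]

    def get(self, *keys, default=None):
        node = self.params
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node

    @property
    def seed(self) -> int:
        return int(self.params["seed"])

    def as_dict(self) -> dict:
        return copy.deepcopy(self.params)


def _merge_strict(defaults: dict, overrides: dict, path: str = "") -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            valid = ", ".join(sorted(defaults))
            raise ConfigError(
                f"unknown config key {path + key!r}; valid keys here: {valid}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {path + key!r} must be a mapping")
            merged[key] = _merge_strict(defaults[key], value, path + key + ".")
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config, filling defaults and rejecting unknown keys."""
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        user = loaded
    params = _merge_strict(_default_config(), user)
    if overrides:
        params = _merge_strict(params, overrides)
    logger.info("materialized config: %s", json.dumps(params, sort_keys=True))
    return PipelineConfig(params=params)


# ---------------------------------------------------------------------------
# Provenance sidecars
# ---------------------------------------------------------------------------

def _write_provenance(target: str | Path, provenance: Mapping | None) -> None:
    if provenance is None:
        return
    record = dict(provenance)
    record.setdefault("writer", "dcmregnet")
    Path(str(target) + ".prov.json").write_text(
        json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
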