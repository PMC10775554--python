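"""Build reference cell-type expression profiles from annotated single-cell data.

A reference profile f_gc is the relative expression of gene g in cell type c,
obtained by pseudobulk aggregation: sum the counts of all cells annotated to
the type, then normalize to sum 1 over the non-excluded genes. Full-length
(Smart-Seq2-class) datasets are TPM-transformed per cell before aggregation to
remove gene-length bias; UMI data are aggregated as raw counts.

Filtering rules applied on the way in: cell types with fewer than 10 cells are
dropped; fine sub-types may be merged under one label; multiple datasets are
intersected on their common (version-stripped ENSEMBL) gene identifiers.
Mitochondrial and ribosomal genes can be flagged excluded, and housekeeping
genes carry a reduced fit weight of 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import (
    strip_ensembl_version,
    tpm_transform_matrix,
    validate_cell_annotation,
)

logger = logging.getLogger("cellsignal")

DEFAULT_MIN_CELLS = 10
HOUSEKEEPING_WEIGHT = 0.5

_DATA_DIR = Path(__file__).parent / "data"


def default_housekeeping_genes() -> list[str]:
    """The housekeeping gene symbols shipped with the package (overridable)."""
    path = _DATA_DIR / "housekeeping_genes.txt"
    return [l.strip() for l in path.read_text().splitlines() if l.strip()]


@dataclass
class ReferenceProfileSet:
    """Genes x cell-types matrix of relative expression with metadata.

    ``profiles`` columns are non-negative and sum to 1 over non-excluded
    genes. ``meta`` has one row per column: (cell_type, group, tissue,
    n_cells). ``gene_weights`` are per-gene fit weights in (0, 1];
    ``excluded_genes`` maps gene_id -> reason tag (mitochondrial, ribosomal,
    user).
    """

    profiles: pd.DataFrame
    meta: pd.DataFrame
    gene_weights: pd.Series
    excluded_genes: dict[str, str] = field(default_factory=dict)
    min_cells: int = DEFAULT_MIN_CELLS

    def __post_init__(self) -> None:
        self.profiles.index = pd.Index(self.profiles.index, name="gene_id")
        if self.profiles.index.has_duplicates:
            raise ValueError("gene_ids must be unique")
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("profiles must be non-negative")
        if list(self.meta["cell_type"]) != list(self.profiles.columns):
            raise ValueError("meta rows must match profile columns in order")
        if (self.meta["n_cells"] < self.min_cells).any():
            raise ValueError(f"every cell type needs >= {self.min_cells} cells")
        self.gene_weights = self.gene_weights.reindex(self.profiles.index).fillna(1.0)
        w = self.gene_weights.to_numpy()
        if ((w <= 0) | (w > 1)).any():
            raise ValueError("gene_weights must lie in (0, 1]")
        incl = self.included_mask()
        sums = self.profiles.loc[incl].sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("profile columns must sum to 1 over non-excluded genes")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    def included_mask(self) -> pd.Series:
        return ~pd.Index(self.profiles.index).isin(self.excluded_genes)

    def group_of(self, cell_type: str) -> str:
        row = self.meta.loc[self.meta["cell_type"] == cell_type]
        return str(row["group"].iloc[0])

    def subset_types(self, keep: Sequence[str]) -> "ReferenceProfileSet":
        """Restrict to a subset of cell types, renormalizing each kept column."""
        keep = [c for c in self.profiles.columns if c in set(keep)]
        if not keep:
            raise ValueError("subset selects zero cell types")
        prof = self.profiles[keep].copy()
        incl = self.included_mask()
        prof = prof / prof.loc[incl].sum(axis=0)
        meta = self.meta[self.meta["cell_type"].isin(keep)].reset_index(drop=True)
        return ReferenceProfileSet(
            prof, meta, self.gene_weights.copy(), dict(self.excluded_genes), self.min_cells
        )

    def exclude_where(self, predicate) -> "ReferenceProfileSet":
        """Drop cell types whose meta row satisfies ``predicate`` (e.g. the
        foetal-heart rule: group == foetal and tissue == heart)."""
        drop = [r["cell_type"] for _, r in self.meta.iterrows() if predicate(r)]
        keep = [c for c in self.cell_types if c not in set(drop)]
        if drop:
            logger.info("excluding reference cell types: %s", drop)
        return self.subset_types(keep)


# ---------------------------------------------------------------------------
# annotation-level filters
# ---------------------------------------------------------------------------

def filter_small_types(
    annotation: pd.DataFrame, min_cells: int = DEFAULT_MIN_CELLS
) -> pd.DataFrame:
    """Remove every cell type represented by fewer than ``min_cells`` cells."""
    if annotation.empty:
        raise ValueError("annotation is empty")
    sizes = annotation["cell_type"].value_counts()
    removed = sizes[sizes < min_cells]
    if len(removed):
        logger.info(
            "removing %d cell types with < %d cells: %s",
            len(removed), min_cells, list(removed.index),
        )
    kept = annotation[~annotation["cell_type"].isin(removed.index)]
    if kept.empty:
        raise ValueError(f"all cell types have < {min_cells} cells")
    return kept.reset_index(drop=True)


def merge_types(annotation: pd.DataFrame, merge_map: Mapping[str, str]) -> pd.DataFrame:
    """Rewrite fine sub-type labels to merged labels; unknown labels pass through."""
    out = annotation.copy()
    out["cell_type"] = out["cell_type"].map(lambda t: merge_map.get(t, t))
    return out


def intersect_genes(gene_id_lists: Sequence[Sequence[str]]) -> list[str]:
    """Sorted intersection of gene identifier lists after version stripping."""
    if not gene_id_lists:
        raise ValueError("need at least one dataset")
    common = set(strip_ensembl_version(gene_id_lists[0]))
    for ids in gene_id_lists[1:]:
        common &= set(strip_ensembl_version(ids))
    if not common:
        raise ValueError("gene intersection across datasets is empty")
    return sorted(common)


# ---------------------------------------------------------------------------
# exclusion / weighting helpers
# ---------------------------------------------------------------------------

def flag_mito_ribo(
    gene_ids: Sequence[str], symbols: Sequence[str] | None = None
) -> dict[str, str]:
    """Identify mitochondrial (MT-) and ribosomal (RPL/RPS) genes by symbol prefix."""
    symbols = list(symbols) if symbols is not None else list(gene_ids)
    flags: dict[str, str] = {}
    for gid, sym in zip(gene_ids, symbols):
        s = str(sym).upper()
        if s.startswith("MT-"):
            flags[gid] = "mitochondrial"
        elif s.startswith(("RPL", "RPS")):
            flags[gid] = "ribosomal"
    return flags


# ---------------------------------------------------------------------------
# profile building
# ---------------------------------------------------------------------------

@dataclass
class ReferenceDataset:
    """One annotated single-cell dataset feeding the reference."""

    counts: np.ndarray | sp.spmatrix  # genes x cells
    gene_ids: Sequence[str]
    annotation: pd.DataFrame
    chemistry: str = "umi"
    symbols: Sequence[str] | None = None
    gene_lengths: np.ndarray | pd.Series | None = None  # required for full_length


def _pseudobulk(counts, annotation: pd.DataFrame) -> pd.DataFrame:
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    types = annotation["cell_type"].to_numpy()
    cols = {}
    for t in pd.unique(types):
        cols[t] = dense[:, types == t].sum(axis=1)
    return pd.DataFrame(cols)


def build_profiles(
    datasets: Sequence[ReferenceDataset],
    exclude_mito_ribo: bool = False,
    housekeeping_genes: Sequence[str] | None = None,
    user_excluded_genes: Sequence[str] | None = None,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> ReferenceProfileSet:
    """Aggregate one or more annotated datasets into a ReferenceProfileSet.

    Cells are summed per type (full-length data TPM-transformed per cell
    first), datasets are intersected on common genes, and each type column is
    normalized to sum 1 over non-excluded genes. Housekeeping genes get fit
    weight 0.5; mitochondrial/ribosomal genes are flagged excluded when
    ``exclude_mito_ribo`` is on.
    """
    if not datasets:
        raise ValueError("no datasets provided")
    common = intersect_genes([ds.gene_ids for ds in datasets])
    symbol_map: dict[str, str] = {}
    pieces = []
    meta_rows = []
    for ds in datasets:
        ann = validate_cell_annotation(ds.annotation)
        ann = filter_small_types(ann, min_cells=min_cells)
        counts = ds.counts
        keep_cells = ds.annotation["cell_id"].isin(ann["cell_id"]).to_numpy()
        counts = counts[:, keep_cells] if not sp.issparse(counts) else counts.tocsc()[:, keep_cells]
        if ds.chemistry == "full_length":
            if ds.gene_lengths is None:
                raise ValueError("full_length dataset requires gene_lengths for TPM")
            counts = tpm_transform_matrix(counts, np.asarray(ds.gene_lengths, dtype=float))
        agg = _pseudobulk(counts, ann)
        stripped = strip_ensembl_version(ds.gene_ids)
        agg.index = stripped
        if ds.symbols is not None:
            symbol_map.update(dict(zip(stripped, ds.symbols)))
        agg = agg.loc[~agg.index.duplicated()]
        pieces.append(agg.reindex(common))
        sizes = ann["cell_type"].value_counts()
        for t in agg.columns:
            meta_rows.append(
                {
                    "cell_type": t,
                    "group": ann.loc[ann["cell_type"] == t, "group"].iloc[0]
                    if "group" in ann.columns
                    else "adult",
                    "tissue": ann.loc[ann["cell_type"] == t, "tissue"].iloc[0]
                    if "tissue" in ann.columns
                    else "",
                    "n_cells": int(sizes[t]),
                }
            )
    profiles = pd.concat(pieces, axis=1)
    if profiles.columns.has_duplicates:
        raise ValueError(
            f"duplicate cell-type names across datasets: "
            f"{sorted(profiles.columns[profiles.columns.duplicated()])}"
        )
    meta = pd.DataFrame(meta_rows)

    excluded: dict[str, str] = {}
    if exclude_mito_ribo:
        symbols = [symbol_map.get(g, g) for g in common]
        excluded.update(flag_mito_ribo(common, symbols))
    for g in user_excluded_genes or []:
        excluded.setdefault(g, "user")

    weights = pd.Series(1.0, index=profiles.index)
    hk = housekeeping_genes if housekeeping_genes is not None else []
    sym_to_id = {str(v).upper(): k for k, v in symbol_map.items()}
    for g in hk:
        gid = g if g in weights.index else sym_to_id.get(str(g).upper())
        if gid in weights.index:
            weights.loc[gid] = HOUSEKEEPING_WEIGHT

    incl = ~profiles.index.isin(excluded)
    col_sums = profiles.loc[incl].sum(axis=0)
    zero = col_sums[col_sums == 0]
    if len(zero):
        raise ValueError(f"cell types with all-zero aggregate expression: {list(zero.index)}")
    profiles = profiles / col_sums

    return ReferenceProfileSet(profiles, meta, weights, excluded, min_cells)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_reference(ref: ReferenceProfileSet, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prof = ref.profiles.copy()
    prof.index.name = "gene_id"
    prof.to_csv(out_dir / "profiles.tsv", sep="\t")
    ref.meta.to_csv(out_dir / "cell_type_meta.tsv", sep="\t", index=False)
    genes = pd.DataFrame(
        {
            "gene_id": ref.gene_ids,
            "weight": ref.gene_weights.to_numpy(),
            "excluded_reason": [ref.excluded_genes.get(g, "") for g in ref.gene_ids],
        }
    )
    genes.to_csv(out_dir / "gene_meta.tsv", sep="\t", index=False)
    return out_dir


def load_reference(ref_dir: str | Path) -> ReferenceProfileSet:
    ref_dir = Path(ref_dir)
    profiles = pd.read_csv(ref_dir / "profiles.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(ref_dir / "cell_type_meta.tsv", sep="\t").fillna({"tissue": ""})
    meta["tissue"] = meta["tissue"].fillna("")
    genes = pd.read_csv(ref_dir / "gene_meta.tsv", sep="\t").fillna({"excluded_reason": ""})
    weights = pd.Series(genes["weight"].to_numpy(), index=genes["gene_id"])
    excluded = {
        r["gene_id"]: r["excluded_reason"]
        for _, r in genes.iterrows()
        if isinstance(r["excluded_reason"], str) and r["excluded_reason"]
    }
    return ReferenceProfileSet(profiles, meta, weights, excluded)
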