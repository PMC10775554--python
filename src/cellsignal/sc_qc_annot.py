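"""Single-cell quality control and marker-based cluster annotation.

QC removes low-quality cells by three criteria, with removal using strict
inequalities exactly as stated in the thresholds' definitions: a cell is
removed when its mitochondrial fraction exceeds ``max_mito_fraction``, when it
has fewer than ``min_genes`` detected genes, or fewer than ``min_umis`` total
UMIs; a cell exactly at a threshold is retained. Typical droplet thresholds
are (0.20, 200, 500) for permissive tumour data and (0.10, 300, 1000) for
stricter processing.

Clustering is graph-based community detection (Leiden) on a k-nearest-
neighbour graph of log-normalized, PCA-reduced profiles, via scanpy. Clusters
are then annotated against a marker panel: each cluster is scored per label by
the mean log-normalized expression of that label's markers, and a cluster is
definitively annotated only when the top label beats the runner-up by a
margin; otherwise it is left unassigned and excluded downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("cellsignal")

DEFAULT_MARGIN = 0.5
DEFAULT_N_PCS = 30
DEFAULT_KNN = 15
DEFAULT_RESOLUTION = 1.0


@dataclass
class QCThresholds:
    """QC cutoffs: removal is strict (>, <); equality retains the cell."""

    max_mito_fraction: float = 0.20
    min_genes: int = 200
    min_umis: int = 500

    def __post_init__(self) -> None:
        if not (0 <= self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.min_genes <= 0 or self.min_umis <= 0:
            raise ValueError("min_genes and min_umis must be positive")


@dataclass
class MarkerPanel:
    """Map from cell-type label to its high-expression marker gene symbols."""

    markers: dict[str, list[str]]
    shared: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker panel is empty")
        seen: dict[str, str] = {}
        for label, genes in self.markers.items():
            if not genes:
                raise ValueError(f"label {label!r} has no markers")
            for g in genes:
                if g in seen and g not in self.shared:
                    raise ValueError(
                        f"marker {g!r} assigned to both {seen[g]!r} and {label!r}; "
                        "flag it as shared if intentional"
                    )
                seen[g] = label


def default_liver_panel() -> MarkerPanel:
    """The liver-tumour marker panel: leukocyte, erythrocyte, tumour cell,
    endothelial, and hepatic stellate markers."""
    return MarkerPanel(
        {
            "leukocyte": ["PTPRC"],  # CD45
            "erythrocyte": ["HBA1", "HBA2", "HBB"],
            "tumour_cell": ["EPCAM", "AFP"],
            "endothelial": ["PECAM1"],
            "hepatic_stellate": ["ACTA2"],
        }
    )


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def _to_dense(counts) -> np.ndarray:
    return np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)


def qc_metrics(
    counts,
    gene_ids: Sequence[str],
    mito_gene_ids: Sequence[str],
    cell_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cell totals, detected-gene counts, and mitochondrial fraction."""
    dense = _to_dense(counts)
    mito = np.isin(np.asarray(list(gene_ids)), np.asarray(list(mito_gene_ids)))
    umis = dense.sum(axis=0)
    genes = (dense > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umis > 0, dense[mito].sum(axis=0) / umis, 0.0)
    idx = list(cell_ids) if cell_ids is not None else [f"cell_{i}" for i in range(dense.shape[1])]
    return pd.DataFrame(
        {"umis": umis, "genes": genes, "mito_frac": mito_frac},
        index=pd.Index(idx, name="cell_id"),
    )


def qc_filter(
    counts,
    gene_ids: Sequence[str],
    mito_gene_ids: Sequence[str],
    thresholds: QCThresholds,
    cell_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove low-quality cells; return (filtered counts, per-cell QC table).

    A cell is kept iff mito_frac <= max_mito_fraction AND genes >= min_genes
    AND umis >= min_umis. The QC table records all three metrics, the keep
    flag, and the removal reason(s).
    """
    if not set(mito_gene_ids) <= set(gene_ids):
        extra = sorted(set(mito_gene_ids) - set(gene_ids))
        warnings.warn(f"mito genes not in gene universe (ignored): {extra}", stacklevel=2)
    if not mito_gene_ids:
        warnings.warn("empty mitochondrial gene list: mito fractions will be 0", stacklevel=2)
    table = qc_metrics(counts, gene_ids, mito_gene_ids, cell_ids)
    reasons = []
    for _, row in table.iterrows():
        r = []
        if row["mito_frac"] > thresholds.max_mito_fraction:
            r.append("mito")
        if row["genes"] < thresholds.min_genes:
            r.append("low_genes")
        if row["umis"] < thresholds.min_umis:
            r.append("low_umis")
        reasons.append(",".join(r))
    table["reasons"] = reasons
    table["kept"] = table["reasons"] == ""
    kept = table["kept"].to_numpy()
    if not kept.any():
        raise ValueError(
            "QC removed every cell; review thresholds "
            f"(max_mito={thresholds.max_mito_fraction}, min_genes={thresholds.min_genes}, "
            f"min_umis={thresholds.min_umis})"
        )
    dense = _to_dense(counts)
    logger.info("QC kept %d/%d cells", int(kept.sum()), len(kept))
    return dense[:, kept], table


def mito_genes_by_symbol(gene_ids: Sequence[str], symbols: Sequence[str]) -> list[str]:
    """Default mitochondrial gene selection: MT- symbol prefix."""
    return [g for g, s in zip(gene_ids, symbols) if str(s).upper().startswith("MT-")]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_cells(
    counts,
    n_pcs: int = DEFAULT_N_PCS,
    n_neighbors: int = DEFAULT_KNN,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a KNN graph of log-normalized cells.

    Counts are genes x cells. PCA dimensionality and the neighbourhood size
    shrink automatically for small inputs; results are deterministic under a
    fixed seed.
    """
    import scanpy as sc

    dense = _to_dense(counts)
    n_cells = dense.shape[1]
    if n_cells < 20:
        raise ValueError("need at least 20 cells to cluster")
    if n_neighbors >= n_cells:
        n_neighbors = max(2, n_cells - 1)
        warnings.warn(f"n_neighbors reduced to {n_neighbors} (few cells)", stacklevel=2)
    adata = ad.AnnData(X=dense.T.astype(np.float32))
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    n_comps = min(n_pcs, n_cells - 1, adata.n_vars - 1)
    if np.allclose(adata.X, adata.X[0]):
        # identical cells: PCA/KNN degenerate; everything is one community
        return np.zeros(n_cells, dtype=int)
    sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed, flavor="igraph", n_iterations=2)
    return adata.obs["leiden"].astype(int).to_numpy()


# ---------------------------------------------------------------------------
# marker annotation
# ---------------------------------------------------------------------------

def annotate_clusters(
    counts,
    gene_ids: Sequence[str],
    cluster_labels: Sequence,
    panel: MarkerPanel,
    margin: float = DEFAULT_MARGIN,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Assign a panel label to each cluster, or ``unassigned`` when ambiguous.

    Each cluster is scored per label by the mean (over its cells and the
    label's present markers) log-normalized marker expression; the top label
    is accepted only when it exceeds the runner-up by ``margin`` on the log
    scale and is positive. Returns a per-cluster table with the score of each
    label, the assignment, and whether it was definitive.
    """
    dense = _to_dense(counts)
    labels = np.asarray(list(cluster_labels))
    if len(labels) != dense.shape[1]:
        raise ValueError("cluster labels must cover all cells")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    missing = sorted(
        {g for genes in panel.markers.values() for g in genes} - set(gene_pos)
    )
    if missing:
        warnings.warn(f"panel markers absent from data: {missing}", stacklevel=2)
    totals = dense.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        logn = np.log1p(np.where(totals > 0, dense / totals * target_sum, 0.0))
    rows = []
    for cl in pd.unique(labels):
        mask = labels == cl
        if not mask.any():
            raise ValueError(f"cluster {cl!r} is empty")
        scores = {}
        for label, genes in panel.markers.items():
            present = [gene_pos[g] for g in genes if g in gene_pos]
            scores[label] = float(logn[np.ix_(present, np.flatnonzero(mask))].mean()) if present else 0.0
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        top_label, top = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0.0
        definitive = top > 0 and (top - runner) > margin
        rows.append(
            {
                "cluster": cl,
                **{f"score_{k}": v for k, v in scores.items()},
                "assigned": top_label if definitive else "unassigned",
                "definitive": definitive,
            }
        )
    return pd.DataFrame(rows)
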