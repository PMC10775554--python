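"""Readers, writers and basic transforms for count matrices and annotation tables.

All tabular interchange is tab-separated UTF-8. Count matrices travel either as
a MatrixMarket bundle (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, the
10x convention) or as a dense TSV with genes as rows, the first column holding
the gene identifier and the header row holding sample/cell identifiers.

Gene identifiers are ENSEMBL-style; a trailing version suffix
(``ENSG00000000003.14``) is stripped before any cross-dataset matching, because
annotation releases disagree on versions while the stable ID is shared.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("cellsignal")

VALID_GROUPS = ("early_embryo", "gastrulation", "foetal", "adult")
VALID_CHEMISTRIES = ("umi", "full_length")
VALID_AGE_CLASSES = ("childhood", "adult", "control", "unspecified")


# ---------------------------------------------------------------------------
# identifiers
# ---------------------------------------------------------------------------

def strip_ensembl_version(gene_ids: Iterable[str]) -> list[str]:
    """Drop the ``.NN`` version suffix from ENSEMBL-style identifiers.

    Identifiers that are not ENSEMBL-like (no ``ENS`` prefix) are returned
    unchanged, so symbol-keyed tables pass through safely.
    """
    out = []
    for g in gene_ids:
        g = str(g)
        if g.startswith("ENS") and "." in g:
            out.append(g.split(".", 1)[0])
        else:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BulkSample:
    """A bulk transcriptome: per-gene counts with matching gene lengths.

    ``lengths`` of 1 is the "already length-normalized" sentinel used for TPM
    inputs (the GTEx dialect). ``counts`` may be non-integer (TPM, effective
    counts from pseudo-alignment).
    """

    sample_id: str
    counts: pd.Series
    lengths: pd.Series
    cohort: str = ""
    age_class: str = "unspecified"

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.lengths = self.lengths.reindex(self.counts.index).astype(float)
        if self.age_class not in VALID_AGE_CLASSES:
            raise ValueError(f"invalid age_class {self.age_class!r}")
        if self.lengths.isna().any():
            raise ValueError(
                f"sample {self.sample_id}: counts and lengths must share one gene set"
            )
        _check_finite_nonneg(self.counts.to_numpy(), f"sample {self.sample_id} counts")
        if (self.lengths.to_numpy() <= 0).any():
            raise ValueError(f"sample {self.sample_id}: gene lengths must be > 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class GeneTable:
    """Gene identifier table with optional symbols and lengths in bases."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if "gene_id" not in self.table.columns:
            raise ValueError("GeneTable requires a gene_id column")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        if "length" in self.table.columns and (self.table["length"] <= 0).any():
            raise ValueError("gene lengths must be > 0")


def _check_finite_nonneg(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{what}: non-finite entries (NaN/inf) are not allowed")
    if (x < 0).any():
        raise ValueError(f"{what}: negative entries are not allowed")


def validate_cell_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-cell annotation table (cell_id, cell_type, group, ...)."""
    required = {"cell_id", "cell_type"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annotation["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique within a dataset")
    if "group" in annotation.columns:
        bad = set(annotation["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
    return annotation


# ---------------------------------------------------------------------------
# MatrixMarket bundles
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _read_id_column(path: Path) -> pd.DataFrame:
    with _open_maybe_gz(Path(path)) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    return df


def read_mtx_bundle(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> tuple[sp.csr_matrix, pd.DataFrame, list[str]]:
    """Read a 10x-style bundle into (genes x cells matrix, features, barcodes).

    The features table has columns ``gene_id`` (first column of the file) and
    ``symbol`` when a second column is present. Dimension mismatches raise with
    the offending file named; non-integer entries are accepted with a warning
    since full-length data may be non-integer after TPM transformation.
    """
    matrix_path = Path(matrix_path)
    for p in (matrix_path, Path(features_path), Path(barcodes_path)):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    mat = scipy.io.mmread(str(matrix_path))
    mat = sp.csr_matrix(mat)
    _check_finite_nonneg(mat.data, f"{matrix_path}")
    feats = _read_id_column(Path(features_path))
    feats.columns = (["gene_id", "symbol"] + [f"col{i}" for i in range(2, feats.shape[1])])[
        : feats.shape[1]
    ]
    barcodes = _read_id_column(Path(barcodes_path))[0].tolist()
    if mat.shape[0] != len(feats):
        raise ValueError(
            f"matrix has {mat.shape[0]} rows but {features_path} lists {len(feats)} features"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[1]} columns but {barcodes_path} lists {len(barcodes)} barcodes"
        )
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        warnings.warn(
            f"{matrix_path}: non-integer entries (expected for TPM-transformed data)",
            stacklevel=2,
        )
    return mat, feats, barcodes


def write_mtx_bundle(
    out_dir: str | Path,
    matrix: sp.spmatrix | np.ndarray,
    gene_ids: Sequence[str],
    barcodes: Sequence[str],
    symbols: Sequence[str] | None = None,
) -> Path:
    """Write a genes x cells matrix as matrix.mtx + features.tsv + barcodes.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(matrix)
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise ValueError("matrix shape does not match gene/barcode lists")
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), mat)
    feats = pd.DataFrame({"gene_id": list(gene_ids)})
    feats["symbol"] = list(symbols) if symbols is not None else list(gene_ids)
    feats.to_csv(out_dir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(list(barcodes)).to_csv(
        out_dir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    return out_dir


# ---------------------------------------------------------------------------
# dense TSV dialect
# ---------------------------------------------------------------------------

def read_dense_tsv(path: str | Path) -> pd.DataFrame:
    """Read a dense genes-as-rows TSV (first column gene_id, header = sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    _check_finite_nonneg(df.to_numpy(dtype=float), str(path))
    return df


def write_dense_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df = df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column (gene_id, length) TSV into a Series in bases."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id, length")
    df.columns = ["gene_id", "length"] + list(df.columns[2:])
    s = df.set_index("gene_id")["length"].astype(float)
    if (s <= 0).any():
        raise ValueError(f"{path}: gene lengths must be > 0")
    return s


def read_bulk_samples(
    counts_path: str | Path,
    lengths_path: str | Path | None = None,
    manifest: pd.DataFrame | None = None,
) -> list[BulkSample]:
    """Read bulk samples from a dense counts TSV plus an optional lengths TSV.

    Without a lengths file all lengths are set to 1 (the TPM/GTEx dialect).
    A manifest with columns (sample_id, cohort, age_class) attaches metadata.
    """
    counts = read_dense_tsv(counts_path)
    counts.index = strip_ensembl_version(counts.index)
    if lengths_path is not None:
        lengths = read_gene_lengths(lengths_path)
        lengths.index = strip_ensembl_version(lengths.index)
    else:
        lengths = pd.Series(1.0, index=counts.index)
    meta = {}
    if manifest is not None:
        meta = manifest.set_index("sample_id").to_dict("index")
    samples = []
    for sid in counts.columns:
        m = meta.get(sid, {})
        samples.append(
            BulkSample(
                sample_id=sid,
                counts=counts[sid],
                lengths=lengths,
                cohort=str(m.get("cohort", "")),
                age_class=str(m.get("age_class", "unspecified")),
            )
        )
    return samples


def write_fit_results(path: str | Path, rows: pd.DataFrame) -> None:
    """Write long-form fit results (sample_id, [stage,] cell_type, contribution)."""
    rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def tpm_transform(counts, lengths):
    """Transcripts-per-kilobase-million transform.

    TPM_g = (y_g / l_g) / sum_h (y_h / l_h) * 1e6.  With all lengths 1 this is
    plain depth normalization to a million, which is how TPM-dialect inputs
    (gene lengths set to 1) pass through unchanged up to scale. All-zero input
    returns all zeros with a warning.
    """
    counts_arr = np.asarray(counts, dtype=float)
    lengths_arr = np.asarray(lengths, dtype=float)
    if counts_arr.shape != lengths_arr.shape:
        raise ValueError("counts and lengths must be aligned")
    if (lengths_arr <= 0).any():
        raise ValueError("gene lengths must be > 0")
    _check_finite_nonneg(counts_arr, "tpm_transform counts")
    rates = counts_arr / lengths_arr
    total = rates.sum()
    if total == 0:
        warnings.warn("tpm_transform: all counts zero; returning zeros", stacklevel=2)
        tpm = np.zeros_like(rates)
    else:
        tpm = rates / total * 1e6
    if isinstance(counts, pd.Series):
        return pd.Series(tpm, index=counts.index)
    return tpm


def tpm_transform_matrix(counts: np.ndarray | sp.spmatrix, lengths: np.ndarray):
    """Column-wise TPM for a genes x cells matrix (each cell sums to 1e6)."""
    lengths = np.asarray(lengths, dtype=float).reshape(-1, 1)
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    rates = dense / lengths
    totals = rates.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(totals > 0, rates / totals * 1e6, 0.0)
    return tpm
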