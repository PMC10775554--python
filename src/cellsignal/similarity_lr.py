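"""Logistic-regression similarity of single cells to reference cell types.

A multinomial logistic model is trained on the reference single-cell dataset
(features: per-cell counts normalized to a fixed library size, then log1p) and
applied to target cells, yielding for each target cell a probability of
similarity to each reference cell type, normalized to 1 across types. L2
regularization (inverse strength 0.1) and per-class balancing keep the model
stable in the p >> n regime and across order-of-magnitude class-size
differences; all randomness is seeded, so scoring is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from .io_formats import strip_ensembl_version, tpm_transform_matrix
from .reference_builder import filter_small_types

logger = logging.getLogger("cellsignal")

FORMAT_VERSION = "cellsignal-similarity-1"
DEFAULT_TARGET_SUM = 1e4
DEFAULT_C = 0.1
DEFAULT_MAX_ITER = 1000
MIN_GENE_COVERAGE = 0.2


def _log_normalize(counts: np.ndarray, target_sum: float) -> np.ndarray:
    """Per-cell depth normalization to ``target_sum`` followed by log1p.

    Cells are columns. All-zero cells pass through as zeros. Library-size
    scaling of a cell leaves its features unchanged by construction.
    """
    totals = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(totals > 0, counts / totals * target_sum, 0.0)
    return np.log1p(norm)


@dataclass
class SimilarityModel:
    """A trained reference model: the classifier plus its gene list and classes."""

    classifier: LogisticRegression
    gene_ids: list[str]
    classes: list[str]
    target_sum: float = DEFAULT_TARGET_SUM
    format_version: str = FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "SimilarityModel":
        model = joblib.load(path)
        if model.format_version != FORMAT_VERSION:
            raise ValueError(
                f"model format {model.format_version!r} != expected {FORMAT_VERSION!r}"
            )
        return model


def train_similarity_model(
    counts: np.ndarray | sp.spmatrix,
    gene_ids: Sequence[str],
    annotation: pd.DataFrame,
    chemistry: str = "umi",
    gene_lengths: np.ndarray | None = None,
    min_cells: int = 10,
    C: float = DEFAULT_C,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> SimilarityModel:
    """Train the multinomial logistic model on an annotated reference dataset.

    Counts are genes x cells. Small cell types (< ``min_cells``) are removed
    first; full-length chemistry is TPM-transformed before featurization.
    A class whose cells are all zero is rejected by name.
    """
    ann = filter_small_types(annotation, min_cells=min_cells)
    if ann["cell_type"].nunique() < 2:
        raise ValueError("need at least two cell types to train")
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    keep = annotation["cell_id"].isin(ann["cell_id"]).to_numpy()
    dense = dense[:, keep]
    labels = annotation.loc[keep, "cell_type"].to_numpy()
    totals = dense.sum(axis=0)
    for t in pd.unique(labels):
        if (totals[labels == t] == 0).all():
            raise ValueError(f"cell type {t!r} has only all-zero cells")
    if chemistry == "full_length":
        if gene_lengths is None:
            raise ValueError("full_length chemistry requires gene_lengths")
        dense = tpm_transform_matrix(dense, gene_lengths)
    X = _log_normalize(dense, target_sum).T  # cells x genes
    clf = LogisticRegression(
        C=C,
        max_iter=max_iter,
        class_weight="balanced",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        clf.fit(X, labels)
    return SimilarityModel(
        classifier=clf,
        gene_ids=strip_ensembl_version(gene_ids),
        classes=[str(c) for c in clf.classes_],
        target_sum=target_sum,
    )


def score_similarity(
    model: SimilarityModel,
    counts: np.ndarray | sp.spmatrix,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Probability of similarity of each target cell to each reference type.

    Target genes are matched to the model's gene list; genes the target lacks
    are imputed as zero (the coverage fraction is logged). Rows sum to 1.
    Overlap below 20% of the model's genes is an error — scores would be
    meaningless.
    """
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    gene_ids = strip_ensembl_version(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    hit = [g for g in model.gene_ids if g in pos]
    coverage = len(hit) / len(model.gene_ids)
    if coverage < MIN_GENE_COVERAGE:
        raise ValueError(
            f"target covers only {coverage:.1%} of model genes "
            f"(< {MIN_GENE_COVERAGE:.0%}); scores would be meaningless"
        )
    logger.info("similarity scoring: %.1f%% of model genes present in target", 100 * coverage)
    n_cells = dense.shape[1]
    aligned = np.zeros((len(model.gene_ids), n_cells))
    for i, g in enumerate(model.gene_ids):
        if g in pos:
            aligned[i] = dense[pos[g]]
    zero_cells = int((aligned.sum(axis=0) == 0).sum())
    if zero_cells:
        logger.warning(
            "%d target cells have zero coverage of model genes; "
            "their scores fall back to the model's baseline prediction",
            zero_cells,
        )
    X = _log_normalize(aligned, model.target_sum).T
    proba = model.classifier.predict_proba(X)
    proba = proba / proba.sum(axis=1, keepdims=True)
    index = list(cell_ids) if cell_ids is not None else [f"cell_{i}" for i in range(n_cells)]
    return pd.DataFrame(proba, index=pd.Index(index, name="cell_id"), columns=model.classes)


def aggregate_similarity_by_group(
    similarity: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Sum per-cell probabilities over reference cell types within each group."""
    group_map = meta.set_index("cell_type")["group"]
    cols = {}
    for g in group_map.unique():
        members = [c for c in similarity.columns if group_map.get(c) == g]
        if members:
            cols[g] = similarity[members].sum(axis=1)
    return pd.DataFrame(cols)
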