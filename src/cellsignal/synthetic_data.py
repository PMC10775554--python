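"""Synthetic single-cell atlases and bulk mixtures with known ground truth.

The generator emulates the structure of a multi-source reference atlas:
distinct per-cell-type expression programs across developmental groups
(early embryo, gastrulation, foetal, adult), Poisson or negative-binomial
counts with per-cell library-size variation, and an optional per-kilobase
gene-length bias for full-length (Smart-Seq2-class) chemistry. Bulk mixtures
are Poisson samples of a known convex combination of type programs plus an
optional planted novel (out-of-reference) program, so every downstream fit
can be checked against the planted truth.

Randomness is hierarchical: one global seed spawns independent child streams
per cell type (and one for the bulk sampler), so appending a cell type to a
spec does not perturb the draws of earlier types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import VALID_CHEMISTRIES, VALID_GROUPS, BulkSample, write_mtx_bundle

logger = logging.getLogger("cellsignal")


@dataclass
class CellTypeSpec:
    """One reference cell type: a name, a developmental group, and a program."""

    name: str
    group: str
    n_cells: int
    expression_program: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        self.expression_program = np.asarray(self.expression_program, dtype=float)
        if (self.expression_program < 0).any():
            raise ValueError(f"type {self.name}: expression program must be non-negative")
        if not (self.expression_program > 0).any():
            raise ValueError(f"type {self.name}: program needs >=1 positive entry")


@dataclass
class AtlasSpec:
    """Specification of a synthetic reference atlas.

    ``dispersion`` is the negative-binomial overdispersion a such that
    var = mu + a * mu^2; 0 means Poisson. ``library_size_range`` is the
    (min, max) of the per-cell expected total count, drawn uniformly.
    Full-length chemistry multiplies each gene's rate by gene_length/1000
    (per-kilobase read-count bias) before sampling.
    """

    n_genes: int
    cell_types: list[CellTypeSpec]
    dispersion: float = 0.0
    library_size_range: tuple[float, float] = (5000.0, 20000.0)
    chemistry: str = "umi"
    gene_lengths: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.chemistry not in VALID_CHEMISTRIES:
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must satisfy 0 < min <= max")
        for ct in self.cell_types:
            if ct.expression_program.shape != (self.n_genes,):
                raise ValueError(
                    f"type {ct.name}: program length {ct.expression_program.size}"
                    f" != n_genes {self.n_genes}"
                )
        if self.gene_lengths is None:
            self.gene_lengths = np.full(self.n_genes, 1000.0)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene_lengths must be > 0")

    @property
    def gene_ids(self) -> list[str]:
        return [f"ENSG{i:011d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Ground-truth mixture for one synthetic bulk sample.

    ``true_fractions`` maps cell-type name to its share of the expected bulk
    signal; ``novel_fraction`` is the share carried by a program absent from
    the reference (the planted unexplained component). Fractions plus the
    novel fraction must sum to 1.
    """

    true_fractions: Mapping[str, float]
    novel_fraction: float = 0.0
    novel_program: np.ndarray | None = None
    depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.true_fractions.values()) + self.novel_fraction
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fractions + novel_fraction must sum to 1, got {total}")
        if any(v < 0 for v in self.true_fractions.values()) or not (
            0 <= self.novel_fraction <= 1
        ):
            raise ValueError("fractions must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.novel_program is not None:
            self.novel_program = np.asarray(self.novel_program, dtype=float)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def _sample_counts(
    rng: np.random.Generator,
    rates: np.ndarray,
    dispersion: float,
) -> np.ndarray:
    """Poisson(rates) or gamma-Poisson with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(rates)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, rates / shape)
    return rng.poisson(lam)


def simulate_reference(spec: AtlasSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw a genes x cells count matrix and its cell annotation table.

    Each cell's expected profile is the type's program (length-biased for
    full-length chemistry), normalized to sum 1 and scaled by a library size
    drawn uniformly from ``library_size_range``. Types requesting zero cells
    are omitted with a warning.
    """
    children = np.random.SeedSequence(spec.seed).spawn(len(spec.cell_types))
    blocks: list[np.ndarray] = []
    ann_rows: list[dict] = []
    lo, hi = spec.library_size_range
    for ct, ss in zip(spec.cell_types, children):
        if ct.n_cells == 0:
            logger.warning("cell type %s requested 0 cells; omitted", ct.name)
            continue
        rng = np.random.default_rng(ss)
        program = ct.expression_program.copy()
        if spec.chemistry == "full_length":
            program = program * (spec.gene_lengths / 1000.0)
        program = program / program.sum()
        lib_sizes = rng.uniform(lo, hi, size=ct.n_cells)
        rates = program[:, None] * lib_sizes[None, :]
        blocks.append(_sample_counts(rng, rates, spec.dispersion))
        for j in range(ct.n_cells):
            ann_rows.append(
                {
                    "cell_id": f"{ct.name}_c{j}",
                    "cell_type": ct.name,
                    "group": ct.group,
                    "dataset": "synthetic",
                    "chemistry": spec.chemistry,
                    "tissue": ct.tissue,
                }
            )
    if not blocks:
        raise ValueError("no cells simulated: every type requested 0 cells")
    counts = np.concatenate(blocks, axis=1)
    annotation = pd.DataFrame(ann_rows)
    return counts, annotation


# ---------------------------------------------------------------------------
# bulk simulation
# ---------------------------------------------------------------------------

def expected_bulk_proportions(
    truth: SyntheticTruth,
    profiles: pd.DataFrame,
    gene_lengths: np.ndarray | pd.Series,
) -> np.ndarray:
    """Expected per-gene count proportions of the mixture (the sampling mean / depth)."""
    missing = set(truth.true_fractions) - set(profiles.columns)
    if missing:
        raise ValueError(f"fraction keys not in profiles: {sorted(missing)}")
    lengths = np.asarray(gene_lengths, dtype=float)
    norm = profiles.to_numpy(dtype=float)
    norm = norm / norm.sum(axis=0, keepdims=True)
    mean = np.zeros(len(profiles))
    for name, frac in truth.true_fractions.items():
        mean += frac * norm[:, profiles.columns.get_loc(name)]
    if truth.novel_fraction > 0:
        if truth.novel_program is None:
            raise ValueError("novel_fraction > 0 requires a novel_program")
        novel = truth.novel_program / truth.novel_program.sum()
        mean += truth.novel_fraction * novel
    mean = mean * lengths
    return mean / mean.sum()


def simulate_bulk(
    truth: SyntheticTruth,
    profiles: pd.DataFrame,
    gene_lengths: np.ndarray | pd.Series,
    sample_id: str = "synthetic_bulk",
    cohort: str = "synthetic",
    age_class: str = "unspecified",
) -> BulkSample:
    """Poisson-sample a bulk transcriptome from a known mixture of programs.

    Expected count of gene g is depth * proportional to
    l_g * (sum_c fraction_c * f_gc + novel term): longer genes accrue more
    reads at equal molar abundance, matching counts-plus-lengths bulk inputs.
    """
    prop = expected_bulk_proportions(truth, profiles, gene_lengths)
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(1)[0])
    counts = rng.poisson(prop * truth.depth).astype(float)
    idx = pd.Index(profiles.index, name="gene_id")
    return BulkSample(
        sample_id=sample_id,
        counts=pd.Series(counts, index=idx),
        lengths=pd.Series(np.asarray(gene_lengths, dtype=float), index=idx),
        cohort=cohort,
        age_class=age_class,
    )


# ---------------------------------------------------------------------------
# convenience atlas factories
# ---------------------------------------------------------------------------

def random_programs(
    n_genes: int,
    n_types: int,
    rng: np.random.Generator,
    marker_fraction: float = 0.1,
    marker_boost: float = 20.0,
) -> np.ndarray:
    """Draw n_types programs sharing a lognormal baseline, each with a private
    block of boosted marker genes so types are distinguishable."""
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    programs = np.tile(base, (n_types, 1)) * rng.lognormal(0.0, 0.3, size=(n_types, n_genes))
    block = max(1, int(n_genes * marker_fraction / n_types))
    for t in range(n_types):
        sl = slice(t * block, (t + 1) * block)
        programs[t, sl] *= marker_boost
    return programs


def make_atlas_spec(
    n_genes: int,
    type_defs: Sequence[tuple[str, str, int]],
    seed: int,
    dispersion: float = 0.0,
    chemistry: str = "umi",
    library_size_range: tuple[float, float] = (5000.0, 20000.0),
    marker_boost: float = 20.0,
) -> AtlasSpec:
    """Build an AtlasSpec with random but distinguishable programs.

    ``type_defs`` is a sequence of (name, group, n_cells). Program randomness
    derives from ``seed`` but uses a dedicated stream, separate from the
    count-sampling streams.
    """
    prog_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA71A5]))
    programs = random_programs(n_genes, len(type_defs), prog_rng, marker_boost=marker_boost)
    cell_types = [
        CellTypeSpec(name=name, group=group, n_cells=n, expression_program=programs[i])
        for i, (name, group, n) in enumerate(type_defs)
    ]
    return AtlasSpec(
        n_genes=n_genes,
        cell_types=cell_types,
        dispersion=dispersion,
        chemistry=chemistry,
        library_size_range=library_size_range,
        seed=seed,
    )


def make_disjoint_novel_scenario(
    n_genes: int,
    type_defs: Sequence[tuple[str, str, int]],
    seed: int,
    ref_gene_fraction: float = 0.075,
    **atlas_kwargs,
) -> tuple[AtlasSpec, np.ndarray]:
    """Atlas with compact reference support plus a disjoint diffuse novel program.

    Reference programs live on the first ``ref_gene_fraction`` share of genes
    (cell-identity programs concentrate their mass in a limited gene
    repertoire); the novel out-of-reference component is uniform over the
    complement, emulating diffuse signal from states absent from the
    reference — the regime in which the flat-intercept unexplained fraction
    is a calibrated estimate of the planted novel mass. Returns
    (atlas spec, novel program).
    """
    n_ref = max(len(type_defs) + 1, int(round(n_genes * ref_gene_fraction)))
    spec = make_atlas_spec(n_ref, type_defs, seed=seed, **atlas_kwargs)
    padded = [
        CellTypeSpec(
            name=ct.name,
            group=ct.group,
            n_cells=ct.n_cells,
            expression_program=np.concatenate(
                [ct.expression_program, np.zeros(n_genes - n_ref)]
            ),
            tissue=ct.tissue,
        )
        for ct in spec.cell_types
    ]
    full_spec = AtlasSpec(
        n_genes=n_genes,
        cell_types=padded,
        dispersion=spec.dispersion,
        library_size_range=spec.library_size_range,
        chemistry=spec.chemistry,
        seed=seed,
    )
    novel = np.zeros(n_genes)
    novel[n_ref:] = 1.0
    return full_spec, novel


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_reference_dataset(
    out_dir: str | Path,
    counts: np.ndarray,
    annotation: pd.DataFrame,
    gene_ids: Sequence[str],
) -> Path:
    """Write a simulated dataset as an MTX bundle plus annotation.tsv."""
    out_dir = Path(out_dir)
    write_mtx_bundle(out_dir, counts, gene_ids, annotation["cell_id"].tolist())
    annotation.to_csv(out_dir / "annotation.tsv", sep="\t", index=False)
    return out_dir


def write_truth_table(path: str | Path, truth: SyntheticTruth) -> None:
    """Truth table as TSV with header (cell_type, fraction); novel under ``novel``."""
    rows = [{"cell_type": k, "fraction": v} for k, v in truth.true_fractions.items()]
    if truth.novel_fraction > 0:
        rows.append({"cell_type": "novel", "fraction": truth.novel_fraction})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
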