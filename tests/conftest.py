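import numpy as np
import pandas as pd
import pytest

import cellsignal as cs


@pytest.fixture(scope="session")
def small_atlas():
    """A 2-type UMI atlas (foetal + adult) with its spec and annotation."""
    spec = cs.make_atlas_spec(
        300, [("hep_f", "foetal", 60), ("hep_a", "adult", 60)], seed=11
    )
    counts, annotation = cs.simulate_reference(spec)
    return spec, counts, annotation


@pytest.fixture(scope="session")
def small_reference(small_atlas):
    spec, counts, annotation = small_atlas
    ds = cs.ReferenceDataset(counts=counts, gene_ids=spec.gene_ids, annotation=annotation)
    return cs.build_profiles([ds])


@pytest.fixture(scope="session")
def true_profiles(small_atlas):
    spec, _, _ = small_atlas
    return pd.DataFrame(
        {ct.name: ct.expression_program for ct in spec.cell_types},
        index=spec.gene_ids,
    )


@pytest.fixture(scope="session")
def four_group_atlas():
    """An atlas spanning all four developmental groups, two types each."""
    defs = [
        ("epiblast", "early_embryo", 40),
        ("hypoblast", "early_embryo", 40),
        ("mesoderm", "gastrulation", 40),
        ("endoderm", "gastrulation", 40),
        ("hep_foetal", "foetal", 40),
        ("ery_foetal", "foetal", 40),
        ("hep_adult", "adult", 40),
        ("tcell_adult", "adult", 40),
    ]
    spec = cs.make_atlas_spec(600, defs, seed=23)
    counts, annotation = cs.simulate_reference(spec)
    ds = cs.ReferenceDataset(counts=counts, gene_ids=spec.gene_ids, annotation=annotation)
    reference = cs.build_profiles([ds])
    profiles = pd.DataFrame(
        {ct.name: ct.expression_program for ct in spec.cell_types},
        index=spec.gene_ids,
    )
    return spec, reference, profiles


def random_fit_instance(rng, n_genes=None, n_types=None, depth=2000):
    """A small random (bulk, reference) pair for property tests."""
    G = n_genes or int(rng.integers(4, 10))
    K = n_types or int(rng.integers(1, 4))
    genes = [f"G{i}" for i in range(G)]
    F = rng.dirichlet(np.ones(G), size=K).T
    profiles = pd.DataFrame(F, index=genes, columns=[f"T{k}" for k in range(K)])
    meta = pd.DataFrame(
        {
            "cell_type": profiles.columns,
            "group": ["foetal"] * K,
            "tissue": "",
            "n_cells": [20] * K,
        }
    )
    reference = cs.ReferenceProfileSet(profiles, meta, pd.Series(1.0, index=genes))
    z = rng.poisson(rng.dirichlet(np.ones(G)) * depth).astype(float)
    bulk = cs.BulkSample("rand", pd.Series(z, index=genes), pd.Series(1.0, index=genes))
    return bulk, reference
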