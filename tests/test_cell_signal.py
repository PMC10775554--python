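import warnings

import numpy as np
import pandas as pd
import pytest

import cellsignal as cs
from cellsignal.cell_signal import grid_search_fit, weighted_poisson_deviance

from conftest import random_fit_instance


def _tiny_reference(F, genes, groups=None):
    K = F.shape[1]
    cols = [f"T{k}" for k in range(K)]
    profiles = pd.DataFrame(F, index=genes, columns=cols)
    meta = pd.DataFrame(
        {
            "cell_type": cols,
            "group": groups or ["foetal"] * K,
            "tissue": "",
            "n_cells": [20] * K,
        }
    )
    return cs.ReferenceProfileSet(profiles, meta, pd.Series(1.0, index=genes))


def _bulk(z, genes, lengths=None, sample_id="s"):
    return cs.BulkSample(
        sample_id,
        pd.Series(np.asarray(z, float), index=genes),
        pd.Series(lengths if lengths is not None else np.ones(len(genes)), index=genes),
    )


@pytest.fixture(autouse=True)
def _quiet_small_instance_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*genes in the fit.*")
        yield


class TestFitSignals:
    def test_pure_in_reference_sample(self, small_reference):
        profile = small_reference.profiles["hep_f"]
        bulk = _bulk(profile.to_numpy() * 10**6, small_reference.gene_ids)
        fit = cs.fit_signals(bulk, small_reference)
        assert fit.contributions["hep_f"] >= 0.99
        assert fit.intercept <= 0.01
        assert fit.pseudo_r2 >= 0.99

    def test_matches_grid_oracle_on_disjoint_three_gene_instance(self):
        genes = ["g0", "g1", "g2"]
        F = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        ref = _tiny_reference(F, genes)
        fit = cs.fit_signals(_bulk([30, 0, 70], genes), ref)
        w_grid, ll_grid = grid_search_fit(
            np.array([30.0, 0.0, 70.0]), F, resolution=1e-3
        )
        fitted = np.r_[fit.contributions.to_numpy(), fit.intercept]
        assert np.abs(fitted - w_grid).max() < 1e-3
        assert fit.log_likelihood >= ll_grid - 1e-4

    def test_recovers_planted_mixture_with_novel_component(self):
        spec, novel = cs.synthetic_data.make_disjoint_novel_scenario(
            2000, [("A", "foetal", 200), ("B", "adult", 200)], seed=31
        )
        counts, ann = cs.simulate_reference(spec)
        ref = cs.build_profiles(
            [cs.ReferenceDataset(counts=counts, gene_ids=spec.gene_ids, annotation=ann)]
        )
        profiles = pd.DataFrame(
            {ct.name: ct.expression_program for ct in spec.cell_types},
            index=spec.gene_ids,
        )
        truth = cs.SyntheticTruth(
            {"A": 0.5, "B": 0.3}, novel_fraction=0.2, novel_program=novel,
            depth=10**6, seed=32,
        )
        bulk = cs.simulate_bulk(truth, profiles, np.full(2000, 1000.0))
        fit = cs.fit_signals(bulk, ref)
        assert abs(fit.intercept - 0.2) < 0.05
        assert abs(fit.contributions["A"] - 0.5) < 0.05
        assert abs(fit.contributions["B"] - 0.3) < 0.05

    def test_length_normalization_undoes_length_bias(self, small_reference, small_atlas):
        spec, _, _ = small_atlas
        lengths = np.random.default_rng(4).uniform(300, 5000, 300)
        profiles = pd.DataFrame(
            {ct.name: ct.expression_program for ct in spec.cell_types},
            index=spec.gene_ids,
        )
        truth = cs.SyntheticTruth({"hep_f": 0.8, "hep_a": 0.2}, depth=10**6, seed=5)
        bulk = cs.simulate_bulk(truth, profiles, lengths)
        fit = cs.fit_signals(bulk, small_reference)
        assert abs(fit.contributions["hep_f"] - 0.8) < 0.05

    def test_empty_overlap_is_an_error(self, small_reference):
        bulk = _bulk([1.0, 2.0], ["X1", "X2"])
        with pytest.raises(ValueError, match="overlap"):
            cs.fit_signals(bulk, small_reference)

    def test_normalization_and_scale_invariance_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            bulk, ref = random_fit_instance(rng)
            fit = cs.fit_signals(bulk, ref)
            assert fit.contributions.sum() + fit.intercept == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= fit.pseudo_r2 <= 1.0
            scaled = cs.BulkSample(
                bulk.sample_id, bulk.counts * 7.5, bulk.lengths
            )
            fit2 = cs.fit_signals(scaled, ref)
            np.testing.assert_allclose(
                fit.contributions, fit2.contributions, atol=1e-6
            )
            assert abs(fit.pseudo_r2 - fit2.pseudo_r2) < 1e-6

    def test_fitted_likelihood_meets_grid_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            bulk, ref = random_fit_instance(rng, n_genes=6)
            fit = cs.fit_signals(bulk, ref)
            z = bulk.counts.to_numpy()
            _, ll_grid = grid_search_fit(z, ref.profiles.to_numpy(), resolution=1e-3)
            assert fit.log_likelihood >= ll_grid - 1e-4

    def test_noise_degrades_goodness_of_fit_monotonically(self, small_reference):
        rng = np.random.default_rng(8)
        profile = small_reference.profiles["hep_a"].to_numpy()
        rhos = []
        for noise in [0.0, 0.2, 0.5, 1.0, 2.0]:
            reps = []
            for _ in range(20):
                clean = profile * 10**5
                noisy = clean + rng.poisson(noise * clean.mean(), size=clean.size)
                fit = cs.fit_signals(
                    _bulk(noisy, small_reference.gene_ids), small_reference
                )
                reps.append(fit.pseudo_r2)
            rhos.append(np.mean(reps))
        assert all(a >= b - 1e-12 for a, b in zip(rhos, rhos[1:]))

    def test_housekeeping_genes_enter_with_half_weight(self):
        genes = ["g0", "g1", "g2", "g3"]
        F = np.array([[0.4], [0.3], [0.2], [0.1]])
        ref = _tiny_reference(F, genes)
        ref.gene_weights.loc["g0"] = 0.5
        z = np.array([10.0, 30.0, 20.0, 40.0])
        fit = cs.fit_signals(_bulk(z, genes), ref)
        w_grid, ll_grid = grid_search_fit(
            z, F, w=np.array([0.5, 1.0, 1.0, 1.0]), resolution=1e-3
        )
        assert fit.log_likelihood >= ll_grid - 1e-4
        fitted = np.r_[fit.contributions.to_numpy(), fit.intercept]
        assert np.abs(fitted - w_grid).max() < 2e-3


class TestGeneExclusion:
    def test_dropping_uninformative_gene_changes_almost_nothing(self, small_reference):
        # a gene with zero bulk count and zero reference mass carries no
        # mixture signal; its only role is the intercept's flat cost there,
        # so dropping it moves the contributions by at most O(w0 / G)
        profile = small_reference.profiles["hep_f"].copy()
        z = profile.to_numpy() * 10**5
        z[5] = 0.0
        bulk = _bulk(z, small_reference.gene_ids)
        ref = small_reference
        prof2 = ref.profiles.copy()
        prof2.iloc[5, :] = 0.0
        incl = ~prof2.index.isin(ref.excluded_genes)
        prof2 = prof2 / prof2.loc[incl].sum(axis=0)
        ref2 = cs.ReferenceProfileSet(
            prof2, ref.meta.copy(), ref.gene_weights.copy(), dict(ref.excluded_genes)
        )
        f1 = cs.fit_signals(bulk, ref2)
        f2 = cs.fit_signals_excluding(bulk, ref2, [ref.gene_ids[5]])
        np.testing.assert_allclose(
            f1.contributions, f2.contributions, atol=1e-4
        )

    def test_empty_drop_list_is_identity(self, small_reference):
        bulk = _bulk(
            small_reference.profiles["hep_a"].to_numpy() * 10**4,
            small_reference.gene_ids,
        )
        f1 = cs.fit_signals(bulk, small_reference)
        f2 = cs.fit_signals_excluding(bulk, small_reference, [])
        pd.testing.assert_series_equal(f1.contributions, f2.contributions)
        assert f1.gene_set_hash == f2.gene_set_hash

    def test_weight_zero_equals_gene_removal_exactly(self):
        # dropping a gene (weight 0) must behave exactly as if the gene had
        # never been measured in the bulk sample: bitwise-equal contributions
        rng = np.random.default_rng(9)
        for _ in range(20):
            bulk, ref = random_fit_instance(rng, n_genes=8)
            drop = [ref.gene_ids[int(rng.integers(0, 8))]]
            f_drop = cs.fit_signals_excluding(bulk, ref, drop)
            keep = [g for g in bulk.gene_ids if g not in drop]
            bulk_removed = cs.BulkSample(
                bulk.sample_id, bulk.counts.loc[keep], bulk.lengths.loc[keep]
            )
            f_removed = cs.fit_signals(bulk_removed, ref)
            assert (
                f_drop.contributions.to_numpy().tobytes()
                == f_removed.contributions.to_numpy().tobytes()
            )
            assert f_drop.intercept == f_removed.intercept

    def test_dominant_type_survives_marker_drop(self):
        # half of type A's mass on one gene; dropping it must not dethrone A
        genes = [f"g{i}" for i in range(6)]
        A = np.array([0.5, 0.3, 0.2, 0.0, 0.0, 0.0])
        B = np.array([0.0, 0.0, 0.0, 0.1, 0.4, 0.5])
        F = np.c_[A, B]
        ref = _tiny_reference(F, genes)
        z = 0.9 * A * 1000 + 0.1 * B * 1000
        fit = cs.fit_signals_excluding(_bulk(z, genes), ref, ["g0"])
        assert fit.contributions.idxmax() == "T0"
        keep = np.array([1, 2, 3, 4, 5])
        Fr = F[keep] / F[keep].sum(axis=0)
        _, ll_grid = grid_search_fit(z[keep], Fr, resolution=1e-3)
        assert fit.log_likelihood >= ll_grid - 1e-4

    def test_unknown_drop_gene_warns(self, small_reference):
        bulk = _bulk(
            small_reference.profiles["hep_f"].to_numpy() * 1000,
            small_reference.gene_ids,
        )
        with pytest.warns(UserWarning, match="not in gene universe"):
            cs.fit_signals_excluding(bulk, small_reference, ["NOT_A_GENE"])


class TestSummaryScores:
    def test_all_mass_on_foetal_types(self, small_reference):
        bulk = _bulk(
            small_reference.profiles["hep_f"].to_numpy() * 10**6,
            small_reference.gene_ids,
        )
        sub = small_reference.subset_types(["hep_f"])
        score = cs.summarize_groups(cs.fit_signals(bulk, sub), sub)
        assert score.foetalness == pytest.approx(1.0, abs=0.01)

    def test_scores_are_direct_sums(self):
        fit = cs.SignalFit(
            sample_id="s",
            contributions=pd.Series({"foetal_hep": 0.4, "adult_hep": 0.35}),
            intercept=0.25,
            pseudo_r2=0.9,
            n_iter=1,
            converged=True,
            log_likelihood=0.0,
            gene_set_hash="x",
        )
        meta = pd.DataFrame(
            {
                "cell_type": ["foetal_hep", "adult_hep"],
                "group": ["foetal", "adult"],
                "tissue": ["", ""],
                "n_cells": [20, 20],
            }
        )
        profiles = pd.DataFrame(
            {"foetal_hep": [0.5, 0.5], "adult_hep": [0.5, 0.5]}, index=["g0", "g1"]
        )
        ref = cs.ReferenceProfileSet(profiles, meta, pd.Series(1.0, index=["g0", "g1"]))
        score = cs.summarize_groups(fit, ref)
        assert score.foetalness == pytest.approx(0.4)
        assert score.adultness == pytest.approx(0.35)
        assert score.unexplained == pytest.approx(0.25)
        assert sum(score.group_scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_absent_group_scores_zero(self, small_reference):
        bulk = _bulk(
            small_reference.profiles["hep_a"].to_numpy() * 10**5,
            small_reference.gene_ids,
        )
        score = cs.summarize_groups(cs.fit_signals(bulk, small_reference), small_reference)
        assert score.embryoness == 0.0

    def test_missing_group_label_is_an_error(self, small_reference):
        bulk = _bulk(
            small_reference.profiles["hep_a"].to_numpy() * 10**4,
            small_reference.gene_ids,
        )
        fit = cs.fit_signals(bulk, small_reference)
        broken = small_reference.meta.copy()
        broken.loc[0, "group"] = np.nan
        ref2 = cs.ReferenceProfileSet(
            small_reference.profiles.copy(), broken,
            small_reference.gene_weights.copy(),
        )
        with pytest.raises(ValueError, match="group"):
            cs.summarize_groups(fit, ref2)


class TestProgressiveFit:
    def test_single_full_stage_equals_plain_fit(self, four_group_atlas):
        _, reference, profiles = four_group_atlas
        truth = cs.SyntheticTruth(
            {"hep_adult": 0.6, "tcell_adult": 0.4}, depth=10**5, seed=41
        )
        bulk = cs.simulate_bulk(truth, profiles, np.full(600, 1000.0))
        stages = {"full": ["early_embryo", "gastrulation", "foetal", "adult"]}
        [staged] = cs.progressive_fit(bulk, reference, stages)
        plain = cs.fit_signals(bulk, reference)
        np.testing.assert_allclose(staged.contributions, plain.contributions, atol=1e-12)
        assert staged.stage == "full"

    def test_adult_bulk_unexplained_shrinks_with_reference_completeness(
        self, four_group_atlas
    ):
        _, reference, profiles = four_group_atlas
        truth = cs.SyntheticTruth({"hep_adult": 1.0}, depth=10**5, seed=42)
        bulk = cs.simulate_bulk(truth, profiles, np.full(600, 1000.0))
        stages = {
            "embryo": ["early_embryo"],
            "embryo_gastrulation": ["early_embryo", "gastrulation"],
            "full": ["early_embryo", "gastrulation", "foetal", "adult"],
        }
        fits = cs.progressive_fit(bulk, reference, stages)
        assert fits[0].intercept > fits[2].intercept
        assert fits[2].intercept < 0.05

    def test_embryonic_bulk_stays_embryonic_across_stages(self, four_group_atlas):
        # blastoid-analogue behaviour: embryonic signal survives reference expansion
        _, reference, profiles = four_group_atlas
        truth = cs.SyntheticTruth(
            {"epiblast": 0.7, "hypoblast": 0.3}, depth=10**5, seed=43
        )
        bulk = cs.simulate_bulk(truth, profiles, np.full(600, 1000.0))
        stages = {
            "embryo": ["early_embryo"],
            "full": ["early_embryo", "gastrulation", "foetal", "adult"],
        }
        for fit in cs.progressive_fit(bulk, reference, stages):
            sub_types = fit.contributions.index
            embry = sum(
                fit.contributions[ct]
                for ct in sub_types
                if reference.group_of(ct) == "early_embryo"
            )
            assert embry >= 0.9

    def test_empty_stage_is_an_error(self, small_reference):
        bulk = _bulk(
            small_reference.profiles["hep_f"].to_numpy() * 1000,
            small_reference.gene_ids,
        )
        with pytest.raises(ValueError, match="zero reference cell types"):
            cs.progressive_fit(bulk, small_reference, {"bad": ["gastrulation"]})


class TestPseudoR2:
    def test_null_model_scores_zero(self):
        # a bulk with no relation to the reference shape and flat truth:
        # fit cannot beat the intercept-only null by much
        genes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(10)
        F = rng.dirichlet(np.ones(40), size=2).T
        ref = _tiny_reference(F, genes)
        z = np.full(40, 50.0)  # exactly flat -> the intercept explains everything
        fit = cs.fit_signals(_bulk(z, genes), ref)
        mu_null = np.full(40, 50.0)
        assert weighted_poisson_deviance(z, mu_null, np.ones(40)) == 0.0
        assert fit.pseudo_r2 in (0.0, 1.0)  # degenerate null handled, bounded

    def test_pseudo_r2_bounded_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            bulk, ref = random_fit_instance(rng)
            assert 0.0 <= cs.fit_signals(bulk, ref).pseudo_r2 <= 1.0
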