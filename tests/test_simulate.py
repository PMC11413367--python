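"""Generator determinism, planted structure, and recovery properties."""

import numpy as np
import pytest
import scipy.stats

from nicherx.errors import ConfigError
from nicherx.pipeline import planted_enrichment_stat

from nicherx.simulate import (
    ACTIVATION_PROGRAM,
    SimConfig,
    clinical_fixture,
    null_config,
    simulate_drug_dictionary,
    simulate_single_cell,
    simulate_spatial,
    simulate_spot_mixtures,
)


class TestDeterminism:
    def test_spatial_bit_identical_under_seed(self, small_config):
        a, coords_a, truth_a = simulate_spatial(small_config, seed=3)
        b, coords_b, truth_b = simulate_spatial(small_config, seed=3)
        assert (a.values != b.values).nnz == 0
        assert coords_a.table.equals(coords_b.table)
        assert truth_a.obs_table.equals(truth_b.obs_table)

    def test_single_cell_and_drugs_deterministic(self, small_config):
        a, _ = simulate_single_cell(small_config, seed=9)
        b, _ = simulate_single_cell(small_config, seed=9)
        assert (a.values != b.values).nnz == 0
        da = simulate_drug_dictionary(small_config, seed=9)
        db = simulate_drug_dictionary(small_config, seed=9)
        assert [(d.drug_id, tuple(d.targets)) for d in da] == [
            (d.drug_id, tuple(d.targets)) for d in db
        ]

    def test_different_seeds_differ(self, small_config):
        a, _, _ = simulate_spatial(small_config, seed=1)
        b, _, _ = simulate_spatial(small_config, seed=2)
        assert (a.values != b.values).nnz > 0


class TestSpatial:
    def test_counts_are_nonnegative_integers_and_truth_covers_all(self, small_config):
        matrix, coords, truth = simulate_spatial(small_config, seed=0)
        data = matrix.values.data
        assert np.all(data >= 0) and np.all(data == np.floor(data))
        assert set(truth.obs_table["obs_id"]) == set(matrix.obs_ids)
        assert set(coords.table["obs_id"]) == set(matrix.obs_ids)

    def test_same_label_spots_are_spatially_contiguous(self, small_config):
        """Voronoi patches: a spot's nearest neighbors mostly share its label."""
        from nicherx.spatial import build_knn_graph

        _, coords, truth = simulate_spatial(small_config, seed=4)
        graph = build_knn_graph(coords, k=6)
        labels = truth.labels().reindex(graph.obs_ids).to_numpy()
        same = labels[graph.edges[:, 0]] == labels[graph.edges[:, 1]]
        assert same.mean() > 0.75

    def test_too_few_spots_rejected(self, small_config):
        small_config.spots_per_sample = 3
        with pytest.raises(ConfigError):
            simulate_spatial(small_config, seed=0)

    def test_activation_program_elevated_in_inflamed(self, small_config):
        """Inflamed spots express the activation program above normal
        glomeruli in every one of 20 seeds."""
        hits = 0
        for seed in range(20):
            matrix, _, truth = simulate_spatial(small_config, seed=seed)
            idx = matrix.gene_index(ACTIVATION_PROGRAM)
            labels = truth.labels().reindex(matrix.obs_ids).to_numpy()
            program = np.asarray(matrix.values[idx, :].sum(axis=0)).ravel()
            totals = np.asarray(matrix.values.sum(axis=0)).ravel()
            frac = program / np.maximum(totals, 1)
            inflamed = np.isin(labels, ["inflamed_glomerular", "inflamed_interstitial"])
            normal = labels == "normal_glomeruli"
            if inflamed.any() and normal.any() and frac[inflamed].mean() > frac[normal].mean():
                hits += 1
        assert hits == 20


class TestSingleCell:
    def test_tissue_sizes_match_config(self, small_config):
        matrix, truth = simulate_single_cell(small_config, seed=0)
        sizes = truth.obs_table["tissue"].value_counts().to_dict()
        assert sizes == small_config.n_cells

    def test_cluster_proportions_within_binomial_ci(self, small_config):
        _, truth = simulate_single_cell(small_config, seed=2)
        kidney = truth.obs_table[truth.obs_table["tissue"] == "kidney"]
        n = len(kidney)
        for spec in small_config.cell_clusters:
            observed = (kidney["label"] == spec.name).sum()
            p = spec.proportions["kidney"]
            lo, hi = scipy.stats.binom.interval(0.9999, n, p)
            assert lo <= observed <= hi, spec.name

    def test_teff_enriched_in_kidney(self, small_config):
        _, truth = simulate_single_cell(small_config, seed=7)
        table = truth.obs_table
        for tissue, expected in [("kidney", 0.70), ("blood", 0.20)]:
            sub = table[table["tissue"] == tissue]
            frac = sub["label"].isin(["CD4_Teff", "CD8_Teff"]).mean()
            assert abs(frac - expected) < 0.1

    def test_unknown_tissue_rejected(self, small_config):
        small_config.n_cells = {"brain": 100}
        with pytest.raises(ConfigError, match="brain"):
            small_config.validate()
            simulate_single_cell(small_config, seed=0)


class TestDrugDictionary:
    def test_planted_drug_is_l04_approved_viable(self, small_config):
        drugs = simulate_drug_dictionary(small_config, seed=0)
        planted = drugs[0]
        assert planted.drug_id == "D_PLANTED"
        assert planted.atc_code.startswith("L04")
        assert planted.approved and planted.viable
        assert set(planted.targets) <= set(ACTIVATION_PROGRAM)

    def test_no_decoys_gives_single_record(self, small_config):
        small_config.n_decoy_drugs = 0
        assert len(simulate_drug_dictionary(small_config, seed=0)) == 1

    def test_decoy_set_exercises_all_downstream_filters(self, small_config):
        drugs = simulate_drug_dictionary(small_config, seed=0)
        ids = {d.drug_id: d for d in drugs}
        assert any(d.atc_code.startswith("L03") for d in drugs)
        assert not ids["D_UNAPPROVED"].approved
        assert not ids["D_UNVIABLE"].viable
        pt_program = next(c.program for c in small_config.compartments if c.name == "PT")
        assert set(ids["D_PT_DECOY"].targets) <= set(pt_program)

    def test_absent_target_rejected(self, small_config):
        small_config.planted_drug.targets = ["NOT_A_GENE"]
        with pytest.raises(ConfigError, match="NOT_A_GENE"):
            simulate_drug_dictionary(small_config, seed=0)


class TestMixtures:
    def test_proportions_sum_to_one(self, small_config):
        import pandas as pd

        sig = pd.DataFrame(
            {"A": [5.0, 1.0, 0.1], "B": [0.1, 2.0, 6.0]}, index=["g1", "g2", "g3"]
        )
        _, truth = simulate_spot_mixtures(sig, n_mixtures=50, noise=0.5, seed=0)
        np.testing.assert_allclose(truth.proportions.sum(axis=1).to_numpy(), 1.0, atol=1e-9)

    def test_noiseless_mixture_is_exact_linear_combination(self):
        """noise = 0: each mixture equals the proportion-weighted signature
        profiles, scaled only by its library size."""
        import pandas as pd

        sig = pd.DataFrame({"A": [8.0, 2.0, 1.0], "B": [1.0, 9.0, 3.0]}, index=["g1", "g2", "g3"])
        matrix, truth = simulate_spot_mixtures(sig, n_mixtures=20, noise=0.0, seed=1)
        sig_norm = sig.to_numpy() / sig.to_numpy().sum(axis=0)
        props = truth.proportions.to_numpy()
        dense = matrix.dense()
        observed = dense / dense.sum(axis=0)
        np.testing.assert_allclose(observed, sig_norm @ props.T, atol=1e-12)

    def test_negative_noise_rejected(self):
        import pandas as pd

        sig = pd.DataFrame({"A": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ConfigError):
            simulate_spot_mixtures(sig, noise=-1.0)


class TestEffectMonotonicity:
    def test_doubling_inflamed_effect_does_not_lower_drug_enrichment(self, small_config):
        """Planted-drug log2FC is monotone in the activation effect (5 seeds,
        paired)."""
        import copy

        stronger = copy.deepcopy(small_config)
        for comp in stronger.compartments:
            if comp.name.startswith("inflamed"):
                comp.effect *= 2
        for seed in range(5):
            base = planted_enrichment_stat(small_config, seed)
            boosted = planted_enrichment_stat(stronger, seed)
            assert boosted >= base - 0.05


def test_null_config_zeroes_every_effect():
    cfg = null_config(n_genes=900)
    assert all(c.effect == 0 for c in cfg.compartments)
    assert all(c.effect == 0 for c in cfg.cell_clusters)


def test_clinical_fixture_shape():
    table = clinical_fixture()
    assert list(table.columns) == ["creatinine_relapse", "egfr_relapse", "acr_relapse"]
    assert (table > 0).all().all()
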