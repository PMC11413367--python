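"""Clustering, annotation, signature scores, Wilcoxon DE, and ORA oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from nicherx.cluster import (
    annotate_by_markers,
    bh_adjust,
    cluster_expression,
    over_representation_test,
    rank_genes_wilcoxon,
    score_gene_set,
    score_gene_set_rank,
)
from nicherx.errors import ValidationError
from nicherx.io import GeneSet
from nicherx.simulate import ALL_CYTOKINES, cytokine_gene_sets

from conftest import make_matrix


def _blob_matrix(rng, n_per=60, n_genes=40, shift=4.0):
    """Two well-separated Gaussian blobs in expression space (log layer)."""
    a = rng.normal(0, 0.3, (n_genes, n_per))
    b = rng.normal(0, 0.3, (n_genes, n_per))
    b[: n_genes // 2] += shift
    values = np.abs(np.concatenate([a, b], axis=1))
    return make_matrix(values, layer="log_transformed"), np.r_[np.zeros(n_per), np.ones(n_per)]


class TestClustering:
    def test_two_blobs_two_clusters(self, rng):
        matrix, truth = _blob_matrix(rng)
        result = cluster_expression(matrix, n_hvg=40, n_pcs=10, resolution=1.0, seed=0)
        assert len(np.unique(result.labels)) == 2
        # perfect agreement up to label order
        assert len(pd.crosstab(result.labels, truth).to_numpy().nonzero()[0]) == 2

    def test_tiny_resolution_gives_single_cluster(self, rng):
        matrix, _ = _blob_matrix(rng, shift=0.0)
        result = cluster_expression(matrix, n_hvg=40, n_pcs=10, resolution=1e-3, seed=0)
        assert len(np.unique(result.labels)) == 1

    def test_deterministic_under_seed(self, rng):
        matrix, _ = _blob_matrix(rng)
        for algorithm in ("leiden", "louvain"):
            a = cluster_expression(matrix, n_pcs=10, resolution=1.0, algorithm=algorithm, seed=7)
            b = cluster_expression(matrix, n_pcs=10, resolution=1.0, algorithm=algorithm, seed=7)
            assert np.array_equal(a.labels, b.labels)

    def test_more_pcs_than_obs_rejected(self, rng):
        matrix = make_matrix(np.abs(rng.normal(size=(30, 10))), layer="log_transformed")
        with pytest.raises(ValidationError, match="PCs"):
            cluster_expression(matrix, n_pcs=20)

    def test_cluster_ids_dense_and_size_ordered(self, rng):
        matrix, _ = _blob_matrix(rng, n_per=40)
        result = cluster_expression(matrix, n_pcs=10, resolution=1.0, seed=0)
        ids, counts = np.unique(result.labels, return_counts=True)
        assert ids.tolist() == list(range(len(ids)))
        assert all(counts[i] >= counts[i + 1] for i in range(len(counts) - 1))


class TestAnnotation:
    def test_pt_panel_wins_for_pt_cluster(self):
        genes = ["LRP2", "CUBN", "SLC13A1", "SLC12A3", "CNNM2", "OTHER"]
        values = np.zeros((6, 20))
        values[:3, :10] = 3.0  # cluster 0 expresses the PT markers
        values[3:5, 10:] = 3.0  # cluster 1 expresses the DCT markers
        matrix = make_matrix(values, gene_ids=genes, layer="log_transformed")
        clusters = cluster_expression(matrix, n_hvg=6, n_pcs=3, resolution=1.0, seed=0)
        panels = [
            GeneSet("PT", ["LRP2", "CUBN", "SLC13A1"]),
            GeneSet("DCT", ["SLC12A3", "CNNM2"]),
        ]
        annotation = annotate_by_markers(matrix, clusters, panels)
        pt_cluster = clusters.labels[0]
        assert annotation[pt_cluster] == "PT"
        assert annotation[clusters.labels[-1]] == "DCT"

    def test_identical_clusters_tie_to_first_panel(self, caplog):
        values = np.ones((4, 12))
        matrix = make_matrix(values, layer="log_transformed")
        clusters = cluster_expression(matrix, n_hvg=4, n_pcs=2, resolution=1.0, seed=0)
        panels = [GeneSet("first", ["g0"]), GeneSet("second", ["g1"])]
        with caplog.at_level("WARNING"):
            annotation = annotate_by_markers(matrix, clusters, panels)
        assert set(annotation.values()) == {"first"}

    def test_absent_panel_skipped_with_warning(self, rng, caplog):
        matrix, _ = _blob_matrix(rng, n_per=20)
        clusters = cluster_expression(matrix, n_pcs=5, resolution=0.5, seed=0)
        panels = [GeneSet("present", ["g0"]), GeneSet("ghost", ["NOT_A_GENE"])]
        with caplog.at_level("WARNING"):
            annotation = annotate_by_markers(matrix, clusters, panels)
        assert set(annotation.values()) <= {"present"}
        assert "ghost" in caplog.text


class TestScoreGeneSet:
    def test_identical_expression_scores_zero(self):
        matrix = make_matrix(np.full((30, 8), 2.5), layer="log_transformed")
        score = score_gene_set(matrix, GeneSet("s", ["g0", "g1"]), n_bins=1, seed=0)
        np.testing.assert_allclose(score.to_numpy(), 0, atol=1e-12)

    def test_single_bin_closed_form(self):
        values = np.zeros((40, 5))
        values[:4] = 3.0  # the set genes at constant value c; everything else 0
        matrix = make_matrix(values, layer="log_transformed")
        score = score_gene_set(
            matrix, GeneSet("s", ["g0", "g1", "g2", "g3"]), n_bins=1, ctrl_size=36, seed=0
        )
        np.testing.assert_allclose(score.to_numpy(), 3.0, atol=1e-12)

    def test_shift_invariance(self, rng):
        values = np.abs(rng.normal(1, 0.5, (60, 12)))
        matrix = make_matrix(values, layer="log_transformed")
        shifted = make_matrix(values + 5.0, layer="log_transformed")
        gs = GeneSet("s", ["g3", "g10", "g20"])
        a = score_gene_set(matrix, gs, seed=4)
        b = score_gene_set(shifted, gs, seed=4)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_missing_set_errors_with_name(self, rng):
        matrix = make_matrix(np.abs(rng.normal(size=(10, 4))), layer="log_transformed")
        with pytest.raises(ValidationError, match="ghost"):
            score_gene_set(matrix, GeneSet("ghost", ["ZZZ"]), seed=0)

    def test_combined_cytokine_union_has_14_genes(self):
        combined = cytokine_gene_sets()[-1]
        assert combined.name == "combined_type_1_3"
        assert len(combined.genes) == 14
        assert set(combined.genes) == set(ALL_CYTOKINES)

    def test_agrees_with_scanpy_reference(self, rng):
        """Independent oracle: scanpy's binned-background score on the same data."""
        scanpy = pytest.importorskip("scanpy")
        import anndata

        values = np.abs(rng.normal(1.0, 0.7, (300, 80)))
        matrix = make_matrix(values, layer="log_transformed")
        genes = ["g5", "g50", "g100", "g200", "g250"]
        ours = score_gene_set(matrix, GeneSet("s", genes), n_bins=25, ctrl_size=50, seed=0)
        adata = anndata.AnnData(X=values.T.copy())
        adata.var_names = matrix.gene_ids
        scanpy.tl.score_genes(adata, genes, ctrl_size=50, n_bins=25, random_state=0)
        r = np.corrcoef(ours.to_numpy(), adata.obs["score"].to_numpy())[0, 1]
        assert r > 0.95


class TestScoreGeneSetRank:
    def test_hand_enumeration_four_genes(self):
        matrix = make_matrix(np.array([[4.0], [3.0], [2.0], [1.0]]), layer="log_transformed")
        es = score_gene_set_rank(matrix, GeneSet("s", ["g0", "g1"]))
        assert es.iloc[0] == pytest.approx(1.0)

    def test_top_m_genes_reach_plus_one(self, rng):
        values = np.abs(rng.normal(0.5, 0.2, (50, 3)))
        values[:5] += 10  # set genes strictly top-5 in every observation
        matrix = make_matrix(values, layer="log_transformed")
        es = score_gene_set_rank(matrix, GeneSet("s", [f"g{i}" for i in range(5)]))
        np.testing.assert_allclose(es.to_numpy(), 1.0, atol=1e-12)

    def test_exchangeable_null_mean_near_zero(self, rng):
        values = rng.normal(0, 1, (100, 200))
        matrix = make_matrix(np.abs(values), layer="log_transformed")
        es = score_gene_set_rank(matrix, GeneSet("s", [f"g{i}" for i in range(0, 40, 4)]))
        se = es.std() / np.sqrt(len(es))
        assert abs(es.mean()) < 3 * se + 1e-3

    def test_monotone_transform_invariance(self, rng):
        values = np.abs(rng.normal(1, 0.5, (30, 6)))
        gs = GeneSet("s", ["g2", "g7", "g20"])
        a = score_gene_set_rank(make_matrix(values, layer="log_transformed"), gs)
        b = score_gene_set_rank(make_matrix(np.exp(values), layer="log_transformed"), gs)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_full_coverage_set_rejected(self):
        matrix = make_matrix(np.ones((3, 2)), layer="log_transformed")
        with pytest.raises(ValidationError):
            score_gene_set_rank(matrix, GeneSet("all", ["g0", "g1", "g2"]))


def _exact_ranksum_p(x, y):
    """Brute-force two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = scipy.stats.rankdata(pooled)
    observed = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    stats = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    stats = np.array(stats)
    return float(np.mean(np.abs(stats - mu) >= abs(observed - mu) - 1e-12))


class TestWilcoxonDE:
    def test_exact_p_on_three_vs_three(self):
        matrix = make_matrix(
            np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]]), layer="log_transformed"
        )
        groups = ["a", "a", "a", "b", "b", "b"]
        res = rank_genes_wilcoxon(matrix, groups, exact=True)
        assert res["p_value"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_exact_mode_matches_enumeration_oracle(self, rng):
        for n1, n2 in [(3, 3), (4, 5), (6, 6)]:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            matrix = make_matrix(
                np.abs(np.concatenate([x, y]))[None, :], layer="log_transformed"
            )
            res = rank_genes_wilcoxon(matrix, ["a"] * n1 + ["b"] * n2, exact=True)
            expected = _exact_ranksum_p(np.abs(x), np.abs(y))
            assert res[res["group"] == "a"]["p_value"].iloc[0] == pytest.approx(
                expected, abs=1e-9
            )

    def test_normal_approx_close_to_exact_at_moderate_n(self, rng):
        values = np.abs(rng.normal(1, 0.4, (5, 40)))
        groups = ["a"] * 20 + ["b"] * 20
        approx = rank_genes_wilcoxon(make_matrix(values, layer="log_transformed"), groups)
        exact = rank_genes_wilcoxon(
            make_matrix(values, layer="log_transformed"), groups, exact=True
        )
        np.testing.assert_allclose(
            approx["p_value"].to_numpy(), exact["p_value"].to_numpy(), atol=0.02
        )

    def test_small_group_skipped_with_warning(self, rng, caplog):
        values = np.abs(rng.normal(1, 0.3, (4, 10)))
        groups = ["a"] * 8 + ["b"] * 2
        with caplog.at_level("WARNING"):
            res = rank_genes_wilcoxon(make_matrix(values, layer="log_transformed"), groups)
        assert set(res["group"]) == {"a"}

    def test_log2fc_uses_recorded_base(self):
        # one gene, de-logged means differ 4x -> log2fc = 2 (base-2 layer)
        vals = np.log2(np.array([[4.0, 4.0, 4.0, 1.0, 1.0, 1.0]]) + 1)
        matrix = make_matrix(vals, layer="log_transformed", log_base="2")
        res = rank_genes_wilcoxon(matrix, ["a"] * 3 + ["b"] * 3)
        assert res[res["group"] == "a"]["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)


class TestBH:
    def test_closed_form_example(self):
        adjusted = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adjusted, 0.04)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert adj.max() <= 1.0
        assert np.all(adj >= p - 1e-12)


class TestOverRepresentation:
    def test_complete_overlap_closed_form(self):
        universe = [f"u{i}" for i in range(20)]
        gs = GeneSet("s", universe[:5])
        table = over_representation_test(universe[:5], [gs], universe)
        assert table["p_value"].iloc[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_minimum_possible_overlap_p_near_one(self):
        universe = [f"u{i}" for i in range(30)]
        gs = GeneSet("s", universe[:2])
        table = over_representation_test(universe[10:13], [gs], universe)
        assert table["p_value"].iloc[0] >= 0.99

    def test_matches_exhaustive_enumeration_small_universe(self):
        universe = [f"u{i}" for i in range(12)]
        set_genes = universe[:4]
        hits = universe[2:7]  # overlap 2
        table = over_representation_test(hits, [GeneSet("s", set_genes)], universe)
        # enumerate all C(12,5) hit draws, count overlap >= 2
        count = sum(
            1
            for combo in itertools.combinations(universe, len(hits))
            if len(set(combo) & set(set_genes)) >= 2
        )
        expected = count / len(list(itertools.combinations(universe, len(hits))))
        assert table["p_value"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            over_representation_test(["x"], [GeneSet("s", ["a"])], ["a", "b"])
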