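"""Tests for the sparse-PLS association network machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micropat import network as net, synthetic as syn
from micropat.network import FeatureBlock, variance_decompose


def toy_block(n_per_stratum=6, p=4, q=3, seed=0, beta=None, noise=0.0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_stratum
    X = rng.normal(size=(n, p))
    beta = np.zeros((p, q)) if beta is None else beta
    Y = X @ beta + noise * rng.normal(size=(n, q))
    samples = [f"s{i}" for i in range(n)]
    strata = pd.Series(
        ["a"] * n_per_stratum + ["b"] * n_per_stratum, index=samples, name="stratum"
    )
    Xd = pd.DataFrame(X, index=samples, columns=[f"t{j}" for j in range(p)])
    Yd = pd.DataFrame(Y, index=samples, columns=[f"g{j}" for j in range(q)])
    return FeatureBlock(
        X=variance_decompose(Xd, strata), Y=variance_decompose(Yd, strata), strata=strata
    )


class TestVarianceDecompose:
    def test_single_stratum_is_global_centering(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 6.0]}, index=list("abcd"))
        strata = pd.Series(["s"] * 4, index=list("abcd"))
        out = variance_decompose(df, strata)
        np.testing.assert_allclose(out["x"], df["x"] - 3.0)

    def test_two_strata_centered_separately(self):
        df = pd.DataFrame({"x": [0.0, 0.0, 5.0, 5.0]}, index=list("abcd"))
        strata = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        out = variance_decompose(df, strata)
        np.testing.assert_allclose(out["x"], [0.0, 0.0, 0.0, 0.0])

    def test_constant_column_zeroed(self):
        df = pd.DataFrame({"x": [7.0, 7.0, 7.0, 7.0]}, index=list("abcd"))
        strata = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        assert (variance_decompose(df, strata)["x"] == 0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"s{i}" for i in range(8)])
        strata = pd.Series(["a"] * 4 + ["b"] * 4, index=df.index)
        once = variance_decompose(df, strata)
        twice = variance_decompose(once, strata)
        pd.testing.assert_frame_equal(once, twice)

    def test_singleton_stratum_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
        strata = pd.Series(["g1", "g1", "g2"], index=list("abc"))
        with pytest.raises(ValueError, match="singleton"):
            variance_decompose(df, strata)


class TestPrepareFeatures:
    def test_absent_taxon_removed(self, single_day_meta):
        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=0)
        taxa["ghost"] = 0
        block = net.prepare_features(taxa, expr, single_day_meta)
        assert "ghost" not in block.X.columns

    def test_abundance_filter_strictly_greater(self, single_day_meta):
        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=0)
        depth = int(taxa.sum(axis=1).iloc[0])
        rare = int(round(depth * 1e-4))  # exactly the boundary relative abundance
        taxa["rare"] = rare
        block = net.prepare_features(taxa, expr, single_day_meta, min_rel_abund=1e-4)
        assert "rare" not in block.X.columns

    def test_stratum_means_zero(self, single_day_meta):
        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=1)
        block = net.prepare_features(taxa, expr, single_day_meta)
        for s in block.strata.unique():
            rows = block.strata == s
            assert np.abs(block.X[rows].mean(axis=0)).max() < 1e-9
            assert np.abs(block.Y[rows].mean(axis=0)).max() < 1e-9

    def test_default_dims_match_study_scale(self, single_day_meta):
        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=2)
        block = net.prepare_features(taxa, expr, single_day_meta)
        assert block.X.shape == (len(single_day_meta), 15)
        assert block.Y.shape == (len(single_day_meta), 43)

    def test_no_shared_samples_rejected(self, single_day_meta):
        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=0)
        taxa.index = ["x" + s for s in taxa.index]
        with pytest.raises(ValueError, match="shared"):
            net.prepare_features(taxa, expr, single_day_meta)


class TestSplsFit:
    def test_univariate_exact_regression(self):
        beta = np.array([[2.0]])
        block = toy_block(p=1, q=1, beta=beta)
        model = net.spls_fit(block, lam=0.0)
        assert model.coefficients.iloc[0, 0] == pytest.approx(2.0, abs=1e-8)

    def test_full_shrinkage_zero_model(self):
        block = toy_block(p=3, q=2, beta=np.ones((3, 2)), noise=0.1)
        model = net.spls_fit(block, lam=1.0)
        assert model.support_size == 0
        assert (model.coefficients.to_numpy() == 0).all()

    def test_lambda_zero_full_k_matches_least_squares(self):
        """Noise-free toys are reproduced exactly at full component count."""
        rng = np.random.default_rng(5)
        beta = rng.normal(size=(5, 3))
        block = toy_block(n_per_stratum=10, p=5, q=3, beta=beta, seed=5)
        model = net.spls_fit(block, lam=0.0, K=5)
        pred = block.X.to_numpy() @ model.coefficients.to_numpy()
        assert np.abs(pred - block.Y.to_numpy()).max() < 1e-6

    def test_all_zero_block_rejected(self):
        block = toy_block(p=2, q=2)
        block.Y.iloc[:, :] = 0.0
        with pytest.raises(ValueError):
            net.spls_fit(block, lam=0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_support_shrinks_with_lambda(self, seed):
        """Support is empty at lam=1, dense at lam=0, and near-nested between.

        The deflation path can switch components as lambda moves, so exact
        nesting is not guaranteed; violations stay within a couple of edges.
        """
        rng = np.random.default_rng(seed)
        beta = np.zeros((5, 4))
        beta[rng.integers(0, 5, 3), rng.integers(0, 4, 3)] = 1.0
        block = toy_block(n_per_stratum=8, p=5, q=4, beta=beta, noise=0.3, seed=seed)
        lams = (1.0, 0.9, 0.6, 0.3, 0.0)
        sizes = [net.spls_fit(block, lam).support_size for lam in lams]
        assert sizes[0] == 0
        assert sizes[-1] == max(sizes)
        assert all(a <= b + 2 for a, b in zip(sizes, sizes[1:]))


class TestStars:
    def test_instability_bounds_and_monotonization(self, single_day_meta):
        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=3)
        block = net.prepare_features(taxa, expr, single_day_meta)
        res = net.stars_select(block, n_subsamples=20, seed=0)
        assert ((res.instability >= 0) & (res.instability <= 0.5)).all()
        assert (np.diff(res.monotone_instability) >= 0).all()
        assert res.selected_lambda in res.lambda_grid

    def test_frequencies_give_stated_instability(self):
        freq = np.array([[1.0, 0.5], [0.0, 0.25]])
        d = (2 * freq * (1 - freq)).mean()
        assert d == pytest.approx((0 + 0.5 + 0 + 0.375) / 4)

    def test_short_grid_rejected(self, single_day_meta):
        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=3)
        block = net.prepare_features(taxa, expr, single_day_meta)
        with pytest.raises(ValueError):
            net.stars_select(block, lambda_grid=np.array([0.5]), seed=0)

    def test_null_data_selects_sparse_model(self):
        fracs = []
        for seed in range(3):
            meta = syn.generate_metadata(12, [23], seed=300 + seed)
            taxa, expr, _ = syn.generate_paired_taxa_gene(
                meta, n_true_edges=0, seed=300 + seed
            )
            block = net.prepare_features(taxa, expr, meta)
            res = net.stars_select(block, n_subsamples=30, seed=seed)
            model = net.spls_fit(block, res.selected_lambda)
            fracs.append(model.support_size / (15 * 43))
        assert np.mean(fracs) <= 0.05


class TestBootstrap:
    def test_small_b_rejected(self, single_day_meta):
        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=4)
        block = net.prepare_features(taxa, expr, single_day_meta)
        model = net.spls_fit(block, 0.5)
        with pytest.raises(ValueError):
            net.bootstrap_significance(block, model, B=50, seed=0)

    def test_strong_noise_free_edges_hit_p_floor(self):
        meta = syn.generate_metadata(12, [23], seed=40)
        taxa, expr, truth = syn.generate_paired_taxa_gene(
            meta, n_true_edges=5, noise_sd=0.0, stratum_offset_sd=0.0, seed=40
        )
        block = net.prepare_features(taxa, expr, meta)
        model = net.spls_fit(block, 0.5)
        edges = net.bootstrap_significance(block, model, B=200, seed=1)
        by_pair = {(e.taxon, e.gene): e for e in edges}
        floors = [
            by_pair[pair].empirical_p for pair in truth.true_edges() if pair in by_pair
        ]
        assert floors and max(floors) == pytest.approx(1 / 201)

    def test_empty_support_returns_no_edges(self, single_day_meta):
        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=4)
        block = net.prepare_features(taxa, expr, single_day_meta)
        model = net.spls_fit(block, 1.0)
        assert net.bootstrap_significance(block, model, B=100, seed=0) == []


class TestBuildNetwork:
    def test_empty_edges_isolated_nodes(self, single_day_meta):
        taxa, _, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=5)
        g = net.build_network([], taxa, genes=["g1", "g2"])
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == taxa.shape[1] + 2

    def test_graphml_deterministic(self, tmp_path, single_day_meta):
        from micropat.io import write_graphml

        taxa, expr, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=5)
        block = net.prepare_features(taxa, expr, single_day_meta)
        model = net.spls_fit(block, 0.6)
        edges = net.bootstrap_significance(block, model, B=100, seed=2)
        g = net.build_network(edges, taxa, genes=list(block.Y.columns))
        write_graphml(g, tmp_path / "a.graphml")
        write_graphml(g, tmp_path / "b.graphml")
        assert (tmp_path / "a.graphml").read_bytes() == (tmp_path / "b.graphml").read_bytes()

    def test_dangling_edge_rejected(self, single_day_meta):
        from micropat.network import AssociationEdge

        taxa, _, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=5)
        bad = AssociationEdge("nope", "g1", 1.0, "+", 0.01, 0.01, True)
        with pytest.raises(ValueError, match="unknown node"):
            net.build_network([bad], taxa, genes=["g1"])

    def test_edge_attributes(self, single_day_meta):
        from micropat.network import AssociationEdge

        taxa, _, _ = syn.generate_paired_taxa_gene(single_day_meta, seed=5)
        taxon = taxa.columns[0]
        e = AssociationEdge(taxon, "g1", -0.5, "-", 0.01, 0.02, True)
        g = net.build_network([e], taxa, genes=["g1"])
        attrs = g.edges[taxon, "g1"]
        assert attrs["sign"] == "-"
        assert attrs["width"] == pytest.approx(2.0)
        assert g.nodes[taxon]["kind"] == "taxon"
        assert 0 < g.nodes[taxon]["mean_rel_abundance"] < 1
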