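"""SOM lattice geometry, training, u-matrix clustering, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from lnchet import som


class TestGridSize:
    @pytest.mark.parametrize(
        "n,expected_units", [(2003, 224), (100, 50), (4, 10)]
    )
    def test_heuristic_unit_count(self, n, expected_units):
        xdim, ydim = som.grid_size(n)
        assert abs(xdim * ydim - expected_units) <= 0.1 * expected_units
        # and the heuristic itself: round(5 * sqrt(N))
        assert expected_units == int(math.floor(5.0 * math.sqrt(n) + 0.5))

    def test_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            som.grid_size(3)


class TestLatticeGeometry:
    def test_toroidal_distance_symmetric(self):
        grid = som.SOMGrid(5, 4)
        d = grid.unit_distances()
        np.testing.assert_allclose(d, d.T)
        assert (np.diag(d) == 0).all()

    def test_wraparound_shortens_edge_distances(self):
        grid = som.SOMGrid(8, 6)
        d = grid.unit_distances()
        # first and last unit of row 0: planar distance 7, toroidal 1
        assert d[0, 7] == pytest.approx(1.0)
        # vertical wrap: row 0 to row 5
        assert d[0, 5 * 8] < 2.0

    def test_six_neighbors_everywhere(self):
        grid = som.SOMGrid(4, 4)
        for i in range(grid.n_units):
            assert len(grid.neighbors(i)) == 6

    def test_neighbor_relation_symmetric_on_even_rows(self):
        grid = som.SOMGrid(6, 4)  # even row count: clean hex torus
        for i in range(grid.n_units):
            for j in grid.neighbors(i):
                assert i in grid.neighbors(j)


class TestInitCodebooks:
    def test_zero_pcs_gives_data_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (50, 12))
        grid = som.init_codebooks(som.SOMGrid(4, 4), X, n_pcs=0, seed=1)
        np.testing.assert_allclose(grid.codebook, np.tile(X.mean(0), (16, 1)))

    def test_codebooks_lie_in_pc_subspace(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (60, 15))
        grid = som.init_codebooks(som.SOMGrid(5, 5), X, n_pcs=10, seed=2)
        from sklearn.decomposition import PCA

        pca = PCA(n_components=10, svd_solver="full").fit(X)
        centered = grid.codebook - X.mean(0)
        recon = centered @ pca.components_.T @ pca.components_
        assert np.abs(centered - recon).max() < 1e-8

    def test_seed_changes_codebooks_not_subspace(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (60, 15))
        a = som.init_codebooks(som.SOMGrid(5, 5), X, n_pcs=10, seed=3).codebook
        b = som.init_codebooks(som.SOMGrid(5, 5), X, n_pcs=10, seed=4).codebook
        assert not np.allclose(a, b)


class TestTrain:
    def test_single_vector_convergence_matches_geometric_decay(self):
        # with the radius pinned at 2 (>= the 3x3 lattice diameter of ~1.98)
        # every codebook is updated at every presentation, so its residual
        # decays exactly by prod_t (1 - alpha_t) -- a closed form
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (1, 10))
        grid = som.SOMGrid(3, 3)
        grid.codebook = x + rng.normal(0, 0.5, (9, 10))
        d0 = np.linalg.norm(grid.codebook - x, axis=1)
        epochs = 200
        alphas = 0.05 + (0.01 - 0.05) * np.arange(epochs) / (epochs - 1)
        expected = d0 * np.prod(1.0 - alphas)
        grid, _qe = som.train(grid, x, epochs=epochs, radius=(2.0, 2.0), seed=4)
        d = np.linalg.norm(grid.codebook - x, axis=1)
        np.testing.assert_allclose(d, expected, rtol=1e-8)
        assert d.min() < 1e-2

    def test_zero_alpha_leaves_codebooks_unchanged(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (20, 8))
        grid = som.SOMGrid(3, 3)
        init = rng.normal(0, 1, (9, 8))
        grid.codebook = init.copy()
        grid, _ = som.train(grid, X, epochs=5, alpha=(0.0, 0.0), seed=6)
        np.testing.assert_array_equal(grid.codebook, init)

    @pytest.mark.parametrize("seed", range(5))
    def test_quantization_error_final_not_worse(self, seed, processed):
        # structured (correlated) gene vectors, as the map is meant to see
        *_rest, z = processed
        X = z.values.to_numpy()[40 * seed : 40 * seed + 40]
        grid = som.init_codebooks(som.SOMGrid(4, 4), X, seed=seed)
        _grid, qe = som.train(grid, X, epochs=30, seed=seed + 100)
        assert qe[-1] <= qe[0]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (30, 6))
        out = []
        for _ in range(2):
            grid = som.init_codebooks(som.SOMGrid(4, 3), X.copy(), seed=8)
            grid, _ = som.train(grid, X.copy(), epochs=10, seed=9)
            out.append(grid.codebook)
        np.testing.assert_array_equal(out[0], out[1])

    def test_nan_rejected(self):
        grid = som.SOMGrid(3, 3)
        grid.codebook = np.zeros((9, 2))
        with pytest.raises(ValueError, match="NaN"):
            som.train(grid, np.array([[1.0, np.nan]]))


class TestMapGenes:
    def test_exact_codebook_match(self):
        grid = som.SOMGrid(3, 3)
        grid.codebook = np.arange(27.0).reshape(9, 3)
        vectors = pd.DataFrame([grid.codebook[4]], index=["gA"])
        mapping = som.map_genes(grid, vectors)
        assert mapping.bmu["gA"] == 4
        assert mapping.quantization_error["gA"] < 1e-6

    def test_identical_genes_share_bmu(self):
        rng = np.random.default_rng(10)
        grid = som.SOMGrid(3, 3)
        grid.codebook = rng.normal(0, 1, (9, 5))
        v = rng.normal(0, 1, 5)
        mapping = som.map_genes(grid, pd.DataFrame([v, v], index=["a", "b"]))
        assert mapping.bmu["a"] == mapping.bmu["b"]

    def test_dimension_mismatch_rejected(self):
        grid = som.SOMGrid(3, 3)
        grid.codebook = np.zeros((9, 4))
        with pytest.raises(ValueError, match="dim"):
            som.map_genes(grid, pd.DataFrame(np.zeros((2, 3))))


class TestUMatrix:
    def test_identical_codebooks_give_zero(self):
        grid = som.SOMGrid(4, 4)
        grid.codebook = np.ones((16, 5))
        np.testing.assert_array_equal(som.compute_umatrix(grid), np.zeros(16))

    def test_outlier_unit_dominates(self):
        grid = som.SOMGrid(4, 4)
        grid.codebook = np.zeros((16, 2))
        grid.codebook[5] = [10.0, 0.0]
        u = som.compute_umatrix(grid)
        hot = {5, *grid.neighbors(5)}
        cold = set(range(16)) - hot
        assert min(u[list(hot)]) > max(u[list(cold)])

    def test_translation_invariance_on_torus(self):
        # shifting all codebooks one column to the right permutes u-values
        rng = np.random.default_rng(11)
        grid = som.SOMGrid(4, 4)
        grid.codebook = rng.normal(0, 1, (16, 3))
        u = som.compute_umatrix(grid)
        shifted = som.SOMGrid(4, 4)
        perm = [(i // 4) * 4 + (i % 4 + 1) % 4 for i in range(16)]
        shifted.codebook = grid.codebook[perm]
        u2 = som.compute_umatrix(shifted)
        np.testing.assert_allclose(u2, u[perm])


class TestClusterUnits:
    def test_constant_codebooks_one_cluster(self):
        # a constant u-matrix is one whole-map plateau -> a single cluster
        grid = som.SOMGrid(4, 4)
        grid.codebook = np.ones((16, 3))
        u = som.compute_umatrix(grid)
        out = som.cluster_units(grid, u)
        assert set(out.unit_cluster) == {0}
        assert len(out.seeds) == 1

    def test_partition_property(self, small_cohort, processed):
        *_rest, z = processed
        X = z.values.to_numpy()[:80]
        grid = som.init_codebooks(som.SOMGrid(5, 4), X, seed=12)
        grid, _ = som.train(grid, X, epochs=20, seed=13)
        u = som.compute_umatrix(grid)
        out = som.cluster_units(grid, u)
        assert len(out.unit_cluster) == grid.n_units
        assert set(out.unit_cluster) == set(range(len(out.seeds)))
        for s_i, s in enumerate(out.seeds):
            assert out.unit_cluster[s] == s_i


class TestCellComponent:
    def test_unit_means(self):
        grid_units = 9
        mapping = som.SOMMapping(
            pd.Series({"g1": 2, "g2": 2, "g3": 2, "g4": 7}),
            pd.Series(0.0, index=["g1", "g2", "g3", "g4"]),
        )
        z = pd.DataFrame(
            {"cellA": [1.0, 2.0, 3.0, 5.0]}, index=["g1", "g2", "g3", "g4"]
        )
        out = som.cell_component(mapping, z, "cellA", grid_units)
        assert out[2] == pytest.approx(2.0)
        assert out[7] == pytest.approx(5.0)
        assert np.isnan(out[0])

    def test_unknown_cell_rejected(self):
        mapping = som.SOMMapping(pd.Series({"g": 0}), pd.Series({"g": 0.0}))
        with pytest.raises(KeyError):
            som.cell_component(mapping, pd.DataFrame({"c": [1.0]}, index=["g"]), "nope", 4)


class TestEnrichment:
    def test_exact_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(100)]
        cluster = universe[:5]
        sets = {"S": cluster}
        out = som.enrich_cluster(cluster, sets, universe)
        expected = 1.0 / comb(100, 5)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)
        # single test: BH q equals raw p
        assert out["q"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = som.enrich_cluster(universe[:5], {"S": universe[10:15]}, universe)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            som.enrich_cluster(["a"], {}, ["a"])
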