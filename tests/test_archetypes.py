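"""Simplex fitting, the t-ratio statistic and its permutation test,
archetype-based phenotyping and the continuum diagnostic."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from tmedyn.archetypes import (
    DegenerateSimplexWarning,
    archetype_enrichment,
    continuum_diagnostic,
    discretize_archetypes,
    distance_to_archetype,
    fit_simplex,
    simplex_regression,
    t_ratio,
    t_ratio_test,
)
from tmedyn.synthetic import simulate_simplex_population


def matched_error(fitted, truth):
    D = np.linalg.norm(fitted[:, None, :] - truth[None, :, :], axis=2)
    r, c = linear_sum_assignment(D)
    return D[r, c].max()


class TestFitSimplex:
    def test_exact_vertices_recovered(self, regular_tetrahedron):
        X = np.repeat(regular_tetrahedron, 50, axis=0)
        fit = fit_simplex(X, 4, n_restarts=2, seed=0)
        assert matched_error(fit.archetypes, regular_tetrahedron) < 1e-6

    def test_weights_are_barycentric(self, regular_tetrahedron):
        X, _ = simulate_simplex_population(300, regular_tetrahedron, 0.2, seed=1)
        fit = fit_simplex(X, 4, n_restarts=2, seed=0)
        assert fit.weights.min() >= 0
        np.testing.assert_allclose(fit.weights.sum(axis=1), 1.0, atol=1e-6)

    def test_objective_monotone_nonincreasing(self, regular_tetrahedron):
        X, _ = simulate_simplex_population(400, regular_tetrahedron, 0.3, seed=2)
        fit = fit_simplex(X, 4, n_restarts=1, seed=3)
        assert np.all(np.diff(fit.objective_history) <= 1e-9 * fit.objective_history[0])

    def test_recovery_improves_with_sample_size(self, regular_tetrahedron):
        diam = 4 * np.sqrt(2)
        errs = {}
        for n in (200, 2000):
            X, _ = simulate_simplex_population(n, regular_tetrahedron, 0.05 * diam, seed=5)
            fit = fit_simplex(X, 4, n_restarts=3, seed=1)
            errs[n] = matched_error(fit.archetypes, regular_tetrahedron)
        assert errs[2000] < errs[200]

    def test_collinear_data_warns_degenerate(self):
        X = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50)])
        with pytest.warns(DegenerateSimplexWarning):
            fit_simplex(X, 3, n_restarts=1, seed=0)

    def test_fewer_cells_than_archetypes_rejected(self):
        with pytest.raises(ValueError, match="fewer cells"):
            fit_simplex(np.zeros((3, 3)), 4)


class TestSimplexRegression:
    def test_interior_point_exact(self, regular_tetrahedron):
        w = np.array([[0.4, 0.3, 0.2, 0.1]])
        x = w @ regular_tetrahedron
        W = simplex_regression(x, regular_tetrahedron)
        np.testing.assert_allclose(W, w, atol=1e-8)

    def test_outside_point_projects_to_face(self, regular_tetrahedron):
        x = regular_tetrahedron[0:1] * 2.0  # beyond vertex 0
        W = simplex_regression(x, regular_tetrahedron)
        np.testing.assert_allclose(W[0], [1, 0, 0, 0], atol=1e-8)


class TestTRatio:
    def test_simplex_vertices_give_unity(self, regular_tetrahedron):
        assert t_ratio(regular_tetrahedron, regular_tetrahedron) == pytest.approx(1.0, abs=1e-6)

    def test_dense_uniform_triangle_approaches_unity(self, rng):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        X = rng.dirichlet([1, 1, 1], 5000) @ tri
        assert t_ratio(X, tri) == pytest.approx(1.0, rel=0.05)

    def test_gaussian_cloud_needs_larger_simplex(self, rng):
        G = rng.normal(size=(1000, 3))
        assert t_ratio(G, seed=0) > 1.3


class TestTRatioTest:
    def test_simplex_data_significant(self, regular_tetrahedron):
        diam = 4 * np.sqrt(2)
        X, _ = simulate_simplex_population(800, regular_tetrahedron, 0.05 * diam, seed=7)
        fit = t_ratio_test(X, 4, n_shuffles=99, seed=7, n_restarts=2)
        assert fit.p_value <= 0.05
        assert fit.t_ratio >= 1 - 1e-9

    def test_coarse_shuffle_count_warns(self, rng):
        with pytest.warns(UserWarning, match="floor"):
            t_ratio_test(rng.normal(size=(60, 2)), 3, n_shuffles=10, seed=0, n_restarts=1)


class TestDistanceAndDiscretization:
    def test_distance_zero_at_archetype(self, regular_tetrahedron):
        d = distance_to_archetype(regular_tetrahedron[:1], regular_tetrahedron, which=0)
        assert d[0] == 0

    def test_centroid_equidistant_in_regular_simplex(self, regular_tetrahedron):
        c = regular_tetrahedron.mean(axis=0, keepdims=True)
        d = distance_to_archetype(c, regular_tetrahedron)[0]
        np.testing.assert_allclose(d, d[0], atol=1e-9)

    def test_hand_computed_2d_distances(self):
        A = np.array([[0.0, 0.0], [3.0, 4.0]])
        d = distance_to_archetype(np.array([[3.0, 0.0]]), A)
        np.testing.assert_allclose(d[0], [3.0, 4.0])

    def test_quantile_counts(self, rng):
        A = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = rng.uniform(0, 10, size=(20, 2))
        labels = discretize_archetypes(X, A, frac_closest=0.25, frac_generalist=0.0)
        # 25% of 20 -> 5 cells per archetype candidate set (before conflicts)
        assert (labels != "unassigned").sum() <= 15

    def test_generalist_count_exact(self, rng):
        A = np.array([[20.0, 0.0], [0.0, 20.0], [-20.0, -20.0]])
        X = rng.normal(0, 1, size=(100, 2))
        labels = discretize_archetypes(X, A, frac_closest=0.0, frac_generalist=0.20)
        assert (labels == "generalist").sum() == 20

    def test_cell_at_archetype_gets_its_label(self, regular_tetrahedron):
        X = np.vstack([regular_tetrahedron[1], np.zeros(3)])
        labels = discretize_archetypes(X, regular_tetrahedron,
                                       frac_closest=0.5, frac_generalist=0.0)
        assert labels[0] == "archetype2"


class TestArchetypeEnrichment:
    def test_planted_monotone_gene_top_ranked(self, rng, regular_tetrahedron):
        X, W = simulate_simplex_population(1000, regular_tetrahedron, 0.2, seed=1)
        D = distance_to_archetype(X, regular_tetrahedron)
        feats = rng.normal(0, 1, size=(30, 1000))
        feats[0] = -D[:, 0] + rng.normal(0, 0.2, 1000)  # peaks toward archetype 1
        import pandas as pd

        table = archetype_enrichment(pd.DataFrame(feats, index=[f"f{i}" for i in range(30)]), D)
        a1 = table[table["archetype"] == "archetype1"].set_index("feature")
        assert a1.loc["f0", "q"] < 0.01
        assert a1["p"].idxmin() == "f0"

    def test_null_feature_p_uniform(self, rng, regular_tetrahedron):
        X, _ = simulate_simplex_population(200, regular_tetrahedron, 0.2, seed=2)
        D = distance_to_archetype(X, regular_tetrahedron)
        import pandas as pd

        ps = []
        for rep in range(100):
            f = pd.DataFrame(rng.normal(size=(1, 200)), index=["f"])
            t = archetype_enrichment(f, D[:, :1])
            ps.append(t["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_feature_table(self, regular_tetrahedron):
        import pandas as pd

        D = distance_to_archetype(regular_tetrahedron, regular_tetrahedron)
        t = archetype_enrichment(pd.DataFrame(np.zeros((0, 4))), D)
        assert len(t) == 0


class TestContinuumDiagnostic:
    def test_tight_blobs_called_cluster_like(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        X = np.vstack([rng.normal(c, 0.3, size=(200, 2)) for c in centers])
        rep = continuum_diagnostic(X, error_radius=1.5)
        assert rep["verdict"] == "cluster_like"
        assert rep["n_peaks"] >= 2

    def test_filled_simplex_called_continuum(self, rng, regular_tetrahedron):
        X, _ = simulate_simplex_population(2000, regular_tetrahedron, 0.1, seed=3)
        rep = continuum_diagnostic(X[:, :2], error_radius=0.05)
        assert rep["verdict"] == "continuum_like"

    def test_single_gaussian_one_peak(self, rng):
        rep = continuum_diagnostic(rng.normal(size=(1000, 2)), error_radius=0.1)
        assert rep["n_peaks"] == 1
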