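"""PCA, elbow rule, graph clustering, isolation filter, annotation and
the recursive typing tree."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from tmedyn.containers import LTQMatrix
from tmedyn.hierarchy import (
    annotate_clusters,
    choose_n_pcs,
    cluster_graph,
    isolation_filter,
    isolation_statistic,
    recursive_typing,
    run_pca,
)


def as_ltq(x_genes_by_cells, gene_error=None):
    g, n = x_genes_by_cells.shape
    return LTQMatrix(
        x_genes_by_cells,
        np.full(g, 0.1) if gene_error is None else gene_error,
        np.array([f"g{i:03d}" for i in range(g)], dtype=object),
        np.array([f"c{i:04d}" for i in range(n)], dtype=object),
    )


class TestRunPca:
    def test_rank_one_data_single_component(self, rng):
        x = np.outer(rng.normal(size=30), rng.normal(size=200))
        p = run_pca(x)
        assert p.variance_explained[0] / p.variance_explained.sum() > 0.999

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        x = rng.normal(size=(20, 100))
        p = run_pca(x)
        np.testing.assert_allclose(p.loadings.T @ p.loadings, np.eye(p.loadings.shape[1]), atol=1e-8)
        centered = (x.T - x.T.mean(axis=0)).T
        np.testing.assert_allclose(p.scores @ p.loadings.T, centered.T, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        x = rng.normal(size=(15, 80))
        p = run_pca(x)
        for k in range(p.loadings.shape[1]):
            col = p.loadings[:, k]
            assert col[np.abs(col).argmax()] > 0

    def test_isotropic_variances_roughly_equal(self, rng):
        x = rng.normal(size=(10, 4000))
        p = run_pca(x)
        ve = p.variance_explained
        se = ve.mean() * np.sqrt(2 / 4000) * 3
        assert ve.max() - ve.min() < 10 * se  # loose: order statistics of 10 eigenvalues


class TestChooseNPcs:
    @pytest.mark.parametrize(
        "variance,expected",
        [([50, 25, 3, 2.8, 2.7], 2), ([40, 30, 20, 2, 1.9], 3)],
    )
    def test_second_difference_rule(self, variance, expected):
        assert choose_n_pcs(np.array(variance)) == expected

    def test_geometric_decay_hits_lower_bound(self):
        v = 100 * 0.5 ** np.arange(10)
        assert choose_n_pcs(v) == 2

    def test_upper_bound_respected(self):
        v = np.array([10, 9.9, 9.8, 1.0, 0.9, 0.01, 0.009])
        assert choose_n_pcs(v, n_pcs_max=3) == 3


class TestClusterGraph:
    def test_two_separated_blobs_recovered(self, rng):
        x = np.vstack([rng.normal(0, 1, (150, 3)), rng.normal(40, 1, (150, 3))])
        truth = np.repeat([0, 1], 150)
        labels = cluster_graph(x, resolution=0.02, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_blob_one_cluster(self, rng):
        labels = cluster_graph(rng.normal(size=(300, 3)), resolution=0.02, seed=0)
        assert len(np.unique(labels)) == 1

    def test_four_blobs_at_paper_resolution(self, rng):
        centers = np.array([[0, 0], [30, 0], [0, 30], [30, 30]], dtype=float)
        x = np.vstack([rng.normal(c, 1.0, (100, 2)) for c in centers])
        labels = cluster_graph(x, resolution=0.02, seed=1)
        assert len(np.unique(labels)) == 4
        assert adjusted_rand_score(np.repeat(np.arange(4), 100), labels) == 1.0

    def test_fixed_seed_reproducible(self, rng):
        x = rng.normal(size=(200, 2))
        a = cluster_graph(x, resolution=0.5, seed=7)
        b = cluster_graph(x, resolution=0.5, seed=7)
        np.testing.assert_array_equal(a, b)


class TestIsolationFilter:
    def test_two_cells_arithmetic(self):
        x = np.array([[0.0], [1.0]])
        stat = isolation_statistic(x, k_neighbors=1)
        np.testing.assert_allclose(stat, [2.0, 2.0])

    def test_nd3_scale_free_in_group_size(self, rng):
        # the d^3 ~ 1/n argument: at 10x the cells from the same smooth
        # density, the distribution of n * d^3 is unchanged
        small = rng.normal(size=(500, 3))
        big = rng.normal(size=(5000, 3))
        s1 = isolation_statistic(small, 10)
        s2 = isolation_statistic(big, 10)
        # the scaling is asymptotic in n (finite-k edge effects remain),
        # so compare at matched sample size
        sub1 = rng.choice(s1, 300, replace=False)
        sub2 = rng.choice(s2, 300, replace=False)
        assert stats.ks_2samp(sub1, sub2).pvalue > 0.01

    def test_far_outlier_has_max_statistic_and_is_cut(self, rng):
        x = rng.normal(0, 1, size=(500, 2))
        x[0] = [200, 200]
        stat = isolation_statistic(x, 15)
        assert stat.argmax() == 0
        assert not isolation_filter(x, 15, cutoff_nd3=stat[0] * 0.5)[0]


class TestAnnotateClusters:
    def make_planted(self, rng, n_types=4, per=60, markers_per=5, boost=2.0):
        g = n_types * markers_per + 10
        x = rng.normal(-8, 0.3, size=(g, n_types * per))
        rows = []
        for t in range(n_types):
            sl = slice(t * markers_per, (t + 1) * markers_per)
            x[sl, t * per:(t + 1) * per] += boost
            rows += [{"cell_type": f"T{t}", "gene": f"g{i:03d}"}
                     for i in range(t * markers_per, (t + 1) * markers_per)]
        labels = np.repeat(np.arange(n_types), per)
        return as_ltq(x), labels, pd.DataFrame(rows)

    def test_planted_four_types_all_correct(self, rng):
        ltq, labels, markers = self.make_planted(rng)
        ann = annotate_clusters(labels, ltq, markers)
        assert [ann[c] for c in range(4)] == ["T0", "T1", "T2", "T3"]

    def test_tied_scores_stay_unresolved(self, rng):
        ltq, labels, markers = self.make_planted(rng, n_types=2)
        # same marker set for both candidate types -> exact tie
        markers["cell_type"] = np.where(markers["cell_type"] == "T0", "A", "B")
        both = pd.concat([markers.assign(cell_type="A"), markers.assign(cell_type="B")])
        ann = annotate_clusters(labels, ltq, both)
        assert set(ann.values()) == {"unresolved"}


class TestRecursiveTyping:
    def build_hierarchical(self, rng, per=120):
        """Two super-types, each split into two subtypes."""
        g = 80
        base = rng.normal(-8, 0.05, size=g)
        profiles = {}
        for i, name in enumerate(["A1", "A2", "B1", "B2"]):
            p = base.copy()
            sup = 0 if name.startswith("A") else 1
            p[sup * 10:(sup + 1) * 10] += 3.0  # super-type block
            p[20 + i * 10:30 + i * 10] += 3.0  # subtype block
            profiles[name] = p
        x = np.hstack([
            rng.normal(profiles[n][:, None], 0.4, size=(g, per))
            for n in ["A1", "A2", "B1", "B2"]
        ])
        truth = np.repeat(["A1", "A2", "B1", "B2"], per)
        markers = pd.DataFrame(
            [{"cell_type": n, "gene": f"g{j:03d}"}
             for i, n in enumerate(["A1", "A2", "B1", "B2"])
             for j in range(20 + i * 10, 30 + i * 10)]
        )
        return as_ltq(x, gene_error=np.full(g, 0.4)), truth, markers

    def test_planted_hierarchy_recovered(self, rng):
        ltq, truth, markers = self.build_hierarchical(rng)
        tree = recursive_typing(ltq, markers, resolution_schedule={0: 0.02, 1: 0.07},
                                min_cells=30, seed=0)
        labels = tree.final_labels(ltq.n_cells)
        typed = labels != "excluded"
        assert adjusted_rand_score(truth[typed], labels[typed]) >= 0.95
        assert set(labels[typed]) == {"A1", "A2", "B1", "B2"}

    def test_homogeneous_population_single_leaf(self, rng):
        x = rng.normal(-8, 0.3, size=(40, 300))
        ltq = as_ltq(x, gene_error=np.full(40, 0.3))
        markers = pd.DataFrame([{"cell_type": "A", "gene": "g000"}])
        tree = recursive_typing(ltq, markers, seed=0)
        assert tree.is_leaf

    def test_cells_partitioned_exactly_once(self, rng):
        ltq, truth, markers = self.build_hierarchical(rng, per=80)
        tree = recursive_typing(ltq, markers, resolution_schedule={0: 0.02, 1: 0.07},
                                min_cells=30, seed=1)
        leaf_cells = np.concatenate([leaf.cell_indices for leaf in tree.leaves()])
        assert len(leaf_cells) == len(np.unique(leaf_cells))
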