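"""The generator must plant a recoverable truth: composition, simplex
weights, marker structure, bimodal channels and NormZ signatures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmedyn.archetypes import barycentric_coordinates
from tmedyn.synthetic import (
    CellTypeSpec,
    SimConfig,
    SimplexSpec,
    default_hifi_panel,
    default_mode_locations,
    simulate_counts,
    simulate_hifi_intensities,
    simulate_normz,
    simulate_simplex_population,
    tumor_timecourse_config,
)


def two_type_config(depth=5000.0, seed=0, n_genes=60):
    base = np.zeros(n_genes)
    a = base.copy()
    a[10:20] += 2.5
    b = base.copy()
    b[20:30] += 2.5
    specs = [
        CellTypeSpec("A", [0.5, 0.5], np.arange(10, 20), a),
        CellTypeSpec("B", [0.5, 0.5], np.arange(20, 30), b),
    ]
    return SimConfig(n_genes=n_genes, timepoints=["t1", "t2"],
                     cells_per_timepoint=[200, 200], cell_type_specs=specs,
                     depth=depth, seed=seed)


class TestSimulateCounts:
    def test_zero_depth_gives_all_zero_matrix(self):
        counts, _ = simulate_counts(two_type_config(depth=0.0))
        assert counts.counts.nnz == 0

    def test_marker_blocks_separate_types(self):
        cfg = two_type_config(depth=5000.0, seed=1)
        counts, gt = simulate_counts(cfg)
        dense = np.asarray(counts.counts.todense(), dtype=float)
        is_a = (gt.cells["true_type"] == "A").to_numpy()
        a_markers = dense[10:20]
        assert a_markers[:, is_a].mean() > 3 * a_markers[:, ~is_a].mean()

    def test_same_seed_bitwise_identical(self):
        c1, _ = simulate_counts(two_type_config(seed=42))
        c2, _ = simulate_counts(two_type_config(seed=42))
        assert (c1.counts != c2.counts).nnz == 0
        assert list(c1.cell_ids) == list(c2.cell_ids)

    def test_degenerate_simplex_spec_rejected(self):
        profiles = np.ones((3, 60))  # affinely dependent
        with pytest.raises(ValueError, match="degenerate"):
            SimplexSpec("A", profiles)

    def test_composition_fidelity_within_binomial_ci(self):
        cfg = tumor_timecourse_config(seed=3)
        counts, gt = simulate_counts(cfg)
        for t_idx, tp in enumerate(cfg.timepoints):
            at_t = gt.cells[gt.cells["timepoint"] == tp]
            n = len(at_t)
            for spec in cfg.cell_type_specs:
                f = spec.frac_per_timepoint[t_idx]
                obs = (at_t["true_type"] == spec.name).mean()
                # integer allocation is deterministic, so the realized
                # fraction can only deviate by rounding
                assert abs(obs - f) <= max(2.58 * np.sqrt(f * (1 - f) / n), 2 / n)

    def test_configured_patterns_satisfy_their_shape(self):
        cfg = tumor_timecourse_config()
        for spec in cfg.cell_type_specs:
            fr = spec.frac_per_timepoint
            if spec.pattern == "wave_like":
                k = int(np.argmax(fr))
                assert 0 < k < len(fr) - 1
                assert fr[k] > max(fr[0], fr[-1])
            elif spec.pattern == "progressive_increase":
                assert np.all(np.diff(fr) >= 0)


class TestSimplexPopulation:
    def test_zero_noise_identity_weights_reproduce_profiles(self, regular_tetrahedron):
        X, _ = simulate_simplex_population(
            4, regular_tetrahedron, noise_sd=0.0, seed=0, weights=np.eye(4))
        np.testing.assert_allclose(X, regular_tetrahedron)

    def test_zero_noise_cells_inside_hull(self, regular_tetrahedron):
        X, _ = simulate_simplex_population(500, regular_tetrahedron, noise_sd=0.0, seed=1)
        b = barycentric_coordinates(X, regular_tetrahedron)
        assert b.min() >= -1e-9

    def test_uniform_dirichlet_mean_weights(self, regular_tetrahedron):
        _, W = simulate_simplex_population(
            2000, regular_tetrahedron, noise_sd=0.0, seed=2, concentration=1.0)
        np.testing.assert_allclose(W.mean(axis=0), 0.25, atol=0.02)


class TestNormZ:
    def test_null_effect_means_indistinguishable(self):
        tab = simulate_normz(2000, range(200), effect=0.0, seed=0)
        sig = tab["normz"][:200]
        bg = tab["normz"][200:]
        se = np.sqrt(sig.var() / len(sig) + bg.var() / len(bg))
        assert abs(sig.mean() - bg.mean()) < 3 * se

    def test_planted_effect_recovered(self):
        tab = simulate_normz(2000, range(50), effect=3.0, seed=1)
        diff = tab["normz"][:50].mean() - tab["normz"][50:].mean()
        assert abs(diff - 3.0) < 0.5

    def test_empty_signature_is_standard_normal(self):
        tab = simulate_normz(5000, [], effect=5.0, seed=2)
        assert abs(tab["normz"].mean()) < 0.05
        assert abs(tab["normz"].std() - 1.0) < 0.05


class TestHifiIntensities:
    def test_single_type_all_positive_mode(self):
        table, truth = simulate_hifi_intensities(
            {"A": 1.0}, {"A": {"m"}}, {"m": (0.1, 1.5)}, 300, seed=0)
        assert (truth == "A").all()
        assert np.log1p(table["m"]).between(1.0, 2.0).all()

    def test_bimodal_channel_has_two_modes(self):
        comp, panel, _ = default_hifi_panel()
        table, _ = simulate_hifi_intensities(
            comp, panel, default_mode_locations(), 4000, seed=1)
        vals = np.log1p(table["CD45"])
        kde = stats.gaussian_kde(vals)
        grid = np.linspace(-0.5, 2.5, 400)
        dens = kde(grid)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(dens, prominence=0.05 * dens.max())
        locs = grid[peaks]
        assert any(abs(x - 0.1) < 0.2 for x in locs)
        assert any(abs(x - 1.5) < 0.2 for x in locs)

    def test_zero_cells_gives_empty_table(self):
        table, truth = simulate_hifi_intensities(
            {"A": 1.0}, {"A": {"m"}}, {"m": (0.1, 1.5)}, 0, seed=0)
        assert len(table) == 0 and len(truth) == 0

    def test_nested_marker_positive_only_within_parent(self):
        comp, panel, _ = default_hifi_panel()
        table, truth = simulate_hifi_intensities(
            comp, panel, default_mode_locations(), 3000, seed=2)
        cd3_pos = np.log1p(table["CD3"]) > 0.8
        cd45_pos = np.log1p(table["CD45"]) > 0.8
        # CD3+ cells are (modulo channel noise) a subset of CD45+ cells
        assert (cd3_pos & ~cd45_pos).mean() < 0.01
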