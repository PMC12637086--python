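"""Mode finding, gated scaling, the k-formula, rule annotation and
cross-modality composition comparison."""

import numpy as np
import pandas as pd
import pytest

from tmedyn.hifi import (
    annotate_hifi,
    cluster_hifi,
    compare_compositions,
    find_high_mode,
    hifi_k_neighbors,
    scale_markers,
)
from tmedyn.synthetic import (
    default_hifi_panel,
    default_mode_locations,
    simulate_hifi_intensities,
)


class TestFindHighMode:
    def test_unimodal_location(self, rng):
        v = rng.normal(2.0, 0.1, size=3000)
        assert find_high_mode(v) == pytest.approx(2.0, abs=0.05)

    def test_rightmost_mode_of_mixture(self, rng):
        v = np.concatenate([rng.normal(0.1, 0.1, 2700), rng.normal(1.5, 0.1, 300)])
        assert find_high_mode(v) == pytest.approx(1.5, abs=0.15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            find_high_mode(np.array([]))


class TestKFormula:
    @pytest.mark.parametrize("n,k", [(5000, 10), (50000, 50), (100, 10)])
    def test_k_neighbors(self, n, k):
        assert hifi_k_neighbors(n) == k


class TestScaleMarkers:
    def test_positive_population_centered_at_one(self):
        comp, panel, gating = default_hifi_panel()
        table, truth = simulate_hifi_intensities(
            comp, panel, default_mode_locations(), 4000, seed=0)
        scaled = scale_markers(table, gating)
        for m in ["CD45", "SOX9"]:
            pos = np.array([m in panel[t] for t in truth])
            assert np.median(scaled.loc[pos, m]) == pytest.approx(1.0, abs=0.1)

    def test_channel_scale_invariance(self):
        comp, panel, gating = default_hifi_panel()
        table, _ = simulate_hifi_intensities(
            comp, panel, default_mode_locations(), 3000, seed=1)
        scaled1 = scale_markers(table, gating)
        # multiplying a raw channel by a constant moves its log1p values
        # by ~log(c) for large intensities; the high mode moves with them
        table2 = table.copy()
        table2["SOX9"] = table2["SOX9"] * 10.0
        scaled2 = scale_markers(table2, gating)
        pos = scaled1["SOX9"] > 0.5
        ratio = scaled2.loc[pos, "SOX9"] / scaled1.loc[pos, "SOX9"]
        assert ratio.std() < 0.1  # same shape, uniform rescaling

    def test_gating_recovers_rare_child_mode(self, rng):
        # 2% positive child marker: global mode search lands on the
        # negative bulk; gating on the parent isolates the true mode
        n = 5000
        parent_pos = rng.random(n) < 0.30
        child_pos = parent_pos & (rng.random(n) < 0.0667)  # ~2% overall
        log_parent = np.where(parent_pos, rng.normal(1.5, 0.1, n), rng.normal(0.1, 0.05, n))
        log_child = np.where(child_pos, rng.normal(1.2, 0.1, n), rng.normal(0.1, 0.05, n))
        table = pd.DataFrame({"P": np.expm1(np.clip(log_parent, 0, None)),
                              "C": np.expm1(np.clip(log_child, 0, None))})
        # rare populations need more permissive smoothing/prominence,
        # which the scaler exposes per call
        _, modes_nogate = scale_markers(table, gating=None, min_prominence=0.02,
                                        return_modes=True)
        _, modes_gate = scale_markers(table, gating={"C": "P"}, min_prominence=0.02,
                                      return_modes=True)
        assert abs(modes_nogate.loc["C", "mode"] - 1.2) > 0.3  # wrong without gate
        assert modes_gate.loc["C", "mode"] == pytest.approx(1.2, rel=0.10)

    def test_all_negative_marker_flagged_and_small(self, rng):
        table = pd.DataFrame({"m": np.expm1(np.abs(rng.normal(0.1, 0.05, 2000)))})
        scaled, modes = scale_markers(table, return_modes=True)
        assert scaled["m"].median() < 0.5 or modes.loc["m", "mode"] < 0.5


class TestAnnotateHifi:
    def make_cluster(self, positives, markers=("A", "B", "C")):
        vals = {m: (1.0 if m in positives else 0.05) + np.zeros(20) for m in markers}
        scaled = pd.DataFrame(vals)
        labels = pd.Series(np.zeros(20, dtype=int))
        return labels, scaled

    def test_nested_rule_matches_specific_type(self):
        labels, scaled = self.make_cluster({"A", "B", "C"})
        rules = {
            "t_cytotoxic": {"necessary": ["A", "B", "C"]},
            "t_helper": {"necessary": ["A", "B"]},
        }
        assert annotate_hifi(labels, scaled, rules) == {0: "t_cytotoxic"}

    def test_unknown_positive_marker_undetermined(self):
        labels, scaled = self.make_cluster({"A", "C"})
        rules = {"x": {"necessary": ["A"]}}  # C positive but not possible for x
        assert annotate_hifi(labels, scaled, rules) == {0: "undetermined"}

    def test_ambiguous_match_warns_undetermined(self):
        labels, scaled = self.make_cluster({"A"})
        rules = {"x": {"necessary": ["A"]}, "y": {"necessary": ["A"]}}
        with pytest.warns(UserWarning, match="several"):
            out = annotate_hifi(labels, scaled, rules)
        assert out == {0: "undetermined"}


class TestCompareCompositions:
    def test_identical_compositions_r_one(self):
        f = pd.Series({"a": 0.5, "b": 0.3, "c": 0.2})
        assert compare_compositions(f, f)["pearson_r"] == pytest.approx(1.0)

    def test_shared_truth_sampled_twice(self, rng):
        truth = np.array([0.4, 0.25, 0.2, 0.1, 0.05])
        types = list("abcde")
        f1 = pd.Series(rng.multinomial(2000, truth) / 2000, index=types)
        f2 = pd.Series(rng.multinomial(2000, truth) / 2000, index=types)
        assert compare_compositions(f1, f2)["pearson_r"] >= 0.9

    def test_missing_type_floored_and_flagged(self):
        out = compare_compositions(pd.Series({"a": 1.0}), pd.Series({"a": 0.7, "b": 0.3}))
        assert "b" in out["floored_types"]


class TestEndToEnd:
    def test_six_type_recovery(self):
        comp, panel, gating = default_hifi_panel()
        table, truth = simulate_hifi_intensities(
            comp, panel, default_mode_locations(), 3000, seed=5)
        scaled = scale_markers(table, gating)
        clusters = cluster_hifi(scaled, seed=0)
        rules = {t: {"necessary": sorted(m)} for t, m in panel.items()}
        ann = annotate_hifi(clusters, scaled, rules)
        called = clusters.map(lambda c: ann.get(int(c), "undetermined") if c >= 0 else "undetermined")
        assert (called == truth).mean() >= 0.9
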