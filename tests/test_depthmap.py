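"""Ancestral depth reconstruction: contrasts, re-rooting, interpolation."""

import numpy as np
import pandas as pd
import pytest

from pelagia import depthmap, synth
from pelagia.depthmap import DepthRecord
from pelagia.trees import read_chronogram

from oracles import gls_ancestral_states, gls_root_estimate


class TestMeanDepth:
    @pytest.mark.parametrize("lo,hi,expected", [(0, 200, 100), (470, 470, 470)])
    def test_arithmetic_mean(self, lo, hi, expected):
        assert depthmap.mean_depth(DepthRecord("sp", lo, hi)) == expected

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            DepthRecord("sp", 300, 100)
        with pytest.raises(ValueError):
            DepthRecord("sp", -5, 100)

    def test_missing_bound_excluded_not_imputed(self, tmp_path):
        path = tmp_path / "depths.tsv"
        path.write_text("species\tdepth_min\tdepth_max\nA\t0\t200\nB\t100\t\n")
        df = depthmap.load_depths(path)
        assert list(df["species"]) == ["A"]
        assert df["mean_depth"].iloc[0] == 100.0


class TestPicRootEstimate:
    def test_symmetric_two_tip_average(self):
        tree = read_chronogram("(A:5,B:5);")
        est, var = depthmap.pic_root_estimate(tree, {"A": 100.0, "B": 300.0})
        assert est == pytest.approx(200.0)
        assert var > 0

    def test_constant_trait_any_topology(self):
        tree = read_chronogram("((A:1,B:2):3,(C:4,D:1):2);")
        est, var = depthmap.pic_root_estimate(tree, dict.fromkeys("ABCD", 470.0))
        assert est == pytest.approx(470.0)
        assert var == pytest.approx(0.0)

    def test_four_taxon_matches_covariance_gls(self):
        tree = read_chronogram("((A:1,B:2):1,(C:3,D:4):2);")
        values = {"A": 10.0, "B": 25.0, "C": 40.0, "D": 5.0}
        est, _ = depthmap.pic_root_estimate(tree, values)
        assert est == pytest.approx(gls_root_estimate(tree, values), abs=1e-8)

    def test_unvalued_tip_rejected(self):
        tree = read_chronogram("(A:5,B:5);")
        with pytest.raises(KeyError, match="B"):
            depthmap.pic_root_estimate(tree, {"A": 1.0})

    def test_zero_length_cherry_limit_rule(self):
        tree = read_chronogram("((A:0,B:0):5,C:10);")
        est, _ = depthmap.pic_root_estimate(tree, {"A": 100.0, "B": 200.0, "C": 150.0})
        # the zero-length cherry collapses to the simple average 150
        assert est == pytest.approx(150.0)


class TestRerootingAncestralStates:
    def test_star_tree_equal_branches_gives_mean(self):
        tree = read_chronogram("(A:2,B:2,C:2,D:2);")
        values = {"A": 10.0, "B": 20.0, "C": 30.0, "D": 40.0}
        asr = depthmap.rerooting_ancestral_states(tree, values)
        (root_label,) = [l for l in asr.states if l not in values]
        assert asr.estimate(root_label) == pytest.approx(25.0)

    def test_constant_tips_constant_ancestors(self):
        tree = read_chronogram("((A:1,B:2):3,(C:4,D:1):2);")
        asr = depthmap.rerooting_ancestral_states(tree, dict.fromkeys("ABCD", 7.0))
        assert all(est == pytest.approx(7.0) for est, _ in asr.states.values())

    def test_matches_joint_gls_oracle_on_random_trees(self):
        for rep in range(6):
            n = 4 + rep % 5  # 4..8 taxa
            tree = synth.simulate_chronogram(n, crown_age=40, seed=rep)
            ts = synth.simulate_bm_traits(tree, 300.0, 50.0, seed=rep + 50)
            asr = depthmap.rerooting_ancestral_states(tree, ts.tip_values)
            oracle = gls_ancestral_states(tree, ts.tip_values)
            for label, expected in oracle.items():
                assert asr.estimate(label) == pytest.approx(expected, abs=1e-8)

    def test_tip_states_exact_with_zero_variance(self):
        tree = read_chronogram("((A:1,B:2):3,C:4);")
        values = {"A": 1.0, "B": 2.0, "C": 3.0}
        asr = depthmap.rerooting_ancestral_states(tree, values)
        for tip, v in values.items():
            assert asr.states[tip] == (v, 0.0)

    def test_root_position_invariance(self):
        """Re-rooting the input tree before analysis leaves every nodal
        estimate unchanged: each internal estimate equals the pruning root
        state of the tree re-rooted at that node."""
        tree = synth.simulate_chronogram(7, crown_age=30, seed=3)
        ts = synth.simulate_bm_traits(tree, 100.0, 20.0, seed=99)
        asr = depthmap.rerooting_ancestral_states(tree, ts.tip_values)
        for node in list(tree.preorder_internal_node_iter()):
            clone = tree.clone(depth=1)
            target = next(
                nd for nd in clone.preorder_node_iter() if nd.label == node.label
            )
            clone.reroot_at_node(target)
            est, _ = depthmap.pic_root_estimate(clone, ts.tip_values)
            assert est == pytest.approx(asr.estimate(node.label), abs=1e-10)

    def test_estimates_within_tip_range(self):
        for rep in range(5):
            tree = synth.simulate_chronogram(8, crown_age=25, seed=rep + 20)
            ts = synth.simulate_bm_traits(tree, 0.0, 100.0, seed=rep + 70)
            asr = depthmap.rerooting_ancestral_states(tree, ts.tip_values)
            lo, hi = min(ts.tip_values.values()), max(ts.tip_values.values())
            for est, _ in asr.states.values():
                assert lo - 1e-9 <= est <= hi + 1e-9


class TestInterpolation:
    def test_endpoints_and_midpoint(self):
        tree = read_chronogram("(A:5,B:5);")
        asr = depthmap.rerooting_ancestral_states(tree, {"A": 100.0, "B": 300.0})
        profiles = depthmap.interpolate_branch_states(asr, tree, n_points=3)
        (root_label,) = [l for l in asr.states if l not in ("A", "B")]
        profile = profiles[(root_label, "A")]
        assert profile[0] == pytest.approx(asr.estimate(root_label))
        assert profile[-1] == pytest.approx(100.0)
        assert profile[1] == pytest.approx((asr.estimate(root_label) + 100.0) / 2)

    def test_two_points_are_exactly_the_endpoints(self):
        tree = read_chronogram("((A:1,B:2):3,C:4);")
        values = {"A": 1.0, "B": 5.0, "C": 3.0}
        asr = depthmap.rerooting_ancestral_states(tree, values)
        profiles = depthmap.interpolate_branch_states(asr, tree, n_points=2)
        for (parent, child), prof in profiles.items():
            assert prof[0] == asr.estimate(parent)
            assert prof[-1] == asr.estimate(child)

    def test_constant_profile_for_constant_endpoints(self):
        tree = read_chronogram("(A:5,B:5);")
        asr = depthmap.rerooting_ancestral_states(tree, {"A": 9.0, "B": 9.0})
        profiles = depthmap.interpolate_branch_states(asr, tree, n_points=7)
        assert all(np.allclose(p, 9.0) for p in profiles.values())

    def test_too_few_points_rejected(self):
        tree = read_chronogram("(A:5,B:5);")
        asr = depthmap.rerooting_ancestral_states(tree, {"A": 1.0, "B": 2.0})
        with pytest.raises(ValueError):
            depthmap.interpolate_branch_states(asr, tree, n_points=1)


class TestReconstructDepths:
    def test_full_pipeline_report(self, demo_tree):
        from pelagia import demo

        asr, report = depthmap.reconstruct_depths(demo_tree, demo.demo_depths())
        assert set(report.columns) >= {"node", "age_ma", "depth_m", "variance_m2", "zone"}
        tips = report[report["is_tip"]]
        assert (tips["variance_m2"] == 0).all()
        assert set(report["zone"]) <= {"epipelagic", "mesopelagic"}

    def test_all_epipelagic_tips_give_epipelagic_ancestors(self):
        tree = read_chronogram("((A:10,B:10):5,C:15);")
        table = pd.DataFrame(
            {"species": list("ABC"), "depth_min": [0, 10, 20], "depth_max": [100, 150, 180]}
        )
        _, report = depthmap.reconstruct_depths(tree, table)
        assert (report["zone"] == "epipelagic").all()

    def test_unmatched_tips_pruned_and_reported(self):
        tree = read_chronogram("((A:10,B:10):5,C:15);")
        table = pd.DataFrame(
            {"species": ["A", "B"], "depth_min": [0, 100], "depth_max": [100, 300]}
        )
        _, report = depthmap.reconstruct_depths(tree, table)
        assert report.attrs["pruned_tips"] == ["C"]
        assert "C" not in set(report["node"])

    def test_fewer_than_two_matched_tips_rejected(self):
        tree = read_chronogram("((A:10,B:10):5,C:15);")
        table = pd.DataFrame({"species": ["A"], "depth_min": [0], "depth_max": [100]})
        with pytest.raises(ValueError):
            depthmap.reconstruct_depths(tree, table)

    def test_root_recovery_unbiased_over_replicates(self):
        """Mean signed error of the root estimate ~ 0 on simulated BM sets."""
        tree = synth.simulate_chronogram(8, crown_age=60, seed=17)
        errors = []
        for rep in range(500):
            ts = synth.simulate_bm_traits(tree, 470.0, 2000.0, seed=rep)
            est, _ = depthmap.pic_root_estimate(tree, ts.tip_values)
            errors.append(est - 470.0)
        errors = np.asarray(errors)
        se = errors.std(ddof=1) / np.sqrt(len(errors))
        assert abs(errors.mean()) < 4 * se + 1e-9
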