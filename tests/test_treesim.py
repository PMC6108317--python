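"""Simulator behavior: age conditioning, grafting, grids."""

import numpy as np
import pytest

from shiftpower import (
    BDRates,
    GridSpec,
    find_graft_candidates,
    generate_grid,
    graft_subtree,
    simulate_bd_tree,
    simulate_composite,
    simulate_set2_composite,
)
from shiftpower.treeio import newick_string


class TestSimulateBdTree:
    def test_no_events_gives_two_pendant_tips(self):
        tree = simulate_bd_tree(7.0, BDRates(0.0, 0.0), 1)
        assert tree.n_tips == 2
        bl = np.delete(tree.branch_lengths(), tree.root)
        np.testing.assert_allclose(bl, [7.0, 7.0])

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_crown_age_and_ultrametricity(self, seed):
        age = 9.0
        tree = simulate_bd_tree(age, BDRates(0.3, 0.1), seed, max_tips=500)
        assert tree.crown_age == pytest.approx(age, rel=1e-12)
        depths = tree.age[tree.parent[tree.tip_ids()]] - 0.0
        # all tips at age exactly zero by construction
        assert np.all(tree.age[tree.tip_ids()] == 0.0)
        assert tree.n_tips >= 2

    def test_yule_crown_mean_tip_count(self):
        """Mean tips of age-conditioned Yule crowns matches 2 e^(lam t)."""
        lam, t, reps = 0.25, 8.0, 4000
        rng = np.random.default_rng(77)
        counts = np.array([
            simulate_bd_tree(t, BDRates(lam, 0.0), rng, max_tips=400).n_tips
            for _ in range(reps)
        ])
        expect = 2.0 * np.exp(lam * t)
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(counts.mean() - expect) < 3 * se


class TestGraftCandidates:
    def test_both_depth_one_nodes_found(self, balanced4):
        assert sorted(find_graft_candidates(balanced4, 4.0)) == sorted(
            int(i) for i in balanced4.internal_ids(include_root=False)
        )

    def test_no_candidate_outside_window(self, balanced4):
        assert find_graft_candidates(balanced4, 8.0) == []

    def test_window_is_relative(self, balanced4):
        # 4 lies inside [4.1*0.975, 4.1*1.025] = [3.9975, 4.2025]
        assert len(find_graft_candidates(balanced4, 4.1)) == 2

    def test_target_must_be_below_crown(self, balanced4):
        with pytest.raises(ValueError):
            find_graft_candidates(balanced4, 11.0)


@pytest.fixture(scope="module")
def grafted():
    base = simulate_bd_tree(10.0, BDRates(0.25, 0.05), 11, max_tips=300)
    target = 0.4 * base.crown_age
    cands = [c for c in find_graft_candidates(base, target, rel_tol=0.2)
             if base.age[base.parent[c]] > target]
    assert cands, "fixture tree must offer a graft point"
    at = cands[0]
    sub = simulate_bd_tree(float(base.age[at]), BDRates(0.6, 0.05), 12,
                           max_tips=300)
    return base, sub, at, graft_subtree(base, sub, at)


class TestGraft:
    def test_tip_bookkeeping(self, grafted):
        base, sub, at, shift = grafted
        pruned = len(base.clade_tips(at))
        assert shift.tree.n_tips == base.n_tips - pruned + sub.n_tips
        assert shift.n_subtree_tips == sub.n_tips

    def test_composite_ultrametric_with_base_crown_age(self, grafted):
        base, _, _, shift = grafted
        tree = shift.tree
        assert tree.crown_age == pytest.approx(base.crown_age, rel=1e-12)
        assert np.all(tree.age[tree.tip_ids()] == 0.0)
        bl = np.delete(tree.branch_lengths(), tree.root)
        assert np.all(bl > 0)

    def test_graft_crown_age_survives_newick_round_trip(self, grafted):
        from shiftpower.treeio import read_newick

        _, sub, _, shift = grafted
        back = read_newick(newick_string(shift.tree))
        node = back.find_by_label("SHIFT")
        assert back.age[node] == pytest.approx(sub.crown_age, rel=1e-9)

    def test_states_partition_by_descent(self, grafted):
        _, _, _, shift = grafted
        tree = shift.tree
        mask = tree.clade_mask(shift.graft_node)
        subtree_tips = {tree.labels[i]
                        for i in np.flatnonzero(mask & tree.is_tip)}
        assert subtree_tips == {t for t, s in shift.tip_states.items() if s == 1}
        assert set(shift.tip_states) == set(tree.tip_labels())

    def test_invalid_graft_points_rejected(self, grafted):
        base, sub, _, _ = grafted
        with pytest.raises(ValueError):
            graft_subtree(base, sub, base.root)
        with pytest.raises(ValueError):
            graft_subtree(base, sub, int(base.tip_ids()[0]))


@pytest.fixture(scope="module")
def composite():
    return simulate_composite((100, 10), BDRates(0.2, 0.05),
                              BDRates(0.5, 0.05), 40.0, seed=5)


class TestComposite:
    def test_size_window(self, composite):
        assert 90 <= composite.tree.n_tips <= 110

    def test_truth_metadata(self, composite):
        assert composite.asymmetry == pytest.approx(2.5)
        assert composite.base_rates.mu == composite.sub_rates.mu == 0.05
        assert composite.subtree_age < composite.tree.crown_age
        assert composite.meta["s_age"] == pytest.approx(
            0.4 * composite.meta["b_age"])
        # graft node crown age matched the target within the 2.5% window
        assert composite.subtree_age == pytest.approx(
            composite.meta["s_age"], rel=0.026)

    def test_ultrametric(self, composite):
        tree = composite.tree
        spread = (tree.age[tree.parent[tree.tip_ids()]]
                  - tree.age[tree.tip_ids()])
        assert np.all(spread > 0)
        assert np.all(tree.age[tree.tip_ids()] == 0.0)


@pytest.fixture(scope="module")
def set2_tree():
    return simulate_set2_composite((50, 10), (1, 9), seed=3)


class TestSet2Composite:
    def test_asymmetry_fixed_at_two(self, set2_tree):
        assert set2_tree.asymmetry == pytest.approx(2.0)
        assert set2_tree.base_rates.lam in (0.2, 0.26, 0.28)

    def test_part_sizes_near_ratio_targets(self, set2_tree):
        nb, ns = set2_tree.n_basetree_tips, set2_tree.n_subtree_tips
        assert 40 <= nb + ns <= 60
        assert 5 * 0.75 <= nb <= 5 * 1.25
        assert 45 * 0.75 <= ns <= 45 * 1.25

    def test_100_at_1_9_remapped_to_1_8(self):
        shift = simulate_set2_composite((100, 10), (1, 9), seed=9)
        assert shift.meta["tip_ratio"] == "1:8"
        nb = shift.n_basetree_tips
        target = 100 / 9.0
        assert target * 0.75 <= nb <= target * 1.25

    def test_unsupported_ratio_rejected(self):
        with pytest.raises(ValueError):
            simulate_set2_composite((50, 10), (2, 5), seed=1)


class TestGrid:
    def _tiny_spec(self):
        return GridSpec(set_id=1, size_classes=[(50, 10)],
                        asymmetries=[3.5, 5.5], rel_ages=[40.0],
                        replicates=2, base_seed=123)

    def test_cell_enumeration(self):
        spec = self._tiny_spec()
        assert len(spec.cells()) == 2
        assert len(list(generate_grid(spec))) == 4

    def test_grid_determinism_byte_identical(self):
        spec = self._tiny_spec()
        out1 = [(row["seed"], newick_string(s.tree))
                for row, s in generate_grid(spec)]
        out2 = [(row["seed"], newick_string(s.tree))
                for row, s in generate_grid(spec)]
        assert out1 == out2

    def test_manifest_matches_truth(self):
        for row, shift in generate_grid(self._tiny_spec()):
            assert row["n_tips"] == shift.tree.n_tips
            assert row["lam1"] == pytest.approx(
                row["asymmetry"] * row["lam0"])
            assert row["n_basetree_tips"] + row["n_subtree_tips"] == row["n_tips"]
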