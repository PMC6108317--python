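"""Likelihood engines against closed forms and independent oracles.

Oracles used here are deliberately independent of the implementation:
the Yule closed form is evaluated by hand, the two-state character
likelihood is recomputed by exhaustive enumeration of internal-node
states, and the BiSSE branch system is re-integrated with scipy's
DOP853 from a plain right-hand side.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from shiftpower import (
    BDRates,
    BisseParams,
    LikelihoodOptions,
    NEG_LL,
    bd_loglik,
    bisse_loglik,
    mk2_loglik,
    simulate_bd_tree,
)
from shiftpower.treeio import read_newick

# ----------------------------------------------------------------------
# independent oracles


def mk2_bruteforce(tree, states, q01, q10, root_weights=(0.5, 0.5)):
    """Sum over all internal-node state assignments with 2x2 expm."""
    q = np.array([[-q01, q01], [q10, -q10]], dtype=float)
    internals = [int(i) for i in tree.postorder_internal]
    total = 0.0
    for assign_bits in range(2 ** len(internals)):
        assign = {v: (assign_bits >> j) & 1 for j, v in enumerate(internals)}
        for root_state in (0, 1):
            a = dict(assign)
            a[int(tree.root)] = root_state
            if assign[int(tree.root)] != root_state:
                continue
            prob = root_weights[root_state]
            for i in range(tree.n_nodes):
                parent = int(tree.parent[i])
                if parent < 0:
                    continue
                s_par = a[parent]
                s_child = (states[tree.labels[i]] if tree.is_tip[i]
                           else a[int(i)])
                p = expm(q * (tree.age[parent] - tree.age[i]))
                prob *= p[s_par, s_child]
            total += prob
    return total


def bisse_scipy(tree, states, p, root_rule="obs", cond=True):
    """Re-integration of the BiSSE system with scipy's DOP853."""

    def rhs(t, y):
        e0, e1, d0, d1 = y
        return [
            p.mu0 - (p.lam0 + p.mu0 + p.q01) * e0 + p.q01 * e1 + p.lam0 * e0 * e0,
            p.mu1 - (p.lam1 + p.mu1 + p.q10) * e1 + p.q10 * e0 + p.lam1 * e1 * e1,
            -(p.lam0 + p.mu0 + p.q01) * d0 + p.q01 * d1 + 2 * p.lam0 * e0 * d0,
            -(p.lam1 + p.mu1 + p.q10) * d1 + p.q10 * d0 + 2 * p.lam1 * e1 * d1,
        ]

    vals = {}
    for i in tree.tip_ids():
        s = states[tree.labels[int(i)]]
        vals[int(i)] = np.array([0.0, 0.0, 1.0 - s, float(s)])
    for v in tree.postorder_internal:
        v = int(v)
        ys = []
        for c in (int(tree.left[v]), int(tree.right[v])):
            sol = solve_ivp(rhs, (tree.age[c], tree.age[v]), vals[c],
                            rtol=1e-11, atol=1e-13, method="DOP853")
            ys.append(sol.y[:, -1])
        yl, yr = ys
        vals[v] = np.array([
            0.5 * (yl[0] + yr[0]), 0.5 * (yl[1] + yr[1]),
            p.lam0 * yl[2] * yr[2], p.lam1 * yl[3] * yr[3],
        ])
    root = vals[int(tree.root)]
    d, e = root[2:], root[:2]
    w = d / d.sum() if root_rule == "obs" else np.array([0.5, 0.5])
    val = float(w @ d)
    if cond:
        val /= float(w @ (np.array([p.lam0, p.lam1]) * (1 - e) ** 2))
    return np.log(val)


# ----------------------------------------------------------------------
# birth-death


class TestBdLoglik:
    # hand-derived: conditioned Yule log-likelihood on the fixed 5-tip
    # caterpillar (node ages 10, 6, 3, 1, total branch time 30) is
    # (n-2) ln lam - lam * 30
    @pytest.mark.parametrize("lam,expected", [
        (0.2, 3 * np.log(0.2) - 6.0),            # = -10.828313737302301
        (0.35, 3 * np.log(0.35) - 10.5),         # = -13.649466373496034
    ])
    def test_yule_closed_form(self, caterpillar5, lam, expected):
        got = bd_loglik(caterpillar5, BDRates(lam, 0.0), conditioned=True)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_mu_to_zero_continuity(self, caterpillar5):
        yule = bd_loglik(caterpillar5, BDRates(0.2, 0.0))
        near = bd_loglik(caterpillar5, BDRates(0.2, 1e-10))
        assert abs(near - yule) < 1e-6

    def test_depends_only_on_branching_times(self):
        # same node ages, different labelings/topologies of attachment
        t1 = read_newick("((((a:1,b:1):2,c:3):3,d:6):4,e:10);")
        t2 = read_newick("((((e:1,d:1):2,c:3):3,b:6):4,a:10);")
        r = BDRates(0.3, 0.12)
        assert bd_loglik(t1, r) == pytest.approx(bd_loglik(t2, r), abs=1e-12)

    def test_supercritical_extinction_allowed(self, caterpillar5):
        # mu > lam is a valid likelihood evaluation
        val = bd_loglik(caterpillar5, BDRates(0.2, 0.3))
        assert np.isfinite(val)

    def test_lambda_zero_rejected(self, caterpillar5):
        with pytest.raises(ValueError):
            bd_loglik(caterpillar5, BDRates(0.0, 0.0))

    def test_critical_lam_equals_mu_continuous(self, caterpillar5):
        at = bd_loglik(caterpillar5, BDRates(0.2, 0.2))
        near = bd_loglik(caterpillar5, BDRates(0.2, 0.2 - 1e-9))
        assert at == pytest.approx(near, abs=1e-5)


# ----------------------------------------------------------------------
# Mk2


class TestMk2:
    def test_frozen_character_equal_weights(self):
        tree = read_newick("(a:5,b:5);")
        ll = mk2_loglik(tree, {"a": 0, "b": 0}, 0.0, 0.0, root_rule="equal")
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_impossible_transition_sentinel(self):
        tree = read_newick("(a:5,b:5);")
        assert mk2_loglik(tree, {"a": 0, "b": 1}, 0.0, 0.0,
                          root_rule="equal") == NEG_LL

    def test_missing_state_named(self):
        tree = read_newick("(a:5,b:5);")
        with pytest.raises(KeyError, match="b"):
            mk2_loglik(tree, {"a": 0}, 0.1, 0.1)

    @pytest.mark.parametrize("newick,states", [
        ("((a:2,b:2):3,c:5);", {"a": 0, "b": 1, "c": 1}),
        ("((a:1,b:1):4,(c:3,d:3):2);", {"a": 0, "b": 0, "c": 1, "d": 0}),
    ])
    @pytest.mark.parametrize("q01,q10", [(0.3, 0.1), (0.05, 0.4), (0.2, 0.2)])
    def test_matches_bruteforce_enumeration(self, newick, states, q01, q10):
        tree = read_newick(newick)
        mine = mk2_loglik(tree, states, q01, q10, root_rule="equal")
        brute = mk2_bruteforce(tree, states, q01, q10)
        assert mine == pytest.approx(np.log(brute), abs=1e-10)


# ----------------------------------------------------------------------
# BiSSE


class TestBisse:
    def test_matches_independent_integration(self, random_trees):
        rng = np.random.default_rng(31)
        tree = random_trees[0]
        states = {lab: int(rng.random() < 0.5) for lab in tree.tip_labels()}
        for _ in range(4):
            p = BisseParams(
                *np.exp(rng.uniform(np.log(0.05), np.log(1.0), 2)),
                *rng.uniform(0.0, 0.3, 2), *rng.uniform(0.005, 0.3, 2))
            assert bisse_loglik(tree, states, p) == pytest.approx(
                bisse_scipy(tree, states, p), abs=1e-5)

    def test_equal_rates_factorization(self, random_trees):
        """bisse = bd + mk2 when both states share lam and mu."""
        rng = np.random.default_rng(7)
        for tree in random_trees[:6]:
            states = {lab: int(rng.random() < 0.5)
                      for lab in tree.tip_labels()}
            lam = rng.uniform(0.05, 1.0)
            mu = rng.uniform(0.0, 0.5 * lam)
            q01, q10 = rng.uniform(0.001, 0.5, 2)
            joint = bisse_loglik(tree, states,
                                 BisseParams(lam, lam, mu, mu, q01, q10))
            split = (bd_loglik(tree, BDRates(lam, mu), conditioned=True)
                     + mk2_loglik(tree, states, q01, q10, root_rule="obs"))
            assert joint == pytest.approx(split, abs=1e-6)

    def test_probability_bounds_along_branches(self, random_trees):
        tree = random_trees[1]
        states = {lab: int(i % 2) for i, lab in enumerate(tree.tip_labels())}
        p = BisseParams(0.4, 0.8, 0.2, 0.1, 0.05, 0.02)
        _, diag = bisse_loglik(tree, states, p, return_diagnostics=True)
        assert 0.0 <= diag["min_E"] and diag["max_E"] <= 1.0
        assert diag["min_D"] >= 0.0

    def test_state_swap_symmetry(self, random_trees):
        tree = random_trees[2]
        states = {lab: int(i % 3 == 0)
                  for i, lab in enumerate(tree.tip_labels())}
        flipped = {k: 1 - v for k, v in states.items()}
        p = BisseParams(0.3, 0.7, 0.1, 0.05, 0.08, 0.02)
        opts = LikelihoodOptions(root_rule="equal")
        assert bisse_loglik(tree, states, p, opts) == pytest.approx(
            bisse_loglik(tree, flipped, p.swapped(), opts), abs=1e-9)

    def test_child_order_invariance(self):
        t1 = read_newick("((a:2,b:2):3,(c:4,d:4):1);")
        t2 = read_newick("((d:4,c:4):1,(b:2,a:2):3);")
        states = {"a": 0, "b": 1, "c": 1, "d": 0}
        p = BisseParams(0.3, 0.5, 0.1, 0.1, 0.1, 0.05)
        assert bisse_loglik(t1, states, p) == pytest.approx(
            bisse_loglik(t2, states, p), abs=1e-9)

    def test_parameter_continuity(self, random_trees):
        tree = random_trees[3]
        states = {lab: int(i % 2) for i, lab in enumerate(tree.tip_labels())}
        base = BisseParams(0.4, 0.6, 0.1, 0.1, 0.05, 0.05)
        ll0 = bisse_loglik(tree, states, base)
        for bumped in [
            BisseParams(0.4 + 1e-6, 0.6, 0.1, 0.1, 0.05, 0.05),
            BisseParams(0.4, 0.6, 0.1 + 1e-6, 0.1, 0.05, 0.05),
            BisseParams(0.4, 0.6, 0.1, 0.1, 0.05 + 1e-6, 0.05),
        ]:
            assert abs(bisse_loglik(tree, states, bumped) - ll0) < 1e-3

    def test_tolerance_insensitivity_large_tree(self):
        tree = simulate_bd_tree(11.0, BDRates(0.55, 0.05), 27, max_tips=2000)
        assert tree.n_tips >= 500
        states = {lab: int(i % 2) for i, lab in enumerate(tree.tip_labels())}
        p = BisseParams(0.5, 0.6, 0.05, 0.05, 0.03, 0.03)
        loose = bisse_loglik(tree, states, p,
                             LikelihoodOptions(rtol=1e-6, atol=1e-8))
        tight = bisse_loglik(tree, states, p,
                             LikelihoodOptions(rtol=1e-9, atol=1e-11))
        assert abs(loose - tight) < 1e-4
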