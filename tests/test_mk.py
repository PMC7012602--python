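"""Mk transition probabilities, pruning likelihoods, fits, AICc machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import enumerate_mk_loglik, random_coding, random_tree_with_lengths
from normevol.mk import (
    DegenerateDataError,
    MkModel,
    aicc,
    aicc_weights,
    compare_hypotheses,
    fit_mk,
    mk_loglik,
    transition_matrix,
)
from normevol.parsimony import MISSING
from normevol.synth import simulate_mk_tips, simulate_tree
from normevol.trees import MissingBranchLengthError, parse_newick


class TestTransitionMatrix:
    def test_identity_at_zero(self):
        P = transition_matrix(MkModel(3, 0.7), 0.0)
        np.testing.assert_allclose(P, np.eye(3), atol=1e-15)

    def test_ergodic_limit_uniform(self):
        P = transition_matrix(MkModel(3, 0.7), 1e6)
        np.testing.assert_allclose(P, np.full((3, 3), 1 / 3), atol=1e-12)

    def test_two_state_closed_form(self):
        # P_same(t) = 1/2 + 1/2 e^{-2qt}
        q, t = 0.5, 1.0
        P = transition_matrix(MkModel(2, q), t)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-1.0), abs=1e-15)
        assert P[0, 0] == pytest.approx(0.6839397205, abs=1e-9)

    @pytest.mark.parametrize("t", [0.0, 0.3, 5.0, 1e3])
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_rows_sum_to_one(self, k, t):
        P = transition_matrix(MkModel(k, 1.3), t)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_matches_generator(self):
        # finite-difference check against the rate matrix at small t
        m = MkModel(3, 0.9)
        dt = 1e-7
        P = transition_matrix(m, dt)
        np.testing.assert_allclose(
            (P - np.eye(3)) / dt, m.rate_matrix, atol=1e-6
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(MkModel(2, 1.0), -0.1)


class TestLoglik:
    def test_cherry_rate_zero_limit_is_prior_only(self):
        t = parse_newick("(A:1,B:1);")
        ll = mk_loglik(t, {"A": 0, "B": 0}, MkModel(2, 1e-12), states=(0, 1))
        assert ll == pytest.approx(math.log(0.5), abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        k = int(rng.integers(2, 4))
        states = tuple(range(k))
        tree = random_tree_with_lengths(n, rng)
        coding = random_coding(tree, states, rng, p_missing=0.2)
        model = MkModel(k, float(rng.uniform(0.05, 2.0)))
        got = mk_loglik(tree, coding, model, states=states)
        want = enumerate_mk_loglik(tree, coding, model, states)
        assert got == pytest.approx(want, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_clamped_likelihoods_sum_to_unclamped(self, seed):
        """Law of total probability at every internal node."""
        rng = np.random.default_rng(200 + seed)
        tree = random_tree_with_lengths(int(rng.integers(4, 8)), rng)
        states = (0, 1, 2)
        coding = random_coding(tree, states, rng)
        model = MkModel(3, float(rng.uniform(0.1, 1.5)))
        total = mk_loglik(tree, coding, model, states=states)
        for v in tree.internal_ids:
            taxa = tree.subtree_taxa(v)
            if len(taxa) < 2:
                continue
            parts = [
                mk_loglik(tree, coding, model, constraint=(taxa, s),
                          states=states)
                for s in states
            ]
            summed = math.log(sum(math.exp(p) for p in parts))
            assert summed == pytest.approx(total, rel=1e-10)

    def test_invariant_to_zero_length_polytomy_resolution(self):
        states = (0, 1)
        coding = {"A": 0, "B": 1, "C": 1}
        poly = parse_newick("(A:1,B:1,C:1);")
        resolved = parse_newick("((B:1,C:1):1e-12,A:1);")
        m = MkModel(2, 0.6)
        # resolving the polytomy with an ~0-length edge changes nothing
        assert mk_loglik(resolved, coding, m, states=states) == pytest.approx(
            mk_loglik(poly, coding, m, states=states), rel=1e-6
        )

    def test_missing_branch_lengths_rejected(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(MissingBranchLengthError):
            mk_loglik(t, {"A": 0, "B": 1, "C": 0}, MkModel(2, 1.0),
                      states=(0, 1))


class TestFit:
    def test_constrained_never_beats_unconstrained(self):
        rng = np.random.default_rng(42)
        tree = random_tree_with_lengths(8, rng)
        coding = random_coding(tree, (0, 1), rng)
        free = fit_mk(tree, coding, n_states=2)
        taxa = tree.subtree_taxa(tree.root_id)
        for s in (0, 1):
            con = fit_mk(tree, coding, n_states=2, constraint=(taxa, s))
            assert con.lnL <= free.lnL + 1e-6

    def test_identical_tips_drive_rate_to_lower_bound(self):
        t = parse_newick("(A:1,B:1);")
        fit = fit_mk(t, {"A": 0, "B": 0}, n_states=2)
        assert fit.at_bound and fit.q_hat < 1e-6

    def test_all_missing_degenerate(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(DegenerateDataError):
            fit_mk(t, {"A": MISSING, "B": MISSING})

    def test_parameter_recovery_smoke(self):
        # pilot-scale recovery; the 200-replicate version runs in acceptance
        q_true = 1.0
        estimates = []
        for seed in range(20):
            tree = simulate_tree(100, seed=seed)
            tips = simulate_mk_tips(tree, MkModel(2, q_true), seed=seed)
            estimates.append(fit_mk(tree, tips, n_states=2).q_hat)
        med = float(np.median(estimates))
        assert 0.6 < med < 1.6


class TestInformationCriteria:
    def test_aicc_thirteen_species_formula(self):
        assert aicc(0.0, 1, 13) == pytest.approx(2 + 4 / 11)

    def test_aicc_limits(self):
        assert aicc(-10.0, 0, 5) == pytest.approx(20.0)
        assert aicc(-10.0, 1, 10**9) == pytest.approx(22.0, abs=1e-6)
        with pytest.raises(ValueError):
            aicc(0.0, 1, 2)

    def test_weight_examples(self):
        np.testing.assert_allclose(aicc_weights([10.0, 10.0]), [1.0, 1.0])
        np.testing.assert_allclose(
            aicc_weights([10.0, 12.0]), [1.0, math.exp(-1)]
        )
        # a 3.2-unit AICc gap sits at the 0.2 decision boundary
        w = aicc_weights([5.0, 8.2])
        assert w[1] == pytest.approx(0.2019, abs=1e-4)

    @given(
        deltas=st.lists(st.floats(0, 50, allow_nan=False), min_size=1,
                        max_size=6)
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_weights_in_unit_interval_best_is_one(self, deltas):
        a = [100.0] + [100.0 + d for d in deltas]
        w = aicc_weights(a)
        assert w[0] == 1.0
        assert ((w > 0) & (w <= 1)).all()
        wn = aicc_weights(a, normalize=True)
        assert wn.sum() == pytest.approx(1.0)


class TestCompareHypotheses:
    def test_self_consistent_constraint_not_significant(self):
        # clamping a node to the state the data already prefer costs ~nothing
        nwk = "((A:0.1,B:0.1):1,(C:0.1,D:0.1):1);"
        tree = parse_newick(nwk)
        coding = {"A": 1, "B": 1, "C": 1, "D": 1}
        tab = compare_hypotheses(
            tree, coding, [("same", {"A", "B"}, 1)], n_states=2,
            states=(0, 1),
        )
        row = tab[tab.model == "same"].iloc[0]
        assert row["delta_lnL"] == pytest.approx(0.0, abs=1e-6)
        assert not row["significant"]

    def test_wrong_root_state_detected_with_strong_signal(self):
        # conserved character on a shallow tree: the root state is nearly
        # certain, so clamping the wrong state is flagged
        rng = np.random.default_rng(0)
        tree = simulate_tree(60, seed=4)
        # rescale so expected change count is tiny
        scaled = parse_newick(tree.write_newick())
        total = sum(l for l in scaled.edge_length[:-1] if l)
        tips = simulate_mk_tips(scaled, MkModel(2, 0.05 / total * 60), seed=9)
        taxa = set(scaled.tip_labels)
        counts = [list(tips.values()).count(s) for s in (0, 1)]
        true_root = int(np.argmax(counts))
        tab = compare_hypotheses(
            tree, tips, [("wrong", taxa, 1 - true_root)], n_states=2,
            states=(0, 1),
        )
        assert bool(tab.iloc[1]["significant"])

    def test_fixture_hypotheses_all_below_two_units(self, fixture_data):
        """No constrained ancestral-state hypothesis is significantly worse
        than the unconstrained model on the comparative dataset."""
        fx = fixture_data
        for char, k in [("size_plasticity", 3), ("titer_20e", 2),
                        ("ecr_eyespot", 2)]:
            hyps = [
                (n, t, s) for n, c, t, s in fx.hypotheses if c == char
            ]
            tab = compare_hypotheses(
                fx.tree, fx.coding(char), hyps, n_states=k,
                states=tuple(range(k)),
            )
            assert (tab["delta_lnL"] < 2.0).all()
            assert not tab["significant"].any()
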