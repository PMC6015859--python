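import numpy as np
import pytest

from tsbisse.bisse_core import (
    EpochRates,
    LikCondition,
    SamplingFractions,
    TimeSliceParams,
    bd_loglik,
    integrate_branch,
    mk_loglik,
    mk_transition_matrix,
    ode_rhs,
    tree_loglik,
)
from tsbisse.errors import LikelihoodError
from tsbisse.treeio import TraitDataset

from conftest import random_states, random_ultrametric_tree
from oracles import bisse_loglik_rk4, mk_loglik_expm


class TestOdeRhs:
    def test_direct_substitution(self):
        r = EpochRates(1.0, 0.0, 0.5, 0.0, 0.1, 0.0)
        d = ode_rhs(0.0, [0.0, 0.0, 1.0, 0.0], r)
        assert d[2] == pytest.approx(-1.6)  # dD0 = -(1 + 0.5 + 0.1)
        assert d[0] == pytest.approx(0.5)  # dE0 = mu0

    def test_zero_rates_zero_derivative(self):
        r = EpochRates(0, 0, 0, 0, 0, 0)
        assert np.all(ode_rhs(0.0, [0.3, 0.7, 0.5, 0.2], r) == 0.0)

    def test_symmetry(self):
        r = EpochRates(0.3, 0.3, 0.1, 0.1, 0.05, 0.05)
        d = ode_rhs(1.0, [0.2, 0.2, 0.6, 0.6], r)
        assert d[0] == pytest.approx(d[1])
        assert d[2] == pytest.approx(d[3])

    def test_nan_rejected(self):
        r = EpochRates(0.1, 0.1, 0, 0, 0, 0)
        with pytest.raises(LikelihoodError):
            ode_rhs(0.0, [np.nan, 0, 1, 1], r)

    def test_negative_rate_rejected(self):
        with pytest.raises(LikelihoodError):
            EpochRates(-0.1, 0, 0, 0, 0, 0)


class TestIntegrateBranch:
    def test_pure_death_closed_form(self):
        # lam = q = 0, mu = 0.5: D(s) = D0 e^{-mu s}, E(s) = 1 - e^{-mu s}
        p = TimeSliceParams.constant(EpochRates(0, 0, 0.5, 0.5, 0, 0))
        E, D, ls = integrate_branch([0, 0], [1, 1], 0.0, 2.0, p)
        assert D[0] * np.exp(ls) == pytest.approx(np.exp(-1.0), abs=1e-8)
        assert E[0] == pytest.approx(1 - np.exp(-1.0), abs=1e-8)

    def test_pure_markov_matrix_exponential(self):
        # lam = mu = 0, q symmetric: D evolves by the 2-state CTMC
        p = TimeSliceParams.constant(EpochRates(0, 0, 0, 0, 0.5, 0.5))
        E, D, ls = integrate_branch([0, 0], [1, 0], 0.0, 1.0, p)
        D = D * np.exp(ls)
        assert D[0] == pytest.approx((1 + np.exp(-1)) / 2, abs=1e-8)
        assert D[1] == pytest.approx((1 - np.exp(-1)) / 2, abs=1e-8)

    def test_identical_epochs_inert(self):
        r = EpochRates(0.3, 0.2, 0.1, 0.05, 0.07, 0.03)
        one = TimeSliceParams.constant(r)
        two = TimeSliceParams.two_epoch(r, r, 1.3)
        E1, D1, l1 = integrate_branch([0.1, 0.2], [1, 0.5], 0.0, 3.0, one)
        E2, D2, l2 = integrate_branch([0.1, 0.2], [1, 0.5], 0.0, 3.0, two)
        np.testing.assert_allclose(E1, E2, atol=1e-8)
        np.testing.assert_allclose(
            D1 * np.exp(l1), D2 * np.exp(l2), rtol=1e-8
        )

    def test_E_monotone_and_bounded_with_extinction(self):
        p = TimeSliceParams.constant(EpochRates(0.2, 0.2, 0.3, 0.1, 0.05, 0.05))
        prev = np.array([0.0, 0.0])
        for hi in np.linspace(0.5, 20, 10):
            E, D, ls = integrate_branch([0, 0], [1, 1], 0.0, float(hi), p)
            assert np.all(E >= prev - 1e-9)
            assert np.all(E <= 1.0)
            prev = E

    def test_invalid_span_rejected(self):
        p = TimeSliceParams.constant(EpochRates(0.1, 0.1, 0, 0, 0, 0))
        with pytest.raises(LikelihoodError):
            integrate_branch([0, 0], [1, 1], 2.0, 1.0, p)


class TestTreeLoglik:
    def test_matches_rk4_oracle_two_tips(self, cherry):
        traits = TraitDataset({"A": 0, "B": 1})
        p = TimeSliceParams.constant(EpochRates(0.2, 0.2, 0.1, 0.1, 0.05, 0.05))
        ll = tree_loglik(cherry, traits, p)
        oracle = bisse_loglik_rk4(
            cherry, traits.state_array(cherry), p, step=1e-4
        )
        assert ll == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_rk4_oracle_random_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tree = random_ultrametric_tree(10, seed)
        traits = random_states(tree, seed + 50)
        er = EpochRates(*rng.uniform(0.02, 0.4, 6))
        if seed % 2:
            er2 = EpochRates(*rng.uniform(0.02, 0.4, 6))
            p = TimeSliceParams.two_epoch(er, er2, 0.5 * tree.height)
        else:
            p = TimeSliceParams.constant(er)
        ll = tree_loglik(tree, traits, p)
        oracle = bisse_loglik_rk4(
            tree, traits.state_array(tree), p, step=5e-4
        )
        assert ll == pytest.approx(oracle, abs=1e-5)

    def test_full_sampling_equals_no_correction(self, bd_tree_traits):
        tree, traits = bd_tree_traits
        p = TimeSliceParams.constant(EpochRates(0.25, 0.2, 0.1, 0.1, 0.05, 0.08))
        a = tree_loglik(tree, traits, p)
        b = tree_loglik(tree, traits, p, SamplingFractions(1.0, 1.0))
        assert a == b

    def test_child_permutation_invariance(self, bd_tree_traits):
        tree, traits = bd_tree_traits
        p = TimeSliceParams.constant(EpochRates(0.25, 0.2, 0.1, 0.05, 0.05, 0.08))
        base = tree_loglik(tree, traits, p)
        swapped = tree.children.copy()
        swapped[tree.n_tips :, 0] = tree.children[tree.n_tips :, 1]
        swapped[tree.n_tips :, 1] = tree.children[tree.n_tips :, 0]
        import tsbisse.treeio as tio

        t2 = tio.PhyloTree(
            tree.tip_labels, tree.parent, swapped, tree.branch_length, tree.age
        )
        assert tree_loglik(t2, traits, p) == pytest.approx(base, abs=1e-10)

    def test_epoch_inertness(self, bd_tree_traits):
        tree, traits = bd_tree_traits
        r = EpochRates(0.3, 0.2, 0.1, 0.05, 0.07, 0.03)
        a = tree_loglik(tree, traits, TimeSliceParams.constant(r))
        for frac in (0.13, 0.5, 0.87):
            b = tree_loglik(
                tree, traits,
                TimeSliceParams.two_epoch(r, r, frac * tree.height),
            )
            assert b == pytest.approx(a, abs=1e-8)

    @pytest.mark.parametrize("seed", range(12))
    def test_factorization_equal_rates(self, seed):
        """With state-independent rates, BiSSE = birth-death x Mk."""
        rng = np.random.default_rng(2000 + seed)
        tree = random_ultrametric_tree(int(rng.integers(5, 60)), seed + 7)
        traits = random_states(tree, seed + 99)
        lam, mu = rng.uniform(0.05, 0.5), rng.uniform(0.0, 0.3)
        q01, q10 = rng.uniform(0.01, 0.4, 2)
        f = float(rng.uniform(0.4, 1.0))
        p = TimeSliceParams.constant(EpochRates(lam, lam, mu, mu, q01, q10))
        ll = tree_loglik(tree, traits, p, SamplingFractions(f, f))
        expected = bd_loglik(tree, lam, mu, f) + mk_loglik(tree, traits, q01, q10)
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_missing_state_raises(self, cherry):
        traits = TraitDataset({"A": 0, "B": None})
        p = TimeSliceParams.constant(EpochRates(0.2, 0.2, 0, 0, 0.05, 0.05))
        with pytest.raises(Exception, match="prune"):
            tree_loglik(cherry, traits, p)


class TestBdLoglik:
    def test_yule_closed_form(self, yule5):
        lam = 0.3
        S = yule5.total_branch_length()
        expected = (5 - 1) * np.log(lam) - lam * S
        got = bd_loglik(yule5, lam, 0.0, 1.0, condition_on_survival=False)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_critical_limit_continuous(self, yule5):
        # lam -> mu handled analytically, continuous in the limit
        near = bd_loglik(yule5, 0.2, 0.2 - 1e-9, 1.0)
        at = bd_loglik(yule5, 0.2, 0.2, 1.0)
        assert near == pytest.approx(at, abs=1e-5)

    def test_reduction_from_tree_loglik(self, bd_tree_small):
        # one effective state: q = 0, all tips state 0, mirrored rates
        tree = bd_tree_small
        traits = TraitDataset({lab: 0 for lab in tree.tip_labels})
        for lam, mu, rho in [(0.3, 0.1, 1.0), (0.25, 0.2, 0.7)]:
            p = TimeSliceParams.constant(EpochRates(lam, lam, mu, mu, 0, 0))
            a = tree_loglik(tree, traits, p, SamplingFractions(rho, rho))
            b = bd_loglik(tree, lam, mu, rho)
            assert a == pytest.approx(b, abs=1e-6)

    def test_invalid_rho(self, cherry):
        with pytest.raises(LikelihoodError):
            bd_loglik(cherry, 0.2, 0.1, 0.0)


class TestMkLoglik:
    def test_cherry_closed_form_equal_root(self, cherry):
        q = 0.5
        P = mk_transition_matrix(q, q, 1.0)
        expected = np.log(0.5 * (P[0, 0] ** 2 + P[1, 0] ** 2))
        traits = TraitDataset({"A": 0, "B": 0})
        got = mk_loglik(cherry, traits, q, q, LikCondition(root_mode="equal", condition_on_survival=False))
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_expm_oracle(self, seed):
        tree = random_ultrametric_tree(15, 300 + seed)
        traits = random_states(tree, seed)
        rng = np.random.default_rng(seed)
        q01, q10 = rng.uniform(0.05, 0.6, 2)
        got = mk_loglik(tree, traits, q01, q10)
        oracle = mk_loglik_expm(tree, traits.state_array(tree), q01, q10)
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_zero_rates_identical_states(self, cherry):
        traits = TraitDataset({"A": 1, "B": 1})
        got = mk_loglik(cherry, traits, 0.0, 0.0, LikCondition(root_mode="equal", condition_on_survival=False))
        assert got == pytest.approx(np.log(0.5), abs=1e-12)

    def test_long_branch_stationarity(self):
        from tsbisse.treeio import read_newick

        t = read_newick("(A:500,B:500);")
        q01, q10 = 0.3, 0.1
        pi1 = q01 / (q01 + q10)
        traits = TraitDataset({"A": 1, "B": 0})
        got = mk_loglik(
            t, traits, q01, q10,
            LikCondition(root_mode="prior", prior=(1 - pi1, pi1), condition_on_survival=False),
        )
        assert got == pytest.approx(np.log(pi1) + np.log(1 - pi1), abs=1e-3)
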