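import numpy as np
import pytest
from scipy import stats

from tsbisse.bisse_core import EpochRates, TimeSliceParams
from tsbisse.errors import SimulationError, TsbisseError
from tsbisse.simulate import (
    apply_sampling,
    sim_bd_tree,
    sim_bisse_timeslice,
    sim_mk_trait,
)

from oracles import yule_branching_cdf


class TestSimMkTrait:
    def test_zero_rates_keep_root_state(self, bd_tree_small):
        h = sim_mk_trait(bd_tree_small, 0.0, 0.0, root_state=1, seed=1)
        assert all(s == 1 for s in h.tip_states.values())
        assert h.n_transitions() == 0

    def test_fast_rates_reach_symmetric_stationarity(self):
        tree = sim_bd_tree(800, 50.0, 0.2, 0.05, seed=2)
        h = sim_mk_trait(tree, 10.0, 10.0, seed=3)
        freq = h.state_count(1) / tree.n_tips
        # stationary 1/2; tips are effectively independent at q = 10
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(tree.n_tips)

    def test_asymmetric_stationary_frequency(self):
        # long branches: tip frequency ~ q01/(q01+q10) = 0.006/0.023
        tree = sim_bd_tree(1000, 400.0, 0.05, 0.0, seed=4)
        q01, q10 = 0.006, 0.017
        h = sim_mk_trait(tree, q01, q10, seed=5)
        pi1 = q01 / (q01 + q10)
        freq = h.state_count(1) / tree.n_tips
        assert abs(freq - pi1) < 4 * np.sqrt(pi1 * (1 - pi1) / 200)

    def test_segments_tile_and_match_tip_states(self, bd_tree_small):
        h = sim_mk_trait(bd_tree_small, 0.3, 0.2, seed=6)
        t = bd_tree_small
        for v in range(t.n_nodes - 1):
            segs = h.segments[v]
            assert segs[0][1] == pytest.approx(float(t.age[t.parent[v]]))
            assert segs[-1][2] == pytest.approx(float(t.age[v]))
            for (s1, _, e1), (s2, b2, _) in zip(segs[:-1], segs[1:]):
                assert e1 == b2 and s1 != s2
            assert segs[-1][0] == h.node_states[v]

    def test_seed_replay(self, bd_tree_small):
        a = sim_mk_trait(bd_tree_small, 0.2, 0.3, seed=7)
        b = sim_mk_trait(bd_tree_small, 0.2, 0.3, seed=7)
        assert a.tip_states == b.tip_states
        assert [e.age for e in a.events] == [e.age for e in b.events]


class TestSimBdTree:
    @pytest.mark.parametrize("seed", range(5))
    def test_exact_conditioning(self, seed):
        t = sim_bd_tree(1774, 105.0, 0.2, 0.19, seed=seed)
        assert t.n_tips == 1774
        assert t.height == pytest.approx(105.0, abs=1e-9)

    def test_two_tip_cherry(self):
        t = sim_bd_tree(2, 7.0, 0.3, 0.1, seed=1)
        assert t.n_tips == 2
        assert t.height == pytest.approx(7.0)

    def test_yule_branching_age_distribution(self):
        """Non-crown branching ages under mu = 0 follow the closed-form
        order-statistic density (KS test over pooled draws)."""
        lam, T, n = 0.35, 12.0, 10
        ages = []
        for seed in range(250):
            t = sim_bd_tree(n, T, lam, 0.0, seed=seed)
            b = t.branching_ages()
            ages.extend(b[1:])  # drop the crown age (fixed at T)
        u = yule_branching_cdf(np.asarray(ages), lam, T)
        p = stats.kstest(u, "uniform").pvalue
        assert p > 0.01

    def test_invalid_args(self):
        with pytest.raises(TsbisseError):
            sim_bd_tree(1, 10.0, 0.2, 0.1)
        with pytest.raises(TsbisseError):
            sim_bd_tree(10, -1.0, 0.2, 0.1)


class TestSimBisseTimeslice:
    def test_yule_expected_tip_count(self):
        # crown start, no death/transitions: E[n] = 2 e^{lam T}
        lam, T = 0.15, 20.0
        p = TimeSliceParams.constant(EpochRates(lam, lam, 0, 0, 0, 0))
        counts = [
            sim_bisse_timeslice(
                p, T, min_tips=2, max_tips=100_000, seed=s, start="crown"
            ).tree.n_tips
            for s in range(40)
        ]
        expect = 2 * np.exp(lam * T)
        # geometric-ish spread; compare the mean within MC error
        assert np.mean(counts) == pytest.approx(expect, rel=0.35)

    def test_all_rates_zero_crown_gives_cherry(self):
        p = TimeSliceParams.constant(EpochRates(0, 0, 0, 0, 0, 0))
        h = sim_bisse_timeslice(p, 5.0, min_tips=2, max_tips=10, seed=1, start="crown")
        assert h.tree.n_tips == 2
        assert h.tree.height == pytest.approx(5.0)

    def test_all_rates_zero_origin_rejected(self):
        p = TimeSliceParams.constant(EpochRates(0, 0, 0, 0, 0, 0))
        with pytest.raises(SimulationError):
            sim_bisse_timeslice(
                p, 5.0, min_tips=2, max_tips=10, seed=1,
                start="origin", max_attempts=5,
            )

    def test_extinction_shift_reduces_state1_fraction(self):
        """Raising the recent-epoch extinction of state 1 lowers its tip
        share versus the no-shift control (one-sided comparison)."""
        base = EpochRates(0.2, 0.2, 0.02, 0.02, 0.02, 0.02)
        shifted = EpochRates(0.2, 0.2, 0.02, 0.3, 0.02, 0.02)
        p_null = TimeSliceParams.two_epoch(base, base, 2.6)
        p_shift = TimeSliceParams.two_epoch(shifted, base, 2.6)
        fr_null, fr_shift = [], []
        for s in range(12):
            h0 = sim_bisse_timeslice(
                p_null, 18.0, root_state=1, min_tips=20, max_tips=5000, seed=s
            )
            h1 = sim_bisse_timeslice(
                p_shift, 18.0, root_state=1, min_tips=20, max_tips=5000, seed=s
            )
            fr_null.append(h0.state_count(1) / h0.tree.n_tips)
            fr_shift.append(h1.state_count(1) / h1.tree.n_tips)
        assert np.mean(fr_shift) < np.mean(fr_null)

    def test_reconstructed_tree_valid_and_replayable(self):
        rec = EpochRates(0.25, 0.25, 0.05, 0.1, 0.03, 0.03)
        old = EpochRates(0.25, 0.25, 0.05, 0.05, 0.03, 0.03)
        p = TimeSliceParams.two_epoch(rec, old, 2.6)
        a = sim_bisse_timeslice(p, 15.0, min_tips=10, max_tips=2000, seed=8)
        b = sim_bisse_timeslice(p, 15.0, min_tips=10, max_tips=2000, seed=8)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.tip_states == b.tip_states
        assert np.all(a.tree.age[: a.tree.n_tips] == 0.0)
        # tip states consistent with the event log's final states
        n_trans = a.n_transitions()
        assert n_trans == sum(1 for e in a.events if e.kind == "transition")


class TestApplySampling:
    def _history(self):
        tree = sim_bd_tree(1000, 40.0, 0.2, 0.02, seed=9)
        return sim_mk_trait(tree, 0.05, 0.05, seed=10)

    def test_full_fractions_identity(self):
        h = self._history()
        out = apply_sampling(h, 1.0, 1.0, seed=1)
        assert out.tree.n_tips == h.tree.n_tips
        assert out.tip_states == h.tip_states

    def test_half_sampling_binomial(self):
        h = self._history()
        out = apply_sampling(h, 0.5, 0.5, seed=2)
        n = out.tree.n_tips
        assert abs(n - 500) < 4 * np.sqrt(1000 * 0.25)

    def test_per_state_retention_matches_study_fractions(self):
        h = self._history()
        out = apply_sampling(h, 0.68, 0.82, seed=3)
        n0 = h.state_count(0)
        n1 = h.state_count(1)
        f0r = out.params["f0_realized"]
        f1r = out.params["f1_realized"]
        assert abs(f0r - 0.68) < 4 * np.sqrt(0.68 * 0.32 / n0)
        assert abs(f1r - 0.82) < 4 * np.sqrt(0.82 * 0.18 / n1)

    def test_invalid_fraction(self):
        h = self._history()
        with pytest.raises(TsbisseError):
            apply_sampling(h, 0.0, 1.0)
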