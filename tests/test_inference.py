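import numpy as np
import pytest
from scipy import stats

from tsbisse.bisse_core import EpochRates, SamplingFractions, TimeSliceParams, bd_loglik
from tsbisse.errors import ConvergenceError, TsbisseError
from tsbisse.inference import (
    MCMCChain,
    fit_mk,
    fit_mle,
    run_mcmc,
    slice_sampler,
    summarize_posterior,
)
from tsbisse.model_space import ConstraintSpec
from tsbisse.simulate import sim_bd_tree, sim_mk_trait


@pytest.fixture(scope="module")
def small_fit_problem():
    tree = sim_bd_tree(60, 20.0, 0.25, 0.05, seed=21)
    hist = sim_mk_trait(tree, 0.08, 0.08, seed=22)
    return tree, hist.traits()


class TestFitMle:
    def test_refit_from_mle_is_fixed_point(self, small_fit_problem):
        tree, traits = small_fit_problem
        spec = ConstraintSpec.from_structures("S", "S", "S")
        fit1 = fit_mle(tree, traits, spec, starts=2, seed=1)
        fit2 = fit_mle(
            tree, traits, spec, starts=1, seed=2, init=fit1.free_values
        )
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-6)

    def test_loglik_at_optimum_beats_start(self, small_fit_problem):
        tree, traits = small_fit_problem
        spec = ConstraintSpec.from_structures("D", "S", "S")
        from tsbisse.inference import make_loglik_fn, _start_values

        fit = fit_mle(tree, traits, spec, starts=2, seed=3)
        fn = make_loglik_fn(tree, traits, spec, 2.6)
        assert fit.loglik >= fn(_start_values(spec, tree)) - 1e-9

    def test_nested_never_beats_full(self, small_fit_problem):
        tree, traits = small_fit_problem
        nested = ConstraintSpec.from_structures("S", "S", "S")
        full = ConstraintSpec.from_structures("D", "D", "S")
        f_n = fit_mle(tree, traits, nested, starts=2, seed=4)
        f_f = fit_mle(
            tree, traits, full, starts=2, seed=5,
        )
        assert f_f.loglik >= f_n.loglik - 1e-4

    def test_parameter_recovery_constant_rate(self):
        """MLEs on data simulated under constant-rate BiSSE recover the
        generating rates within 30% relative error on average."""
        spec = ConstraintSpec.from_structures("S", "S", "S")
        lam_hat, q_hat = [], []
        for rep in range(4):
            tree = sim_bd_tree(500, 30.0, 0.2, 0.05, seed=600 + rep)
            hist = sim_mk_trait(tree, 0.05, 0.05, seed=700 + rep)
            fit = fit_mle(tree, hist.traits(), spec, starts=1, seed=rep)
            d = fit.param_dict()
            lam_hat.append(d["lam_a"])
            q_hat.append(d["q_a"])
        assert np.mean(lam_hat) == pytest.approx(0.2, rel=0.30)
        assert np.mean(q_hat) == pytest.approx(0.05, rel=0.30)

    def test_invalid_starts(self, small_fit_problem):
        tree, traits = small_fit_problem
        spec = ConstraintSpec.from_structures("S", "S", "S")
        with pytest.raises(TsbisseError):
            fit_mle(tree, traits, spec, starts=0)


class TestFitMk:
    def test_symmetric_recovers_rate(self):
        tree = sim_bd_tree(600, 40.0, 0.2, 0.02, seed=31)
        hist = sim_mk_trait(tree, 0.05, 0.05, seed=32)
        r = fit_mk(tree, hist.traits(), symmetric=True)
        assert r["q01"] == r["q10"]
        assert r["q01"] == pytest.approx(0.05, rel=0.5)


class TestSliceSampler:
    def test_gaussian_target_moments(self):
        # positive-orthant Gaussian bump centred away from zero
        def logpost(x):
            return -0.5 * ((x[0] - 3.0) / 0.5) ** 2

        s, lps, w = slice_sampler(logpost, np.array([2.0]), 8000, seed=5)
        assert np.mean(s) == pytest.approx(3.0, abs=0.05)
        assert np.std(s) == pytest.approx(0.5, abs=0.05)

    def test_seeded_determinism(self):
        def logpost(x):
            return -x.sum()

        a, _, _ = slice_sampler(logpost, np.array([1.0, 1.0]), 200, seed=9)
        b, _, _ = slice_sampler(logpost, np.array([1.0, 1.0]), 200, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_yule_posterior_matches_conjugate_gamma(self):
        """Slice sampling the Yule speciation-rate posterior with an
        exponential prior reproduces the analytic Gamma posterior."""
        tree = sim_bd_tree(50, 10.0, 0.4, 0.0, seed=41)
        n, S, b = tree.n_tips, tree.total_branch_length(), 1.0

        def logpost(x):
            if x[0] <= 0:
                return -np.inf
            return (
                bd_loglik(tree, float(x[0]), 0.0, 1.0, condition_on_survival=False)
                - b * x[0]
            )

        s, _, _ = slice_sampler(logpost, np.array([0.3]), 10_000, seed=42)
        # posterior ∝ lam^{n-1} e^{-lam(S+b)} = Gamma(n, S+b)
        for q in (0.05, 0.5, 0.95):
            analytic = stats.gamma.ppf(q, a=n, scale=1.0 / (S + b))
            sampled = np.quantile(s[:, 0], q)
            assert sampled == pytest.approx(analytic, rel=0.03)


class TestRunMcmc:
    def test_reproducible_and_positive(self, small_fit_problem):
        tree, traits = small_fit_problem
        spec = ConstraintSpec.from_structures("S", "S", "S")
        kw = dict(generations=60, warmup=20, seed=13)
        a = run_mcmc(tree, traits, spec, **kw)
        b = run_mcmc(tree, traits, spec, **kw)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.generations == 60
        assert np.all(a.samples >= 0)

    def test_concentrated_prior_dominates(self, small_fit_problem):
        tree, traits = small_fit_problem
        spec = ConstraintSpec.from_structures("S", "S", "S")
        # prior mean far below the data scale pulls the posterior down
        tight = run_mcmc(
            tree, traits, spec, generations=150, warmup=50, seed=14,
            prior_mean=1e-4,
        )
        loose = run_mcmc(
            tree, traits, spec, generations=150, warmup=50, seed=14,
            prior_mean=10.0,
        )
        assert np.median(tight.samples) < np.median(loose.samples)


class TestSummarizePosterior:
    def _chain(self, values, spec=None):
        spec = spec or ConstraintSpec.from_structures("S", "S", "S")
        samples = np.tile(np.asarray(values, float), (20, 1))
        return MCMCChain(
            spec=spec, cutoff=2.6, samples=samples, loglik=np.zeros(20)
        )

    def test_constant_chain_all_quantiles_equal(self):
        ch = self._chain([0.2, 0.1, 0.05])
        summ = summarize_posterior([ch], burn_in=0.1)
        q = summ.quantiles("lam0", "recent")
        assert np.all(q == pytest.approx(0.2))
        # derived net diversification
        r = summ.quantiles("r0", "recent")
        assert np.all(r == pytest.approx(0.1))

    def test_quantile_monotonicity(self, small_fit_problem):
        tree, traits = small_fit_problem
        spec = ConstraintSpec.from_structures("S", "S", "S")
        ch = run_mcmc(tree, traits, spec, generations=80, warmup=20, seed=15)
        summ = summarize_posterior([ch], burn_in=0.25)
        for _, row in summ.table.iterrows():
            qs = row[["q05", "q25", "q50", "q75", "q95"]].to_numpy(float)
            assert np.all(np.diff(qs) >= -1e-12)

    def test_pooling_identical_chains_is_identity(self):
        a = self._chain([0.2, 0.1, 0.05])
        b = self._chain([0.2, 0.1, 0.05])
        one = summarize_posterior([a], burn_in=0.0).table
        two = summarize_posterior([a, b], burn_in=0.0).table
        merged = one.merge(two, on=["rate", "epoch"], suffixes=("_1", "_2"))
        for q in ("q05", "q50", "q95"):
            np.testing.assert_allclose(merged[f"{q}_1"], merged[f"{q}_2"])

    def test_empty_burn_in_window_errors(self):
        ch = self._chain([0.2, 0.1, 0.05])
        with pytest.raises(TsbisseError):
            summarize_posterior([ch], burn_in=1.0)
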