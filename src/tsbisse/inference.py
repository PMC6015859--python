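"""Maximum-likelihood fitting and Bayesian MCMC for constrained models.

Fitting maximizes the time-sliced BiSSE log-likelihood over the free
parameters of a :class:`~tsbisse.model_space.ConstraintSpec`, working on
log-rates within box bounds and combining L-BFGS-B with a Nelder-Mead
polish from multiple perturbed starts (SSE likelihood surfaces can be
multimodal under constraints).

The sampler is a univariate stepping-out slice sampler (one coordinate
sweep per generation) with independent exponential priors on the rates,
initialized at the MLE, with step widths tuned during a short warm-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .bisse_core import LikCondition, SamplingFractions, tree_loglik
from .errors import ConvergenceError, TsbisseError
from .model_space import ConstraintSpec, FitResult
from .treeio import PhyloTree, TraitDataset

RATE_BOUNDS = (1e-8, 1e3)  # Myr^-1, applied to every free rate

_BAD = -1e12  # finite stand-in for -inf inside optimizers


def diversification_heuristic(tree: PhyloTree) -> float:
    """Character-independent net-diversification guess from tip count and
    age: r_hat = log(n/2) / T (crown Yule-style estimate, Myr^-1)."""
    n, T = tree.n_tips, tree.height
    return max(np.log(n / 2.0) / T, 1e-4)


def _start_values(spec: ConstraintSpec, tree: PhyloTree) -> np.ndarray:
    """Heuristic start: lam from the diversification guess, mu somewhat
    below lam, q an order of magnitude below."""
    r_hat = diversification_heuristic(tree)
    base = {"lam": 2.0 * r_hat, "mu": r_hat, "q": 0.2 * r_hat}
    vals = []
    for pid in spec.free_params:
        fam = pid.split("_")[0]
        vals.append(base[fam])
    return np.array(vals)


def make_loglik_fn(
    tree: PhyloTree,
    traits: TraitDataset,
    spec: ConstraintSpec,
    cutoff: float,
    f: SamplingFractions = SamplingFractions(),
    cond: LikCondition = LikCondition(),
    rtol: float = None,
    atol: float = None,
) -> Callable[[np.ndarray], float]:
    """Log-likelihood as a function of the free-parameter vector.

    ``rtol``/``atol`` override the solver tolerances (long MCMC runs on
    large trees are well served by looser-than-default tolerances; the
    posterior is insensitive to log-likelihood errors far below 1)."""
    from .bisse_core import DEFAULT_ATOL, DEFAULT_RTOL

    rtol = DEFAULT_RTOL if rtol is None else rtol
    atol = DEFAULT_ATOL if atol is None else atol
    states = traits.state_array(tree)  # validates completeness up front
    _ = states

    def fn(values: np.ndarray) -> float:
        try:
            params = spec.to_params(values, cutoff)
        except Exception:
            return -np.inf
        return tree_loglik(
            tree, traits, params, f, cond, rtol=rtol, atol=atol,
            on_fail="neginf",
        )

    return fn


def fit_mle(
    tree: PhyloTree,
    traits: TraitDataset,
    spec: ConstraintSpec,
    cutoff: float = 2.6,
    f: SamplingFractions = SamplingFractions(),
    cond: LikCondition = LikCondition(),
    starts: int = 5,
    seed: int = 0,
    init: Optional[np.ndarray] = None,
    bounds: Tuple[float, float] = RATE_BOUNDS,
    rtol: float = None,
    atol: float = None,
) -> FitResult:
    """Box-constrained ML fit of one constrained two-epoch model.

    ``starts`` multi-starts perturb the heuristic (or supplied) initial
    values on the log scale; the best converged optimum is returned.
    """
    if starts < 1:
        raise TsbisseError("starts must be >= 1")
    rng = np.random.default_rng(seed)
    loglik = make_loglik_fn(tree, traits, spec, cutoff, f, cond, rtol, atol)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    x0 = np.log(np.clip(init if init is not None else _start_values(spec, tree),
                        bounds[0], bounds[1]))
    n_evals = 0

    def neg(logx: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        ll = loglik(np.exp(logx))
        return -ll if np.isfinite(ll) else -_BAD

    best_x, best_ll = None, -np.inf
    start_lls = []
    for s in range(starts):
        x = x0 if s == 0 else np.clip(x0 + rng.normal(0, 0.75, x0.size), lo, hi)
        start_lls.append(-neg(x))
        res = optimize.minimize(
            neg, x, method="L-BFGS-B",
            bounds=[(lo, hi)] * x.size,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        # simplex polish catches rough spots of the finite-difference path
        res2 = optimize.minimize(
            neg, res.x, method="Nelder-Mead",
            options={"maxfev": 150 * x.size, "fatol": 1e-8, "xatol": 1e-6},
        )
        cand = res2 if res2.fun < res.fun else res
        if -cand.fun > best_ll:
            best_ll = -cand.fun
            best_x = np.clip(cand.x, lo, hi)
    if best_x is None or not np.isfinite(best_ll) or best_ll <= _BAD / 2:
        raise ConvergenceError(
            f"all {starts} starts failed for model {spec.name}; "
            f"start log-likelihoods: {start_lls}"
        )
    return FitResult(
        spec=spec,
        cutoff=cutoff,
        free_values=np.exp(best_x),
        loglik=float(best_ll),
        converged=True,
        n_starts=starts,
        n_evals=n_evals,
        message=f"best of {starts} starts",
    )


def fit_mk(
    tree: PhyloTree,
    traits: TraitDataset,
    symmetric: bool = True,
    cond: LikCondition = LikCondition(condition_on_survival=False),
    bounds: Tuple[float, float] = RATE_BOUNDS,
) -> Dict[str, float]:
    """Maximum-likelihood Mk transition rates (trait-only model).

    Returns ``{"q01": ..., "q10": ..., "loglik": ...}``; with
    ``symmetric=True`` a single shared rate is estimated.
    """
    from .bisse_core import mk_loglik

    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def neg(logx: np.ndarray) -> float:
        q = np.exp(logx)
        q01, q10 = (q[0], q[0]) if symmetric else (q[0], q[1])
        try:
            return -mk_loglik(tree, traits, q01, q10, cond)
        except Exception:
            return -_BAD

    k = 1 if symmetric else 2
    x0 = np.full(k, np.log(0.05))
    res = optimize.minimize(
        neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * k,
        options={"maxiter": 200},
    )
    res2 = optimize.minimize(
        neg, res.x, method="Nelder-Mead", options={"fatol": 1e-9, "xatol": 1e-7}
    )
    best = res2 if res2.fun < res.fun else res
    q = np.exp(best.x)
    q01, q10 = (float(q[0]), float(q[0])) if symmetric else (float(q[0]), float(q[1]))
    return {"q01": q01, "q10": q10, "loglik": float(-best.fun)}


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class MCMCChain:
    """Posterior samples for one tree under one model structure."""

    spec: ConstraintSpec
    cutoff: float
    samples: np.ndarray  # (generations, k)
    loglik: np.ndarray  # (generations,)
    tree_id: str = ""
    seed: int = 0
    step_widths: Optional[np.ndarray] = None
    prior_mean: float = np.nan

    @property
    def generations(self) -> int:
        return self.samples.shape[0]

    @property
    def param_names(self) -> List[str]:
        return self.spec.free_params

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=self.param_names)
        df.insert(0, "generation", np.arange(1, self.generations + 1))
        df["loglik"] = self.loglik
        return df


def _slice_sample_coord(logpost, x, i, w, lp0, rng, max_steps=50):
    """One stepping-out/shrinkage slice update of coordinate i (Neal 2003),
    respecting the positivity constraint."""
    y = lp0 + np.log(rng.random())
    u = rng.random()
    L = max(x[i] - u * w, 0.0)
    R = L + w
    j = int(np.floor(rng.random() * max_steps))
    k = max_steps - 1 - j
    xi = x.copy()
    while j > 0 and L > 0:
        xi[i] = L
        if logpost(xi) <= y:
            break
        L = max(L - w, 0.0)
        j -= 1
    while k > 0:
        xi[i] = R
        if logpost(xi) <= y:
            break
        R += w
        k -= 1
    while True:
        xnew = L + rng.random() * (R - L)
        xi[i] = xnew
        lp = logpost(xi)
        if lp > y:
            return xnew, lp
        if xnew < x[i]:
            L = xnew
        else:
            R = xnew
        if R - L < 1e-14 * max(1.0, x[i]):
            return x[i], lp0


def slice_sampler(
    logpost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    generations: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    widths: Optional[np.ndarray] = None,
    warmup: int = 500,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generic coordinate-wise slice sampler on the positive orthant.

    One full coordinate sweep per generation.  ``warmup`` extra
    generations tune the step widths from the sampled spread and are
    discarded.  Returns (samples, log-posterior trace, final widths).
    """
    x = np.asarray(x0, dtype=float).copy()
    k = x.size
    if rng is None:
        rng = np.random.default_rng(seed)
    w = (
        np.asarray(widths, dtype=float).copy()
        if widths is not None
        else np.maximum(0.5 * np.abs(x), 0.1)
    )
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ConvergenceError("non-finite posterior at the initial point")
    if warmup > 0:
        warm = np.empty((warmup, k))
        for g in range(warmup):
            for i in range(k):
                x[i], lp = _slice_sample_coord(logpost, x, i, w[i], lp, rng)
            warm[g] = x
        spread = warm[warmup // 2 :].std(axis=0)
        w = np.where(spread > 0, 3.0 * spread, w)
    samples = np.empty((generations, k))
    lps = np.empty(generations)
    for g in range(generations):
        for i in range(k):
            x[i], lp = _slice_sample_coord(logpost, x, i, w[i], lp, rng)
        samples[g] = x
        lps[g] = lp
    return samples, lps, w


def run_mcmc(
    tree: PhyloTree,
    traits: TraitDataset,
    spec: ConstraintSpec,
    cutoff: float = 2.6,
    f: SamplingFractions = SamplingFractions(),
    cond: LikCondition = LikCondition(),
    generations: int = 10_000,
    seed: int = 0,
    init: Optional[np.ndarray] = None,
    prior_mean: Optional[float] = None,
    warmup: int = 500,
    tree_id: str = "",
    rtol: float = None,
    atol: float = None,
) -> MCMCChain:
    """Slice-sampling MCMC over the free rates of one constrained model.

    Priors are independent exponentials with mean ``prior_mean`` (default
    2 * r_hat, the character-independent diversification heuristic).  The
    chain starts at ``init`` (e.g. the MLE) or the heuristic start; step
    widths are tuned during ``warmup`` extra generations, which are not
    part of the returned trace.
    """
    if generations < 1:
        raise TsbisseError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    loglik = make_loglik_fn(tree, traits, spec, cutoff, f, cond, rtol, atol)
    k = spec.k
    if prior_mean is None:
        prior_mean = 2.0 * diversification_heuristic(tree)
    prior_rate = 1.0 / prior_mean

    def logpost_fn(x: np.ndarray) -> float:
        if np.any(x < 0):
            return -np.inf
        ll = loglik(x)
        if not np.isfinite(ll):
            return -np.inf
        return ll - prior_rate * float(x.sum())  # + const

    x0 = np.asarray(
        init if init is not None else _start_values(spec, tree), dtype=float
    ).copy()
    w0 = np.maximum(0.5 * x0, 0.05 * prior_mean)
    samples, lps, w = slice_sampler(
        logpost_fn, x0, generations, rng=rng, widths=w0, warmup=warmup
    )
    lls = lps + prior_rate * samples.sum(axis=1)
    return MCMCChain(
        spec=spec,
        cutoff=cutoff,
        samples=samples,
        loglik=lls,
        tree_id=tree_id,
        seed=seed,
        step_widths=w,
        prior_mean=prior_mean,
    )


QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)

_SLOT_RATES = ("lam0", "lam1", "mu0", "mu1", "q01", "q10")


@dataclass
class PosteriorSummary:
    """Pooled posterior quantiles per rate slot and epoch.

    ``table`` has one row per (rate, epoch) including the derived net
    diversification rates r0 = lam0 - mu0 and r1 = lam1 - mu1, with
    columns q05/q25/q50/q75/q95.
    """

    table: pd.DataFrame
    pooled_n: int

    def quantiles(self, rate: str, epoch: str) -> np.ndarray:
        row = self.table[(self.table.rate == rate) & (self.table.epoch == epoch)]
        if row.empty:
            raise TsbisseError(f"no summary row for ({rate}, {epoch})")
        return row[[f"q{int(q * 100):02d}" for q in QUANTILES]].to_numpy()[0]


def summarize_posterior(
    chains: Sequence[MCMCChain], burn_in: float = 0.1
) -> PosteriorSummary:
    """Pool post-burn-in samples across chains (trees) and summarize.

    Returns 5/25/50/75/95% quantiles for every rate slot in both epochs
    plus the per-state net diversification rates.
    """
    if not chains:
        raise TsbisseError("need at least one chain")
    if not (0 <= burn_in < 1):
        raise TsbisseError("burn_in must be in [0, 1)")
    spec = chains[0].spec
    cutoff = chains[0].cutoff
    pooled: Dict[Tuple[str, str], List[np.ndarray]] = {}
    total = 0
    for ch in chains:
        if ch.spec.name != spec.name:
            raise TsbisseError("all chains must share one model structure")
        drop = int(np.floor(burn_in * ch.generations))
        kept = ch.samples[drop:]
        if kept.shape[0] == 0:
            raise ConvergenceError("no post-burn-in samples")
        total += kept.shape[0]
        cols = {pid: j for j, pid in enumerate(ch.param_names)}
        for ep in ("recent", "old"):
            slot_vals = {}
            for rate in _SLOT_RATES:
                v = kept[:, cols[spec.param_of(rate, ep)]]
                slot_vals[rate] = v
                pooled.setdefault((rate, ep), []).append(v)
            pooled.setdefault(("r0", ep), []).append(
                slot_vals["lam0"] - slot_vals["mu0"]
            )
            pooled.setdefault(("r1", ep), []).append(
                slot_vals["lam1"] - slot_vals["mu1"]
            )
    rows = []
    for (rate, ep), chunks in pooled.items():
        v = np.concatenate(chunks)
        qs = np.quantile(v, QUANTILES)
        rows.append(
            {
                "rate": rate,
                "epoch": ep,
                **{f"q{int(q * 100):02d}": val for q, val in zip(QUANTILES, qs)},
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["model"] = spec.name
    table.attrs["cutoff"] = cutoff
    return PosteriorSummary(table=table, pooled_n=total)
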