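"""Time-sliced BiSSE likelihood and its constant-rate reductions.

The binary-state speciation-extinction (BiSSE) model gives every lineage a
state-dependent speciation rate lam_i, extinction rate mu_i and transition
rate q_ij (all in Myr^-1).  Along a branch the per-state extinction
probability E_i(s) and data partial D_i(s) obey

    dE_i/ds = mu_i - (lam_i + mu_i + q_ij) E_i + q_ij E_j + lam_i E_i^2
    dD_i/ds = -(lam_i + mu_i + q_ij) D_i + q_ij D_j + 2 lam_i E_i D_i

with s measured in age (towards the past).  Time-slicing makes all six
rates piecewise constant in age, switching at fixed breakpoints; the ODE is
integrated segment by segment, restarting exactly at each boundary.

Incomplete sampling enters only through the tip initial conditions
(skeletal-tree correction): a tip in state i starts with D_i = f_i and
E_j = 1 - f_j for both states, where f_j is the per-state sampling
fraction.  At each internal node the partials combine as
D_i = lam_i(node age) * D_left,i * D_right,i; at the root the two states
are aggregated under a configurable weighting, optionally conditioning on
the survival of both root lineages (dividing state i's contribution by
lam_i (1 - E_i(T))^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .errors import LikelihoodError, TreeValidationError
from .treeio import PhyloTree, TraitDataset, validate_breakpoints

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

_RATE_NAMES = ("lam0", "lam1", "mu0", "mu1", "q01", "q10")


@dataclass(frozen=True)
class EpochRates:
    """One epoch's rate set (all Myr^-1, finite, non-negative)."""

    lam0: float
    lam1: float
    mu0: float
    mu1: float
    q01: float
    q10: float

    def __post_init__(self):
        for name in _RATE_NAMES:
            x = getattr(self, name)
            if not np.isfinite(x) or x < 0:
                raise LikelihoodError(f"rate {name} must be finite and >= 0, got {x}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _RATE_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "EpochRates":
        return cls(*[float(x) for x in arr])


@dataclass(frozen=True)
class TimeSliceParams:
    """Piecewise-constant BiSSE rates.

    ``breakpoints`` are strictly increasing ages (Ma); ``epochs[0]`` is the
    most recent epoch [0, breakpoints[0]).  Empty breakpoints give the
    constant-rate model.
    """

    breakpoints: Tuple[float, ...]
    epochs: Tuple[EpochRates, ...]

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size and np.any(np.diff(bp) <= 0):
            raise LikelihoodError("breakpoints must be strictly increasing")
        if len(self.epochs) != bp.size + 1:
            raise LikelihoodError(
                f"need {bp.size + 1} epochs for {bp.size} breakpoints, "
                f"got {len(self.epochs)}"
            )
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in bp))
        object.__setattr__(self, "epochs", tuple(self.epochs))

    @classmethod
    def constant(cls, rates: EpochRates) -> "TimeSliceParams":
        return cls(breakpoints=(), epochs=(rates,))

    @classmethod
    def two_epoch(
        cls, recent: EpochRates, old: EpochRates, cutoff: float
    ) -> "TimeSliceParams":
        return cls(breakpoints=(cutoff,), epochs=(recent, old))

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def rates_matrix(self) -> np.ndarray:
        return np.stack([e.as_array() for e in self.epochs])

    def bp_array(self) -> np.ndarray:
        return np.asarray(self.breakpoints, dtype=np.float64)

    def epoch_at(self, age: float) -> EpochRates:
        return self.epochs[_kernels.epoch_index(age, self.bp_array())]


@dataclass(frozen=True)
class SamplingFractions:
    """Per-state probability that an extant species is in the tree."""

    f0: float = 1.0
    f1: float = 1.0

    def __post_init__(self):
        for name in ("f0", "f1"):
            x = getattr(self, name)
            if not (0 < x <= 1):
                raise LikelihoodError(f"sampling fraction {name} must be in (0, 1]")


ROOT_MODES = {"fitzjohn": 0, "equal": 1, "prior": 2}


@dataclass(frozen=True)
class LikCondition:
    """Root treatment: state-weighted ("fitzjohn", the default), equal
    weights, or a fixed prior; plus optional survival conditioning."""

    root_mode: str = "fitzjohn"
    condition_on_survival: bool = True
    prior: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.root_mode not in ROOT_MODES:
            raise LikelihoodError(f"unknown root mode {self.root_mode!r}")
        if self.root_mode == "prior":
            if self.prior is None or not np.isclose(sum(self.prior), 1.0):
                raise LikelihoodError("fixed root prior must sum to 1")

    def _mode_int(self) -> int:
        return ROOT_MODES[self.root_mode]

    def _prior(self) -> Tuple[float, float]:
        return self.prior if self.prior is not None else (0.5, 0.5)


def ode_rhs(age: float, y: Sequence[float], rates: EpochRates) -> np.ndarray:
    """Right-hand side of the BiSSE ODEs at a given age (pure function).

    ``y = (E0, E1, D0, D1)``; the age argument only documents the time
    convention -- within one epoch the system is autonomous.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (4,) or not np.all(np.isfinite(y)):
        raise LikelihoodError("state vector must be 4 finite numbers")
    return _kernels._rhs(y, rates.as_array())


def integrate_branch(
    E_init: Sequence[float],
    D_init: Sequence[float],
    age_lo: float,
    age_hi: float,
    params: TimeSliceParams,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Integrate (E, D) from ``age_lo`` to ``age_hi`` across epochs.

    Returns ``(E, D, log_scale)`` with D renormalized to unit maximum and
    the factor accumulated in ``log_scale``; E is unaffected by rescaling.
    """
    if not age_lo < age_hi:
        raise LikelihoodError("require age_lo < age_hi")
    E = np.asarray(E_init, dtype=np.float64)
    D = np.asarray(D_init, dtype=np.float64)
    if np.any(E < 0) or np.any(E > 1) or np.any(D < 0):
        raise LikelihoodError("require E in [0,1] and D >= 0 initially")
    y0 = np.concatenate([E, D])
    y, logsc, ok = _kernels.integrate_branch(
        y0, float(age_lo), float(age_hi), params.bp_array(), params.rates_matrix(),
        rtol, atol,
    )
    if not ok:
        raise LikelihoodError(
            f"branch integration failed on [{age_lo}, {age_hi}] "
            f"(rates={params.epochs})"
        )
    return y[:2].copy(), y[2:].copy(), float(logsc)


def tree_loglik(
    tree: PhyloTree,
    traits: TraitDataset,
    params: TimeSliceParams,
    f: SamplingFractions = SamplingFractions(),
    cond: LikCondition = LikCondition(),
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    on_fail: str = "raise",
) -> float:
    """Time-sliced BiSSE log-likelihood of a tree with binary tip states.

    All tips must carry an observed state (prune or impute first).  With
    ``on_fail="neginf"`` a numerically failed evaluation returns -inf
    instead of raising (useful inside optimizers).
    """
    states = traits.state_array(tree)
    bp = validate_breakpoints(params.breakpoints, tree.height) if params.breakpoints else np.empty(0)
    p0, p1 = cond._prior()
    ll = _kernels.tree_loglik_arrays(
        tree.n_tips,
        tree.children,
        tree.parent,
        tree.age,
        states,
        params.bp_array(),
        params.rates_matrix(),
        f.f0,
        f.f1,
        cond._mode_int(),
        p0,
        p1,
        cond.condition_on_survival,
        rtol,
        atol,
    )
    if not np.isfinite(ll) and on_fail == "raise":
        raise LikelihoodError(
            "non-finite BiSSE log-likelihood (degenerate parameters?)"
        )
    return float(ll)


# -- constant-rate reductions (closed forms; independent oracles) -----------


def _one_minus_E(t, lam: float, mu: float, rho: float):
    """1 - E(t) for the constant-rate birth-death with sampling rho
    (vectorized over t; lam -> mu limit handled analytically)."""
    t = np.asarray(t, dtype=float)
    r = lam - mu
    if abs(r) < 1e-12 * max(lam, mu, 1.0):
        return rho / (1.0 + rho * lam * t)
    return rho * r / (rho * lam + (lam * (1 - rho) - mu) * np.exp(-r * t))


def bd_loglik(
    tree: PhyloTree,
    lam: float,
    mu: float,
    rho: float = 1.0,
    condition_on_survival: bool = True,
) -> float:
    """Closed-form reconstructed constant-rate birth-death log-likelihood.

    Matches :func:`tree_loglik` with one effective state (same node and
    root conventions): tips contribute log rho, each branch contributes
    the deterministic flow factor, each internal node a speciation rate,
    and conditioning divides by lam (1 - E(T))^2.  The lam -> mu limit is
    handled analytically.
    """
    if not (0 < rho <= 1):
        raise LikelihoodError("rho must be in (0, 1]")
    if mu < 0:
        raise LikelihoodError("mu must be >= 0")
    n = tree.n_tips
    if lam <= 0:
        raise LikelihoodError("lam must be > 0 for a tree with internal nodes")
    r = lam - mu
    ll = n * np.log(rho) + (n - 1) * np.log(lam)
    a_lo = tree.age[: tree.n_nodes - 1]
    a_hi = tree.age[tree.parent[: tree.n_nodes - 1]]
    u_lo = _one_minus_E(a_lo, lam, mu, rho)
    u_hi = _one_minus_E(a_hi, lam, mu, rho)
    ll += float(
        np.sum(-r * (a_hi - a_lo) + 2.0 * (np.log(u_hi) - np.log(u_lo)))
    )
    if condition_on_survival:
        uT = _one_minus_E(tree.height, lam, mu, rho)
        ll -= np.log(lam) + 2.0 * np.log(uT)
    return float(ll)


def mk_transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Exact 2-state CTMC transition matrix P(t) (closed form)."""
    total = q01 + q10
    if total == 0:
        return np.eye(2)
    pi0, pi1 = q10 / total, q01 / total
    e = np.exp(-total * t)
    return np.array(
        [[pi0 + pi1 * e, pi1 * (1 - e)], [pi0 * (1 - e), pi1 + pi0 * e]]
    )


def mk_loglik(
    tree: PhyloTree,
    traits: TraitDataset,
    q01: float,
    q10: float,
    cond: LikCondition = LikCondition(condition_on_survival=False),
) -> float:
    """Two-state Markov (Mk) pruning log-likelihood of the tip states.

    Root weighting follows ``cond.root_mode``; survival conditioning does
    not apply to the pure character process and is ignored.
    """
    if q01 < 0 or q10 < 0:
        raise LikelihoodError("transition rates must be >= 0")
    states = traits.state_array(tree)
    n, N = tree.n_tips, tree.n_nodes
    M = np.zeros((N, 2))
    M[np.arange(n), states] = 1.0
    logsc = 0.0
    for v in range(n, N):
        part = np.ones(2)
        for c in tree.children[v]:
            P = mk_transition_matrix(q01, q10, float(tree.branch_length[c]))
            part = part * (P @ M[c])
        mx = part.max()
        if not mx > 0:
            raise LikelihoodError("zero Mk likelihood (incompatible rates/states)")
        M[v] = part / mx
        logsc += np.log(mx)
    m = M[N - 1]
    mode = cond.root_mode
    if mode == "fitzjohn":
        lik = float((m**2).sum() / m.sum())
    elif mode == "equal":
        lik = float(m.mean())
    else:
        p0, p1 = cond._prior()
        lik = float(p0 * m[0] + p1 * m[1])
    if not lik > 0:
        raise LikelihoodError("zero Mk likelihood at root")
    return float(np.log(lik) + logsc)
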