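"""Ancestral states: BiSSE marginal reconstructions and Mk stochastic maps.

Marginal probabilities are exact: for each internal node the full pruning
likelihood is recomputed with the node clamped to each state, and the two
clamped likelihoods are normalized.  This conditions on all tips and on
the same root treatment and survival conditioning as the fit itself.

Stochastic character maps sample complete trait histories conditional on
the tip states under the plain Mk (trait-only) process: node states are
drawn root-to-tips from their conditional distributions, then each
branch's path is drawn exactly, conditioned on its endpoint states, by
uniformization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .bisse_core import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    LikCondition,
    SamplingFractions,
    TimeSliceParams,
    mk_transition_matrix,
)
from .errors import LikelihoodError, SimulationError, TsbisseError
from .treeio import PhyloTree, TraitDataset

__all__ = ["SimMap", "marginal_ancestral_states", "stochastic_maps"]


@dataclass
class SimMap:
    """One sampled character history.

    ``segments`` maps each non-root node to its branch's ordered state
    segments ``(state, start_age, end_age)`` (old -> young); adjacent
    segments differ in state and the youngest segment matches the node's
    sampled (tips: observed) state.
    """

    segments: Dict[int, List[Tuple[int, float, float]]]
    node_states: Dict[int, int]
    index: int
    seed: int

    def n_transitions(self) -> int:
        return sum(len(s) - 1 for s in self.segments.values())


def marginal_ancestral_states(
    tree: PhyloTree,
    traits: TraitDataset,
    params: TimeSliceParams,
    f: SamplingFractions = SamplingFractions(),
    cond: LikCondition = LikCondition(),
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> pd.DataFrame:
    """Marginal P(state) at every internal node under fitted BiSSE rates.

    Returns a table keyed by internal node index with node age and
    columns ``p0``/``p1`` (summing to 1).
    """
    states = traits.state_array(tree)
    p0, p1 = cond._prior()
    args = (
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
    rows = []
    for v in range(tree.n_tips, tree.n_nodes):
        ll = np.array(
            [
                _kernels.tree_loglik_arrays(*args, v, 0),
                _kernels.tree_loglik_arrays(*args, v, 1),
            ]
        )
        if not np.any(np.isfinite(ll)):
            raise LikelihoodError(f"non-finite clamped likelihoods at node {v}")
        m = np.nanmax(ll[np.isfinite(ll)])
        w = np.where(np.isfinite(ll), np.exp(ll - m), 0.0)
        w = w / w.sum()
        rows.append({"node": v, "age": float(tree.age[v]), "p0": w[0], "p1": w[1]})
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# stochastic character maps (Mk process)


def _mk_partials(tree: PhyloTree, states: np.ndarray, q01: float, q10: float):
    """Scaled conditional likelihoods M[v] and per-branch P matrices."""
    n, N = tree.n_tips, tree.n_nodes
    M = np.zeros((N, 2))
    M[np.arange(n), states] = 1.0
    P = np.empty((N, 2, 2))
    for v in range(N - 1):
        P[v] = mk_transition_matrix(q01, q10, float(tree.branch_length[v]))
    for v in range(n, N):
        part = np.ones(2)
        for c in tree.children[v]:
            part = part * (P[c] @ M[c])
        mx = part.max()
        if not mx > 0:
            raise LikelihoodError("tip states impossible under these Mk rates")
        M[v] = part / mx
    return M, P


def _sample_branch_path(
    a: int, b: int, t: float, q01: float, q10: float, rng, max_jumps: int = 10_000
) -> List[Tuple[int, float]]:
    """Jump times (as elapsed time from the older end) of an endpoint-
    conditioned 2-state path, sampled exactly by uniformization."""
    if t <= 0:
        return []
    omega = max(q01, q10)
    if omega == 0:
        return []
    Q = np.array([[-q01, q01], [q10, -q10]])
    B = np.eye(2) + Q / omega
    Pt = mk_transition_matrix(q01, q10, t)
    pab = Pt[a, b]
    if pab <= 0:
        raise SimulationError("impossible endpoint combination")
    # sample the number of uniformized jumps m
    u = rng.random() * pab
    log_pois = -omega * t
    Bm = np.eye(2)
    acc = np.exp(log_pois) * Bm[a, b]
    m = 0
    powers = [Bm.copy()]
    while acc < u:
        m += 1
        if m > max_jumps:
            raise SimulationError("uniformization series did not converge")
        Bm = Bm @ B
        powers.append(Bm.copy())
        log_pois += np.log(omega * t) - np.log(m)
        acc += np.exp(log_pois) * Bm[a, b]
    if m == 0:
        return []
    # uniformized jump times and the conditioned state sequence
    times = np.sort(rng.random(m) * t)
    seq = [a]
    for j in range(1, m + 1):
        rem = powers[m - j]
        s_prev = seq[-1]
        w = np.array([B[s_prev, 0] * rem[0, b], B[s_prev, 1] * rem[1, b]])
        seq.append(int(rng.random() * w.sum() >= w[0]))
    path = []
    for j in range(m):
        if seq[j + 1] != seq[j]:  # drop virtual (self) jumps
            path.append((seq[j + 1], float(times[j])))
    return path


def stochastic_maps(
    tree: PhyloTree,
    traits: TraitDataset,
    q01: float,
    q10: float,
    n_maps: int = 500,
    seed: int = 0,
    root_prior: Optional[Tuple[float, float]] = None,
) -> Tuple[List[SimMap], pd.DataFrame]:
    """Sample ``n_maps`` character histories conditional on the tip states.

    The default root prior is the stationary distribution of the rates
    (uniform when both rates are zero or equal).  Returns the maps and a
    per-node table of sampled state frequencies (columns ``p0``/``p1``).
    """
    if n_maps < 1:
        raise TsbisseError("n_maps must be >= 1")
    if q01 < 0 or q10 < 0:
        raise TsbisseError("rates must be >= 0")
    states = traits.state_array(tree)
    rng = np.random.default_rng(seed)
    M, P = _mk_partials(tree, states, q01, q10)
    n, N = tree.n_tips, tree.n_nodes
    if root_prior is None:
        total = q01 + q10
        root_prior = (0.5, 0.5) if total == 0 else (q10 / total, q01 / total)
    pi = np.asarray(root_prior, dtype=float)
    counts = np.zeros((N, 2))
    maps: List[SimMap] = []
    for idx in range(n_maps):
        node_state: Dict[int, int] = {}
        # root draw, then preorder conditional draws
        w = pi * M[tree.root]
        node_state[tree.root] = int(rng.random() * w.sum() >= w[0])
        for v in range(N - 2, -1, -1):
            p = tree.parent[v]
            sp = node_state[p]
            w = P[v][sp] * M[v]
            node_state[v] = int(rng.random() * w.sum() >= w[0])
        segments: Dict[int, List[Tuple[int, float, float]]] = {}
        for v in range(N - 1):
            p = tree.parent[v]
            a_hi, a_lo = float(tree.age[p]), float(tree.age[v])
            path = _sample_branch_path(
                node_state[p], node_state[v], a_hi - a_lo, q01, q10, rng
            )
            segs = []
            s, t_prev = node_state[p], a_hi
            for s_new, dt in path:
                segs.append((s, t_prev, a_hi - dt))
                s, t_prev = s_new, a_hi - dt
            segs.append((s, t_prev, a_lo))
            if s != node_state[v]:  # safety: endpoint must match
                raise SimulationError("endpoint-conditioned path mismatch")
            segments[v] = segs
        for v in range(N):
            counts[v, node_state[v]] += 1
        maps.append(SimMap(segments=segments, node_states=node_state, index=idx, seed=seed))
    freq = counts / n_maps
    table = pd.DataFrame(
        {
            "node": np.arange(N),
            "age": tree.age,
            "p0": freq[:, 0],
            "p1": freq[:, 1],
        }
    ).set_index("node")
    return maps, table
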