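"""Simulators: neutral traits, conditioned birth-death trees, joint
tree+trait evolution under time-sliced BiSSE, and incomplete sampling.

Three study designs are covered:

1. neutral binary traits evolved down a fixed tree (exact CTMC simulation
   with exponential waiting times),
2. constant-rate birth-death trees conditioned jointly on tip count and
   crown age, via the conditional branching-age density (no naive
   rejection), and
3. forward-in-time Gillespie simulation of tree and trait together under
   piecewise-constant state-dependent rates, with extinct lineages pruned
   to the reconstructed tree and a tip-count acceptance window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bisse_core import TimeSliceParams
from .errors import SimulationError, TsbisseError
from .treeio import PhyloTree, TraitDataset

__all__ = [
    "SimHistory",
    "sim_mk_trait",
    "sim_bd_tree",
    "sim_bisse_timeslice",
    "apply_sampling",
]


@dataclass
class Event:
    age: float  # Ma before present
    kind: str  # "speciation" | "extinction" | "transition"
    lineage: int
    state: int
    new_state: Optional[int] = None


@dataclass
class SimHistory:
    """A simulated tree + trait history.

    ``segments`` (when the history runs over a fixed tree) maps each
    non-root node of ``tree`` to its branch's state segments as
    ``(state, start_age, end_age)`` ordered old -> young; segments tile
    the branch and the last segment's state is the node/tip state.
    For joint tree+trait simulations the pre-pruning history is retained
    in ``events`` (ages and states of every speciation, extinction and
    transition of the full process).
    """

    tree: PhyloTree
    tip_states: Dict[str, int]
    seed: int
    params: Dict[str, object] = field(default_factory=dict)
    events: List[Event] = field(default_factory=list)
    segments: Optional[Dict[int, List[Tuple[int, float, float]]]] = None
    node_states: Optional[Dict[int, int]] = None

    def traits(self) -> TraitDataset:
        return TraitDataset({t: int(s) for t, s in self.tip_states.items()})

    def state_count(self, s: int) -> int:
        return sum(1 for v in self.tip_states.values() if v == s)

    def n_transitions(self) -> int:
        return sum(1 for e in self.events if e.kind == "transition")


# ---------------------------------------------------------------------------
# 1. neutral / Mk trait simulation on a fixed tree


def sim_mk_trait(
    tree: PhyloTree,
    q01: float,
    q10: float,
    root_state: Optional[int] = None,
    seed: int = 0,
) -> SimHistory:
    """Exact CTMC simulation of a binary trait down ``tree``.

    ``root_state=None`` draws the root from the stationary distribution
    (50/50 when both rates are zero or equal).
    """
    if q01 < 0 or q10 < 0:
        raise TsbisseError("transition rates must be >= 0")
    rng = np.random.default_rng(seed)
    total = q01 + q10
    if root_state is None:
        p1 = 0.5 if total == 0 else q01 / total
        root_state = int(rng.random() < p1)
    rates = (q01, q10)  # leave-rate per current state
    node_states: Dict[int, int] = {tree.root: int(root_state)}
    segments: Dict[int, List[Tuple[int, float, float]]] = {}
    events: List[Event] = []
    # preorder: parents before children (root has the highest index)
    for v in range(tree.n_nodes - 2, -1, -1):
        p = tree.parent[v]
        state = node_states[p]
        a_hi = float(tree.age[p])
        a_lo = float(tree.age[v])
        t = a_hi
        branch_transitions: List[float] = []
        while True:
            rate = rates[state]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if t - wait <= a_lo:
                break
            t -= wait
            events.append(
                Event(age=t, kind="transition", lineage=v, state=state, new_state=1 - state)
            )
            branch_transitions.append(t)
            state = 1 - state
        node_states[v] = state
        segments[v] = _segments_from_transitions(
            int(node_states[p]), a_hi, a_lo, branch_transitions
        )
    tip_states = {tree.tip_labels[i]: node_states[i] for i in range(tree.n_tips)}
    return SimHistory(
        tree=tree,
        tip_states=tip_states,
        seed=seed,
        params={"q01": q01, "q10": q10, "root_state": int(root_state)},
        events=events,
        segments=segments,
        node_states=node_states,
    )


def _segments_from_transitions(
    start_state: int, a_hi: float, a_lo: float, transition_ages: List[float]
) -> List[Tuple[int, float, float]]:
    segs = []
    state, t = start_state, a_hi
    for a in sorted(transition_ages, reverse=True):
        segs.append((state, t, a))
        state, t = 1 - state, a
    segs.append((state, t, a_lo))
    return segs


# ---------------------------------------------------------------------------
# 2. birth-death trees conditioned on tip count and crown age


def _branching_age_cdf_inverse(
    u: np.ndarray, T: float, lam: float, mu: float
) -> np.ndarray:
    """Inverse CDF of the iid branching-age density on (0, T).

    For a reconstructed constant-rate birth-death tree conditioned on crown
    age T and n tips, the n-2 non-crown branching ages are iid with density
    proportional to p1(t) = r^2 e^{-rt} / (lam - mu e^{-rt})^2 (r = lam-mu),
    whose CDF is proportional to g(t) = (1 - e^{-rt}) / (lam - mu e^{-rt});
    both the CDF and its inverse are available in closed form, including
    the lam -> mu limit.
    """
    r = lam - mu
    if abs(r) < 1e-12 * max(lam, 1.0):
        gT = T / (1.0 + lam * T)
        c = u * gT
        return c / (1.0 - lam * c)
    gT = (1.0 - np.exp(-r * T)) / (lam - mu * np.exp(-r * T))
    c = u * gT
    x = (1.0 - c * lam) / (1.0 - c * mu)
    return -np.log(x) / r


def sim_bd_tree(
    n_tips: int,
    age: float,
    lam: float,
    mu: float,
    seed: int = 0,
) -> PhyloTree:
    """Reconstructed birth-death tree with exactly ``n_tips`` tips and crown
    age exactly ``age`` (Ma), drawn from the process conditioned on both.

    Branching ages are drawn from their closed-form conditional density and
    the topology by uniform sequential splitting, which together give the
    conditioned reconstructed-tree distribution.
    """
    if n_tips < 2:
        raise TsbisseError("need at least 2 tips")
    if age <= 0 or lam <= 0 or mu < 0:
        raise TsbisseError("require age > 0, lam > 0, mu >= 0")
    rng = np.random.default_rng(seed)
    extra = _branching_age_cdf_inverse(rng.random(n_tips - 2), age, lam, mu)
    branching = np.concatenate([[age], np.sort(extra)[::-1]])
    # forward construction: at each branching age split a uniform lineage
    temp_children: Dict[int, Tuple[int, int]] = {}
    temp_age: Dict[int, float] = {}
    counter = 0

    def new_node(a: float) -> int:
        nonlocal counter
        counter += 1
        temp_age[counter] = a
        return counter

    root = new_node(age)
    active = []
    l1, l2 = new_node(np.nan), new_node(np.nan)
    temp_children[root] = (l1, l2)
    active = [l1, l2]
    for a in branching[1:]:
        pick = int(rng.integers(len(active)))
        v = active[pick]
        temp_age[v] = float(a)
        c1, c2 = new_node(np.nan), new_node(np.nan)
        temp_children[v] = (c1, c2)
        active[pick] = c1
        active.append(c2)
    for v in active:
        temp_age[v] = 0.0
    return _phylo_from_temp(root, temp_children, temp_age, tip_prefix="t")


def _phylo_from_temp(
    root: int,
    temp_children: Dict[int, Tuple[int, int]],
    temp_age: Dict[int, float],
    tip_prefix: str = "t",
    tip_names: Optional[Dict[int, str]] = None,
) -> PhyloTree:
    """Assemble a PhyloTree (tips first, internals postorder) from a temp
    id -> children map."""
    labels: List[str] = []
    order: List[int] = []  # temp ids of internals, postorder
    final_of: Dict[int, int] = {}
    stack: List[Tuple[int, bool]] = [(root, False)]
    while stack:
        v, expanded = stack.pop()
        if v not in temp_children:
            if tip_names is not None:
                labels.append(tip_names[v])
            else:
                labels.append(f"{tip_prefix}{len(labels) + 1}")
            final_of[v] = len(labels) - 1
            continue
        if not expanded:
            stack.append((v, True))
            c1, c2 = temp_children[v]
            stack.append((c2, False))
            stack.append((c1, False))
        else:
            order.append(v)
    m = len(labels)
    M = 2 * m - 1
    if len(order) != m - 1:
        raise SimulationError("inconsistent simulated tree structure")
    children = np.full((M, 2), -1, dtype=np.int64)
    parent_arr = np.full(M, -1, dtype=np.int64)
    age = np.zeros(M, dtype=np.float64)
    for k, v in enumerate(order):
        final_of[v] = m + k
    for k, v in enumerate(order):
        f = m + k
        c1, c2 = temp_children[v]
        children[f, 0] = final_of[c1]
        children[f, 1] = final_of[c2]
        parent_arr[final_of[c1]] = f
        parent_arr[final_of[c2]] = f
        age[f] = temp_age[v]
    blen = np.zeros(M, dtype=np.float64)
    for v in range(M - 1):
        blen[v] = age[parent_arr[v]] - age[v]
    return PhyloTree(labels, parent_arr, children, blen, age)


# ---------------------------------------------------------------------------
# 3. joint tree + trait simulation under time-sliced BiSSE


def sim_bisse_timeslice(
    params: TimeSliceParams,
    root_age: float,
    root_state: Optional[int] = None,
    min_tips: int = 2,
    max_tips: int = 10_000,
    seed: int = 0,
    start: str = "origin",
    max_attempts: int = 1000,
) -> SimHistory:
    """Forward Gillespie simulation of tree and binary trait together.

    Starts at ``root_age`` with a single lineage (``start="origin"``) or
    two lineages (``start="crown"``); per-state speciation, extinction and
    transition rates switch at the epoch breakpoints.  Histories whose
    surviving (extant) tip count falls outside ``[min_tips, max_tips]``
    are rejected and redrawn; the reconstructed tree of survivors is
    returned together with the full pre-pruning event log.
    """
    if root_age <= 0:
        raise TsbisseError("root_age must be positive")
    if start not in ("origin", "crown"):
        raise TsbisseError("start must be 'origin' or 'crown'")
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_attempts + 1):
        out = _sim_bisse_once(params, root_age, root_state, rng, start)
        if out is None:
            continue
        tree, tip_states, events = out
        if min_tips <= len(tip_states) <= max_tips:
            return SimHistory(
                tree=tree,
                tip_states=tip_states,
                seed=seed,
                params={
                    "params": params,
                    "root_age": root_age,
                    "root_state": root_state,
                    "start": start,
                    "attempts": attempt,
                },
                events=events,
            )
    raise SimulationError(
        f"no history with {min_tips}-{max_tips} surviving tips in "
        f"{max_attempts} attempts (acceptance rate too low)"
    )


def _sim_bisse_once(params, root_age, root_state, rng, start):
    bp = params.bp_array()
    rates = params.rates_matrix()  # (n_epochs, 6): lam0 lam1 mu0 mu1 q01 q10
    n_ep = rates.shape[0]

    def epoch_at(a: float) -> int:
        return int(np.searchsorted(bp, a, side="right"))

    if root_state is None:
        root_state = int(rng.random() < 0.5)
    # lineage records
    state: List[int] = []
    birth_age: List[float] = []
    alive: List[bool] = []
    temp_children: Dict[int, Tuple[int, int]] = {}
    temp_age: Dict[int, float] = {}
    events: List[Event] = []

    def new_lineage(s: int, a: float) -> int:
        state.append(s)
        birth_age.append(a)
        alive.append(True)
        return len(state) - 1

    active: List[int] = []
    if start == "origin":
        root = new_lineage(int(root_state), root_age)
        active = [root]
    else:
        root = new_lineage(int(root_state), root_age)  # virtual stem node
        alive[root] = False
        c1 = new_lineage(int(root_state), root_age)
        c2 = new_lineage(int(root_state), root_age)
        temp_children[root] = (c1, c2)
        temp_age[root] = root_age
        events.append(Event(root_age, "speciation", root, int(root_state)))
        active = [c1, c2]
    a = root_age
    ep = epoch_at(a)
    while a > 0 and active:
        lam0, lam1, mu0, mu1, q01, q10 = rates[ep]
        per_state_rate = (lam0 + mu0 + q01, lam1 + mu1 + q10)
        n0 = sum(1 for li in active if state[li] == 0)
        n1 = len(active) - n0
        R = n0 * per_state_rate[0] + n1 * per_state_rate[1]
        next_bp = bp[ep - 1] if ep > 0 else 0.0
        if R <= 0:
            a = next_bp
        else:
            wait = rng.exponential(1.0 / R)
            if a - wait <= next_bp:
                a = next_bp
            else:
                a -= wait
                # pick lineage weighted by its total rate
                w = np.array([per_state_rate[state[li]] for li in active])
                li = active[int(rng.choice(len(active), p=w / w.sum()))]
                s = state[li]
                lam = lam0 if s == 0 else lam1
                mu = mu0 if s == 0 else mu1
                q = q01 if s == 0 else q10
                u = rng.random() * per_state_rate[s]
                if u < lam:
                    events.append(Event(a, "speciation", li, s))
                    alive[li] = False
                    temp_age[li] = a
                    c1 = new_lineage(s, a)
                    c2 = new_lineage(s, a)
                    temp_children[li] = (c1, c2)
                    active.remove(li)
                    active.extend((c1, c2))
                elif u < lam + mu:
                    events.append(Event(a, "extinction", li, s))
                    alive[li] = False
                    temp_age[li] = a
                    active.remove(li)
                else:
                    events.append(Event(a, "transition", li, s, 1 - s))
                    state[li] = 1 - s
        if a <= next_bp and ep > 0:
            ep -= 1
    survivors = list(active)
    if len(survivors) < 2:
        return None
    for li in survivors:
        temp_age[li] = 0.0
    # prune to the reconstructed tree of survivors
    n_surv_desc: Dict[int, int] = {}

    def count_desc(v: int) -> int:
        if v in n_surv_desc:
            return n_surv_desc[v]
        if v in temp_children:
            c1, c2 = temp_children[v]
            n = count_desc(c1) + count_desc(c2)
        else:
            n = 1 if alive[v] else 0
        n_surv_desc[v] = n
        return n

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * len(state) + 1000))
    try:
        count_desc(root if start == "origin" else root)
        pruned_children: Dict[int, Tuple[int, int]] = {}

        def resolve(v: int) -> int:
            while v in temp_children:
                c1, c2 = temp_children[v]
                s1, s2 = n_surv_desc[c1], n_surv_desc[c2]
                if s1 > 0 and s2 > 0:
                    return v
                v = c1 if s1 > 0 else c2
            return v

        def build(v: int) -> int:
            v = resolve(v)
            if v not in temp_children:
                return v
            c1, c2 = temp_children[v]
            pruned_children[v] = (build(c1), build(c2))
            return v

        new_root = build(root)
    finally:
        sys.setrecursionlimit(old_limit)
    tip_names = {li: f"t{li}" for li in survivors}
    tree = _phylo_from_temp(new_root, pruned_children, temp_age, tip_names=tip_names)
    tip_states = {f"t{li}": int(state[li]) for li in survivors}
    return tree, tip_states, events


# ---------------------------------------------------------------------------
# 4. incomplete sampling


def apply_sampling(
    history: SimHistory, f0: float, f1: float, seed: int = 0
) -> SimHistory:
    """Skeletal-tree sampling: retain each tip of state i with probability
    f_i, independently; the tree is pruned to the retained tips."""
    if not (0 < f0 <= 1 and 0 < f1 <= 1):
        raise TsbisseError("sampling fractions must be in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = [
        tip
        for tip, s in history.tip_states.items()
        if rng.random() < (f0 if s == 0 else f1)
    ]
    if len(keep) < 2:
        raise SimulationError("sampling removed all (or all but one) tips")
    if len(keep) == len(history.tip_states):
        tree = history.tree
    else:
        tree = history.tree.prune_to(keep)
    kept_states = {t: history.tip_states[t] for t in keep}
    n0_before = history.state_count(0)
    n1_before = history.state_count(1)
    n0_after = sum(1 for v in kept_states.values() if v == 0)
    n1_after = len(kept_states) - n0_after
    realized = {
        "f0_realized": n0_after / n0_before if n0_before else np.nan,
        "f1_realized": n1_after / n1_before if n1_before else np.nan,
    }
    return SimHistory(
        tree=tree,
        tip_states=kept_states,
        seed=seed,
        params={**history.params, "f0": f0, "f1": f1, **realized},
        events=history.events,
    )
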