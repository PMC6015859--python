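"""Constrained two-epoch BiSSE model space and model selection.

A candidate model is a :class:`ConstraintSpec`: a mapping from the twelve
rate slots -- {lam0, lam1, mu0, mu1, q01, q10} x {recent, old} -- onto
shared free-parameter identifiers.  Constraining slots to share an
identifier expresses "equal across states" and/or "equal across epochs".

Per rate family (lam, mu, q) the generator knows six structures:

====  =========================================================  ==
code  meaning                                                    k
====  =========================================================  ==
S     shared between states, constant in time                    1
D     state-dependent, constant in time                          2
St    shared between states, shifts at the breakpoint            2
Dt    state-dependent, both states shift                         4
Dt0   state-dependent, only state 0 shifts                       3
Dt1   state-dependent, only state 1 shifts                       3
====  =========================================================  ==

The canonical set (43 models) combines: the full time-constant cross
(8 models), every single-family shift St/Dt against all time-constant
backgrounds (24), one-state-only shifts of extinction or transition
against the all-shared and all-state-dependent backgrounds (8), the joint
mu+q shift models (2), and the fully free model (1).  The composition is
deliberately auditable and the selection machinery accepts any
user-supplied list of :class:`ConstraintSpec` instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .bisse_core import EpochRates, TimeSliceParams
from .errors import TsbisseError

RATE_FAMILIES = ("lam", "mu", "q")
_FAMILY_RATES = {"lam": ("lam0", "lam1"), "mu": ("mu0", "mu1"), "q": ("q01", "q10")}
#: slot order: family-major, state, then epoch (recent first)
SLOTS: Tuple[Tuple[str, str], ...] = tuple(
    (rate, ep)
    for fam in RATE_FAMILIES
    for rate in _FAMILY_RATES[fam]
    for ep in ("recent", "old")
)

# per-family structure -> slot suffix -> parameter tag template
_STRUCTURES: Dict[str, Dict[Tuple[str, str], str]] = {
    "S": {("0", "recent"): "a", ("0", "old"): "a", ("1", "recent"): "a", ("1", "old"): "a"},
    "D": {("0", "recent"): "a", ("0", "old"): "a", ("1", "recent"): "b", ("1", "old"): "b"},
    "St": {("0", "recent"): "a", ("0", "old"): "b", ("1", "recent"): "a", ("1", "old"): "b"},
    "Dt": {("0", "recent"): "a", ("0", "old"): "b", ("1", "recent"): "c", ("1", "old"): "d"},
    "Dt0": {("0", "recent"): "a", ("0", "old"): "b", ("1", "recent"): "c", ("1", "old"): "c"},
    "Dt1": {("0", "recent"): "c", ("0", "old"): "c", ("1", "recent"): "a", ("1", "old"): "b"},
}

_RATE_TO_FAMILY = {"lam0": "lam", "lam1": "lam", "mu0": "mu", "mu1": "mu", "q01": "q", "q10": "q"}
_RATE_STATE = {"lam0": "0", "lam1": "1", "mu0": "0", "mu1": "1", "q01": "0", "q10": "1"}


@dataclass(frozen=True)
class ConstraintSpec:
    """One candidate model: slot -> free-parameter identifier."""

    name: str
    mapping: Tuple[Tuple[Tuple[str, str], str], ...]  # ((rate, epoch), param_id)

    @classmethod
    def from_structures(cls, lam: str, mu: str, q: str) -> "ConstraintSpec":
        """Build a spec from per-family structure codes (see module doc)."""
        mapping = []
        for code, fam in zip((lam, mu, q), RATE_FAMILIES):
            if code not in _STRUCTURES:
                raise TsbisseError(f"unknown structure code {code!r}")
            struct = _STRUCTURES[code]
            for rate, ep in SLOTS:
                if _RATE_TO_FAMILY[rate] != fam:
                    continue
                tag = struct[(_RATE_STATE[rate], ep)]
                mapping.append(((rate, ep), f"{fam}_{tag}"))
        name = f"lam:{lam}|mu:{mu}|q:{q}"
        return cls(name=name, mapping=tuple(mapping))

    @classmethod
    def from_dict(cls, name: str, mapping: Dict[Tuple[str, str], str]) -> "ConstraintSpec":
        if set(mapping) != set(SLOTS):
            raise TsbisseError("mapping must cover exactly the 12 rate slots")
        ordered = tuple((slot, mapping[slot]) for slot in SLOTS)
        return cls(name=name, mapping=ordered)

    @property
    def slot_map(self) -> Dict[Tuple[str, str], str]:
        return dict(self.mapping)

    @property
    def free_params(self) -> List[str]:
        """Unique parameter ids in first-appearance (canonical slot) order."""
        seen: List[str] = []
        for _, pid in self.mapping:
            if pid not in seen:
                seen.append(pid)
        return seen

    @property
    def k(self) -> int:
        return len(self.free_params)

    def param_of(self, rate: str, epoch: str) -> str:
        return self.slot_map[(rate, epoch)]

    def to_params(self, values: Sequence[float], cutoff: float) -> TimeSliceParams:
        """Instantiate a two-epoch rate set from free-parameter values."""
        vals = dict(zip(self.free_params, np.asarray(values, dtype=float)))
        if len(vals) != self.k or len(values) != self.k:
            raise TsbisseError(f"expected {self.k} values for model {self.name}")
        sm = self.slot_map
        epochs = []
        for ep in ("recent", "old"):
            epochs.append(
                EpochRates(
                    lam0=vals[sm[("lam0", ep)]],
                    lam1=vals[sm[("lam1", ep)]],
                    mu0=vals[sm[("mu0", ep)]],
                    mu1=vals[sm[("mu1", ep)]],
                    q01=vals[sm[("q01", ep)]],
                    q10=vals[sm[("q10", ep)]],
                )
            )
        return TimeSliceParams.two_epoch(epochs[0], epochs[1], cutoff)

    def partition(self) -> Dict[str, Tuple[Tuple[str, str], ...]]:
        out: Dict[str, List[Tuple[str, str]]] = {}
        for slot, pid in self.mapping:
            out.setdefault(pid, []).append(slot)
        return {pid: tuple(slots) for pid, slots in out.items()}

    def is_nested_in(self, full: "ConstraintSpec") -> bool:
        """True if this model is a constrained submodel of ``full``.

        Structurally: this spec's slot partition must coarsen the full
        spec's (slots tied in ``full`` remain tied here).
        """
        mine, theirs = self.slot_map, full.slot_map
        for s1, s2 in itertools.combinations(SLOTS, 2):
            if theirs[s1] == theirs[s2] and mine[s1] != mine[s2]:
                return False
        return True


def enumerate_models(
    families: Sequence[str] = RATE_FAMILIES,
) -> List[ConstraintSpec]:
    """The canonical deterministic 43-model set (see module docstring).

    ``families`` restricts which rate families may vary at all; families
    not listed are held shared and time-constant ("S").
    """
    allow = set(families)

    def opts(fam: str, codes: Sequence[str]) -> List[str]:
        return list(codes) if fam in allow else ["S"]

    combos: List[Tuple[str, str, str]] = []
    # 1. full time-constant cross
    combos += list(
        itertools.product(opts("lam", "SD"), opts("mu", "SD"), opts("q", "SD"))
    )
    # 2. single-family shifts (St/Dt) against time-constant backgrounds
    for fam in RATE_FAMILIES:
        for shift in ("St", "Dt"):
            if fam not in allow:
                continue
            others = [o for o in RATE_FAMILIES if o != fam]
            for bg in itertools.product(*(opts(o, "SD") for o in others)):
                combo = dict(zip(others, bg))
                combo[fam] = shift
                combos.append((combo["lam"], combo["mu"], combo["q"]))
    # 3. one-state-only shifts of mu or q on uniform backgrounds
    for fam in ("mu", "q"):
        if fam not in allow:
            continue
        for shift in ("Dt0", "Dt1"):
            for bg in ("S", "D"):
                combo = {f: (bg if f in allow else "S") for f in RATE_FAMILIES}
                combo[fam] = shift
                combos.append((combo["lam"], combo["mu"], combo["q"]))
    # 4. joint mu+q shifts
    if "mu" in allow and "q" in allow:
        for lamcode in opts("lam", "SD"):
            combos.append((lamcode, "Dt", "Dt"))
    # 5. fully free
    combos.append(
        tuple(("Dt" if f in allow else "S") for f in RATE_FAMILIES)  # type: ignore
    )
    specs: Dict[str, ConstraintSpec] = {}
    for lam, mu, q in combos:
        spec = ConstraintSpec.from_structures(lam, mu, q)
        specs[spec.name] = spec  # dedupe by name
    return sorted(specs.values(), key=lambda s: (s.k, s.name))


def fully_free_model() -> ConstraintSpec:
    return ConstraintSpec.from_structures("Dt", "Dt", "Dt")


@dataclass
class FitResult:
    """A maximum-likelihood fit of one ConstraintSpec."""

    spec: ConstraintSpec
    cutoff: float
    free_values: np.ndarray
    loglik: float
    converged: bool
    n_starts: int = 1
    n_evals: int = 0
    message: str = ""

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)

    @property
    def params(self) -> TimeSliceParams:
        return self.spec.to_params(self.free_values, self.cutoff)

    def param_dict(self) -> Dict[str, float]:
        return dict(zip(self.spec.free_params, map(float, self.free_values)))

    def rate(self, rate: str, epoch: str) -> float:
        """MLE of one rate slot, e.g. ``rate("mu1", "recent")``."""
        return self.param_dict()[self.spec.param_of(rate, epoch)]


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    if k < 1:
        raise TsbisseError("k must be >= 1")
    return 2.0 * k - 2.0 * loglik


def lrt(nested: FitResult, full: FitResult, tol: float = 1e-4) -> float:
    """Likelihood-ratio test p-value for a structurally nested pair."""
    if not nested.spec.is_nested_in(full.spec):
        raise TsbisseError(
            f"model {nested.spec.name!r} is not nested in {full.spec.name!r}"
        )
    df = full.k - nested.k
    if df <= 0:
        raise TsbisseError("full model must have more free parameters")
    if full.loglik < nested.loglik - tol:
        raise TsbisseError(
            "full model log-likelihood below nested model's beyond tolerance "
            f"({full.loglik:.6f} < {nested.loglik:.6f}); refit with multi-start"
        )
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    return float(stats.chi2.sf(stat, df))


def selection_report(fits: Sequence[FitResult]) -> pd.DataFrame:
    """All candidates with k, logL, AIC, dAIC and the selected flag."""
    fits = list(fits)
    rows = [
        {
            "model": f.spec.name,
            "k": f.k,
            "loglik": f.loglik,
            "AIC": f.aic,
            "converged": f.converged,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    ok = df[df.converged]
    if ok.empty:
        raise TsbisseError("no converged fits to select among")
    best_aic = ok.AIC.min()
    df["dAIC"] = df.AIC - best_aic
    sel = stepwise_select(fits)
    df["selected"] = df.model == sel.spec.name
    return df.sort_values(["AIC", "k", "model"]).reset_index(drop=True)


def stepwise_select(fits: Sequence[FitResult]) -> FitResult:
    """Parsimony pick: among models with dAIC < 2 of the optimum, the one
    with fewest parameters; ties broken by lower AIC, then model name."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise TsbisseError("no converged fits to select among")
    best = min(f.aic for f in ok)
    window = [f for f in ok if f.aic - best < 2.0]
    return min(window, key=lambda f: (f.k, f.aic, f.spec.name))
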