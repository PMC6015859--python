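"""Trees, trait tables and epoch bookkeeping.

Rooted, strictly bifurcating ultrametric trees are stored in a flat array
layout: tips occupy indices ``0..n_tips-1`` (in newick order), internal
nodes follow in postorder, so index ``n_nodes-1`` is always the root.  Ages
are measured in Ma before present: every tip sits at age 0 and the root at
age = tree height.  This layout feeds the compiled pruning kernels directly.

Newick parsing and writing is delegated to dendropy; the arrays are built
from its tree object and validated here (branch lengths present, binary
internal nodes, ultrametric within a relative tolerance of the height).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    NewickParseError,
    TraitError,
    TreeValidationError,
    UltrametricityError,
)

#: relative tolerance (fraction of tree height) for the ultrametric check
ULTRAMETRIC_RTOL = 1e-6

MISSING = -1  # sentinel for a missing binary state


class PhyloTree:
    """A rooted, binary, ultrametric phylogeny in array form.

    Attributes
    ----------
    n_tips : int
        Number of extant tips.
    tip_labels : list of str
        Labels of tips ``0..n_tips-1`` (unique).
    parent : ndarray of int, shape (n_nodes,)
        Parent index per node; the root has parent ``-1``.
    children : ndarray of int, shape (n_nodes, 2)
        Child indices per internal node, ``-1`` for tips.
    branch_length : ndarray of float, shape (n_nodes,)
        Length (Myr) of the edge subtending each node; 0 for the root.
    age : ndarray of float, shape (n_nodes,)
        Node ages in Ma before present (tips at 0, root = height).
    """

    def __init__(
        self,
        tip_labels: Sequence[str],
        parent: np.ndarray,
        children: np.ndarray,
        branch_length: np.ndarray,
        age: np.ndarray,
    ):
        self.tip_labels = list(tip_labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=np.float64)
        self.age = np.asarray(age, dtype=np.float64)
        self.n_tips = len(self.tip_labels)
        self.n_nodes = self.parent.shape[0]
        self._validate()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        n, N = self.n_tips, self.n_nodes
        if N != 2 * n - 1:
            raise TreeValidationError(
                f"expected {2 * n - 1} nodes for {n} tips (binary tree), got {N}"
            )
        if len(set(self.tip_labels)) != n:
            dupes = sorted(
                {x for x in self.tip_labels if self.tip_labels.count(x) > 1}
            )
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        if np.any(self.branch_length < 0):
            raise TreeValidationError("negative branch length")
        root = N - 1
        if self.parent[root] != -1:
            raise TreeValidationError("last node must be the root")
        height = self.age[root]
        if not height > 0:
            raise TreeValidationError("tree height must be positive")
        # parent age >= child age (equality only across zero-length edges)
        for v in range(N - 1):
            p = self.parent[v]
            if self.age[p] < self.age[v] - 1e-9 * max(height, 1.0):
                raise TreeValidationError(
                    f"parent age {self.age[p]} < child age {self.age[v]}"
                )
        # children must appear before their parent (postorder for internals)
        for v in range(n, N):
            l, r = self.children[v]
            if l >= v or r >= v:
                raise TreeValidationError("internal nodes not in postorder")

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def height(self) -> float:
        """Root age (Ma) = distance from root to any tip."""
        return float(self.age[self.root])

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise TraitError(f"unknown tip label: {label!r}") from None

    def total_branch_length(self) -> float:
        return float(self.branch_length[: self.n_nodes - 1].sum())

    def branching_ages(self) -> np.ndarray:
        """Ages of all internal nodes (incl. the root), descending order."""
        return np.sort(self.age[self.n_tips :])[::-1]

    def clade_tips(self, node: int) -> List[int]:
        """Tip indices descending from ``node`` (inclusive if a tip)."""
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        dtree = dtree.clone(depth=1)
        # collapse a degree-1 root chain if present (e.g. "(...)root:0;")
        dtree.suppress_unifurcations()
        seed = dtree.seed_node
        if seed.is_leaf():
            raise TreeValidationError("tree has a single tip")
        leaves = [lf for lf in dtree.leaf_node_iter()]
        n = len(leaves)
        labels: List[str] = []
        for lf in leaves:
            if lf.taxon is not None and lf.taxon.label is not None:
                labels.append(str(lf.taxon.label))
            elif lf.label:
                labels.append(str(lf.label))
            else:
                raise TreeValidationError("unlabelled tip")
        index: Dict[int, int] = {id(lf): i for i, lf in enumerate(leaves)}
        N = 2 * n - 1
        parent = np.full(N, -1, dtype=np.int64)
        children = np.full((N, 2), -1, dtype=np.int64)
        blen = np.zeros(N, dtype=np.float64)
        depth = np.zeros(N, dtype=np.float64)

        next_internal = n
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                continue
            ch = nd.child_nodes()
            if len(ch) != 2:
                raise TreeValidationError(
                    f"non-binary internal node with {len(ch)} children "
                    "(polytomies are not supported)"
                )
            index[id(nd)] = next_internal
            next_internal += 1
        for nd in dtree.postorder_node_iter():
            v = index[id(nd)]
            if nd is not seed:
                if nd.edge.length is None:
                    raise TreeValidationError(
                        "missing branch length on a non-root edge"
                    )
                blen[v] = float(nd.edge.length)
            if not nd.is_leaf():
                l, r = nd.child_nodes()
                children[v, 0] = index[id(l)]
                children[v, 1] = index[id(r)]
                parent[index[id(l)]] = v
                parent[index[id(r)]] = v
        # depths from root, then ages
        for nd in dtree.preorder_node_iter():
            v = index[id(nd)]
            p = parent[v]
            depth[v] = (depth[p] if p >= 0 else 0.0) + blen[v]
        height = float(depth[:n].max())
        if height <= 0:
            raise TreeValidationError("tree height must be positive")
        bad = np.abs(depth[:n] - height) > ULTRAMETRIC_RTOL * height
        if np.any(bad):
            worst = int(np.argmax(np.abs(depth[:n] - height)))
            raise UltrametricityError(
                f"tree is not ultrametric: tip {labels[worst]!r} at depth "
                f"{depth[worst]:.9g} vs height {height:.9g}"
            )
        age = height - depth
        age[:n] = 0.0  # snap tips exactly to the present
        return cls(labels, parent, children, blen, age)

    def to_dendropy(self, taxon_namespace=None) -> "dendropy.Tree":
        ns = taxon_namespace or dendropy.TaxonNamespace()
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.tip_labels):
            nodes[i].taxon = ns.require_taxon(label=lab)
        for v in range(self.n_tips, self.n_nodes):
            l, r = self.children[v]
            nodes[v].add_child(nodes[l])
            nodes[v].add_child(nodes[r])
        for v in range(self.n_nodes - 1):
            nodes[v].edge.length = float(self.branch_length[v])
        tree = dendropy.Tree(taxon_namespace=ns)
        tree.seed_node = nodes[self.root]
        return tree

    def to_newick(self) -> str:
        """Serialize with branch lengths at full double precision."""

        def fmt(x: float) -> str:
            return format(x, ".17g")

        out = io.StringIO()
        # iterative traversal: tokens are ("open", v) / literal strings
        stack: List = [("node", self.root)]
        while stack:
            item = stack.pop()
            if isinstance(item, str):
                out.write(item)
                continue
            _, v = item
            suffix = "" if v == self.root else ":" + fmt(float(self.branch_length[v]))
            if v < self.n_tips:
                out.write(_quote_label(self.tip_labels[v]) + suffix)
            else:
                out.write("(")
                stack.append(")" + suffix)
                stack.append(("node", int(self.children[v, 1])))
                stack.append(",")
                stack.append(("node", int(self.children[v, 0])))
        out.write(";")
        return out.getvalue()

    # -- manipulation ------------------------------------------------------

    def prune_to(self, keep_labels: Iterable[str]) -> "PhyloTree":
        """Reconstructed subtree on ``keep_labels`` (unifurcations collapsed).

        The result is ultrametric with tips at age 0; its height is the age
        of the MRCA of the retained tips.
        """
        keep = set(keep_labels)
        unknown = keep - set(self.tip_labels)
        if unknown:
            raise TraitError(f"cannot prune: unknown tips {sorted(unknown)}")
        if len(keep) < 2:
            raise TreeValidationError("pruning must retain at least two tips")
        n, N = self.n_tips, self.n_nodes
        keep_mask = np.zeros(N, dtype=bool)
        for i, lab in enumerate(self.tip_labels):
            keep_mask[i] = lab in keep
        n_desc = np.zeros(N, dtype=np.int64)
        n_desc[:n] = keep_mask[:n].astype(np.int64)
        for v in range(n, N):
            l, r = self.children[v]
            n_desc[v] = n_desc[l] + n_desc[r]

        labels: List[str] = []
        child_list: List[Tuple[Tuple[str, int], Tuple[str, int]]] = []
        int_ages: List[float] = []

        # iterative postorder emit; handles are ("t", idx) or ("i", idx)
        def resolve(v: int) -> int:
            # descend through chains with a single surviving side
            while v >= n:
                l, r = self.children[v]
                if n_desc[l] > 0 and n_desc[r] > 0:
                    break
                v = int(l if n_desc[l] > 0 else r)
            return v

        handles: Dict[int, Tuple[str, int]] = {}
        stack: List[Tuple[int, bool]] = [(resolve(self.root), False)]
        while stack:
            v, expanded = stack.pop()
            if v < n:
                labels.append(self.tip_labels[v])
                handles[v] = ("t", len(labels) - 1)
                continue
            l = resolve(int(self.children[v, 0]))
            r = resolve(int(self.children[v, 1]))
            if not expanded:
                stack.append((v, True))
                stack.append((r, False))
                stack.append((l, False))
            else:
                child_list.append((handles[l], handles[r]))
                int_ages.append(float(self.age[v]))
                handles[v] = ("i", len(child_list) - 1)

        m = len(labels)
        M = 2 * m - 1
        children = np.full((M, 2), -1, dtype=np.int64)
        parent = np.full(M, -1, dtype=np.int64)
        age = np.zeros(M, dtype=np.float64)

        def final(h: Tuple[str, int]) -> int:
            return h[1] if h[0] == "t" else m + h[1]

        for k, (hl, hr) in enumerate(child_list):
            v = m + k
            children[v, 0] = final(hl)
            children[v, 1] = final(hr)
            parent[final(hl)] = v
            parent[final(hr)] = v
            age[v] = int_ages[k]
        blen = np.zeros(M, dtype=np.float64)
        for v in range(M - 1):
            blen[v] = age[parent[v]] - age[v]
        return PhyloTree(labels, parent, children, blen, age)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_tips={self.n_tips} height={self.height:.4g} Ma>"


def _quote_label(label: str) -> str:
    if any(c in label for c in " (),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


# -- newick I/O -------------------------------------------------------------


def read_newick(text: str) -> PhyloTree:
    """Parse a single newick string into a validated :class:`PhyloTree`."""
    text = text.strip()
    if not text:
        raise NewickParseError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return PhyloTree.from_dendropy(dtree)


def read_newick_file(path) -> List[PhyloTree]:
    """Read one tree per non-empty line (posterior sample convention)."""
    trees = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(read_newick(line))
            except NewickParseError as exc:
                raise NewickParseError(f"line {ln}: {exc}") from exc
    if not trees:
        raise NewickParseError(f"no trees found in {path}")
    return trees


def write_newick_file(trees: Sequence[PhyloTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# -- trait data -------------------------------------------------------------


@dataclass
class TraitDataset:
    """Per-tip binary trait (0 = small, 1 = megafaunal) with optional extras.

    ``states`` maps tip label to 0, 1 or ``None`` (missing).  Optional
    companions: fruit length in cm (> 0), region label ("NW"/"OW"), and a
    free-form clade tag.
    """

    states: Dict[str, Optional[int]]
    fruit_length_cm: Optional[Dict[str, float]] = None
    region: Optional[Dict[str, str]] = None
    clade: Optional[Dict[str, str]] = None

    def __post_init__(self):
        for tip, s in self.states.items():
            if s is not None and s not in (0, 1):
                raise TraitError(f"state for {tip!r} must be 0, 1 or missing")
        if self.fruit_length_cm is not None:
            for tip, x in self.fruit_length_cm.items():
                if not x > 0:
                    raise TraitError(f"non-positive fruit length for {tip!r}")

    @property
    def tips(self) -> List[str]:
        return list(self.states)

    def n_state(self, s: int) -> int:
        return sum(1 for v in self.states.values() if v == s)

    def n_missing(self) -> int:
        return sum(1 for v in self.states.values() if v is None)

    def complete_tips(self) -> List[str]:
        return [t for t, v in self.states.items() if v is not None]

    def validate_against(self, tree: PhyloTree) -> None:
        extra = set(self.states) - set(tree.tip_labels)
        if extra:
            raise TraitError(f"trait tips absent from tree: {sorted(extra)[:5]}")

    def state_array(self, tree: PhyloTree) -> np.ndarray:
        """States aligned to tip indices; raises on any missing state."""
        out = np.empty(tree.n_tips, dtype=np.int64)
        for i, lab in enumerate(tree.tip_labels):
            s = self.states.get(lab)
            if s is None:
                raise TraitError(
                    f"tip {lab!r} has no observed state; prune unscored tips "
                    "or impute before computing the likelihood"
                )
            out[i] = s
        return out

    def subset(self, labels: Iterable[str]) -> "TraitDataset":
        labels = [l for l in labels if l in self.states]
        pick = lambda d: {l: d[l] for l in labels if l in d} if d else None
        return TraitDataset(
            states={l: self.states[l] for l in labels},
            fruit_length_cm=pick(self.fruit_length_cm),
            region=pick(self.region),
            clade=pick(self.clade),
        )

    def rethreshold(self, threshold_cm: float) -> "TraitDataset":
        """Recompute binary states from fruit lengths at a new threshold."""
        if self.fruit_length_cm is None:
            raise TraitError("no fruit lengths available to re-threshold")
        states: Dict[str, Optional[int]] = {}
        for tip, old in self.states.items():
            if tip in self.fruit_length_cm:
                states[tip] = classify_fruit_lengths(
                    {tip: self.fruit_length_cm[tip]}, threshold_cm
                )[tip]
            else:
                states[tip] = None if old is None else old
        return TraitDataset(states, self.fruit_length_cm, self.region, self.clade)

    # table I/O (TSV/CSV with header: tip, state [, length_cm, region, clade])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tip, s in self.states.items():
            rows.append(
                {
                    "tip": tip,
                    "state": "NA" if s is None else int(s),
                    **(
                        {"length_cm": self.fruit_length_cm[tip]}
                        if self.fruit_length_cm and tip in self.fruit_length_cm
                        else {}
                    ),
                    **({"region": self.region[tip]} if self.region and tip in self.region else {}),
                    **({"clade": self.clade[tip]} if self.clade and tip in self.clade else {}),
                }
            )
        return pd.DataFrame(rows)

    def to_table(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False, na_rep="NA")

    @classmethod
    def from_table(cls, path, sep: Optional[str] = None) -> "TraitDataset":
        if sep is None:
            sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, dtype={"tip": str}, na_values=["NA"])
        if "tip" not in df.columns or "state" not in df.columns:
            raise TraitError("trait table must have 'tip' and 'state' columns")
        states: Dict[str, Optional[int]] = {}
        for _, row in df.iterrows():
            s = row["state"]
            states[row["tip"]] = None if pd.isna(s) else int(s)
        opt = {}
        for col, key in [("length_cm", "fruit_length_cm"), ("region", "region"), ("clade", "clade")]:
            if col in df.columns:
                d = {
                    row["tip"]: (float(row[col]) if col == "length_cm" else str(row[col]))
                    for _, row in df.iterrows()
                    if not pd.isna(row[col])
                }
                opt[key] = d or None
        return cls(states, **opt)


def classify_fruit_lengths(
    lengths: Dict[str, float], threshold_cm: float = 4.0
) -> Dict[str, int]:
    """Binary fruit-size states: 1 ("megafaunal") iff length >= threshold.

    The boundary is inclusive: a 4.0 cm fruit at the default 4 cm threshold
    is megafaunal.
    """
    if not threshold_cm > 0:
        raise TraitError("threshold must be positive")
    out = {}
    for tip, x in lengths.items():
        if not x > 0:
            raise TraitError(f"non-positive fruit length for {tip!r}: {x}")
        out[tip] = 1 if x >= threshold_cm else 0
    return out


# -- epoch slicing ----------------------------------------------------------


def validate_breakpoints(breakpoints: Sequence[float], height: float) -> np.ndarray:
    bp = np.asarray(breakpoints, dtype=np.float64)
    if bp.size and (np.any(np.diff(bp) <= 0)):
        raise TreeValidationError("breakpoints must be strictly increasing")
    if bp.size and (bp[0] <= 0 or bp[-1] >= height):
        raise TreeValidationError(
            f"breakpoints must lie strictly within (0, {height}) Ma"
        )
    return bp


def epoch_of_age(age: float, breakpoints: Sequence[float]) -> int:
    """Epoch index containing ``age``; an age exactly at a breakpoint maps
    to the older epoch (deterministic tie-break)."""
    return int(np.searchsorted(np.asarray(breakpoints, float), age, side="right"))


def branch_segments(
    tree: PhyloTree, breakpoints: Sequence[float]
) -> Dict[int, List[Tuple[float, float, int]]]:
    """Partition every edge into epoch-homogeneous age segments.

    Returns, per non-root node, a list of ``(start_age, end_age, epoch)``
    ordered young to old; segments tile the edge exactly.
    """
    bp = validate_breakpoints(breakpoints, tree.height)
    out: Dict[int, List[Tuple[float, float, int]]] = {}
    for v in range(tree.n_nodes - 1):
        lo = float(tree.age[v])
        hi = float(tree.age[tree.parent[v]])
        cuts = [lo] + [float(b) for b in bp if lo < b < hi] + [hi]
        segs = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            segs.append((a, b, epoch_of_age(a, bp)))
        out[v] = segs
    return out
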