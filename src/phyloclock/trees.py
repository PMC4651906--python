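"""Rooted tree topologies, Newick I/O, and resolution enumeration.

Trees here are rooted, possibly multifurcating, with optional internal-node
(clade) labels used to anchor fossil calibrations.  Node ages, when present,
are measured backwards from the present in units of 100 Myr (tips at 0);
conversion to Ma happens only at the reporting layer.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Topology",
    "TimeTree",
    "TreeError",
    "read_newick",
    "write_newick",
    "enumerate_resolutions",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or inconsistent tree operations."""


class Topology:
    """A rooted topology stored as parent/children index arrays.

    Nodes are integer ids ``0..n_nodes-1``; the root has parent ``-1``.
    Tip labels are unique; internal nodes may carry clade labels
    (e.g. ``"Protostomia"``) used to anchor calibrations.
    """

    def __init__(self, parent: list[int], labels: list[str | None]):
        self.parent = list(parent)
        self.labels = list(labels)
        n = len(parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.root = -1
        for v, p in enumerate(self.parent):
            if p == -1:
                if self.root != -1:
                    raise TreeError("multiple roots")
                self.root = v
            else:
                self.children[p].append(v)
        if self.root == -1:
            raise TreeError("no root found")
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        tips = [self.labels[v] for v in range(n) if self.is_tip[v]]
        if any(t is None for t in tips):
            raise TreeError("unlabeled tip")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        self._tip_index = {self.labels[v]: v for v in range(n) if self.is_tip[v]}
        self._label_index: dict[str, int] = {}
        for v in range(n):
            if self.labels[v] is not None:
                self._label_index.setdefault(self.labels[v], v)
        # depth-first postorder (children before parents)
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.preorder = order
        self.postorder = order[::-1]
        self._depth = np.zeros(n, dtype=int)
        for v in self.preorder:
            if self.parent[v] != -1:
                self._depth[v] = self._depth[self.parent[v]] + 1

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in range(self.n_nodes) if self.is_tip[v]]

    @property
    def internal_nodes(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.is_tip[v]]

    @property
    def polytomies(self) -> list[int]:
        """Internal nodes with more than two children."""
        return [v for v in range(self.n_nodes) if len(self.children[v]) > 2]

    @property
    def is_binary(self) -> bool:
        return not self.polytomies

    def tip(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"unknown tip label: {label!r}") from None

    def node_by_label(self, label: str) -> int:
        """Node id for a clade or tip label."""
        if label in self._label_index:
            return self._label_index[label]
        raise TreeError(f"unknown clade label: {label!r}")

    def mrca(self, tips) -> int:
        """Most recent common ancestor of a set of tip labels.

        The MRCA of a single tip is that tip itself.
        """
        ids = [self.tip(t) for t in tips]
        if not ids:
            raise TreeError("empty tip set")
        cur = ids[0]
        for v in ids[1:]:
            a, b = cur, v
            while a != b:
                if self._depth[a] < self._depth[b]:
                    b = self.parent[b]
                else:
                    a = self.parent[a]
            cur = a
        return cur

    def clade_tips(self, v: int) -> frozenset[str]:
        """Labels of all tips descending from node ``v``."""
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_tip[u]:
                out.append(self.labels[u])
            else:
                stack.extend(self.children[u])
        return frozenset(out)

    # -- Newick ----------------------------------------------------------

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if self.is_tip[v]:
                return self.labels[v]
            inner = ",".join(rec(c) for c in self.children[v])
            lab = self.labels[v] or ""
            return f"({inner}){lab}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Topology {self.n_tips} tips, {self.n_nodes} nodes>"


def read_newick(text: str) -> Topology:
    """Parse a Newick string (clade labels allowed) into a :class:`Topology`.

    Polytomies are preserved.  Raises :class:`TreeError` naming the offending
    token for unbalanced parentheses or duplicate tip labels.
    """
    if text.count("(") != text.count(")"):
        raise TreeError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise TreeError(f"newick parse error: {exc}") from exc

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = []
    labels: list[str | None] = []
    for nd in nodes:
        parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
        if nd.taxon is not None:
            labels.append(nd.taxon.label.replace(" ", "_"))
        else:
            labels.append(nd.label if nd.label else None)
    return Topology(parent, labels)


def write_newick(top: Topology) -> str:
    return top.to_newick()


# -- resolution enumeration ------------------------------------------------


def _pairings(k: int):
    """All ways to join two of k children under a new node (rooted resolutions)."""
    return list(itertools.combinations(range(k), 2))


def enumerate_resolutions(
    top: Topology,
    alternatives: dict[str, list[tuple[str, str]]] | None = None,
) -> list[Topology]:
    """Enumerate binary resolutions of a partially unresolved topology.

    Each trichotomy contributes its three rooted resolutions.  A node whose
    label appears in ``alternatives`` instead contributes only the listed
    arrangements; each alternative is a pair of tip labels identifying (one
    tip from each of) the two children to be joined under a new node.  The
    result is the Cartesian product of the local choices; for a binary input
    the list contains just the input topology.
    """
    alternatives = alternatives or {}
    choices: list[tuple[int, list[tuple[int, int]]]] = []
    for v in top.polytomies:
        kids = top.children[v]
        lab = top.labels[v]
        if lab is not None and lab in alternatives:
            pairs = []
            for ta, tb in alternatives[lab]:
                ia = _child_containing(top, v, ta)
                ib = _child_containing(top, v, tb)
                if ia == ib:
                    raise TreeError(
                        f"alternative ({ta!r}, {tb!r}) maps to one child of {lab!r}"
                    )
                pairs.append(tuple(sorted((kids.index(ia), kids.index(ib)))))
            choices.append((v, pairs))
        elif len(kids) == 3:
            choices.append((v, _pairings(3)))
        else:
            raise TreeError(
                f"polytomy of degree {len(kids)} at node {v} requires an "
                "explicit alternatives annotation"
            )
    if not choices:
        return [top]

    results = []
    for combo in itertools.product(*(pairs for _, pairs in choices)):
        results.append(_resolve(top, [v for v, _ in choices], combo))
    return results


def _child_containing(top: Topology, v: int, tip_label: str) -> int:
    t = top.tip(tip_label)
    u = t
    while top.parent[u] != v:
        u = top.parent[u]
        if u == -1:
            raise TreeError(f"tip {tip_label!r} not below node {v}")
    return u


def _resolve(top: Topology, nodes: list[int], pairings) -> Topology:
    parent = list(top.parent)
    labels = list(top.labels)
    for v, (i, j) in zip(nodes, pairings):
        kids = top.children[v]
        new = len(parent)
        parent.append(v)
        labels.append(None)
        parent[kids[i]] = new
        parent[kids[j]] = new
    return Topology(parent, labels)


# -- time trees ------------------------------------------------------------


@dataclass
class TimeTree:
    """A binary topology with node ages (unit: 100 Myr, present = 0)."""

    topology: Topology
    ages: np.ndarray  # per node id, tips typically 0

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.shape != (self.topology.n_nodes,):
            raise TreeError("ages array does not match node count")

    @property
    def root_age(self) -> float:
        return float(self.ages[self.topology.root])

    def validate(self) -> None:
        """Check every internal node is strictly older than its children."""
        top = self.topology
        for v in top.internal_nodes:
            for c in top.children[v]:
                if not self.ages[v] > self.ages[c]:
                    raise TreeError(
                        f"age ordering violated: node {v} (t={self.ages[v]:.4f}) "
                        f"not older than child {c} (t={self.ages[c]:.4f})"
                    )
        if (self.ages[self.topology.is_tip] < 0).any():
            raise TreeError("tip age below 0")

    def is_valid(self) -> bool:
        try:
            self.validate()
        except TreeError:
            return False
        return True

    def branch_durations(self) -> np.ndarray:
        """Per-node duration of the branch to the parent (root entry 0)."""
        top = self.topology
        d = np.zeros(top.n_nodes)
        for v in range(top.n_nodes):
            p = top.parent[v]
            if p != -1:
                d[v] = self.ages[p] - self.ages[v]
        return d

    def to_newick(self, unit: float = 1.0) -> str:
        """Newick with branch lengths (durations) scaled by ``unit``."""
        top = self.topology

        def rec(v: int) -> str:
            if top.is_tip[v]:
                s = top.labels[v]
            else:
                s = "(" + ",".join(rec(c) for c in top.children[v]) + ")"
                if top.labels[v]:
                    s += top.labels[v]
            p = top.parent[v]
            if p != -1:
                s += f":{(self.ages[p] - self.ages[v]) * unit:.6g}"
            return s

        return rec(top.root) + ";"
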