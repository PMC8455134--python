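"""Rooted, time-calibrated species trees.

A :class:`TimeTree` is the coordinate system for every reconstruction in this
package: node IDs are assigned by a deterministic post-order traversal of the
input Newick, so results are reproducible across runs and serializable by ID.
Branch lengths are durations in millions of years (My) and must be strictly
positive; a branch is identified by its *child* node (the root has no branch),
matching the "branch leading to X" phrasing used throughout comparative
genomics.

Parsing and serialization are delegated to :mod:`dendropy`; this module adds
validation, the ID scheme, and the traversal/MRCA utilities the analysis
stages need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

from .errors import TreeError

__all__ = ["TimeTree", "read_newick", "write_newick"]


@dataclass
class TimeTree:
    """Rooted tree with post-order integer node IDs.

    Attributes
    ----------
    parent : np.ndarray
        ``parent[i]`` is the parent node ID of node ``i``; ``-1`` for the root.
    branch_length : np.ndarray
        Duration (My) of the branch leading to each node; ``nan`` for the root.
    children : list[list[int]]
        Child IDs per node, in input order.
    tip_label : dict[int, str]
        Labels of tip nodes, preserved verbatim from the input.
    """

    parent: np.ndarray
    branch_length: np.ndarray
    children: list[list[int]]
    tip_label: dict[int, str] = field(default_factory=dict)

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1  # post-order: root is visited last

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    @property
    def tips(self) -> list[int]:
        return sorted(self.tip_label)

    @property
    def tip_labels(self) -> list[str]:
        return [self.tip_label[i] for i in self.tips]

    def branches(self) -> list[int]:
        """All branch IDs (every node except the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def duration(self, node: int) -> float:
        """Duration t (My) of the branch leading to ``node``."""
        if node == self.root:
            raise TreeError("the root has no branch")
        return float(self.branch_length[node])

    # -------------------------------------------------------------- traversal
    def postorder(self) -> range:
        return range(self.n_nodes)  # IDs *are* the post-order

    def preorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    def subtree_tips(self, node: int) -> list[int]:
        """Tip IDs descending from (or equal to) ``node``."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)

    def depth(self, node: int) -> int:
        """Number of edges from the root."""
        d, v = 0, node
        while self.parent[v] >= 0:
            v = self.parent[v]
            d += 1
        return d

    def ancestors(self, node: int, include_self: bool = False) -> list[int]:
        out = [node] if include_self else []
        v = node
        while self.parent[v] >= 0:
            v = self.parent[v]
            out.append(v)
        return out

    def mrca(self, nodes: Iterable[int]) -> int:
        """Most recent common ancestor of a set of node IDs."""
        nodes = list(nodes)
        if not nodes:
            raise TreeError("MRCA of an empty node set is undefined")
        paths = [set(self.ancestors(v, include_self=True)) for v in nodes]
        common = set.intersection(*paths)
        # the deepest common ancestor
        return max(common, key=self.depth)

    def ancestor_matrix(self) -> np.ndarray:
        """Boolean matrix A with ``A[v, a]`` true iff ``a`` is ``v`` or an ancestor of ``v``."""
        n = self.n_nodes
        A = np.zeros((n, n), dtype=bool)
        for v in self.preorder():
            A[v, v] = True
            p = self.parent[v]
            if p >= 0:
                A[v] |= A[p]
        return A

    def label_of(self, node: int) -> str:
        return self.tip_label.get(node, f"N{node}")

    def node_by_label(self, label: str) -> int:
        """Resolve a tip label, an internal ``N<id>`` label, or a bare integer ID."""
        for i, lab in self.tip_label.items():
            if lab == label:
                return i
        if label.startswith("N") and label[1:].isdigit():
            idx = int(label[1:])
        elif label.isdigit():
            idx = int(label)
        else:
            raise TreeError(f"unknown node label {label!r}")
        if not 0 <= idx < self.n_nodes:
            raise TreeError(f"node ID {idx} out of range")
        return idx

    # ------------------------------------------------------------------- io
    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if self.is_tip(v):
                core = self.tip_label[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{self.branch_length[v]:.10g}"

        return rec(self.root) + ";"

    def total_branch_length(self) -> float:
        return float(np.nansum(self.branch_length))


def _from_dendropy(dtree: dendropy.Tree, *, allow_polytomies: bool,
                   zero_length_epsilon: float | None) -> TimeTree:
    nodes = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.full(n, np.nan)
    children: list[list[int]] = [[] for _ in range(n)]
    tip_label: dict[int, str] = {}

    root = nodes[-1]
    if len(root.child_nodes()) > 2 and not allow_polytomies:
        raise TreeError(
            "basal polytomy: the tree appears unrooted "
            "(pass allow_polytomies=True to accept it)"
        )

    for i, nd in enumerate(nodes):
        for ch in nd.child_nodes():
            j = index[id(ch)]
            parent[j] = i
            children[i].append(j)
        if nd is not root:
            el = nd.edge.length
            if el is None:
                raise TreeError("missing branch length on a non-root branch")
            el = float(el)
            if el <= 0:
                if zero_length_epsilon is not None and el == 0:
                    el = zero_length_epsilon
                else:
                    raise TreeError(
                        f"non-positive branch length {el} (branch durations must be > 0 My)"
                    )
            blen[i] = el
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("unlabeled tip")
            tip_label[i] = nd.taxon.label

    # children lists must be in input (left-to-right) order; dendropy preserves it
    labels = list(tip_label.values())
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    return TimeTree(parent=parent, branch_length=blen, children=children,
                    tip_label=tip_label)


def read_newick(source: str, *, allow_polytomies: bool = False,
                zero_length_epsilon: float | None = None) -> TimeTree:
    """Read a rooted Newick tree (branch lengths in My) from a path or string.

    Node IDs are assigned by post-order traversal of the file as written, so
    the same file always yields the same IDs.  Zero-length input branches are
    an error unless ``zero_length_epsilon`` substitutes a small positive
    duration.
    """
    import os

    if os.path.exists(source):
        try:
            with open(source) as fh:
                text = fh.read()
        except OSError as exc:
            raise TreeError(f"cannot read tree file {source!r}: {exc}") from exc
    elif "(" in source:
        text = source  # inline newick data
    else:
        raise TreeError(f"cannot read tree file {source!r}: no such file")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse failure: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise TreeError("empty tree")
    return _from_dendropy(dtree, allow_polytomies=allow_polytomies,
                          zero_length_epsilon=zero_length_epsilon)


def write_newick(tree: TimeTree, path: str | None = None) -> str:
    """Serialize a :class:`TimeTree` back to Newick; returns the string."""
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s
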