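"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from famevol import FamilyCountTable, PresenceMatrix, read_newick
from famevol.trees import TimeTree


@pytest.fixture
def small_tree() -> TimeTree:
    """((A,B),((C,D),E)) with unit-ish branch durations."""
    return read_newick("((A:10,B:10):20,((C:5,D:5):15,E:20):10);")


@pytest.fixture
def two_tip_tree() -> TimeTree:
    return read_newick("(A:10,B:20);")


def presence_from_sets(tree: TimeTree, fam_tips: dict[str, set[str]]) -> PresenceMatrix:
    labels = tree.tip_labels
    data = {f: [sp in tips for sp in labels] for f, tips in fam_tips.items()}
    return PresenceMatrix(pd.DataFrame(data, index=labels).T)


def counts_table(tree: TimeTree, rows: dict[str, list[int]]) -> FamilyCountTable:
    return FamilyCountTable(
        pd.DataFrame(rows, index=tree.tip_labels).T.astype(int))


# ------------------------------------------------------------- Dollo oracle
def all_tree_shapes(n_tips: int) -> list[str]:
    """Newick strings for every unordered rooted binary shape with n tips.

    Tips are labeled t1..tn left to right; all branch lengths 1.
    """

    def shapes(n: int):
        if n == 1:
            return [None]  # leaf marker
        out = []
        seen = set()
        for k in range(1, n // 2 + 1):
            for left in shapes(k):
                for right in shapes(n - k):
                    key = tuple(sorted([repr(left), repr(right)]))
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append((left, right))
        return out

    def render(shape, counter):
        if shape is None:
            counter[0] += 1
            return f"t{counter[0]}:1"
        left, right = shape
        return f"({render(left, counter)},{render(right, counter)}):1"

    result = []
    for shape in shapes(n_tips):
        counter = [0]
        s = render(shape, counter)
        # strip the root's branch length
        result.append(s.rsplit(":", 1)[0] + ";")
    return result


def dollo_bruteforce(tree: TimeTree, present_tips: set[int]) -> int:
    """Minimum number of losses over all single-gain / any-loss histories.

    Exhaustively enumerates every origin node and every presence assignment
    to internal nodes below it that is connected through the origin, counting
    present-parent → absent-child edges.
    """
    best = None
    for origin in range(tree.n_nodes):
        sub = set()
        stack = [origin]
        while stack:
            v = stack.pop()
            sub.add(v)
            stack.extend(tree.children[v])
        if not present_tips <= sub:
            continue
        internals = [v for v in sub if not tree.is_tip(v)]
        for bits in itertools.product([False, True], repeat=len(internals)):
            state = {v: b for v, b in zip(internals, bits)}
            for t in sub:
                if tree.is_tip(t):
                    state[t] = t in present_tips
            if internals and not state.get(origin, True):
                continue
            if tree.is_tip(origin) and origin not in present_tips:
                continue
            # presence must be connected: present child needs present parent
            ok = True
            losses = 0
            for v in sub:
                if v == origin:
                    continue
                p = tree.parent[v]
                if state[v] and not state[p]:
                    ok = False
                    break
                if state[p] and not state[v]:
                    losses += 1
            if not ok:
                continue
            if best is None or losses < best:
                best = losses
    assert best is not None
    return best
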