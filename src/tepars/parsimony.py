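"""Equal-weights unordered parsimony: Fitch/Hartigan length and
most-parsimonious-reconstruction (MPR) state sets.

All operations treat missing and inapplicable cells as full ambiguity
(any state at zero cost), the conventional "gaps as missing" reading.
Lengths are computed by the Hartigan generalization of the Fitch
down-pass (exact on multifurcating trees); MPR sets and per-branch
minimum change counts come from a uniform-cost dynamic program over
states (down-pass + up-pass).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from tepars.trees import Node, PhyloTree

INF = 10**9


class ParsimonyError(ValueError):
    pass


@dataclass(frozen=True)
class Column:
    """One character: per-taxon allowed state sets over 0..nstates-1."""

    states: Mapping[str, frozenset[int]]
    nstates: int

    def allowed(self, label: str) -> frozenset[int]:
        try:
            sets = self.states[label]
        except KeyError:
            raise ParsimonyError(f"leaf {label!r} has no data in column")
        return sets if sets else frozenset(range(self.nstates))


def fitch_length(tree: PhyloTree, column: Column) -> int:
    """Minimum number of unordered state changes on ``tree``.

    Hartigan's count-based down-pass: at each internal node the states
    hit by the maximal number of child state sets are kept; each child
    set missing them contributes one change. Exact for any arity and
    invariant under rerooting.
    """
    down: dict[int, frozenset[int]] = {}
    length = 0
    for node in tree.postorder():
        if node.is_leaf:
            down[id(node)] = column.allowed(node.label)
            continue
        counts = [0] * column.nstates
        for child in node.children:
            for s in down[id(child)]:
                counts[s] += 1
        best = max(counts)
        down[id(node)] = frozenset(
            s for s in range(column.nstates) if counts[s] == best
        )
        length += len(node.children) - best
    return length


def tree_length(tree: PhyloTree, matrix) -> int:
    """Sum of per-character minimum changes (equal weights).

    ``matrix`` is anything exposing ``columns() -> list[Column]``
    (e.g. a CombinedMatrix).
    """
    missing = set(tree.leaf_labels()) - set(matrix.taxa)
    if missing:
        raise ParsimonyError(
            f"tree leaves absent from matrix: {sorted(missing)}"
        )
    return sum(fitch_length(tree, col) for col in matrix.columns())


def _down_pass(tree: PhyloTree, column: Column) -> dict[int, list[int]]:
    """g[v][s] = min cost of v's subtree given v has state s."""
    k = column.nstates
    g: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            allowed = column.allowed(node.label)
            g[id(node)] = [0 if s in allowed else INF for s in range(k)]
        else:
            tot = [0] * k
            for child in node.children:
                gc = g[id(child)]
                m = min(gc) + 1
                for s in range(k):
                    tot[s] += min(gc[s], m)
            g[id(node)] = tot
    return g


def _up_pass(
    tree: PhyloTree, column: Column, g: dict[int, list[int]]
) -> tuple[dict[int, list[int]], dict[int, bool], int]:
    """R[v][s] = min cost of the whole tree given v has state s.

    Also reports, per non-root node v, whether every optimal
    reconstruction implies a change on the branch (parent(v), v).
    """
    k = column.nstates
    R: dict[int, list[int]] = {id(tree.root): list(g[id(tree.root)])}
    forced: dict[int, bool] = {}
    total = min(R[id(tree.root)])
    for node in tree.preorder():
        Ru = R[id(node)]
        for child in node.children:
            gc = g[id(child)]
            m = min(gc) + 1
            rest = [Ru[s] - min(gc[s], m) for s in range(k)]
            mrest = min(rest) + 1
            R[id(child)] = [
                (gc[s] + min(rest[s], mrest)) if gc[s] < INF else INF
                for s in range(k)
            ]
            forced[id(child)] = (
                min(rest[s] + gc[s] for s in range(k)) > total
            )
    return R, forced, total


def mpr_sets(tree: PhyloTree, column: Column) -> dict[Node, frozenset[int]]:
    """Per-node MPR sets: states appearing in at least one
    minimum-length reconstruction.

    Leaves report their allowed set (the observed state, or the full
    state set for missing/inapplicable cells).
    """
    if not tree.rooted:
        raise ParsimonyError("mpr_sets requires a rooted tree")
    g = _down_pass(tree, column)
    R, _forced, total = _up_pass(tree, column, g)
    out: dict[Node, frozenset[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            out[node] = column.allowed(node.label)
        else:
            out[node] = frozenset(
                s for s in range(column.nstates) if R[id(node)][s] == total
            )
    return out


def forced_branch_changes(tree: PhyloTree, column: Column) -> set[int]:
    """ids of nodes whose parent branch carries at least one change in
    every most-parsimonious reconstruction of this column."""
    g = _down_pass(tree, column)
    _R, forced, _total = _up_pass(tree, column, g)
    return {nid for nid, flag in forced.items() if flag}
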