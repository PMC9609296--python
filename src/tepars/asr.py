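"""Unordered-parsimony ancestral state reconstruction and per-branch
transformation extraction for morphological matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from tepars.catalog import (
    CharacterCatalog,
    MorphMatrix,
    validate_matrix,
)
from tepars.parsimony import Column, mpr_sets
from tepars.trees import Node, PhyloTree, TreeError


class ASRError(ValueError):
    pass


@dataclass(frozen=True)
class Transformation:
    node_id: int  # preorder id of the child node of the branch
    char_id: int
    parent_states: frozenset[int]
    child_states: frozenset[int]


@dataclass
class ASRResult:
    tree: PhyloTree
    # preorder node id -> char_id -> MPR state set
    states: dict[int, dict[int, frozenset[int]]]
    node_ids: dict[int, Node] = field(repr=False, default_factory=dict)
    # (node_id, char_id) pairs where the controlling character's MPR set
    # lies entirely in states that switch the dependent character off
    inapplicable_context: set[tuple[int, int]] = field(default_factory=set)

    def node_id_of(self, node: Node) -> int:
        for nid, n in self.node_ids.items():
            if n is node:
                return nid
        raise ASRError("node not part of this reconstruction")

    def ambiguous(self, node_id: int, char_id: int) -> bool:
        return len(self.states[node_id][char_id]) > 1

    def char_ids(self) -> list[int]:
        any_row = next(iter(self.states.values()))
        return sorted(any_row)


def reconstruct(
    tree: PhyloTree,
    matrix: MorphMatrix,
    catalog: CharacterCatalog,
    validated: bool = False,
) -> ASRResult:
    """MPR state sets for every node and character.

    The matrix is validated against the catalog first; hard violations
    (anything except warnings about undeclared controlling states)
    abort the reconstruction. Requires a rooted binary tree whose
    leaves are matrix taxa.
    """
    if not tree.rooted:
        raise ASRError("reconstruction requires a rooted tree")
    if not tree.is_binary:
        raise ASRError(
            "reconstruction requires a fully resolved (binary) tree; "
            "resolve polytomies explicitly before calling"
        )
    if not validated:
        report = validate_matrix(matrix, catalog)
        hard = [v for v in report.violations if v.kind != "UNDECLARED_CONTROLLING_STATE"]
        if hard:
            raise ASRError(
                f"matrix fails validation ({len(hard)} violation(s), first: "
                f"{hard[0]}); fix the matrix or inspect the ValidationReport"
            )
    missing = set(tree.leaf_labels()) - set(matrix.taxa)
    if missing:
        raise ASRError(f"tree leaves without matrix rows: {sorted(missing)}")

    node_ids = {i: node for i, node in enumerate(tree.preorder())}
    id_of = {id(node): nid for nid, node in node_ids.items()}
    states: dict[int, dict[int, frozenset[int]]] = {
        nid: {} for nid in node_ids
    }
    per_char_sets: dict[int, dict[Node, frozenset[int]]] = {}
    for char in catalog:
        universe = frozenset(char.state_codes)
        col_states = {}
        for taxon in tree.leaf_labels():
            cell = matrix.row(taxon)[char.char_id]
            col_states[taxon] = (
                frozenset((cell,)) if isinstance(cell, int) else universe
            )
        column = Column(states=col_states, nstates=max(universe) + 1)
        sets = mpr_sets(tree, column)
        per_char_sets[char.char_id] = sets
        for node, stateset in sets.items():
            states[id_of[id(node)]][char.char_id] = stateset

    inapplicable_context: set[tuple[int, int]] = set()
    for char in catalog:
        for cond in char.inapplicable_if:
            controlling = cond.states & catalog.get(cond.controller).state_codes
            if not controlling:
                continue
            for nid in node_ids:
                ctrl_set = states[nid].get(cond.controller)
                if ctrl_set and ctrl_set <= controlling:
                    inapplicable_context.add((nid, char.char_id))

    return ASRResult(
        tree=tree,
        states=states,
        node_ids=node_ids,
        inapplicable_context=inapplicable_context,
    )


def transformations(asr: ASRResult) -> list[Transformation]:
    """Branch/character pairs whose parent and child MPR sets are
    disjoint — a change implied by every most-parsimonious
    reconstruction. Ordered by preorder node id, then char_id."""
    id_of = {id(node): nid for nid, node in asr.node_ids.items()}
    out: list[Transformation] = []
    for nid in sorted(asr.node_ids):
        node = asr.node_ids[nid]
        if node.parent is None:
            continue
        pid = id_of[id(node.parent)]
        for cid in asr.char_ids():
            pset = asr.states[pid][cid]
            cset = asr.states[nid][cid]
            if pset and cset and not (pset & cset):
                out.append(Transformation(nid, cid, pset, cset))
    return out


def stem_state(
    asr: ASRResult, clade: set[str], char_id: int
) -> frozenset[int]:
    """MPR set for ``char_id`` at the most recent common ancestor of a
    monophyletic leaf-label set."""
    clade = set(clade)
    try:
        mrca = asr.tree.mrca(clade)
    except TreeError as exc:
        raise ASRError(str(exc)) from exc
    descendants = asr.tree.leafset(mrca)
    intruders = descendants - clade
    if intruders:
        raise ASRError(
            f"label set is not monophyletic; MRCA also contains "
            f"{sorted(intruders)}"
        )
    nid = asr.node_id_of(mrca)
    try:
        return asr.states[nid][char_id]
    except KeyError:
        raise ASRError(f"character {char_id} not reconstructed") from None


def asr_table(asr: ASRResult) -> list[dict]:
    """Flat per-node export (one record per node/character)."""
    rows = []
    for nid in sorted(asr.node_ids):
        node = asr.node_ids[nid]
        for cid in asr.char_ids():
            stateset = asr.states[nid][cid]
            rows.append(
                {
                    "node_id": nid,
                    "label": node.label or "",
                    "is_leaf": node.is_leaf,
                    "char_id": cid,
                    "states": "/".join(map(str, sorted(stateset))),
                    "ambiguous": len(stateset) > 1,
                    "inapplicable_context": (nid, cid)
                    in asr.inapplicable_context,
                }
            )
    return rows
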