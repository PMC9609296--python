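"""Synthetic data generation: Yule trees, dependency-respecting
discrete morphology with known ancestral states, and nucleotide
partitions under GTR+G+I — everything needed to exercise the full
pipeline without external downloads."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from tepars.catalog import (
    INAPPLICABLE,
    CharacterCatalog,
    MorphMatrix,
    load_default_catalog,
)
from tepars.assembly import AlignedPartition, OtuMap
from tepars.morphotype import MorphotypeRule, load_default_rule
from tepars.trees import Node, PhyloTree

NUCS = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_taxa: int = 12
    seed: int = 0
    birth_rate: float = 1.0
    # morphology
    catalog: Optional[CharacterCatalog] = None
    morph_rate: float = 0.1
    # molecular
    partition_lengths: dict[str, int] = field(
        default_factory=lambda: {"16S": 671, "COI": 657, "NADH1": 426, "H3": 328}
    )
    gtr_rates: tuple[float, ...] = (1.0, 2.0, 1.0, 1.0, 4.0, 1.0)  # AC AG AT CG CT GT
    base_freqs: tuple[float, ...] = (0.3, 0.2, 0.2, 0.3)
    gamma_shape: float = 0.5
    p_invariant: float = 0.2
    mol_rate: float = 1.0

    def __post_init__(self):
        if self.birth_rate <= 0 or self.morph_rate < 0 or self.mol_rate <= 0:
            raise SimulationError("rates must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise SimulationError("base frequencies must sum to 1")
        if any(length <= 0 for length in self.partition_lengths.values()):
            raise SimulationError("partition lengths must be positive")
        if not (0.0 <= self.p_invariant < 1.0):
            raise SimulationError("p_invariant must lie in [0, 1)")


@dataclass
class SimTruth:
    tree: PhyloTree
    # preorder node id -> char_id -> true (unmasked) state
    node_states: dict[int, dict[int, int]]
    # (preorder node id, char_id) -> realized change count on parent branch
    branch_changes: dict[tuple[int, int], int]
    node_ids: dict[int, Node] = field(repr=False, default_factory=dict)

    def total_changes(self, char_id: Optional[int] = None) -> int:
        return sum(
            n
            for (_nid, cid), n in self.branch_changes.items()
            if char_id is None or cid == char_id
        )


def simulate_tree(config: SimConfig) -> PhyloTree:
    """Pure-birth (Yule) tree conditioned on ``n_taxa`` tips, leaves
    labelled T1..Tn, branch lengths in time units."""
    if config.n_taxa < 4:
        raise SimulationError("need at least 4 taxa")
    rng = np.random.default_rng(config.seed)
    root = Node()
    a, b = Node(), Node()
    root.add_child(a)
    root.add_child(b)
    active = [a, b]
    birth_time = {id(a): 0.0, id(b): 0.0}
    now = 0.0
    while len(active) < config.n_taxa:
        now += rng.exponential(1.0 / (config.birth_rate * len(active)))
        parent = active.pop(int(rng.integers(0, len(active))))
        parent.length = now - birth_time.pop(id(parent))
        for _ in range(2):
            child = parent.add_child(Node())
            birth_time[id(child)] = now
            active.append(child)
    # hold past the last split so terminal branches are non-zero
    now += rng.exponential(1.0 / (config.birth_rate * len(active)))
    for leaf in active:
        leaf.length = now - birth_time.pop(id(leaf))
    tree = PhyloTree(root, rooted=True)
    for i, leaf in enumerate(tree.leaves()):
        leaf.label = f"T{i + 1}"
    return tree


def _evolve_discrete(
    state: int, k: int, rate: float, t: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Jump-chain simulation of a symmetric k-state chain; returns
    (final state, number of state-changing events)."""
    n_events = rng.poisson(rate * t)
    changes = 0
    for _ in range(n_events):
        new = int(rng.integers(0, k - 1))
        if new >= state:
            new += 1
        state = new
        changes += 1
    return state, changes


def simulate_morphology(
    tree: PhyloTree, config: SimConfig
) -> tuple[MorphMatrix, SimTruth]:
    """Simulate every catalog character down the tree under a symmetric
    Mk model, controllers before dependents, then mask dependent cells
    as inapplicable wherever a taxon's controller state switches them
    off. The emitted matrix passes catalog validation by construction.
    """
    catalog = config.catalog or load_default_catalog()
    rng = np.random.default_rng(config.seed + 1)
    node_ids = {i: node for i, node in enumerate(tree.preorder())}
    id_of = {id(node): nid for nid, node in node_ids.items()}
    node_states: dict[int, dict[int, int]] = {nid: {} for nid in node_ids}
    branch_changes: dict[tuple[int, int], int] = {}

    order = catalog.dependency_order()
    for cid in order:
        char = catalog.get(cid)
        k = len(char.states)
        root_state = int(rng.integers(0, k))
        for node in tree.preorder():
            nid = id_of[id(node)]
            if node.parent is None:
                node_states[nid][cid] = root_state
                continue
            pstate = node_states[id_of[id(node.parent)]][cid]
            t = node.length or 0.0
            state, changes = _evolve_discrete(
                pstate, k, config.morph_rate, t, rng
            )
            node_states[nid][cid] = state
            branch_changes[(nid, cid)] = changes

    # emit leaf rows with inapplicability masking (controllers first)
    cells: dict[str, dict[int, object]] = {}
    for node in tree.leaves():
        nid = id_of[id(node)]
        row: dict[int, object] = {}
        for cid in order:
            char = catalog.get(cid)
            masked = False
            for cond in char.inapplicable_if:
                ctrl = row.get(cond.controller)
                if isinstance(ctrl, int) and ctrl in cond.states:
                    masked = True
                    break
            row[cid] = INAPPLICABLE if masked else node_states[nid][cid]
        cells[node.label] = {cid: row[cid] for cid in catalog.char_ids()}
    matrix = MorphMatrix(
        taxa=[leaf.label for leaf in tree.leaves()],
        char_ids=catalog.char_ids(),
        cells=cells,
    )
    truth = SimTruth(
        tree=tree,
        node_states=node_states,
        branch_changes=branch_changes,
        node_ids=node_ids,
    )
    return matrix, truth


def _gtr_q(config: SimConfig) -> np.ndarray:
    freqs = np.asarray(config.base_freqs)
    r = config.gtr_rates
    idx = {(0, 1): 0, (0, 2): 1, (0, 3): 2, (1, 2): 3, (1, 3): 4, (2, 3): 5}
    Q = np.zeros((4, 4))
    for (i, j), k in idx.items():
        Q[i, j] = r[k] * freqs[j]
        Q[j, i] = r[k] * freqs[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(freqs * np.diag(Q)).sum()
    return Q / scale


def simulate_sequences(
    tree: PhyloTree, config: SimConfig
) -> list[AlignedPartition]:
    """GTR+G+I sequence simulation: per-site rate is 0 with probability
    p_invariant, otherwise drawn from a mean-one discrete gamma (4
    categories)."""
    rng = np.random.default_rng(config.seed + 2)
    Q = _gtr_q(config)
    freqs = np.asarray(config.base_freqs)
    ncat = 4
    quantiles = (np.arange(ncat) + 0.5) / ncat
    cat_rates = gamma_dist.ppf(
        quantiles, a=config.gamma_shape, scale=1.0 / config.gamma_shape
    )
    cat_rates = cat_rates / cat_rates.mean()

    partitions = []
    nodes = list(tree.preorder())
    for name, length in config.partition_lengths.items():
        invariant = rng.random(length) < config.p_invariant
        cats = rng.integers(0, ncat, size=length)
        site_rates = np.where(invariant, 0.0, cat_rates[cats])
        seqs: dict[int, np.ndarray] = {}
        seqs[id(nodes[0])] = rng.choice(4, size=length, p=freqs)
        pmats: dict[tuple[float, float], np.ndarray] = {}
        for node in nodes[1:]:
            parent_seq = seqs[id(node.parent)]
            t = (node.length or 0.0) * config.mol_rate
            child = parent_seq.copy()
            for r in np.unique(site_rates):
                if r == 0.0:
                    continue
                key = (round(t, 12), round(float(r), 12))
                if key not in pmats:
                    pmats[key] = expm(Q * t * r)
                P = pmats[key]
                sites = np.where(site_rates == r)[0]
                for s in range(4):
                    block = sites[parent_seq[sites] == s]
                    if block.size:
                        child[block] = rng.choice(4, size=block.size, p=P[s])
            seqs[id(node)] = child
        rows = {
            leaf.label: "".join(NUCS[s] for s in seqs[id(leaf)])
            for leaf in tree.leaves()
        }
        partitions.append(
            AlignedPartition(name=name, length=length, rows=rows)
        )
    return partitions


@dataclass
class FixtureStudy:
    catalog: CharacterCatalog
    morphology: MorphMatrix
    partitions: list[AlignedPartition]
    otu_map: OtuMap
    true_tree: PhyloTree
    rule: MorphotypeRule
    swimmer_clade: frozenset[str]
    loss_leaf: str


# full-row templates consistent with the shipped catalog's dependencies
SWIMMER_TEMPLATE: dict[int, object] = {
    1: 1, 2: 1, 3: 1, 4: 0, 5: 0, 6: 0, 7: 1, 8: 1, 9: 1, 10: 0, 11: 1,
    12: 1, 13: INAPPLICABLE, 14: 1, 15: 1, 16: 1, 17: 1, 18: 2, 19: 1,
    20: 0, 21: 1, 22: 1, 23: 0, 24: 0, 25: 0, 26: 0, 27: INAPPLICABLE,
    28: 3, 29: 0, 30: 1, 31: 2, 32: 1, 33: 2, 34: 2, 35: INAPPLICABLE,
    36: 0, 37: 0, 38: 3, 39: 1, 40: 0, 41: 4, 42: 0, 43: 0, 44: 1, 45: 1,
    46: 1, 47: 1, 48: 1, 49: 1, 50: 0, 51: 0, 52: 0, 53: 1, 54: 0, 55: 0,
    56: 1, 57: 1, 58: 0, 59: 1,
}
WALKER_TEMPLATE: dict[int, object] = {
    1: 0, 2: 0, 3: 0, 4: 1, 5: 0, 6: 0, 7: 0, 8: INAPPLICABLE,
    9: INAPPLICABLE, 10: INAPPLICABLE, 11: INAPPLICABLE, 12: INAPPLICABLE,
    13: INAPPLICABLE, 14: INAPPLICABLE, 15: INAPPLICABLE, 16: INAPPLICABLE,
    17: INAPPLICABLE, 18: 0, 19: 0, 20: INAPPLICABLE, 21: 0,
    22: INAPPLICABLE, 23: INAPPLICABLE, 24: 1, 25: 0, 26: 1,
    27: INAPPLICABLE, 28: 0, 29: 1, 30: 0, 31: 0, 32: 0, 33: 0, 34: 0,
    35: INAPPLICABLE, 36: INAPPLICABLE, 37: 1, 38: 0, 39: 0,
    40: INAPPLICABLE, 41: INAPPLICABLE, 42: 0, 43: 1, 44: 0, 45: 0, 46: 0,
    47: 0, 48: 0, 49: 0, 50: 1, 51: 1, 52: 3, 53: 0, 54: 1, 55: 1, 56: 0,
    57: 0, 58: 1, 59: 0,
}


def make_fixture_study(seed: int = 0) -> FixtureStudy:
    """Miniature end-to-end study: 12 taxa, a designated swimmer clade
    whose terminals satisfy the shipped morphotype rule, and one leaf
    inside it on which the paddle characters were lost."""
    catalog = load_default_catalog()
    rule = load_default_rule()
    config = SimConfig(
        n_taxa=12,
        seed=seed,
        catalog=catalog,
        partition_lengths={"16S": 300, "COI": 300, "NADH1": 220, "H3": 180},
        mol_rate=0.5,
        gamma_shape=5.0,
        p_invariant=0.05,
    )
    tree = simulate_tree(config)
    # clamp branch lengths into a low-homoplasy band: long enough for
    # signal on every edge, short enough to avoid saturation
    for node in tree.postorder():
        if node.length is not None:
            node.length = min(max(node.length, 0.08), 0.6)
    # swimmer clade: first internal node (preorder) with 3..5 leaves
    clade_node = None
    for node in tree.preorder():
        if not node.is_leaf and node is not tree.root:
            size = len(tree.leafset(node))
            if 3 <= size <= 5:
                clade_node = node
                break
    assert clade_node is not None
    swimmer_clade = tree.leafset(clade_node)
    loss_leaf = sorted(swimmer_clade)[0]

    cells: dict[str, dict[int, object]] = {}
    for leaf in tree.leaf_labels():
        if leaf in swimmer_clade:
            row = dict(SWIMMER_TEMPLATE)
            if leaf == loss_leaf:
                row.update({46: 0, 47: 0, 48: 0})
        else:
            row = dict(WALKER_TEMPLATE)
        cells[leaf] = row
    morphology = MorphMatrix(
        taxa=tree.leaf_labels(), char_ids=catalog.char_ids(), cells=cells
    )
    partitions = simulate_sequences(tree, config)
    otu_map = OtuMap(
        entries={
            taxon: [(taxon, p.name, "") for p in partitions]
            for taxon in tree.leaf_labels()
        }
    )
    return FixtureStudy(
        catalog=catalog,
        morphology=morphology,
        partitions=partitions,
        otu_map=otu_map,
        true_tree=tree,
        rule=rule,
        swimmer_clade=frozenset(swimmer_clade),
        loss_leaf=loss_leaf,
    )
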