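"""Heuristic maximum-parsimony tree search and support estimation.

Search strategy: random-addition-sequence starting trees followed by
first-improvement branch swapping (NNI, SPR, or TBR = SPR with
rerooting of the pruned subtree). Scoring uses a vectorized bitmask
Fitch pass over pattern-compressed columns. Trees are manipulated in a
rooted-binary representation; topology identity and all reported
results are unrooted (bipartition-based).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from tepars.parsimony import Column
from tepars.trees import Node, PhyloTree
from tepars import parsimony


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchConfig:
    n_addition_replicates: int = 10
    swap: str = "SPR"  # NNI | SPR | TBR
    seed: int = 0
    keep_all_optimal: bool = True
    max_trees: int = 100

    def __post_init__(self):
        if self.n_addition_replicates < 1:
            raise SearchError("n_addition_replicates must be positive")
        if self.swap.upper() not in ("NNI", "SPR", "TBR"):
            raise SearchError(f"unknown swap mode {self.swap!r}")
        if self.max_trees < 1:
            raise SearchError("max_trees must be positive")


# ---------------------------------------------------------------------------
# fast Fitch scoring over bitmask patterns


class _Scorer:
    """Weighted vectorized Fitch over pattern-compressed columns."""

    def __init__(self, taxa: list[str], columns: Iterable[Column]):
        self.taxa = list(taxa)
        index = {t: i for i, t in enumerate(self.taxa)}
        patterns: dict[tuple[int, ...], float] = {}
        self.n_columns = 0
        for col in columns:
            masks = []
            full = (1 << col.nstates) - 1
            for t in self.taxa:
                m = 0
                for s in col.allowed(t):
                    m |= 1 << s
                masks.append(m if m else full)
            key = tuple(masks)
            patterns[key] = patterns.get(key, 0.0) + 1.0
            self.n_columns += 1
        self.index = index
        self.keys = list(patterns)
        self.masks = np.array(self.keys, dtype=np.int64).T.copy()  # taxa x P
        self.weights = np.array([patterns[k] for k in self.keys])
        # map each original column to its pattern (for bootstrap resampling)
        self._col_pattern: list[int] = []
        pat_index = {k: i for i, k in enumerate(self.keys)}
        for col_key in self._iter_keys_again(columns):
            self._col_pattern.append(pat_index[col_key])

    def _iter_keys_again(self, columns):
        # second pass kept separate for clarity; columns may be a list
        for col in columns:
            masks = []
            full = (1 << col.nstates) - 1
            for t in self.taxa:
                m = 0
                for s in col.allowed(t):
                    m |= 1 << s
                masks.append(m if m else full)
            yield tuple(masks)

    def resampled_weights(self, rng: np.random.Generator) -> np.ndarray:
        """Pattern weights after resampling columns with replacement."""
        draws = rng.integers(0, self.n_columns, size=self.n_columns)
        w = np.zeros(len(self.keys))
        for d in draws:
            w[self._col_pattern[d]] += 1.0
        return w

    def score(self, root: Node, weights: Optional[np.ndarray] = None) -> float:
        w = self.weights if weights is None else weights
        length = 0.0
        stack = [(root, False)]
        cache: dict[int, np.ndarray] = {}
        while stack:
            node, done = stack.pop()
            if node.children and not done:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
                continue
            if not node.children:
                cache[id(node)] = self.masks[self.index[node.label]]
            else:
                acc = cache.pop(id(node.children[0]))
                for c in node.children[1:]:
                    other = cache.pop(id(c))
                    inter = acc & other
                    zero = inter == 0
                    length += w[zero].sum()
                    acc = np.where(zero, acc | other, inter)
                cache[id(node)] = acc
        return length


# ---------------------------------------------------------------------------
# rooted-binary tree manipulation helpers (search internal)


def _canonical(tree: PhyloTree) -> frozenset[frozenset[str]]:
    return frozenset(tree.bipartitions())


def _insert_leaf_above(tree: PhyloTree, target: Node, label: str) -> PhyloTree:
    """New tree with ``label`` attached on the edge above ``target``."""
    new = tree.copy()
    # locate corresponding node by positional path
    path = _path_to(tree.root, target)
    node = _follow(new.root, path)
    parent = node.parent
    joint = Node()
    leaf = Node(label=label)
    if parent is None:
        # attach at root: new root with (old root, leaf)
        joint.add_child(node)
        joint.add_child(leaf)
        return PhyloTree(joint, rooted=tree.rooted)
    idx = parent.children.index(node)
    node.parent = joint
    joint.add_child(leaf)
    joint.children.insert(0, node)
    node.parent = joint
    joint.parent = parent
    parent.children[idx] = joint
    return PhyloTree(new.root, rooted=tree.rooted)


def _path_to(root: Node, target: Node) -> list[int]:
    path: list[int] = []
    node = target
    while node is not root:
        path.append(node.parent.children.index(node))
        node = node.parent
    path.reverse()
    return path


def _follow(root: Node, path: list[int]) -> Node:
    node = root
    for idx in path:
        node = node.children[idx]
    return node


def _prune_regraft(
    tree: PhyloTree, prune_path: list[int], graft_path: list[int]
) -> Optional[PhyloTree]:
    """SPR move on a copy. Paths are positional (child indices from the
    root). Returns None for degenerate moves."""
    new = tree.copy()
    pruned = _follow(new.root, prune_path)
    parent = pruned.parent
    if parent is None:
        return None
    grand = parent.parent
    sibling = [c for c in parent.children if c is not pruned]
    if len(sibling) != 1:
        return None
    sibling = sibling[0]
    # detach: replace parent with sibling
    if grand is None:
        new_root = sibling
        sibling.parent = None
    else:
        idx = grand.children.index(parent)
        grand.children[idx] = sibling
        sibling.parent = grand
        new_root = new.root
    # locate graft target in the reduced tree
    try:
        target = _follow(new_root, graft_path)
    except IndexError:
        return None
    if target is pruned or _is_descendant(target, pruned):
        return None
    joint = Node()
    tparent = target.parent
    if tparent is None:
        joint.add_child(target)
        joint.add_child(pruned)
        return PhyloTree(joint, rooted=tree.rooted)
    tidx = tparent.children.index(target)
    joint.add_child(target)
    joint.add_child(pruned)
    joint.parent = tparent
    tparent.children[tidx] = joint
    return PhyloTree(new_root, rooted=tree.rooted)


def _is_descendant(node: Node, ancestor: Node) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def _reroot_subtree(node: Node, edge_child: Node) -> Node:
    """Reroot the (detached) subtree ``node`` on the edge above
    ``edge_child``; returns the new subtree apex (a binary node)."""
    parent = edge_child.parent
    parent.children.remove(edge_child)
    edge_child.parent = None
    apex = Node()
    apex.add_child(edge_child)
    rehung = _invert_to(parent, node)
    apex.add_child(rehung)
    _suppress(apex)
    return apex


def _invert_to(node: Node, old_root: Node) -> Node:
    parent = node.parent
    node.parent = None
    current = node
    while parent is not None:
        grand = parent.parent
        parent.children.remove(current)
        current.add_child(parent)
        current, parent = parent, grand
    return node


def _suppress(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for i, child in enumerate(list(node.children)):
            while len(child.children) == 1:
                only = child.children[0]
                only.parent = node
                node.children[node.children.index(child)] = only
                child = only
            stack.append(child)


def _all_node_paths(tree: PhyloTree) -> list[list[int]]:
    out = []
    def walk(node: Node, path: list[int]):
        if node is not tree.root:
            out.append(path)
        for i, c in enumerate(node.children):
            walk(c, path + [i])
    walk(tree.root, [])
    return out


def _neighbors(
    tree: PhyloTree, swap: str, rng: np.random.Generator
):
    """Yield swap neighbourhood trees in randomized order."""
    swap = swap.upper()
    moves = []
    paths = _all_node_paths(tree)
    for ppath in paths:
        pruned = _follow(tree.root, ppath)
        if swap == "NNI" and (pruned.is_leaf or pruned.parent is tree.root):
            # NNI: swap a node with its "uncle"; realized as SPR of the
            # node onto edges two steps away — restrict prune targets
            pass
        for gpath in paths:
            if gpath[: len(ppath)] == ppath:
                continue  # graft inside pruned subtree
            if swap == "NNI" and not _nni_move(ppath, gpath):
                continue
            moves.append((ppath, gpath, None))
        if swap == "TBR" and not pruned.is_leaf:
            sub_paths = _all_node_paths(PhyloTree(pruned, rooted=True))
            for spath in sub_paths:
                if not spath:
                    continue
                for gpath in paths:
                    if gpath[: len(ppath)] == ppath:
                        continue
                    moves.append((ppath, gpath, spath))
    rng.shuffle(moves)
    for ppath, gpath, spath in moves:
        if spath is None:
            result = _prune_regraft(tree, ppath, gpath)
        else:
            result = _tbr_move(tree, ppath, gpath, spath)
        if result is not None:
            yield result


def _nni_move(ppath: list[int], gpath: list[int]) -> bool:
    # NNI ~ regraft onto an edge adjacent to the original position
    if len(gpath) > len(ppath) + 1 or len(ppath) > len(gpath) + 2:
        return False
    return True


def _tbr_move(tree, ppath, gpath, spath) -> Optional[PhyloTree]:
    new = tree.copy()
    pruned = _follow(new.root, ppath)
    edge_child = _follow(pruned, spath)
    parent = pruned.parent
    if parent is None:
        return None
    grand = parent.parent
    siblings = [c for c in parent.children if c is not pruned]
    if len(siblings) != 1:
        return None
    sibling = siblings[0]
    if grand is None:
        new_root = sibling
        sibling.parent = None
    else:
        grand.children[grand.children.index(parent)] = sibling
        sibling.parent = grand
        new_root = new.root
    pruned.parent = None
    if len(pruned.children) >= 2 and spath:
        pruned = _reroot_subtree(pruned, edge_child)
    try:
        target = _follow(new_root, gpath)
    except IndexError:
        return None
    if _is_descendant(target, pruned):
        return None
    joint = Node()
    tparent = target.parent
    if tparent is None:
        joint.add_child(target)
        joint.add_child(pruned)
        return PhyloTree(joint, rooted=tree.rooted)
    tparent.children[tparent.children.index(target)] = joint
    joint.parent = tparent
    joint.add_child(target)
    joint.add_child(pruned)
    return PhyloTree(new_root, rooted=tree.rooted)


# ---------------------------------------------------------------------------
# public operations


def mp_search(
    matrix, config: SearchConfig
) -> tuple[list[PhyloTree], int]:
    """Heuristic MP search; returns (optimal trees found, best length).

    Deterministic given ``config.seed``. Returned trees are binary and
    distinct as unrooted topologies.
    """
    taxa = list(matrix.taxa)
    if len(taxa) < 4:
        raise SearchError("mp_search requires at least 4 taxa")
    scorer = _Scorer(taxa, matrix.columns())
    rng = np.random.default_rng(config.seed)
    best_len = np.inf
    best: dict[frozenset, PhyloTree] = {}

    for _rep in range(config.n_addition_replicates):
        order = [taxa[i] for i in rng.permutation(len(taxa))]
        tree = _addition_tree(order, scorer, rng)
        tree, length = _swap_to_optimum(tree, scorer, config.swap, rng)
        if length < best_len - 1e-9:
            best_len = length
            best = {_canonical(tree): tree}
        elif abs(length - best_len) < 1e-9 and len(best) < config.max_trees:
            best.setdefault(_canonical(tree), tree)

    if config.keep_all_optimal:
        _expand_plateau(best, best_len, scorer, config, rng)
    trees = list(best.values())
    for t in trees:
        t.rooted = False
    return trees, int(round(best_len))


def _addition_tree(
    order: list[str], scorer: _Scorer, rng: np.random.Generator
) -> PhyloTree:
    root = Node()
    root.add_child(Node(label=order[0]))
    inner = Node()
    inner.add_child(Node(label=order[1]))
    inner.add_child(Node(label=order[2]))
    root.add_child(inner)
    tree = PhyloTree(root, rooted=True)
    for label in order[3:]:
        candidates = []
        best = np.inf
        for path in _all_node_paths(tree) + [[]]:
            target = _follow(tree.root, path)
            cand = _insert_leaf_above(tree, target, label)
            length = scorer.score(cand.root)
            if length < best - 1e-9:
                best = length
                candidates = [cand]
            elif abs(length - best) < 1e-9:
                candidates.append(cand)
        tree = candidates[rng.integers(0, len(candidates))]
    return tree


def _swap_to_optimum(
    tree: PhyloTree, scorer: _Scorer, swap: str, rng: np.random.Generator
) -> tuple[PhyloTree, float]:
    length = scorer.score(tree.root)
    improved = True
    while improved:
        improved = False
        for cand in _neighbors(tree, swap, rng):
            cand_len = scorer.score(cand.root)
            if cand_len < length - 1e-9:
                tree, length = cand, cand_len
                improved = True
                break
    return tree, length


def _expand_plateau(
    best: dict, best_len: float, scorer: _Scorer, config: SearchConfig,
    rng: np.random.Generator,
) -> None:
    """Collect equally-optimal neighbours of the optimal trees (closure
    up to max_trees)."""
    frontier = list(best.values())
    while frontier and len(best) < config.max_trees:
        tree = frontier.pop()
        for cand in _neighbors(tree, config.swap, rng):
            if len(best) >= config.max_trees:
                break
            if abs(scorer.score(cand.root) - best_len) < 1e-9:
                key = _canonical(cand)
                if key not in best:
                    best[key] = cand
                    frontier.append(cand)


def collapse_unsupported(tree: PhyloTree, matrix) -> PhyloTree:
    """Contract every internal branch whose minimum length over all
    most-parsimonious reconstructions is zero (across all characters).

    The result may contain polytomies; tree length is preserved.
    """
    new = tree.copy()
    forced_any: set[int] = set()
    root_pair_forced = False
    node_list = list(new.postorder())
    columns = matrix.columns()
    for col in columns:
        forced_any |= parsimony.forced_branch_changes(new, col)
        # root-degree-2: the two root-child edges are one unrooted edge;
        # it is forced iff no optimal labeling assigns both ends the
        # same state, i.e. min_s(g_c1[s] + g_c2[s]) exceeds the optimum
        if len(new.root.children) == 2:
            g = parsimony._down_pass(new, col)
            c1, c2 = new.root.children
            joint = min(a + b for a, b in zip(g[id(c1)], g[id(c2)]))
            if joint > min(g[id(new.root)]):
                root_pair_forced = True
    if len(new.root.children) == 2:
        c1, c2 = new.root.children
        for c in (c1, c2):
            forced_any.discard(id(c))
        if root_pair_forced:
            forced_any.add(id(c1))
            forced_any.add(id(c2))
    for node in node_list:
        if node.is_leaf or node.parent is None:
            continue
        if id(node) not in forced_any:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx: idx + 1] = node.children
            for c in node.children:
                c.parent = parent
    if len(new.root.children) == 2 and not tree.rooted:
        pass
    result = PhyloTree(new.root, rooted=tree.rooted)
    return result


def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the bipartitions common to all inputs."""
    if not trees:
        raise SearchError("strict_consensus of empty tree set")
    leafsets = [frozenset(t.leaf_labels()) for t in trees]
    if len(set(leafsets)) != 1:
        raise SearchError("strict_consensus requires identical leaf sets")
    shared = set(trees[0].bipartitions())
    for t in trees[1:]:
        shared &= t.bipartitions()
    return tree_from_splits(sorted(leafsets[0]), shared)


def tree_from_splits(
    leaves: list[str], splits: Iterable[frozenset[str]]
) -> PhyloTree:
    """Build a (possibly multifurcating) tree realizing a set of
    pairwise-compatible splits, each given as the side not containing
    the first leaf."""
    root = Node()
    for label in leaves:
        root.add_child(Node(label=label))
    tree = PhyloTree(root, rooted=False)
    for split in sorted(set(splits), key=len, reverse=True):
        node = root
        descended = True
        while descended:
            descended = False
            for child in node.children:
                if not child.is_leaf and tree.leafset(child) >= split:
                    node = child
                    descended = True
                    break
        group = [
            c for c in node.children if tree.leafset(c) <= split
        ]
        covered = frozenset().union(*(tree.leafset(c) for c in group))
        if covered != split or len(group) == len(node.children):
            continue  # incompatible or trivial; skip defensively
        fresh = Node()
        for c in group:
            node.children.remove(c)
            fresh.add_child(c)
        node.add_child(fresh)
    return PhyloTree(root, rooted=False)


def bootstrap(
    matrix, config: SearchConfig, n_reps: int
) -> dict[frozenset[str], float]:
    """Nonparametric bootstrap support (percent per bipartition).

    Each replicate resamples all characters with replacement and runs a
    reduced search; when a replicate yields several optimal trees, each
    contributes fractional credit. Deterministic given config.seed.
    """
    if n_reps < 1:
        raise SearchError("n_reps must be positive")
    taxa = list(matrix.taxa)
    if len(taxa) < 4:
        raise SearchError("bootstrap requires at least 4 taxa")
    scorer = _Scorer(taxa, matrix.columns())
    rng = np.random.default_rng(config.seed)
    credit: dict[frozenset[str], float] = {}
    rep_adds = max(1, config.n_addition_replicates // 3)
    for _rep in range(n_reps):
        weights = scorer.resampled_weights(rng)
        best_len = np.inf
        best: dict[frozenset, PhyloTree] = {}
        for _add in range(rep_adds):
            order = [taxa[i] for i in rng.permutation(len(taxa))]
            tree = _addition_tree_weighted(order, scorer, weights, rng)
            tree, length = _swap_weighted(tree, scorer, weights, config.swap, rng)
            if length < best_len - 1e-9:
                best_len, best = length, {_canonical(tree): tree}
            elif abs(length - best_len) < 1e-9 and len(best) < config.max_trees:
                best.setdefault(_canonical(tree), tree)
        share = 1.0 / len(best)
        for t in best.values():
            for split in t.bipartitions():
                credit[split] = credit.get(split, 0.0) + share
    return {s: 100.0 * c / n_reps for s, c in credit.items()}


def _addition_tree_weighted(order, scorer, weights, rng):
    root = Node()
    root.add_child(Node(label=order[0]))
    inner = Node()
    inner.add_child(Node(label=order[1]))
    inner.add_child(Node(label=order[2]))
    root.add_child(inner)
    tree = PhyloTree(root, rooted=True)
    for label in order[3:]:
        best, cands = np.inf, []
        for path in _all_node_paths(tree) + [[]]:
            target = _follow(tree.root, path)
            cand = _insert_leaf_above(tree, target, label)
            length = scorer.score(cand.root, weights)
            if length < best - 1e-9:
                best, cands = length, [cand]
            elif abs(length - best) < 1e-9:
                cands.append(cand)
        tree = cands[rng.integers(0, len(cands))]
    return tree


def _swap_weighted(tree, scorer, weights, swap, rng):
    length = scorer.score(tree.root, weights)
    improved = True
    while improved:
        improved = False
        for cand in _neighbors(tree, swap, rng):
            cand_len = scorer.score(cand.root, weights)
            if cand_len < length - 1e-9:
                tree, length = cand, cand_len
                improved = True
                break
    return tree, length


def root_on_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root so that ``outgroup`` is sister to all remaining taxa."""
    return tree.rerooted_above(outgroup)
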