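"""Independent brute-force / DP oracles used to verify the parsimony
implementations. These deliberately share no code with the package:
lengths come from exhaustive enumeration over internal labelings (or a
uniform-cost Sankoff DP for larger cases), MPR sets and branch tests
from the same enumeration.
"""

from __future__ import annotations

import itertools

from tepars.parsimony import Column
from tepars.trees import Node, PhyloTree


def _edges(tree: PhyloTree):
    return [
        (node.parent, node)
        for node in tree.postorder()
        if node.parent is not None
    ]


def enumerate_labelings(tree: PhyloTree, column: Column):
    """Yield (assignment dict node->state, cost) for every combination
    of internal-node states and ambiguous-leaf resolutions."""
    nodes = list(tree.postorder())
    choices = []
    for node in nodes:
        if node.is_leaf:
            choices.append(sorted(column.allowed(node.label)))
        else:
            choices.append(list(range(column.nstates)))
    edges = _edges(tree)
    for combo in itertools.product(*choices):
        assignment = {id(n): s for n, s in zip(nodes, combo)}
        cost = sum(
            1 for p, c in edges if assignment[id(p)] != assignment[id(c)]
        )
        yield assignment, cost


def brute_force_length(tree: PhyloTree, column: Column) -> int:
    return min(cost for _a, cost in enumerate_labelings(tree, column))


def brute_force_mpr(tree: PhyloTree, column: Column):
    """MPR sets for internal nodes by exhaustive enumeration."""
    best = brute_force_length(tree, column)
    sets: dict[int, set[int]] = {}
    for assignment, cost in enumerate_labelings(tree, column):
        if cost == best:
            for node in tree.internal_nodes():
                sets.setdefault(id(node), set()).add(assignment[id(node)])
    return {nid: frozenset(s) for nid, s in sets.items()}, best


def brute_force_zero_change_branches(tree: PhyloTree, column: Column):
    """ids of child nodes whose parent branch is change-free in at
    least one minimum-length labeling."""
    best = brute_force_length(tree, column)
    free: set[int] = set()
    for assignment, cost in enumerate_labelings(tree, column):
        if cost == best:
            for p, c in _edges(tree):
                if assignment[id(p)] == assignment[id(c)]:
                    free.add(id(c))
    return free


def sankoff_length(tree: PhyloTree, column: Column) -> int:
    """Uniform-cost Sankoff DP (independent of the package's scorers)."""
    INF = 10**9
    k = column.nstates
    cost: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            allowed = column.allowed(node.label)
            cost[id(node)] = [0 if s in allowed else INF for s in range(k)]
        else:
            acc = [0] * k
            for child in node.children:
                cc = cost[id(child)]
                for s in range(k):
                    acc[s] += min(
                        cc[t] + (0 if s == t else 1) for t in range(k)
                    )
            cost[id(node)] = acc
    return min(cost[id(tree.root)])


def random_tree(labels, rng, rooted=True) -> PhyloTree:
    """Uniform-ish random binary tree built by sequential attachment."""
    labels = list(labels)
    root = Node()
    root.add_child(Node(label=labels[0]))
    root.add_child(Node(label=labels[1]))
    tree = PhyloTree(root, rooted=rooted)
    for label in labels[2:]:
        nodes = [n for n in tree.postorder() if n.parent is not None]
        target = nodes[rng.integers(0, len(nodes))]
        parent = target.parent
        idx = parent.children.index(target)
        joint = Node()
        joint.add_child(target)
        joint.add_child(Node(label=label))
        joint.parent = parent
        parent.children[idx] = joint
        tree = PhyloTree(root, rooted=rooted)
    return tree


def random_column(labels, rng, max_states=4, ambiguous=True) -> Column:
    k = int(rng.integers(2, max_states + 1))
    states = {}
    for label in labels:
        if ambiguous and rng.random() < 0.15:
            states[label] = frozenset(range(k))  # missing
        else:
            states[label] = frozenset({int(rng.integers(0, k))})
    return Column(states=states, nstates=k)


def exhaustive_unrooted_topologies(labels):
    """All unrooted binary topologies (as rooted representations with
    the first label attached at the root)."""
    labels = list(labels)
    base = Node()
    base.add_child(Node(label=labels[0]))
    base.add_child(Node(label=labels[1]))
    trees = [base]
    for label in labels[2:]:
        nxt = []
        for tree in trees:
            ptree = PhyloTree(tree, rooted=True)
            targets = [n for n in ptree.postorder() if n.parent is not None]
            for i in range(len(targets)):
                clone = ptree.copy()
                ctargets = [
                    n for n in clone.postorder() if n.parent is not None
                ]
                target = ctargets[i]
                parent = target.parent
                idx = parent.children.index(target)
                joint = Node()
                joint.add_child(target)
                joint.add_child(Node(label=label))
                joint.parent = parent
                parent.children[idx] = joint
                nxt.append(clone.root)
        trees = nxt
    return [PhyloTree(t, rooted=False) for t in trees]
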