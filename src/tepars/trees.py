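"""Rooted/unrooted phylogenetic tree structure with Newick I/O.

Trees are stored as rooted node structures; an "unrooted" tree is
represented with a basal trifurcation. Newick parsing is delegated to
dendropy; writing is a direct serialization of the node structure.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("children", "parent", "label", "length", "support")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.label = label
        self.length = length
        self.support = support

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '(internal)'}>"


class PhyloTree:
    """A tree over uniquely labelled leaves.

    ``rooted`` is a semantic flag: scoring operations accept either, but
    ancestral-state reconstruction requires a rooted binary tree.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        labels = [leaf.label for leaf in self.leaves() if leaf.label is not None]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise TreeError(f"leaf {label!r} not found in tree")

    @property
    def is_binary(self) -> bool:
        """True if every internal node has exactly two children.

        A basal trifurcation is accepted when the tree is flagged
        unrooted (the usual representation of an unrooted binary tree).
        """
        for node in self.internal_nodes():
            if node is self.root and not self.rooted:
                if len(node.children) not in (2, 3):
                    return False
            elif len(node.children) != 2:
                return False
        return True

    # -- construction / copying -------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted)

    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
            if dnode.child_nodes() and dnode.label is not None:
                # internal labels carry support values when numeric
                try:
                    node.support = float(dnode.label)
                except (TypeError, ValueError):
                    pass
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node), rooted=rooted)

    def to_newick(
        self,
        lengths: bool = True,
        supports: bool = False,
        node_comment: Optional[Callable[[Node], Optional[str]]] = None,
    ) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _quote(node.label or "")
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if supports and node.support is not None:
                    s += f"{node.support:g}"
                elif node.label:
                    s += _quote(node.label)
            if node_comment is not None:
                comment = node_comment(node)
                if comment:
                    s += f"[&{comment}]"
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    # -- splits / clades ---------------------------------------------------

    def leafset(self, node: Node) -> frozenset[str]:
        return frozenset(
            n.label for n in _subtree_postorder(node) if n.is_leaf
        )

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the side that does
        not contain the lexicographically smallest leaf label."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = self.leafset(node)
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def mrca(self, labels) -> Node:
        labels = set(labels)
        missing = labels - set(self.leaf_labels())
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        node_sets: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                node_sets[id(node)] = {node.label} & labels
            else:
                s = set()
                for c in node.children:
                    s |= node_sets[id(c)]
                node_sets[id(node)] = s
        best = None
        for node in self.postorder():
            if node_sets[id(node)] == labels:
                best = node
                break
        assert best is not None
        return best

    # -- rerooting ---------------------------------------------------------

    def rerooted_above(self, leaf_label: str) -> "PhyloTree":
        """Return a copy rooted on the edge subtending ``leaf_label``:
        the named leaf becomes sister to everything else."""
        tree = self.copy()
        leaf = tree.find_leaf(leaf_label)
        if leaf.parent is None:
            raise TreeError("cannot root on a single-leaf tree")
        if leaf.parent is tree.root and len(tree.root.children) == 2:
            tree.rooted = True
            return tree

        new_root = Node()
        old_parent = leaf.parent
        old_parent.children.remove(leaf)
        leaf.parent = None
        half = (leaf.length / 2.0) if leaf.length is not None else None
        leaf.length = half
        new_root.add_child(leaf)
        flipped = _invert_path(old_parent)
        flipped.length = half
        new_root.add_child(flipped)
        _suppress_unifurcations(new_root)
        return PhyloTree(new_root, rooted=True)


def _subtree_postorder(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    out.reverse()
    return out


def _invert_path(node: Node) -> Node:
    """Reverse parent pointers from ``node`` up to the old root so that
    ``node`` becomes the apex of the re-hung subtree."""
    parent = node.parent
    node.parent = None
    edge_length = node.length
    current = node
    while parent is not None:
        grand = parent.parent
        next_len = parent.length
        parent.children.remove(current)
        current.add_child(parent)
        parent.length = edge_length
        edge_length = next_len
        current, parent = parent, grand
    return node


def _suppress_unifurcations(root: Node) -> None:
    for node in _subtree_postorder(root):
        for child in list(node.children):
            while len(child.children) == 1:
                only = child.children[0]
                idx = node.children.index(child)
                only.parent = node
                if only.length is not None and child.length is not None:
                    only.length += child.length
                node.children[idx] = only
                child = only


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label
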