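"""Rooted species tree with unique node labels.

The tree is the backbone every other module traverses: gene lineages,
adjacency propagation and dating are all expressed in terms of its nodes.
Newick parsing is delegated to :mod:`dendropy`; the parsed topology is then
re-indexed into a lightweight structure with parent pointers, stable child
order and O(1) label lookup.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Sequence

import dendropy

__all__ = ["TreeNode", "SpeciesTree", "TreeError", "read_species_tree"]


class TreeError(ValueError):
    """Raised for structurally invalid species trees."""


class TreeNode:
    __slots__ = ("label", "parent", "children", "length", "depth")

    def __init__(self, label: str, length: float = 0.0) -> None:
        self.label = label
        self.parent: Optional["TreeNode"] = None
        self.children: List["TreeNode"] = []
        self.length = length  # branch length to parent
        self.depth = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        node.depth = self.depth + 1
        self.children.append(node)
        return node

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.label!r})"


class SpeciesTree:
    """Rooted tree indexed by unique, non-empty node labels."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self.nodes: Dict[str, TreeNode] = {}
        self._leafsets: Dict[str, frozenset] = {}
        for node in self._walk_preorder(root):
            if not node.label:
                raise TreeError("every node must carry a non-empty label")
            if node.label in self.nodes:
                raise TreeError(f"duplicate node label: {node.label!r}")
            node.depth = 0 if node.parent is None else node.parent.depth + 1
            self.nodes[node.label] = node
        if len(self.leaf_labels()) < 2:
            raise TreeError("species tree must have at least 2 leaves")

    # -- traversal -------------------------------------------------------

    @staticmethod
    def _walk_preorder(root: TreeNode) -> Iterator[TreeNode]:
        stack = [root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def preorder(self) -> Iterator[TreeNode]:
        return self._walk_preorder(self.root)

    def postorder(self) -> Iterator[TreeNode]:
        out: List[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> List[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    # -- queries ---------------------------------------------------------

    def __contains__(self, label: str) -> bool:
        return label in self.nodes

    def node(self, label: str) -> TreeNode:
        try:
            return self.nodes[label]
        except KeyError:
            raise TreeError(f"unknown tree node: {label!r}") from None

    def leaf_set(self, label: str) -> frozenset:
        """Labels of all leaves in the clade rooted at ``label`` (cached)."""
        cached = self._leafsets.get(label)
        if cached is None:
            node = self.node(label)
            acc = set()
            for n in self._walk_preorder(node):
                if n.is_leaf:
                    acc.add(n.label)
            cached = self._leafsets[label] = frozenset(acc)
        return cached

    def is_ancestor_or_self(self, anc: str, desc: str) -> bool:
        node: Optional[TreeNode] = self.node(desc)
        target = self.node(anc)
        while node is not None:
            if node is target:
                return True
            node = node.parent
        return False

    def mrca(self, labels: Sequence[str]) -> str:
        if not labels:
            raise TreeError("mrca of empty label set")
        nodes = [self.node(lab) for lab in set(labels)]
        current = nodes[0]
        for other in nodes[1:]:
            a, b = current, other
            while a.depth > b.depth:
                a = a.parent
            while b.depth > a.depth:
                b = b.parent
            while a is not b:
                a, b = a.parent, b.parent
            current = a
        return current.label

    def path_down(self, anc: str, desc: str) -> List[str]:
        """Labels strictly below ``anc`` down to and including ``desc``."""
        path: List[str] = []
        node: Optional[TreeNode] = self.node(desc)
        target = self.node(anc)
        while node is not None and node is not target:
            path.append(node.label)
            node = node.parent
        if node is None:
            raise TreeError(f"{desc!r} is not a descendant of {anc!r}")
        path.reverse()
        return path

    # -- serialization ---------------------------------------------------

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.label
            if lengths and node.parent is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"


def read_species_tree(newick_text: str) -> SpeciesTree:
    """Parse a rooted newick string into a :class:`SpeciesTree`.

    Internal nodes lacking a label receive a deterministic synthetic label
    ``N<k>`` where ``k`` is the node's preorder index (collisions with
    existing labels are avoided by appending underscores). An explicit
    unrooted marker (``[&U]``) is rejected; multifurcations, including at
    the root, are preserved.
    """
    stripped = newick_text.strip()
    if stripped.upper().startswith("[&U]"):
        raise TreeError("unrooted tree ([&U]) rejected: a rooted tree is required")
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"invalid newick: {exc}") from exc

    used = set()
    for dnode in dtree.preorder_node_iter():
        lab = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if lab:
            used.add(lab)

    def convert(dnode, index_counter) -> TreeNode:
        lab = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if not lab:
            lab = f"N{index_counter[0]}"
            while lab in used:
                lab += "_"
            used.add(lab)
        node = TreeNode(lab, length=dnode.edge.length or 0.0)
        for dchild in dnode.child_nodes():
            index_counter[0] += 1
            node.add_child(convert(dchild, index_counter))
        return node

    root = convert(dtree.seed_node, [0])
    if not root.children:
        raise TreeError("tree has no internal structure")
    return SpeciesTree(root)
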