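"""Adjacency dating: emergence nodes, ages, phylostratigraphy, clusters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .lineage import LineageForest
from .synteny import Adjacency, LinearContig, SyntenyGraph
from .tree import SpeciesTree

__all__ = [
    "DatedEdge",
    "PhylostratRecord",
    "AdjacencyCluster",
    "date_edges",
    "resolve_node_ages",
    "ages_from_table",
    "phylostratigraphy",
    "find_adjacency_clusters",
]


@dataclass
class DatedEdge:
    level: str
    gene1: str
    gene2: str
    emergence: str
    age_ma: Optional[float] = None


@dataclass
class PhylostratRecord:
    level: str
    gained: int
    retained: int
    lost: int
    duplicated: int


@dataclass
class AdjacencyCluster:
    contig_id: str
    adjacencies: List[Tuple[str, str]]

    @property
    def size(self) -> int:
        return len(self.adjacencies)


def date_edges(
    filtered: Dict[str, SyntenyGraph], tree: SpeciesTree
) -> List[DatedEdge]:
    """One dated record per retained ancestral edge and per extant edge.

    Emergence stamps are produced by the top-down filter: an extant edge
    inherits the emergence of its root-most retained ancestor lineage, or
    its own leaf when never retained ancestrally.
    """
    out: List[DatedEdge] = []
    for node in tree.preorder():
        graph = filtered[node.label]
        for key in sorted(graph.edges):
            edge = graph.edges[key]
            if edge.emergence is None:
                raise ValueError(
                    f"edge {key} at {node.label} has no emergence stamp; "
                    "run filter_top_down first"
                )
            out.append(DatedEdge(node.label, key[0], key[1], edge.emergence))
    return out


def resolve_node_ages(
    tree: SpeciesTree, ages: Dict[str, float]
) -> Dict[str, float]:
    """Complete a partial node→age (Ma) table over the whole tree.

    Leaves get age 0. A node with no tabulated age gets the average of its
    nearest aged ancestor and the oldest of its children carrying age
    information, applied iteratively root-to-leaves until stable. Nodes
    that can never be resolved raise.
    """
    resolved: Dict[str, float] = {}
    for leaf in tree.leaves():
        resolved[leaf.label] = 0.0
    for label, age in ages.items():
        resolved[label] = 0.0 if tree.node(label).is_leaf else age

    order = [n for n in tree.preorder() if not n.is_leaf]
    changed = True
    while changed:
        changed = False
        for node in order:
            if node.label in resolved:
                continue
            anc = node.parent
            anc_age = None
            while anc is not None:
                if anc.label in resolved:
                    anc_age = resolved[anc.label]
                    break
                anc = anc.parent
            child_ages = [
                resolved[c.label] for c in node.children if c.label in resolved
            ]
            if anc_age is None or not child_ages:
                continue
            resolved[node.label] = (anc_age + max(child_ages)) / 2.0
            changed = True
    missing = sorted(set(tree.nodes) - set(resolved))
    if missing:
        raise ValueError(
            "cannot resolve ages for nodes (no aged node on the path to "
            "root): " + ", ".join(missing)
        )
    return resolved


def ages_from_table(
    dated: Sequence[DatedEdge], ages: Dict[str, float], tree: SpeciesTree
) -> List[DatedEdge]:
    """Attach an age (Ma) to each dated edge via its emergence node."""
    node_ages = resolve_node_ages(tree, ages)
    for rec in dated:
        rec.age_ma = node_ages[rec.emergence]
    return list(dated)


def phylostratigraphy(
    node_label: str,
    filtered: Dict[str, SyntenyGraph],
    tree: SpeciesTree,
) -> PhylostratRecord:
    """Adjacency gains/retentions/losses/duplications at one internal node.

    lost counts parent edges whose two endpoint gene lineages both survive
    at this node yet no retained edge here descends from the parent edge —
    isolating adjacency loss from gene loss. duplicated counts edges fed by
    two or more child edges from within a single child level (paralogous
    adjacency copies merged during propagation).
    """
    node = tree.node(node_label)
    if node.is_leaf:
        raise ValueError("phylostratigraphy is defined for internal nodes")
    graph = filtered[node_label]

    gained = retained = duplicated = 0
    retained_parents = set()
    for edge in graph.edges.values():
        if edge.emergence == node_label:
            gained += 1
        pe = edge.parent_edge
        if pe is not None and pe.status == "retained":
            retained += 1
            retained_parents.add(pe.key)
        by_child: Dict[str, int] = {}
        for ce in edge.child_edges:
            by_child[ce.level] = by_child.get(ce.level, 0) + 1
        if any(n >= 2 for n in by_child.values()):
            duplicated += 1

    lost = 0
    if node.parent is not None:
        parent_graph = filtered[node.parent.label]
        for key in sorted(parent_graph.edges):
            pedge = parent_graph.edges[key]
            if pedge.status not in ("retained", "observed"):
                continue
            s1 = any(c.level == node_label for c in pedge.g1.children)
            s2 = any(c.level == node_label for c in pedge.g2.children)
            if s1 and s2 and key not in retained_parents:
                lost += 1
    return PhylostratRecord(node_label, gained, retained, lost, duplicated)


def find_adjacency_clusters(
    contigs: Sequence[LinearContig],
    qualifying: Callable[[Adjacency], bool],
    graph: SyntenyGraph,
    min_adjacencies: int = 5,
    max_gap: int = 10,
    contig_ids: Optional[Sequence[str]] = None,
) -> List[AdjacencyCluster]:
    """Runs of qualifying adjacencies along contigs.

    A cluster needs at least ``min_adjacencies`` qualifying adjacencies
    ("over four" with the default) and consecutive qualifying adjacencies
    separated by fewer than ``max_gap`` genes.
    """
    out: List[AdjacencyCluster] = []
    for ci, contig in enumerate(contigs):
        cid = contig_ids[ci] if contig_ids else f"ctg{ci + 1}"
        positions: List[int] = []
        pairs: List[Tuple[str, str]] = []
        for i in range(len(contig.genes) - 1):
            u, w = contig.genes[i].uid, contig.genes[i + 1].uid
            edge = graph.edge_between(u, w)
            if qualifying(edge):
                positions.append(i)
                pairs.append(edge.key)
        run: List[Tuple[str, str]] = []
        last_pos: Optional[int] = None
        for pos, pair in zip(positions, pairs):
            if last_pos is not None and (pos - last_pos - 1) >= max_gap:
                if len(run) >= min_adjacencies:
                    out.append(AdjacencyCluster(cid, run))
                run = []
            run.append(pair)
            last_pos = pos
        if len(run) >= min_adjacencies:
            out.append(AdjacencyCluster(cid, run))
    return out
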