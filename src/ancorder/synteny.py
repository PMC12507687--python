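"""Synteny graphs: extant construction, bottom-up adjacency propagation,
top-down parsimony filtering, linearization and orientation calls.

Phases operate on one :class:`SyntenyGraph` per tree node:

* bottom-up: each child edge whose two endpoint genes both have parents at
  the node is lifted onto the parent gene pair; weights (extant propagation
  counts) are summed when lifted edges coincide. Runs of parentless genes
  (gene gains) are bridged by a single edge between the parents of the two
  flanking parented genes. Copies of a duplicated gene merge at and above
  the duplication point, so do their edges.
* top-down: an edge is kept only where parsimony supports it — at least two
  supporting child subtrees, or a retained parent edge. Weights play no
  role in removal. Each maximal retained lineage is stamped with its
  root-most node of retention (the adjacency's emergence).
* linearization: genes with more than two neighbours keep the two with the
  heaviest linear paths; residual cycles are broken at their lightest edge.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .lineage import LineageForest
from .model import AncestralGene, ExtantGene
from .tree import SpeciesTree

__all__ = [
    "Adjacency",
    "SyntenyGraph",
    "LinearContig",
    "orientation_class",
    "build_extant_graph",
    "propagate_bottom_up",
    "filter_top_down",
    "linearize",
    "infer_orientation",
    "neighbor_path_weight",
]

log = logging.getLogger(__name__)

ORIENTATIONS = ("HT", "HH", "TT")  # head-to-tail, head-to-head, tail-to-tail


def orientation_class(strand_left: str, strand_right: str) -> str:
    """Relative-orientation class of two neighbouring genes.

    Computed from strands in left-to-right contig order; the class is
    invariant under reading the pair in the opposite direction, so it needs
    no further canonicalization.
    """
    if strand_left == strand_right:
        return "HT"
    return "HH" if strand_left == "+" else "TT"


class Adjacency:
    """A weighted, unordered gene pair at one tree level."""

    __slots__ = (
        "key", "g1", "g2", "level", "weight", "child_edges", "bridge_runs",
        "supporting_children", "parent_edge", "tally", "status", "emergence",
    )

    def __init__(self, g1: AncestralGene, g2: AncestralGene, level: str) -> None:
        if g1.uid == g2.uid:
            raise ValueError(f"self-adjacency on {g1.uid!r}")
        if g1.uid > g2.uid:
            g1, g2 = g2, g1
        self.key: Tuple[str, str] = (g1.uid, g2.uid)
        self.g1 = g1
        self.g2 = g2
        self.level = level
        self.weight = 0
        self.child_edges: List["Adjacency"] = []
        # (child label, run edge keys, weight contribution) per gain bridge
        self.bridge_runs: List[Tuple[str, Tuple[Tuple[str, str], ...], int]] = []
        self.supporting_children: Set[str] = set()
        self.parent_edge: Optional["Adjacency"] = None
        self.tally: Dict[str, int] = {}
        self.status = "propagated"  # observed|propagated|retained|removed
        self.emergence: Optional[str] = None

    def add_tally(self, cls: str, count: int = 1) -> None:
        self.tally[cls] = self.tally.get(cls, 0) + count

    def __repr__(self) -> str:  # pragma: no cover
        return f"Adjacency({self.key[0]}--{self.key[1]}, w={self.weight})"


class SyntenyGraph:
    """Genes and weighted adjacencies at one tree node."""

    def __init__(self, level: str, phase: str) -> None:
        self.level = level
        self.phase = phase  # extant|propagated|filtered|linearized
        self.genes: Dict[str, AncestralGene] = {}
        self.edges: Dict[Tuple[str, str], Adjacency] = {}
        self.nbr: Dict[str, Set[str]] = {}

    def add_gene(self, gene: AncestralGene) -> None:
        if gene.uid not in self.genes:
            self.genes[gene.uid] = gene
            self.nbr[gene.uid] = set()

    def get_or_make_edge(self, g1: AncestralGene, g2: AncestralGene) -> Adjacency:
        key = (g1.uid, g2.uid) if g1.uid < g2.uid else (g2.uid, g1.uid)
        edge = self.edges.get(key)
        if edge is None:
            edge = Adjacency(g1, g2, self.level)
            self.edges[key] = edge
            self.add_gene(g1)
            self.add_gene(g2)
            self.nbr[g1.uid].add(g2.uid)
            self.nbr[g2.uid].add(g1.uid)
        return edge

    def attach_edge(self, edge: Adjacency) -> None:
        self.edges[edge.key] = edge
        self.add_gene(edge.g1)
        self.add_gene(edge.g2)
        self.nbr[edge.key[0]].add(edge.key[1])
        self.nbr[edge.key[1]].add(edge.key[0])

    def remove_edge(self, key: Tuple[str, str]) -> None:
        del self.edges[key]
        self.nbr[key[0]].discard(key[1])
        self.nbr[key[1]].discard(key[0])

    def degree(self, uid: str) -> int:
        return len(self.nbr.get(uid, ()))

    def edge_between(self, u: str, v: str) -> Adjacency:
        return self.edges[(u, v) if u < v else (v, u)]

    def __len__(self) -> int:
        return len(self.edges)


class LinearContig:
    """An ordered, oriented path of genes (length >= 2)."""

    __slots__ = ("level", "genes", "orientations")

    def __init__(self, level: str, genes: List[AncestralGene],
                 orientations: List[str]) -> None:
        self.level = level
        self.genes = genes
        self.orientations = orientations

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# extant graphs


def build_extant_graph(
    species: str,
    genes_by_contig: Dict[str, List[ExtantGene]],
    lineage: LineageForest,
) -> SyntenyGraph:
    """Observed adjacency graph of one extant genome.

    Genes present in the GFF but unknown to the lineage forest raise; bind
    them first (HOG membership or singleton). Genes known to the lineage
    but absent here simply acquire no adjacencies.
    """
    graph = SyntenyGraph(species, phase="extant")
    for contig in sorted(genes_by_contig):
        genes = genes_by_contig[contig]
        nodes = []
        for g in genes:
            anc = lineage.extant_index.get(g.gene_id)
            if anc is None:
                raise ValueError(
                    f"{species}: gene {g.gene_id!r} has no lineage entry"
                )
            anc.extant = g
            nodes.append(anc)
            graph.add_gene(anc)
        for left, right, gl, gr in zip(nodes, nodes[1:], genes, genes[1:]):
            edge = graph.get_or_make_edge(left, right)
            edge.weight += 1
            edge.status = "observed"
            edge.add_tally(orientation_class(gl.strand, gr.strand))
    return graph


# ---------------------------------------------------------------------------
# bottom-up propagation


def _parent_at(gene: AncestralGene, level: str) -> Optional[AncestralGene]:
    p = gene.parent
    if p is not None and p.level == level:
        return p
    return None


def _bridge_runs(
    child_graph: SyntenyGraph, level: str
) -> List[Tuple[AncestralGene, AncestralGene, Tuple[Tuple[str, str], ...], int]]:
    """Find maximal runs of parentless genes flanked by parented genes.

    Returns (left parent gene, right parent gene, run edge keys, weight)
    tuples, where weight is the minimum edge weight along the run. Interior
    run genes must have degree exactly 2; runs reaching a contig end or a
    branching gene yield no bridge. Each run is reported once.
    """
    out = []
    seen: Set[frozenset] = set()
    for key in sorted(child_graph.edges):
        u, v = key
        gu, gv = child_graph.genes[u], child_graph.genes[v]
        pu, pv = _parent_at(gu, level), _parent_at(gv, level)
        if (pu is None) == (pv is None):
            continue  # need exactly one parented flank to start a walk
        if pu is not None:
            start, first = gu, gv
        else:
            start, first = gv, gu
        run_keys = [key]
        weights = [child_graph.edges[key].weight]
        prev, cur = start, first
        ok = False
        while True:
            if _parent_at(cur, level) is not None:
                ok = True
                break
            if child_graph.degree(cur.uid) != 2:
                break
            nxt_uid = next(
                iter(child_graph.nbr[cur.uid] - {prev.uid}), None
            )
            if nxt_uid is None or nxt_uid == start.uid:
                break  # dead end or cycle back to the start
            nxt = child_graph.genes[nxt_uid]
            ek = (cur.uid, nxt_uid) if cur.uid < nxt_uid else (nxt_uid, cur.uid)
            run_keys.append(ek)
            weights.append(child_graph.edges[ek].weight)
            prev, cur = cur, nxt
        if not ok:
            continue
        sig = frozenset((start.uid, cur.uid, run_keys[0], run_keys[-1]))
        if sig in seen:
            continue
        seen.add(sig)
        out.append(
            (
                _parent_at(start, level),
                _parent_at(cur, level),
                tuple(run_keys),
                min(weights),
            )
        )
    return out


def propagate_bottom_up(
    tree: SpeciesTree,
    lineage: LineageForest,
    extant_graphs: Dict[str, SyntenyGraph],
) -> Dict[str, SyntenyGraph]:
    """Propagate adjacencies leaf→root; returns graphs for every node.

    Leaf entries are the extant graphs passed in; every internal node gets
    a phase=``propagated`` graph.
    """
    graphs: Dict[str, SyntenyGraph] = dict(extant_graphs)
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in graphs:
                raise ValueError(f"no extant graph for leaf {node.label!r}")
            continue
        graph = SyntenyGraph(node.label, phase="propagated")
        for gene in lineage.genes_at[node.label].values():
            graph.add_gene(gene)
        for child in node.children:
            child_graph = graphs[child.label]
            for key in sorted(child_graph.edges):
                cedge = child_graph.edges[key]
                p1 = _parent_at(cedge.g1, node.label)
                p2 = _parent_at(cedge.g2, node.label)
                if p1 is None or p2 is None:
                    continue
                if p1.uid == p2.uid:
                    continue  # tandem copies merging into one parent gene
                edge = graph.get_or_make_edge(p1, p2)
                edge.weight += cedge.weight
                edge.child_edges.append(cedge)
                edge.supporting_children.add(child.label)
                for cls, n in cedge.tally.items():
                    edge.add_tally(cls, n)
                cedge.parent_edge = edge
            for pu, pv, run_keys, w in _bridge_runs(child_graph, node.label):
                if pu.uid == pv.uid:
                    continue
                edge = graph.get_or_make_edge(pu, pv)
                edge.weight += w
                edge.bridge_runs.append((child.label, run_keys, w))
                edge.supporting_children.add(child.label)
                if child_graph.phase == "extant":
                    # orientation from the strands of the flanking genes
                    flanks = []
                    for uid in (run_keys[0] + run_keys[-1]):
                        g = child_graph.genes[uid]
                        if _parent_at(g, node.label) is not None:
                            flanks.append(g)
                    if len(flanks) == 2 and all(
                        f.extant is not None for f in flanks
                    ) and flanks[0].extant.contig == flanks[1].extant.contig:
                        a, b = sorted(flanks, key=lambda f: f.extant.rank)
                        edge.add_tally(
                            orientation_class(a.extant.strand, b.extant.strand)
                        )
        graphs[node.label] = graph
    return graphs


# ---------------------------------------------------------------------------
# top-down filtering


def filter_top_down(
    graphs: Dict[str, SyntenyGraph], tree: SpeciesTree
) -> Dict[str, SyntenyGraph]:
    """Remove edges not supported by parsimony; stamp emergence labels.

    Root: keep iff >=2 supporting child subtrees. Elsewhere: keep iff >=2
    supporting children or the parent edge was kept. Edge weights are never
    consulted. Extant (leaf) edges are real observations: they are always
    kept and inherit the emergence of their retained parent lineage, or are
    stamped with the leaf itself.
    """
    filtered: Dict[str, SyntenyGraph] = {}
    for node in tree.preorder():
        graph = graphs[node.label]
        if node.is_leaf:
            for edge in graph.edges.values():
                pe = edge.parent_edge
                if pe is not None and pe.status == "retained":
                    edge.emergence = pe.emergence
                else:
                    edge.emergence = node.label
            filtered[node.label] = graph
            continue
        out = SyntenyGraph(node.label, phase="filtered")
        for gene in graph.genes.values():
            out.add_gene(gene)
        for key in sorted(graph.edges):
            edge = graph.edges[key]
            pe = edge.parent_edge
            parent_retained = (
                node.parent is not None
                and pe is not None
                and pe.status == "retained"
            )
            if len(edge.supporting_children) >= 2 or parent_retained:
                edge.status = "retained"
                edge.emergence = pe.emergence if parent_retained else node.label
                out.attach_edge(edge)
            else:
                edge.status = "removed"
        filtered[node.label] = out
    return filtered


def apply_prefilters(
    graph: SyntenyGraph,
    tree: SpeciesTree,
    min_weight: int = 0,
    min_completeness: float = 0.0,
) -> SyntenyGraph:
    """Optional confidence filters applied before linearization."""
    from .lineage import completeness_score

    out = SyntenyGraph(graph.level, phase=graph.phase)
    keep_gene: Dict[str, bool] = {}
    for uid, gene in graph.genes.items():
        ok = True
        if min_completeness > 0 and not gene.is_extant:
            ok = completeness_score(gene, tree) >= min_completeness
        keep_gene[uid] = ok
        if ok:
            out.add_gene(gene)
    for key in sorted(graph.edges):
        edge = graph.edges[key]
        if edge.weight < min_weight:
            continue
        if keep_gene[key[0]] and keep_gene[key[1]]:
            out.attach_edge(edge)
    return out


# ---------------------------------------------------------------------------
# linearization


def neighbor_path_weight(
    graph: SyntenyGraph, focal: str, neighbor: str
) -> int:
    """Sum of edge weights along the path through ``neighbor`` up to the
    first gene with a neighbour count other than two."""
    total = graph.edge_between(focal, neighbor).weight
    prev, cur = focal, neighbor
    while graph.degree(cur) == 2:
        nxt = next(iter(graph.nbr[cur] - {prev}))
        if nxt == focal:
            break  # closed a cycle
        total += graph.edge_between(cur, nxt).weight
        prev, cur = cur, nxt
    return total


def _conflict_order(graph: SyntenyGraph) -> List[str]:
    def sort_key(uid: str):
        weights = [graph.edge_between(uid, v).weight for v in graph.nbr[uid]]
        return (-max(weights), -sum(weights), uid)

    return sorted(
        (uid for uid in graph.genes if graph.degree(uid) > 2), key=sort_key
    )


def linearize(graph: SyntenyGraph) -> Tuple[SyntenyGraph, List[LinearContig]]:
    """Resolve conflicting genes, break cycles, emit linear contigs.

    Conflicting genes (degree > 2) are processed in decreasing order of
    their maximum incident edge weight (ties: total incident weight, then
    uid); each keeps the two neighbours with maximal linear path weight
    (ties: direct edge weight, then uid). Residual cycles lose their
    minimum-weight edge. Contigs of length >= 2 are emitted, singleton
    genes are not.
    """
    work = SyntenyGraph(graph.level, phase="linearized")
    for gene in graph.genes.values():
        work.add_gene(gene)
    for edge in graph.edges.values():
        work.attach_edge(edge)

    for uid in _conflict_order(graph):
        if work.degree(uid) <= 2:
            continue
        ranked = sorted(
            work.nbr[uid],
            key=lambda v: (
                -neighbor_path_weight(work, uid, v),
                -work.edge_between(uid, v).weight,
                v,
            ),
        )
        for v in ranked[2:]:
            work.remove_edge((uid, v) if uid < v else (v, uid))

    _break_cycles(work)
    contigs = _extract_contigs(work)
    return work, contigs


def _break_cycles(graph: SyntenyGraph) -> None:
    visited: Set[str] = set()
    for start in sorted(graph.genes):
        if start in visited or graph.degree(start) == 0:
            continue
        comp: List[str] = []
        stack = [start]
        visited.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in graph.nbr[u]:
                if v not in visited:
                    visited.add(v)
                    stack.append(v)
        n_edges = sum(graph.degree(u) for u in comp) // 2
        if n_edges == len(comp):  # simple cycle (all degrees are 2 here)
            worst = min(
                (
                    graph.edges[(u, v) if u < v else (v, u)]
                    for u in comp
                    for v in graph.nbr[u]
                    if u < v
                ),
                key=lambda e: (e.weight, e.key),
            )
            graph.remove_edge(worst.key)


def _extract_contigs(graph: SyntenyGraph) -> List[LinearContig]:
    contigs: List[LinearContig] = []
    visited: Set[str] = set()
    endpoints = sorted(
        uid for uid in graph.genes if graph.degree(uid) == 1
    )
    for start in endpoints:
        if start in visited:
            continue
        order = [start]
        visited.add(start)
        prev, cur = None, start
        while True:
            nxt = next(
                (v for v in sorted(graph.nbr[cur]) if v != prev), None
            )
            if nxt is None or nxt in visited:
                break
            order.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        genes = [graph.genes[u] for u in order]
        contigs.append(
            LinearContig(graph.level, genes, _orient_contig(graph, order))
        )
    return contigs


def _orient_contig(graph: SyntenyGraph, order: Sequence[str]) -> List[str]:
    # left end anchored to "+"; HT keeps the strand, HH/TT flips it, an
    # unknown class marks the next gene unknown and re-anchors the carrier
    orientations = ["+"]
    carrier = "+"
    for u, v in zip(order, order[1:]):
        cls = infer_orientation(graph.edge_between(u, v))
        if cls == "unknown":
            orientations.append("unknown")
        else:
            if cls in ("HH", "TT"):
                carrier = "-" if carrier == "+" else "+"
            orientations.append(carrier)
    return orientations


def infer_orientation(edge: Adjacency) -> str:
    """Majority orientation class of the propagation tally; ties → unknown."""
    if not edge.tally:
        return "unknown"
    best = max(edge.tally.values())
    winners = [cls for cls in ORIENTATIONS if edge.tally.get(cls, 0) == best]
    return winners[0] if len(winners) == 1 else "unknown"
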