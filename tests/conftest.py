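from typing import Dict, List

import pytest

from ancorder.lineage import LineageForest, build_gene_lineage
from ancorder.model import ExtantGene, HOGForest, HOGGroup
from ancorder.synteny import (
    SyntenyGraph,
    build_extant_graph,
    filter_top_down,
    propagate_bottom_up,
)
from ancorder.tree import SpeciesTree, read_species_tree


def contig_genes(
    species: str, order, contig: str = "c1"
) -> List[ExtantGene]:
    """Build ranked genes from ``order``: ids or (id, strand) tuples."""
    genes = []
    for i, item in enumerate(order):
        gid, strand = item if isinstance(item, tuple) else (item, "+")
        genes.append(
            ExtantGene(gid, species, contig, 1000 * i + 1, 1000 * i + 500,
                       strand, rank=i)
        )
    return genes


def make_genomes(layout: Dict[str, Dict[str, list]]):
    """{species: {contig: order}} → {species: {contig: [ExtantGene]}}."""
    return {
        sp: {c: contig_genes(sp, order, c) for c, order in contigs.items()}
        for sp, contigs in layout.items()
    }


@pytest.fixture
def toy_tree() -> SpeciesTree:
    return read_species_tree("((S1,S2)A12,S3)R;")


class WorkedExample:
    """The 3-species worked case: single-copy families A, B, C; B lost in
    S3; S1 = a-b-c, S2 = a-b-c, S3 = a-c."""

    def __init__(self) -> None:
        self.tree = read_species_tree("((S1,S2)A12,S3)R;")
        self.forest = HOGForest(
            roots=[
                HOGGroup(level="R", children=["a1", "a2", "a3"],
                         family_id="A"),
                HOGGroup(level="R", children=["b1", "b2"], family_id="B"),
                HOGGroup(level="R", children=["c1", "c2", "c3"],
                         family_id="C"),
            ],
            gene_species={
                "a1": "S1", "b1": "S1", "c1": "S1",
                "a2": "S2", "b2": "S2", "c2": "S2",
                "a3": "S3", "c3": "S3",
            },
        )
        self.lineage = build_gene_lineage(self.forest, self.tree)
        genomes = make_genomes({
            "S1": {"c1": ["a1", "b1", "c1"]},
            "S2": {"c1": ["a2", "b2", "c2"]},
            "S3": {"c1": ["a3", "c3"]},
        })
        self.extant = {
            sp: build_extant_graph(sp, genomes[sp], self.lineage)
            for sp in genomes
        }
        self.propagated = propagate_bottom_up(
            self.tree, self.lineage, self.extant
        )
        self.filtered = filter_top_down(self.propagated, self.tree)


@pytest.fixture
def worked() -> WorkedExample:
    return WorkedExample()


def assert_linear(graph: SyntenyGraph) -> None:
    """Degree <= 2 everywhere and no cycles (per-component edge count)."""
    for uid in graph.genes:
        assert graph.degree(uid) <= 2, uid
    visited = set()
    for start in graph.genes:
        if start in visited:
            continue
        comp = []
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
        assert n_edges <= len(comp) - 1, f"cycle in component of {start}"
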