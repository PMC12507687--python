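"""TSV inputs/outputs: age tables and ancestral genome writers."""

from __future__ import annotations

import os
from typing import Dict, List, TYPE_CHECKING

from ..tree import SpeciesTree

if TYPE_CHECKING:  # pragma: no cover
    from ..synteny import LinearContig, SyntenyGraph

__all__ = ["read_age_table", "write_ancestral_genome"]

ADJACENCY_HEADER = ("gene1", "gene2", "weight", "orientation_class",
                    "lca_label", "contig_id")
CONTIG_HEADER = ("contig_id", "n_genes", "genes", "orientations")


def read_age_table(text: str, tree: SpeciesTree) -> Dict[str, float]:
    """Parse a two-column (node label, age in Ma) TSV into a mapping.

    Validates that labels are tree nodes, ages are non-negative, and that a
    child is never older than its parent when both are present.
    """
    ages: Dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"age table line {lineno}: expected 2 columns")
        label, raw = parts[0], parts[1]
        if label not in tree.nodes:
            raise ValueError(f"age table line {lineno}: unknown node {label!r}")
        age = float(raw)
        if age < 0:
            raise ValueError(f"age table line {lineno}: negative age {age}")
        ages[label] = age
    for label, age in ages.items():
        node = tree.node(label).parent
        while node is not None:
            if node.label in ages and ages[node.label] < age:
                raise ValueError(
                    f"age table: {label} ({age} Ma) older than ancestor "
                    f"{node.label} ({ages[node.label]} Ma)"
                )
            node = node.parent
    return ages


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in label)


def write_ancestral_genome(
    node_label: str,
    graph: "SyntenyGraph",
    contigs: List["LinearContig"],
    out_dir: str,
) -> List[str]:
    """Write the per-node adjacency and contig TSVs; returns file paths.

    Rows are ordered deterministically: contigs by id, adjacencies by the
    sorted (gene1, gene2) pair. Edges dropped during linearization are not
    listed; singleton genes are excluded from the contig table.
    """
    os.makedirs(out_dir, exist_ok=True)
    base = _safe(node_label)
    adj_path = os.path.join(out_dir, f"{base}_adjacencies.tsv")
    contig_path = os.path.join(out_dir, f"{base}_contigs.tsv")

    contig_of: Dict[str, str] = {}
    for i, contig in enumerate(contigs):
        cid = f"{base}_ctg{i + 1}"
        for g in contig.genes:
            contig_of[g.uid] = cid

    from ..synteny import infer_orientation  # local import to avoid cycle

    rows = []
    for key in sorted(graph.edges):
        edge = graph.edges[key]
        rows.append((
            key[0], key[1], str(edge.weight), infer_orientation(edge),
            edge.emergence or "", contig_of.get(key[0], ""),
        ))
    with open(adj_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ADJACENCY_HEADER) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    with open(contig_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CONTIG_HEADER) + "\n")
        for i, contig in enumerate(contigs):
            cid = f"{base}_ctg{i + 1}"
            fh.write("\t".join([
                cid,
                str(len(contig.genes)),
                ",".join(g.uid for g in contig.genes),
                ",".join(contig.orientations),
            ]) + "\n")
    return [adj_path, contig_path]
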