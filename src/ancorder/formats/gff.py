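"""GFF3 reading: extract ordered gene lists per contig."""

from __future__ import annotations

import logging
from typing import Dict, List

from gffutils.iterators import DataIterator

from ..model import ExtantGene

__all__ = ["read_gff"]

log = logging.getLogger(__name__)


def read_gff(
    gff3_text: str,
    species: str,
    feature_type: str = "gene",
    id_attribute: str = "ID",
    id_map: Dict[str, str] | None = None,
) -> Dict[str, List[ExtantGene]]:
    """Parse GFF3 text into ranked gene lists, one per contig.

    Features of ``feature_type`` are selected; each must carry
    ``id_attribute`` (records without it are skipped with a warning).
    Genes are grouped by seqid and sorted by (start, end, gene_id); ranks
    are 0-based and consecutive within each contig. ``id_map`` optionally
    translates GFF identifiers to the identifiers used by the orthology
    input.

    Raises ``ValueError`` when no feature is selected at all.
    """
    by_contig: Dict[str, List[ExtantGene]] = {}
    n_selected = 0
    for feat in DataIterator(gff3_text, from_string=True):
        if feat.featuretype != feature_type:
            continue
        n_selected += 1
        ids = feat.attributes.get(id_attribute)
        if not ids or not ids[0]:
            log.warning(
                "%s: %s feature at %s:%s-%s lacks %r attribute; skipped",
                species, feature_type, feat.seqid, feat.start, feat.end,
                id_attribute,
            )
            continue
        gene_id = ids[0]
        if id_map is not None:
            gene_id = id_map.get(gene_id, gene_id)
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        if feat.strand not in ("+", "-"):
            log.warning("%s: gene %s has strand %r; defaulting to '+'",
                        species, gene_id, feat.strand)
        by_contig.setdefault(feat.seqid, []).append(
            ExtantGene(
                gene_id=gene_id,
                species=species,
                contig=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=strand,
            )
        )
    if n_selected == 0:
        raise ValueError(
            f"{species}: no {feature_type!r} feature found in GFF3 input"
        )

    seen: Dict[str, str] = {}
    for contig in sorted(by_contig):
        genes = by_contig[contig]
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for rank, gene in enumerate(genes):
            gene.rank = rank
            if gene.gene_id in seen:
                raise ValueError(
                    f"{species}: duplicate gene id {gene.gene_id!r} "
                    f"(contigs {seen[gene.gene_id]} and {contig})"
                )
            seen[gene.gene_id] = contig
    return {c: by_contig[c] for c in sorted(by_contig)}


def write_gff(genes_by_contig: Dict[str, List[ExtantGene]]) -> str:
    """Serialize ranked genes back to GFF3 text (used by the simulator)."""
    lines = ["##gff-version 3"]
    for contig in sorted(genes_by_contig):
        for g in genes_by_contig[contig]:
            lines.append(
                "\t".join(
                    [
                        contig,
                        "ancorder",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"
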