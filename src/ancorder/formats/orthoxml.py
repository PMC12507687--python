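"""OrthoXML reading/writing of hierarchical orthologous groups.

Only the structural content is consumed: species/gene declarations,
orthologGroup/paralogGroup nesting and the per-group taxonomic level
(``TaxRange`` property when present, MRCA of member species otherwise).
Scores and other annotations are ignored.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Dict, List, Union

from ..model import HOGForest, HOGGroup
from ..tree import SpeciesTree

__all__ = ["read_orthoxml", "write_orthoxml"]

NS = "http://orthoXML.org/2011/"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_orthoxml(xml_text: str, tree: SpeciesTree) -> HOGForest:
    """Parse OrthoXML into a :class:`HOGForest` validated against ``tree``.

    Gene references must point at declared genes; declared species must all
    be leaves of the species tree. Explicit ``TaxRange`` levels must be
    known tree labels.
    """
    root = ET.fromstring(xml_text)

    gene_species: Dict[str, str] = {}
    internal_to_prot: Dict[str, str] = {}
    bad_species: List[str] = []
    for sp in root.iter():
        if _local(sp.tag) != "species":
            continue
        name = sp.get("name")
        if name not in tree.nodes or not tree.node(name).is_leaf:
            bad_species.append(str(name))
            continue
        for gene in sp.iter():
            if _local(gene.tag) != "gene":
                continue
            prot = gene.get("protId") or gene.get("geneId") or gene.get("id")
            internal_to_prot[gene.get("id")] = prot
            if prot in gene_species:
                raise ValueError(
                    f"gene id {prot!r} declared for both "
                    f"{gene_species[prot]} and {name}"
                )
            gene_species[prot] = name
    if bad_species:
        raise ValueError(
            "species absent from tree: " + ", ".join(sorted(bad_species))
        )

    def parse_group(elem, family_id: str) -> HOGGroup:
        group = HOGGroup(
            is_paralog=_local(elem.tag) == "paralogGroup",
            family_id=family_id,
        )
        for child in elem:
            tag = _local(child.tag)
            if tag == "property":
                if child.get("name") in ("TaxRange", "TaxId", "Level"):
                    level = child.get("value")
                    if child.get("name") == "TaxRange":
                        if level not in tree.nodes:
                            raise ValueError(
                                f"group level {level!r} is not a tree node"
                            )
                        group.level = level
            elif tag in ("orthologGroup", "paralogGroup"):
                group.children.append(parse_group(child, family_id))
            elif tag == "geneRef":
                ref = child.get("id")
                prot = internal_to_prot.get(ref)
                if prot is None:
                    raise ValueError(f"geneRef {ref!r} is not a declared gene")
                group.children.append(prot)
        return group

    roots: List[HOGGroup] = []
    seen_genes: Dict[str, str] = {}
    for groups in root.iter():
        if _local(groups.tag) != "groups":
            continue
        for idx, elem in enumerate(groups):
            if _local(elem.tag) not in ("orthologGroup", "paralogGroup"):
                continue
            family_id = elem.get("id") or f"HOG{idx + 1:06d}"
            g = parse_group(elem, family_id)
            g.family_id = family_id
            for uid in g.member_genes():
                if uid in seen_genes:
                    raise ValueError(
                        f"gene {uid!r} appears in two root groups "
                        f"({seen_genes[uid]} and {family_id})"
                    )
                seen_genes[uid] = family_id
            roots.append(g)
    return HOGForest(roots=roots, gene_species=gene_species)


def resolve_level(group: HOGGroup, forest: HOGForest, tree: SpeciesTree) -> str:
    """Explicit level if declared, else the MRCA of member species."""
    if group.level is not None:
        return group.level
    species = {forest.gene_species[g] for g in group.member_genes()}
    return tree.mrca(sorted(species))


def write_orthoxml(forest: HOGForest) -> str:
    """Serialize a :class:`HOGForest` to OrthoXML text.

    Gene declarations are grouped per species; internal numeric gene ids
    are assigned deterministically in sorted (species, protId) order.
    """
    root = ET.Element("orthoXML", {
        "xmlns": NS, "version": "0.3", "origin": "ancorder", "originVersion": "1",
    })
    prot_to_internal: Dict[str, str] = {}
    by_species: Dict[str, List[str]] = {}
    for uid, sp in forest.gene_species.items():
        by_species.setdefault(sp, []).append(uid)
    counter = 1
    for sp in sorted(by_species):
        sp_el = ET.SubElement(root, "species", {"name": sp, "NCBITaxId": "0"})
        db_el = ET.SubElement(sp_el, "database", {"name": "sim", "version": "1"})
        genes_el = ET.SubElement(db_el, "genes")
        for uid in sorted(by_species[sp]):
            internal = str(counter)
            counter += 1
            prot_to_internal[uid] = internal
            ET.SubElement(genes_el, "gene", {"id": internal, "protId": uid})

    groups_el = ET.SubElement(root, "groups")

    def emit(group: Union[HOGGroup, str], parent_el, family_id: str) -> None:
        if isinstance(group, str):
            ET.SubElement(parent_el, "geneRef", {"id": prot_to_internal[group]})
            return
        tag = "paralogGroup" if group.is_paralog else "orthologGroup"
        attrs = {}
        if parent_el is groups_el:
            attrs["id"] = family_id
        el = ET.SubElement(parent_el, tag, attrs)
        if group.level is not None and not group.is_paralog:
            ET.SubElement(
                el, "property", {"name": "TaxRange", "value": group.level}
            )
        for child in group.children:
            emit(child, el, family_id)

    for g in forest.roots:
        emit(g, groups_el, g.family_id or "")

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"
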