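"""Shared domain types: extant genes, HOG groups, ancestral genes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

__all__ = ["ExtantGene", "HOGGroup", "HOGForest", "AncestralGene"]


@dataclass(eq=False)  # identity semantics: instances live in sets/graphs
class ExtantGene:
    """A gene with coordinates on an extant contig.

    ``start``/``end`` are 1-based inclusive bp; ``rank`` is the 0-based
    position within its contig after sorting by (start, end, gene_id).
    """

    gene_id: str
    species: str
    contig: str
    start: int
    end: int
    strand: str  # "+" or "-"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class HOGGroup:
    """A (possibly nested) orthologous group node.

    ``children`` holds nested :class:`HOGGroup` instances and/or extant gene
    ids (strings). ``level`` is an explicit tree-node label when declared in
    the input, otherwise ``None`` (resolved later as the MRCA of member
    species). ``is_paralog`` marks duplication nodes.
    """

    level: Optional[str] = None
    children: List[Union["HOGGroup", str]] = field(default_factory=list)
    is_paralog: bool = False
    family_id: Optional[str] = None

    def member_genes(self) -> List[str]:
        out: List[str] = []
        stack: List[Union[HOGGroup, str]] = [self]
        while stack:
            item = stack.pop()
            if isinstance(item, str):
                out.append(item)
            else:
                stack.extend(reversed(item.children))
        return out


@dataclass
class HOGForest:
    """All HOG root groups plus the gene→species declaration map."""

    roots: List[HOGGroup]
    gene_species: Dict[str, str]

    def species(self) -> set:
        return set(self.gene_species.values())


class AncestralGene:
    """A gene at one tree node, linked to its parent gene one node up.

    Lineage links never skip tree nodes: ``parent.level`` is always the
    parent tree node of ``level``. ``via_duplication`` flags the link to the
    parent when the parent has two or more child genes at the same level.
    Leaf-level instances may carry the matching :class:`ExtantGene` in
    ``extant`` once coordinates are bound.
    """

    __slots__ = (
        "uid",
        "family_id",
        "level",
        "parent",
        "children",
        "via_duplication",
        "extant",
        "species",
    )

    def __init__(
        self,
        uid: str,
        family_id: str,
        level: str,
        parent: Optional["AncestralGene"] = None,
        species: Optional[str] = None,
    ) -> None:
        self.uid = uid
        self.family_id = family_id
        self.level = level
        self.parent = parent
        self.children: List["AncestralGene"] = []
        self.via_duplication = False
        self.extant: Optional[ExtantGene] = None
        self.species = species  # set for leaf-level genes
        if parent is not None:
            parent.children.append(self)

    @property
    def is_extant(self) -> bool:
        return self.species is not None

    def __repr__(self) -> str:  # pragma: no cover
        return f"AncestralGene({self.uid!r}@{self.level!r})"
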