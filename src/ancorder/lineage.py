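"""Gene-lineage graph: ancestral gene content per tree node.

Each HOG root group becomes a family of :class:`AncestralGene` nodes, one
per tree node the family crosses, linked child→parent one tree level at a
time. Implicit intermediate levels are materialized: a family observed at a
level and next at a grandchild level gets genes at every intervening node,
except in clades where the HOG has no members at all (interpreted as loss).
"""

from __future__ import annotations

import logging
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Union

from .formats.orthoxml import resolve_level
from .model import AncestralGene, ExtantGene, HOGForest, HOGGroup
from .tree import SpeciesTree

__all__ = [
    "LineageForest",
    "build_gene_lineage",
    "completeness_score",
    "descendant_genes",
]

log = logging.getLogger(__name__)


class LineageForest:
    """Per-tree-node ancestral gene sets plus family/extant indexes."""

    def __init__(self, tree: SpeciesTree) -> None:
        self.tree = tree
        self.genes_at: Dict[str, Dict[str, AncestralGene]] = {
            label: {} for label in tree.nodes
        }
        self.extant_index: Dict[str, AncestralGene] = {}
        self._family_counts: Dict[tuple, int] = {}
        self._descendant_cache: Optional[Dict[str, FrozenSet[str]]] = None

    # -- construction ----------------------------------------------------

    def new_internal(
        self, family_id: str, level: str, parent: Optional[AncestralGene]
    ) -> AncestralGene:
        n = self._family_counts.get((family_id, level), 0) + 1
        self._family_counts[(family_id, level)] = n
        uid = f"{family_id}@{level}" if n == 1 else f"{family_id}@{level}#{n}"
        gene = AncestralGene(uid, family_id, level, parent=parent)
        self.genes_at[level][uid] = gene
        self._descendant_cache = None
        return gene

    def new_leaf(
        self,
        uid: str,
        family_id: str,
        species: str,
        parent: Optional[AncestralGene],
    ) -> AncestralGene:
        if uid in self.extant_index:
            raise ValueError(f"extant gene {uid!r} bound twice")
        gene = AncestralGene(uid, family_id, species, parent=parent,
                             species=species)
        self.genes_at[species][uid] = gene
        self.extant_index[uid] = gene
        self._descendant_cache = None
        return gene

    def add_singleton(self, uid: str, species: str) -> AncestralGene:
        """Species-specific single-gene family (gene not in any HOG)."""
        return self.new_leaf(uid, f"SG_{uid}", species, parent=None)

    # -- queries ---------------------------------------------------------

    def genes(self) -> Iterable[AncestralGene]:
        for label in self.genes_at:
            yield from self.genes_at[label].values()

    def descendant_extant(self) -> Dict[str, FrozenSet[str]]:
        """uid → frozenset of descendant extant gene uids (postorder DP)."""
        if self._descendant_cache is None:
            sets: Dict[str, FrozenSet[str]] = {}
            for node in self.tree.postorder():
                for gene in self.genes_at[node.label].values():
                    if gene.is_extant:
                        sets[gene.uid] = frozenset((gene.uid,))
                    else:
                        acc: Set[str] = set()
                        for child in gene.children:
                            acc.update(sets[child.uid])
                        sets[gene.uid] = frozenset(acc)
            self._descendant_cache = sets
        return self._descendant_cache


def _flag_duplications(lineage: LineageForest) -> None:
    # >=2 children of one parent at the same child level => duplication links
    for gene in lineage.genes():
        by_level: Dict[str, List[AncestralGene]] = {}
        for child in gene.children:
            by_level.setdefault(child.level, []).append(child)
        for level_children in by_level.values():
            if len(level_children) >= 2:
                for child in level_children:
                    child.via_duplication = True


class _Builder:
    def __init__(self, forest: HOGForest, tree: SpeciesTree) -> None:
        self.forest = forest
        self.tree = tree
        self.lineage = LineageForest(tree)
        # implicit chain genes shared per (parent gene, level)
        self._implicit: Dict[tuple, AncestralGene] = {}

    def build(self) -> LineageForest:
        covered: Set[str] = set()
        for root in self.forest.roots:
            self._build_family(root)
            covered.update(root.member_genes())
        for uid in self.forest.gene_species:
            if uid not in covered:
                self.lineage.add_singleton(uid, self.forest.gene_species[uid])
        _flag_duplications(self.lineage)
        return self.lineage

    # helpers ------------------------------------------------------------

    def _level_of(self, item: Union[HOGGroup, str]) -> str:
        if isinstance(item, str):
            return self.forest.gene_species[item]
        return resolve_level(item, self.forest, self.tree)

    def _check_path(self, anc: str, desc: str, family_id: str) -> List[str]:
        try:
            return self.tree.path_down(anc, desc)
        except Exception:
            raise ValueError(
                f"family {family_id}: level {desc!r} is not within the "
                f"clade of its enclosing group level {anc!r}"
            ) from None

    def _implicit_chain(
        self, owner: AncestralGene, labels: List[str], family_id: str
    ) -> AncestralGene:
        """Walk/extend the shared implicit gene chain below ``owner``."""
        g = owner
        for label in labels:
            key = (id(g), label)
            nxt = self._implicit.get(key)
            if nxt is None:
                nxt = self.lineage.new_internal(family_id, label, g)
                self._implicit[key] = nxt
            g = nxt
        return g

    def _build_family(self, root: HOGGroup) -> None:
        fam = root.family_id or "HOG?"
        level = self._level_of(root)
        if self.tree.node(level).is_leaf:
            # family confined to one species: leaf genes only
            for uid in root.member_genes():
                self.lineage.new_leaf(uid, fam, level, parent=None)
            return
        gene = self.lineage.new_internal(fam, level, parent=None)
        for child in root.children:
            self._attach(child, gene, fam)

    def _attach(
        self,
        item: Union[HOGGroup, str],
        owner: AncestralGene,
        fam: str,
        dup_context: bool = False,
    ) -> None:
        if isinstance(item, str):
            species = self.forest.gene_species[item]
            path = self._check_path(owner.level, species, fam)
            anchor = self._implicit_chain(owner, path[:-1], fam)
            self.lineage.new_leaf(item, fam, species, parent=anchor)
            return

        if item.is_paralog:
            for sub in item.children:
                self._attach(sub, owner, fam, dup_context=True)
            return

        level = self._level_of(item)
        if level == owner.level:
            if dup_context:
                self._attach_same_level_copy(item, owner, fam)
            else:
                for sub in item.children:  # redundant nesting: collapse
                    self._attach(sub, owner, fam)
            return

        path = self._check_path(owner.level, level, fam)
        if self.tree.node(level).is_leaf:
            # in-paralogs within one species: anchor above the leaf,
            # then hang each member extant gene off the anchor
            anchor = self._implicit_chain(owner, path[:-1], fam)
            for uid in item.member_genes():
                self.lineage.new_leaf(uid, fam, level, parent=anchor)
            return

        gene = owner
        for label in path:
            gene = self.lineage.new_internal(fam, label, gene)
        for sub in item.children:
            self._attach(sub, gene, fam)

    def _attach_same_level_copy(
        self, item: HOGGroup, owner: AncestralGene, fam: str
    ) -> None:
        # A duplication child whose level equals the enclosing level: place
        # the copy's genes one tree level down, split per child clade.
        copies: Dict[str, AncestralGene] = {}
        for sub in item.children:
            sub_level = self._level_of(sub)
            if sub_level == owner.level:
                self._attach(sub, owner, fam, dup_context=True)
                continue
            step = self._check_path(owner.level, sub_level, fam)[0]
            if self.tree.node(step).is_leaf and isinstance(sub, str):
                self._attach(sub, owner, fam)
                continue
            copy = copies.get(step)
            if copy is None:
                copy = copies[step] = self.lineage.new_internal(
                    fam, step, owner
                )
            if sub_level == step:
                if isinstance(sub, HOGGroup):
                    for s2 in sub.children:
                        self._attach(s2, copy, fam)
                else:
                    self._attach(sub, copy, fam)
            else:
                self._attach(sub, copy, fam)


def build_gene_lineage(forest: HOGForest, tree: SpeciesTree) -> LineageForest:
    """Materialize the gene-lineage graph implied by HOG nesting."""
    return _Builder(forest, tree).build()


def descendant_genes(
    gene: AncestralGene, species: str
) -> Set[ExtantGene]:
    """Extant genes of ``species`` reachable from ``gene`` via child links.

    Returns the empty set when ``species`` is not under ``gene.level``.
    """
    out: Set[ExtantGene] = set()
    stack = [gene]
    while stack:
        g = stack.pop()
        if g.is_extant:
            if g.species == species and g.extant is not None:
                out.add(g.extant)
        else:
            stack.extend(g.children)
    return out


def descendant_species(gene: AncestralGene) -> Set[str]:
    out: Set[str] = set()
    stack = [gene]
    while stack:
        g = stack.pop()
        if g.is_extant:
            out.add(g.species)
        else:
            stack.extend(g.children)
    return out


def completeness_score(gene: AncestralGene, tree: SpeciesTree) -> float:
    """Fraction of the clade's species with at least one descendant gene."""
    clade = tree.leaf_set(gene.level)
    if not clade:
        return 0.0
    present = descendant_species(gene) & clade
    return len(present) / len(clade)
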