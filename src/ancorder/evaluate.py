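"""Evaluation protocol: map inferred ancestral genes to truth by maximal
shared extant descendants, score precision/recall per level, aggregate
with harmonic means, and project ancestral adjacencies into masked
genomes."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .lineage import LineageForest, descendant_genes
from .synteny import SyntenyGraph

__all__ = [
    "PRRecord",
    "map_ancestral_genes",
    "precision_recall",
    "harmonic_mean",
    "project_to_masked",
]

log = logging.getLogger(__name__)

DescSets = Dict[str, FrozenSet[str]]
Pair = FrozenSet[str]


@dataclass
class PRRecord:
    level: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        """Percent; None (reported as NA) when nothing was predicted."""
        total = self.tp + self.fp
        return None if total == 0 else 100.0 * self.tp / total

    @property
    def recall(self) -> Optional[float]:
        total = self.tp + self.fn
        return None if total == 0 else 100.0 * self.tp / total


def map_ancestral_genes(
    inferred: DescSets, true: DescSets
) -> Dict[str, str]:
    """Greedy maximal-overlap assignment of inferred → true genes.

    Pairs are ranked by descending overlap of extant descendant sets, ties
    broken by (inferred uid, true uid); each side is used at most once;
    zero overlap never maps.
    """
    by_extant: Dict[str, List[str]] = {}
    for tuid, members in true.items():
        for ext in members:
            by_extant.setdefault(ext, []).append(tuid)

    candidates: List[Tuple[int, str, str]] = []
    for iuid, members in inferred.items():
        overlap: Dict[str, int] = {}
        for ext in members:
            for tuid in by_extant.get(ext, ()):
                overlap[tuid] = overlap.get(tuid, 0) + 1
        for tuid, n in overlap.items():
            candidates.append((n, iuid, tuid))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    mapping: Dict[str, str] = {}
    used_true: Set[str] = set()
    for _n, iuid, tuid in candidates:
        if iuid in mapping or tuid in used_true:
            continue
        mapping[iuid] = tuid
        used_true.add(tuid)
    return mapping


def precision_recall(
    level: str,
    inferred_pairs: Iterable[Pair],
    true_pairs: Set[Pair],
    mapping: Dict[str, str],
) -> PRRecord:
    """Score inferred adjacencies against truth under a gene mapping.

    An inferred pair is a true positive iff both endpoints map and the
    mapped pair is a true adjacency; otherwise a false positive. False
    negatives are true adjacencies hit by no inferred pair.
    """
    tp = fp = 0
    hit: Set[Pair] = set()
    for pair in inferred_pairs:
        a, b = sorted(pair)
        ta, tb = mapping.get(a), mapping.get(b)
        if ta is not None and tb is not None:
            mapped = frozenset((ta, tb))
            if mapped in true_pairs:
                tp += 1
                hit.add(mapped)
                continue
        fp += 1
    fn = len(true_pairs - hit)
    return PRRecord(level, tp, fp, fn)


def harmonic_mean(values: Sequence[float]) -> float:
    """n / sum(1/v) over percentages; any zero yields 0 with a warning."""
    values = list(values)
    if not values:
        raise ValueError("harmonic mean of empty sequence")
    if any(v == 0 for v in values):
        log.warning("harmonic_mean: zero value present; result is 0")
        return 0.0
    return len(values) / sum(1.0 / v for v in values)


def project_to_masked(
    ancestor_graph: SyntenyGraph,
    masked_species: str,
    lineage: LineageForest,
) -> Set[Pair]:
    """Predict extant adjacencies of a masked genome from its direct
    ancestor: an ancestral edge projects iff both endpoint genes have
    exactly one descendant gene in the masked species."""
    out: Set[Pair] = set()
    for edge in ancestor_graph.edges.values():
        d1 = descendant_genes(edge.g1, masked_species)
        d2 = descendant_genes(edge.g2, masked_species)
        if len(d1) == 1 and len(d2) == 1:
            g1, g2 = next(iter(d1)), next(iter(d2))
            if g1.gene_id != g2.gene_id:
                out.add(frozenset((g1.gene_id, g2.gene_id)))
    return out
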