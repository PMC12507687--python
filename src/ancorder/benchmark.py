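"""Benchmark harness: score an inference run against simulated truth.

Two entry points: :func:`evaluate_inference` scores in-memory objects
(fast path used by the acceptance report), :func:`score_against_truth`
re-reads everything from a simulation directory and an inference output
directory (used by the ``evaluate`` CLI subcommand).
"""

from __future__ import annotations

import logging
import os
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .evaluate import PRRecord, harmonic_mean, map_ancestral_genes, precision_recall
from .formats import read_gff, read_orthoxml, read_species_tree
from .lineage import LineageForest, build_gene_lineage
from .simulate import SimulationTruth
from .tree import SpeciesTree

log = logging.getLogger(__name__)

Pair = FrozenSet[str]


def run_simulated_benchmark(
    seed: int = 1,
    n_leaves: int = 100,
    root_genes: int = 1000,
    preset_name: str = "low",
    workdir: Optional[str] = None,
):
    """Simulate, write inputs, infer end-to-end from files, score.

    Returns ``(records, harmonic_precision, harmonic_recall, truth,
    result)``. The inference consumes the written newick/GFF3/OrthoXML
    files, exercising the whole pipeline including parsing.
    """
    import tempfile

    from .cli import RunConfig, run_infer
    from .simulate import preset, simulate_evolution, write_truth

    params = preset(
        preset_name, n_leaves=n_leaves, root_genes=root_genes, seed=seed
    )
    truth = simulate_evolution(params)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        paths = write_truth(truth, tmp)
        config = RunConfig(
            tree_path=paths["tree"],
            gff_dir=paths["gff_dir"],
            orthoxml_path=paths["orthoxml"],
        )
        result = run_infer(config)
    records, hp, hr = evaluate_inference(truth, result)
    return records, hp, hr, truth, result


def _level_desc_sets(
    lineage: LineageForest, level: str
) -> Dict[str, FrozenSet[str]]:
    all_sets = lineage.descendant_extant()
    return {
        uid: all_sets[uid]
        for uid, gene in lineage.genes_at[level].items()
        if not gene.is_extant
    }


def _summarize(
    records: List[PRRecord],
) -> Tuple[float, float]:
    precisions = [r.precision for r in records if r.precision is not None]
    recalls = [r.recall for r in records if r.recall is not None]
    n_na = len(records) - len(precisions)
    if n_na:
        log.warning("%d levels with no predictions excluded from the "
                    "precision harmonic mean", n_na)
    hp = harmonic_mean(precisions) if precisions else 0.0
    hr = harmonic_mean(recalls) if recalls else 0.0
    return hp, hr


def evaluate_inference(
    truth: SimulationTruth, result
) -> Tuple[List[PRRecord], float, float]:
    """Per-internal-node precision/recall of ``result`` against ``truth``.

    Inferred ancestral genes are mapped to true genes per level by maximal
    shared extant descendants; inferred adjacencies are the linearized
    contig adjacencies.
    """
    true_desc = truth.descendant_extant()
    records: List[PRRecord] = []
    for node in truth.tree.internal_nodes():
        level = node.label
        inferred_sets = _level_desc_sets(result.lineage, level)
        true_sets = {
            uid: true_desc[uid]
            for uid, _fam, _s in truth.genes_at(level)
        }
        mapping = map_ancestral_genes(inferred_sets, true_sets)
        inferred_pairs = {
            frozenset(k) for k in result.linearized[level].edges
        }
        true_pairs = truth.adjacency_set(level)
        records.append(
            precision_recall(level, inferred_pairs, true_pairs, mapping)
        )
    hp, hr = _summarize(records)
    return records, hp, hr


# ---------------------------------------------------------------------------
# file-based path


def _read_truth_lineage(
    path: str, tree: SpeciesTree
) -> Tuple[Dict[str, List[str]], Dict[str, str], Dict[str, Optional[str]]]:
    genes_by_level: Dict[str, List[str]] = {lab: [] for lab in tree.nodes}
    level_of: Dict[str, str] = {}
    parent_of: Dict[str, Optional[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            uid, level, _fam, parent = line.rstrip("\n").split("\t")
            genes_by_level[level].append(uid)
            level_of[uid] = level
            parent_of[uid] = parent or None
    return genes_by_level, level_of, parent_of


def _read_pairs_tsv(path: str, col1: int = 0, col2: int = 1) -> Set[Pair]:
    pairs: Set[Pair] = set()
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            pairs.add(frozenset((parts[col1], parts[col2])))
    return pairs


def score_against_truth(
    truth_dir: str, pred_dir: str
) -> Tuple[List[PRRecord], float, float]:
    """Score a written inference run against a written simulation.

    ``truth_dir`` is a simulation output directory (species_tree.nwk,
    gff/, hogs.orthoxml, truth/); ``pred_dir`` an inference output
    directory (ancestral/). The inferred gene lineage is rebuilt from the
    same inputs, which is deterministic, so inferred gene uids in the
    prediction TSVs resolve.
    """
    with open(os.path.join(truth_dir, "species_tree.nwk"), encoding="utf-8") as fh:
        tree = read_species_tree(fh.read())
    with open(os.path.join(truth_dir, "hogs.orthoxml"), encoding="utf-8") as fh:
        forest = read_orthoxml(fh.read(), tree)
    lineage = build_gene_lineage(forest, tree)
    gff_dir = os.path.join(truth_dir, "gff")
    for name in sorted(os.listdir(gff_dir)):
        stem, ext = os.path.splitext(name)
        if ext.lower() not in (".gff", ".gff3"):
            continue
        with open(os.path.join(gff_dir, name), encoding="utf-8") as fh:
            for contig_genes in read_gff(fh.read(), stem).values():
                for gene in contig_genes:
                    if gene.gene_id not in lineage.extant_index:
                        lineage.add_singleton(gene.gene_id, stem)

    genes_by_level, _level_of, parent_of = _read_truth_lineage(
        os.path.join(truth_dir, "truth", "gene_lineage.tsv"), tree
    )
    children: Dict[str, List[str]] = {}
    for uid, parent in parent_of.items():
        if parent is not None:
            children.setdefault(parent, []).append(uid)
    true_desc: Dict[str, FrozenSet[str]] = {}
    for node in tree.postorder():
        for uid in genes_by_level[node.label]:
            if node.is_leaf:
                true_desc[uid] = frozenset((uid,))
            else:
                acc: Set[str] = set()
                for c in children.get(uid, ()):
                    acc.update(true_desc.get(c, ()))
                true_desc[uid] = frozenset(acc)

    records: List[PRRecord] = []
    for node in tree.internal_nodes():
        label = node.label
        inferred_sets = _level_desc_sets(lineage, label)
        true_sets = {
            uid: true_desc[uid] for uid in genes_by_level[label]
        }
        mapping = map_ancestral_genes(inferred_sets, true_sets)
        safe = "".join(
            c if c.isalnum() or c in "._-" else "_" for c in label
        )
        pred_path = os.path.join(pred_dir, "ancestral", f"{safe}_adjacencies.tsv")
        inferred_pairs = _read_pairs_tsv(pred_path)
        true_pairs = _read_pairs_tsv(
            os.path.join(truth_dir, "truth", f"{safe}_adjacencies.tsv")
        )
        records.append(
            precision_recall(label, inferred_pairs, true_pairs, mapping)
        )
    hp, hr = _summarize(records)
    return records, hp, hr
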