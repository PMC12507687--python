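"""Desk-scale genome evolution simulator.

Produces a seeded random species tree (or uses a supplied one), a root
genome, and per-branch Poisson-distributed events — gene gain, loss, tandem
and dispersed duplication, segment inversion and translocation — recording
the true gene order at every node, the full gene lineage (hence the
ground-truth HOG forest) and a replayable event log.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np

from .formats.gff import write_gff
from .formats.orthoxml import write_orthoxml
from .model import ExtantGene, HOGForest, HOGGroup
from .tree import SpeciesTree, TreeNode

__all__ = [
    "SimParams",
    "SimEvent",
    "SimulationTruth",
    "SimulationError",
    "preset",
    "simulate_evolution",
    "write_truth",
    "yule_tree",
]

Gene = Tuple[str, str, str]  # (uid, family, strand)
Genome = List[List[Gene]]  # contigs of genes

EVENT_KINDS = (
    "gain",
    "loss",
    "tandem_dup",
    "dispersed_dup",
    "inversion",
    "translocation",
)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Rates are per gene per unit branch length."""

    n_leaves: int = 20
    root_genes: int = 200
    root_contigs: int = 4
    gain_rate: float = 0.0
    loss_rate: float = 0.0
    tandem_dup_rate: float = 0.0
    dispersed_dup_rate: float = 0.0
    inversion_rate: float = 0.0
    translocation_rate: float = 0.0
    inversion_mean_len: float = 3.0
    seed: int = 0

    def rate(self, kind: str) -> float:
        return getattr(self, f"{kind}_rate")


#: Named rate presets. ``low`` mirrors a low-rearrangement regime (few
#: dozen events across a 100-genome tree); ``harsh`` applies roughly 40x
#: higher rearrangement pressure; ``none`` is the zero-event limit.
PRESETS: Dict[str, Dict[str, float]] = {
    "none": {},
    "low": {
        "gain_rate": 2e-4,
        "loss_rate": 2e-4,
        "tandem_dup_rate": 1e-4,
        "dispersed_dup_rate": 5e-5,
        "inversion_rate": 5e-5,
        "translocation_rate": 2e-5,
    },
    "harsh": {
        "gain_rate": 2e-3,
        "loss_rate": 2e-3,
        "tandem_dup_rate": 1e-3,
        "dispersed_dup_rate": 5e-4,
        "inversion_rate": 2e-3,
        "translocation_rate": 1e-3,
    },
}


def preset(name: str, **overrides) -> SimParams:
    try:
        rates = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return replace(SimParams(**rates), **overrides)


@dataclass
class SimEvent:
    branch: str  # label of the child node of the branch
    kind: str
    payload: dict


@dataclass
class SimulationTruth:
    tree: SpeciesTree
    params: SimParams
    orders: Dict[str, Tuple[Tuple[Gene, ...], ...]]
    gene_parent: Dict[str, Optional[str]]
    gene_family: Dict[str, str]
    gene_level: Dict[str, str]
    events: List[SimEvent] = field(default_factory=list)
    _desc_cache: Optional[Dict[str, FrozenSet[str]]] = None

    # -- derived views ---------------------------------------------------

    def adjacency_set(self, label: str) -> Set[FrozenSet[str]]:
        out: Set[FrozenSet[str]] = set()
        for contig in self.orders[label]:
            for a, b in zip(contig, contig[1:]):
                out.add(frozenset((a[0], b[0])))
        return out

    def children_index(self) -> Dict[str, List[str]]:
        idx: Dict[str, List[str]] = {}
        for node in self.tree.preorder():
            for contig in self.orders[node.label]:
                for uid, _fam, _s in contig:
                    parent = self.gene_parent.get(uid)
                    if parent is not None:
                        idx.setdefault(parent, []).append(uid)
        return idx

    def descendant_extant(self) -> Dict[str, FrozenSet[str]]:
        """uid → extant descendant uids, for every true gene."""
        if self._desc_cache is None:
            children = self.children_index()
            sets: Dict[str, FrozenSet[str]] = {}
            for node in self.tree.postorder():
                is_leaf = node.is_leaf
                for contig in self.orders[node.label]:
                    for uid, _fam, _s in contig:
                        if is_leaf:
                            sets[uid] = frozenset((uid,))
                        else:
                            acc: Set[str] = set()
                            for c in children.get(uid, ()):
                                acc.update(sets.get(c, ()))
                            sets[uid] = frozenset(acc)
            self._desc_cache = sets
        return self._desc_cache

    def genes_at(self, label: str) -> List[Gene]:
        return [g for contig in self.orders[label] for g in contig]


# ---------------------------------------------------------------------------
# tree generation


def yule_tree(n_leaves: int, rng: np.random.Generator) -> SpeciesTree:
    """Birth-only topology with unit-mean exponential branch lengths."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    root = TreeNode("tmp")
    tips = [root]
    while len(tips) < n_leaves:
        idx = int(rng.integers(len(tips)))
        node = tips.pop(idx)
        left, right = TreeNode("tmp"), TreeNode("tmp")
        node.add_child(left)
        node.add_child(right)
        tips.extend([left, right])
    n_int = n_leaf = 0
    stack = [root]
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    for node in order:
        if node.children:
            n_int += 1
            node.label = f"A{n_int}"
        else:
            n_leaf += 1
            node.label = f"S{n_leaf}"
        if node.parent is not None:
            node.length = float(rng.exponential(1.0))
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# event operators (explicit loci so the event log can be replayed)


def apply_gain(genome: Genome, contig: int, pos: int, gene: Gene) -> None:
    genome[contig].insert(pos, gene)


def apply_loss(genome: Genome, contig: int, pos: int) -> Gene:
    gene = genome[contig].pop(pos)
    if not genome[contig]:
        del genome[contig]
    return gene


def apply_duplication(
    genome: Genome, src: Tuple[int, int], dst: Tuple[int, int], uid: str
) -> Gene:
    suid, fam, strand = genome[src[0]][src[1]]
    copy = (uid, fam, strand)
    genome[dst[0]].insert(dst[1], copy)
    return copy


def apply_inversion(genome: Genome, contig: int, start: int, length: int) -> None:
    seg = genome[contig][start : start + length]
    genome[contig][start : start + length] = [
        (u, f, "+" if s == "-" else "-") for (u, f, s) in reversed(seg)
    ]


def apply_translocation(
    genome: Genome,
    src_contig: int,
    start: int,
    length: int,
    dst_contig: int,
    dst_pos: int,
) -> None:
    seg = genome[src_contig][start : start + length]
    del genome[src_contig][start : start + length]
    genome[dst_contig][dst_pos:dst_pos] = seg
    if not genome[src_contig]:
        del genome[src_contig]


# ---------------------------------------------------------------------------
# branch evolution


def _genome_size(genome: Genome) -> int:
    return sum(len(c) for c in genome)


def _pick_locus(genome: Genome, rng: np.random.Generator) -> Tuple[int, int]:
    flat = int(rng.integers(_genome_size(genome)))
    for ci, contig in enumerate(genome):
        if flat < len(contig):
            return ci, flat
        flat -= len(contig)
    raise AssertionError("unreachable")


def _seg_length(rng: np.random.Generator, mean_len: float) -> int:
    return int(rng.geometric(1.0 / max(mean_len, 1.0)))


class _Sim:
    def __init__(self, params: SimParams, rng: np.random.Generator) -> None:
        self.params = params
        self.rng = rng
        self.family_counter = itertools.count(1)
        self.truth_events: List[SimEvent] = []

    def new_family(self) -> str:
        return f"F{next(self.family_counter):05d}"

    def evolve_branch(
        self,
        parent_genome: Genome,
        child_label: str,
        branch_len: float,
        truth_maps: Tuple[Dict[str, Optional[str]], Dict[str, str], Dict[str, str]],
    ) -> Genome:
        gene_parent, gene_family, gene_level = truth_maps
        counter = itertools.count(1)

        def new_uid() -> str:
            return f"{child_label}_{next(counter):05d}"

        genome: Genome = []
        for contig in parent_genome:
            nc: List[Gene] = []
            for uid, fam, strand in contig:
                nuid = new_uid()
                gene_parent[nuid] = uid
                gene_family[nuid] = fam
                gene_level[nuid] = child_label
                nc.append((nuid, fam, strand))
            genome.append(nc)

        size0 = _genome_size(genome)
        kinds: List[str] = []
        for kind in EVENT_KINDS:
            lam = self.params.rate(kind) * size0 * branch_len
            kinds.extend([kind] * int(self.rng.poisson(lam)))
        if kinds:
            kinds = [kinds[i] for i in self.rng.permutation(len(kinds))]
        for kind in kinds:
            self._apply_random_event(
                kind, genome, child_label, new_uid,
                gene_parent, gene_family, gene_level,
            )
        if not genome:
            raise SimulationError(
                f"genome emptied by losses on branch to {child_label}; "
                "lower the loss rate"
            )
        return genome

    def _apply_random_event(
        self, kind, genome, child_label, new_uid,
        gene_parent, gene_family, gene_level,
    ) -> None:
        rng = self.rng
        if not genome:
            raise SimulationError(
                f"genome emptied on branch to {child_label}; "
                "lower the loss rate"
            )
        if kind == "gain":
            fam = self.new_family()
            uid = new_uid()
            gene_parent[uid] = None
            gene_family[uid] = fam
            gene_level[uid] = child_label
            contig = int(rng.integers(len(genome)))
            pos = int(rng.integers(len(genome[contig]) + 1))
            strand = "+" if rng.integers(2) == 0 else "-"
            apply_gain(genome, contig, pos, (uid, fam, strand))
            self.truth_events.append(SimEvent(child_label, kind, {
                "contig": contig, "pos": pos, "uid": uid, "family": fam,
                "strand": strand,
            }))
        elif kind == "loss":
            ci, pos = _pick_locus(genome, rng)
            apply_loss(genome, ci, pos)
            self.truth_events.append(
                SimEvent(child_label, kind, {"contig": ci, "pos": pos})
            )
        elif kind in ("tandem_dup", "dispersed_dup"):
            ci, pos = _pick_locus(genome, rng)
            src_uid, src_fam, _ = genome[ci][pos]
            uid = new_uid()
            if gene_parent.get(src_uid) is None:
                # copy of a gene born on this very branch: treated as an
                # independent new family to keep one root gene per family
                fam = self.new_family()
                gene_parent[uid] = None
            else:
                fam = src_fam
                gene_parent[uid] = gene_parent[src_uid]
            gene_family[uid] = fam
            gene_level[uid] = child_label
            if kind == "tandem_dup":
                dst = (ci, pos + 1)
            else:
                dc = int(rng.integers(len(genome)))
                dst = (dc, int(rng.integers(len(genome[dc]) + 1)))
            apply_duplication(genome, (ci, pos), dst, uid)
            if fam != src_fam:
                # rewrite the copy's family in place
                genome[dst[0]][dst[1]] = (uid, fam, genome[dst[0]][dst[1]][2])
            self.truth_events.append(SimEvent(child_label, kind, {
                "src": (ci, pos), "dst": dst, "uid": uid, "family": fam,
            }))
        elif kind == "inversion":
            ci, pos = _pick_locus(genome, rng)
            length = min(
                _seg_length(rng, self.params.inversion_mean_len),
                len(genome[ci]) - pos,
            )
            apply_inversion(genome, ci, pos, length)
            self.truth_events.append(SimEvent(child_label, kind, {
                "contig": ci, "start": pos, "length": length,
            }))
        elif kind == "translocation":
            ci, pos = _pick_locus(genome, rng)
            length = min(
                _seg_length(rng, self.params.inversion_mean_len),
                len(genome[ci]) - pos,
            )
            seg = genome[ci][pos : pos + length]
            del genome[ci][pos : pos + length]
            src_emptied = not genome[ci]
            if src_emptied:
                del genome[ci]
            if genome:
                dc = int(rng.integers(len(genome)))
                dpos = int(rng.integers(len(genome[dc]) + 1))
            else:
                genome.append([])
                dc, dpos = 0, 0
            genome[dc][dpos:dpos] = seg
            self.truth_events.append(SimEvent(child_label, kind, {
                "src_contig": ci, "start": pos, "length": length,
                "dst_contig": dc, "dst_pos": dpos,
                "src_emptied": src_emptied,
            }))
        else:  # pragma: no cover
            raise AssertionError(kind)


def simulate_evolution(
    params: SimParams, tree: Optional[SpeciesTree] = None
) -> SimulationTruth:
    """Run the full simulation; the seed fixes every random choice."""
    rng = np.random.default_rng(params.seed)
    if tree is None:
        tree = yule_tree(params.n_leaves, rng)

    sim = _Sim(params, rng)
    gene_parent: Dict[str, Optional[str]] = {}
    gene_family: Dict[str, str] = {}
    gene_level: Dict[str, str] = {}

    root_label = tree.root.label
    n = params.root_genes
    k = max(1, params.root_contigs)
    bounds = [round(i * n / k) for i in range(k + 1)]
    genome: Genome = []
    for ci in range(k):
        contig: List[Gene] = []
        for gi in range(bounds[ci], bounds[ci + 1]):
            fam = sim.new_family()
            uid = f"{root_label}_{gi + 1:05d}"
            strand = "+" if rng.integers(2) == 0 else "-"
            gene_parent[uid] = None
            gene_family[uid] = fam
            gene_level[uid] = root_label
            contig.append((uid, fam, strand))
        if contig:
            genome.append(contig)

    orders: Dict[str, Tuple[Tuple[Gene, ...], ...]] = {}
    genomes: Dict[str, Genome] = {root_label: genome}
    orders[root_label] = tuple(tuple(c) for c in genome)
    for node in tree.preorder():
        if node.parent is None:
            continue
        child_genome = sim.evolve_branch(
            genomes[node.parent.label],
            node.label,
            node.length,
            (gene_parent, gene_family, gene_level),
        )
        genomes[node.label] = child_genome
        orders[node.label] = tuple(tuple(c) for c in child_genome)

    return SimulationTruth(
        tree=tree,
        params=params,
        orders=orders,
        gene_parent=gene_parent,
        gene_family=gene_family,
        gene_level=gene_level,
        events=sim.truth_events,
    )


# ---------------------------------------------------------------------------
# ground-truth HOG forest and file export


def truth_hog_forest(truth: SimulationTruth) -> HOGForest:
    """Build the HOG forest implied by the recorded gene lineage.

    Lineages with no extant descendants are pruned (a HOG only exists for
    gene families observable today); families whose surviving part is a
    single extant gene become singleton species-specific families, i.e.
    declared genes outside any group.
    """
    desc = truth.descendant_extant()
    children = truth.children_index()
    leaf_labels = set(truth.tree.leaf_labels())

    gene_species: Dict[str, str] = {}
    for leaf in sorted(leaf_labels):
        for contig in truth.orders[leaf]:
            for uid, _fam, _s in contig:
                gene_species[uid] = leaf

    def build(uid: str) -> object:
        level = truth.gene_level[uid]
        if level in leaf_labels:
            return uid
        group = HOGGroup(level=level, family_id=truth.gene_family[uid])
        by_level: Dict[str, List[str]] = {}
        for c in sorted(children.get(uid, ())):
            if desc.get(c):
                by_level.setdefault(truth.gene_level[c], []).append(c)
        for level_children in by_level.values():
            if len(level_children) >= 2:
                pg = HOGGroup(is_paralog=True,
                              family_id=truth.gene_family[uid])
                for c in level_children:
                    pg.children.append(build(c))
                group.children.append(pg)
            else:
                group.children.append(build(level_children[0]))
        return group

    roots: List[HOGGroup] = []
    root_uids = sorted(
        uid for uid, parent in truth.gene_parent.items()
        if parent is None and desc.get(uid)
    )
    for uid in root_uids:
        built = build(uid)
        if isinstance(built, str):
            continue  # singleton: declared but not grouped
        # collapse single-extant-gene families to singletons as well
        member_count = len(desc[uid])
        if member_count < 2:
            continue
        roots.append(built)
    return HOGForest(roots=roots, gene_species=gene_species)


def extant_gff_genes(
    truth: SimulationTruth, leaf: str
) -> Dict[str, List[ExtantGene]]:
    """Synthesize coordinates from ranks: gene i spans [1000i+1, 1000i+500]."""
    out: Dict[str, List[ExtantGene]] = {}
    for ci, contig in enumerate(truth.orders[leaf]):
        cid = f"{leaf}_c{ci + 1}"
        genes = []
        for i, (uid, _fam, strand) in enumerate(contig):
            genes.append(
                ExtantGene(
                    gene_id=uid,
                    species=leaf,
                    contig=cid,
                    start=1000 * i + 1,
                    end=1000 * i + 500,
                    strand=strand,
                    rank=i,
                )
            )
        out[cid] = genes
    return out


def write_truth(truth: SimulationTruth, out_dir: str) -> Dict[str, str]:
    """Emit newick + per-leaf GFF3 + OrthoXML + per-node adjacency TSVs."""
    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    tree_path = os.path.join(out_dir, "species_tree.nwk")
    with open(tree_path, "w", encoding="utf-8") as fh:
        fh.write(truth.tree.to_newick() + "\n")
    paths["tree"] = tree_path

    gff_dir = os.path.join(out_dir, "gff")
    os.makedirs(gff_dir, exist_ok=True)
    for leaf in truth.tree.leaf_labels():
        p = os.path.join(gff_dir, f"{leaf}.gff3")
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(write_gff(extant_gff_genes(truth, leaf)))
    paths["gff_dir"] = gff_dir

    hog_path = os.path.join(out_dir, "hogs.orthoxml")
    with open(hog_path, "w", encoding="utf-8") as fh:
        fh.write(write_orthoxml(truth_hog_forest(truth)))
    paths["orthoxml"] = hog_path

    truth_dir = os.path.join(out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    for label in sorted(truth.orders):
        p = os.path.join(truth_dir, f"{label}_adjacencies.tsv")
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("gene1\tgene2\tstrand1\tstrand2\tcontig_id\n")
            for ci, contig in enumerate(truth.orders[label]):
                for a, b in zip(contig, contig[1:]):
                    fh.write(
                        f"{a[0]}\t{b[0]}\t{a[2]}\t{b[2]}\t{label}_c{ci + 1}\n"
                    )
    paths["truth_dir"] = truth_dir
    return paths


def replay(truth: SimulationTruth) -> Dict[str, Tuple[Tuple[Gene, ...], ...]]:
    """Re-derive every node's gene order from the event log alone.

    Uses the same uid-assignment rule as the forward simulation, so the
    result must match ``truth.orders`` exactly (internal consistency
    oracle).
    """
    by_branch: Dict[str, List[SimEvent]] = {}
    for ev in truth.events:
        by_branch.setdefault(ev.branch, []).append(ev)

    orders = {truth.tree.root.label: truth.orders[truth.tree.root.label]}
    genomes: Dict[str, Genome] = {
        truth.tree.root.label: [list(c) for c in orders[truth.tree.root.label]]
    }
    for node in truth.tree.preorder():
        if node.parent is None:
            continue
        counter = itertools.count(1)
        genome: Genome = []
        for contig in genomes[node.parent.label]:
            nc = []
            for uid, fam, strand in contig:
                nc.append((f"{node.label}_{next(counter):05d}", fam, strand))
            genome.append(nc)
        for ev in by_branch.get(node.label, ()):
            p = ev.payload
            if ev.kind == "gain":
                next(counter)
                apply_gain(
                    genome, p["contig"], p["pos"],
                    (p["uid"], p["family"], p["strand"]),
                )
            elif ev.kind == "loss":
                apply_loss(genome, p["contig"], p["pos"])
            elif ev.kind in ("tandem_dup", "dispersed_dup"):
                next(counter)
                apply_duplication(genome, p["src"], p["dst"], p["uid"])
                dc, dpos = p["dst"]
                genome[dc][dpos] = (p["uid"], p["family"], genome[dc][dpos][2])
            elif ev.kind == "inversion":
                apply_inversion(genome, p["contig"], p["start"], p["length"])
            elif ev.kind == "translocation":
                seg = genome[p["src_contig"]][p["start"]: p["start"] + p["length"]]
                del genome[p["src_contig"]][p["start"]: p["start"] + p["length"]]
                if p["src_emptied"]:
                    del genome[p["src_contig"]]
                if not genome:
                    genome.append([])
                genome[p["dst_contig"]][p["dst_pos"]:p["dst_pos"]] = seg
        genomes[node.label] = genome
        orders[node.label] = tuple(tuple(c) for c in genome)
    return orders
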