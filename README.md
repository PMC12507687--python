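# ancorder

Ancestral gene-order inference along a rooted species tree, driven by
hierarchical orthologous groups (HOGs). Given a newick species tree, one
GFF3 file per extant genome and the genomes' HOGs in OrthoXML, `ancorder`
reconstructs ordered, oriented ancestral contigs at every internal node,
dates every gene adjacency to its clade of emergence and converts clades to
ages with a node→age table. A bundled genome-evolution simulator produces
ground-truth inputs (tree, GFF3, OrthoXML, true ancestral orders) so the
whole method can be benchmarked offline.

## How it works

1. **Gene lineage** — HOG nesting is unfolded into a gene-lineage graph:
   one ancestral gene per tree node a family crosses, with child→parent
   links and duplication flags.
2. **Bottom-up propagation** — extant adjacencies are lifted leaf→root
   along lineage links. Weights count extant propagations; runs of
   parentless genes (gene gains) are bridged between their flanking
   neighbours' parents; duplicated genes and edges merge at the
   duplication point.
3. **Top-down filtering** — root→leaf, an edge is kept only with at least
   two supporting child subtrees or a retained parent edge (weights play no
   role). Each retained lineage is stamped with its root-most node: the
   adjacency's emergence, used for dating.
4. **Linearization** — genes with more than two neighbours keep the two
   with maximal linear path weight; residual cycles are broken at their
   lightest edge; contigs of length ≥ 2 are emitted with majority-vote
   gene orientations.

## CLI

```sh
# simulate a dataset with ground truth
ancorder simulate --preset low --n-leaves 20 --root-genes 200 --seed 1 --out sim/

# infer ancestral gene orders (TSVs per internal node + manifest)
ancorder infer --tree sim/species_tree.nwk --hogs sim/hogs.orthoxml \
    --gff-dir sim/gff --out run/ --date

# score the run against the simulated truth
ancorder evaluate --truth sim/ --pred run/ --out pr.tsv

# date adjacencies in Ma using a node->age TSV
ancorder date --tree ... --hogs ... --gff-dir ... --ages ages.tsv --out run/

# project an ancestor's adjacencies into one extant genome
ancorder project --tree ... --hogs ... --gff-dir ... --species S1 --out proj.tsv
```

Optional confidence filters: `--min-weight` (drop light edges) and
`--min-completeness` (drop ancestral genes whose HOG covers too small a
fraction of the clade's species) are applied before linearization.

Exit codes: 0 success, 2 invalid/inconsistent inputs, 1 internal error.

## Layout

- `src/ancorder/formats/` — newick, GFF3, OrthoXML, TSV I/O
- `src/ancorder/lineage.py` — HOG nesting → per-node ancestral gene sets
- `src/ancorder/synteny.py` — propagation, parsimony filter, linearization
- `src/ancorder/dating.py` — emergence, ages, phylostratigraphy, clusters
- `src/ancorder/simulate.py` — genome-evolution simulator with event log
- `src/ancorder/evaluate.py` — gene mapping, precision/recall, projection
- `src/ancorder/benchmark.py` — end-to-end simulated benchmark harness
- `src/ancorder/cli.py` — pipeline orchestration and `ancorder` commands
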