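# mtminer

Mining and annotation of **metallothionein (MT) gene clusters** in
genomic contigs, built for the cetacean MT gene family but applicable
to any mammalian-style MT locus.

Metallothioneins are small cysteine-rich metal-binding proteins with a
rigid structural grammar: 61–68 residues, more than 30 % cysteine
arranged in Cys-Cys / Cys-X-Cys / Cys-X-X-Cys motifs, and two metal
binding domains — an N-terminal β domain (9 Cys binding 3 metal
cations, encoded by exons I–II) and a C-terminal α domain (11 Cys
binding 4 cations, encoded by exon III). Mammals carry four isoforms
(Mt1–Mt4) in a single co-oriented genomic cluster, ordered
**Mt4-Mt3-Mt2-Mt1**, with Mt1 often tandemly duplicated (Mt1a/b/c) and
occasionally retrotransposed into dispersed intron-free copies.
`mtminer` turns those regularities into a tested annotation pipeline:

1. **detect** — nominate candidate loci by exact k-mer seeding against
   reference coding sequences, with co-linear chaining that jumps
   introns, plus six-frame ORF scanning and an MT-likeness protein
   score built from the structural grammar;
2. **annotate** — delineate the canonical three-exon/two-intron gene
   model by spliced dynamic-programming alignment in which contig-only
   gaps are scored as introns only when they start `GT` and end `AG`,
   then validate by in-silico translation;
3. **architecture** — order the validated genes, name tandem Mt1
   copies, and compute InterGenic Region (IGR) lengths with mean ±
   sample SD summaries;
4. **phylogeny** — Kimura two-parameter (K2P) distances
   `d = −½·ln((1−2P−Q)·√(1−2Q))` (P transitions, Q transversions),
   in-house Saitou–Nei neighbor joining, and column-resampling
   bootstrap support, used to verify the four-isoform cluster
   structure and to classify genes;
5. **simulate** — a seeded generator of synthetic cluster genomes with
   exact ground-truth annotations (exon/intron/IGR lengths drawn from
   the observed per-isoform envelopes), the oracle every stage is
   scored against.

The package also ships machine-readable transcriptions of the
published per-species tables (species/accession inventory, IGR
lengths, exon lengths, intron lengths) under `src/mtminer/data/`, with
their printed summary rows deliberately excluded so the statistics are
recomputed, not echoed.

## Worked example

```python
import mtminer as mt
from mtminer.simulate import reference_records

config = mt.SimulationConfig(seed=3)
truth = mt.simulate_cluster_genome(config)          # ~50 kb contig, 4 genes
refs = reference_records(config)                    # one reference CDS per isoform

hits = mt.find_candidate_loci(truth.contig, [r for l in refs.values() for r in l])
mt3 = next(m for m in truth.annotations if m.isoform == "Mt3")
win = next(h for h in hits if h.window[0] <= mt3.start < h.window[1])
seq = truth.contig.residues[win.window[0]:win.window[1]]
aln = mt.spliced_align(refs["Mt3"][0], mt.SequenceRecord(id="w", residues=seq))
model = mt.alignment_to_gene_model(aln, seq, "cand", truth.contig.id,
                                   window_offset=win.window[0])
print(model.exons, mt.classify_isoform(model, refs).isoform)
```

The same analysis, with its checks against the simulator's truth, is
`examples/annotate_contig.py`; running it prints (abridged)

```
spliced alignment: identity 0.990, 2 introns
exons:   ((36027, 36058), (36234, 36300), (37268, 37375))  (truth ((36027, 36058), (36234, 36300), (37268, 37375)))
lengths: exons (31, 66, 107), introns (176, 968)
isoform call: Mt3 (high) evidence={'exon3_length': 107, 'nearest_reference': 'Mt3', 'nearest_distance': 0.009877}
```

The recovered exon
intervals equal the simulator's ground truth exactly, the 31/66/107 bp
exon lengths match the Mt3 envelope — the 104–107 bp exon III is the
Mt3 length signature — and the nearest-reference K2P distance confirms
the call. The other scripts in `examples/` walk through simulation,
protein scoring, the table summaries, the four-isoform bootstrap tree
and the full pipeline; each prints what the numbers mean.

A thin CLI wraps the same library:

```sh
mtminer simulate --seed 5 --species 2 --outdir sim/
mtminer run sim/genomes.fasta --refs refs.fasta --outdir out/ --seed 1
mtminer tables          # recompute the per-species table summaries
```

Pipeline runs are pure functions of (inputs, configuration, seed):
reruns are byte-identical, and every report file carries the tool
version, a configuration hash and the seed in its header.

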