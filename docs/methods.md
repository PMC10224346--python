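# Methods

This note records the models, conventions and numerical choices behind
`mtminer`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and the gene span convention

All in-memory intervals are 0-based half-open; the GFF3 reader/writer
is the single place where the shift to 1-based inclusive happens. A
gene span runs from the start codon through the **stop codon
inclusive**, so the stop sits inside exon III and exon III's length
includes it. Published exon tables do not state whether their exon III
lengths include the stop; we adopt one convention, apply it uniformly
in the annotator, the simulator and the IGR computation, and note that
the observed envelopes (exon III of 92 bp, or 104–107 bp for Mt3) are
consistent with it. An InterGenic Region (IGR) is the count of bases
strictly between two consecutive gene spans; abutting genes have IGR
0. IGRs are computed on genomic coordinates irrespective of strand;
mixed-orientation clusters trigger a warning because the canonical
cluster is co-oriented.

## MT-likeness score

`score_mt_protein` grades four constraints, each in [0, 1], combined
as a weighted mean (equal weights by default, pass threshold 0.75):

* **length** — 1.0 on 61–68 aa, decaying linearly to 0 outside a halo
  of 57–72 aa;
* **cysteine fraction** — 1.0 above 0.30, otherwise `fraction / 0.30`;
* **motif participation** — the fraction of cysteines within 3
  residues of another cysteine, i.e. engaged in at least one CC, CXC
  or CXXC motif. Motif *counts* are reported with overlaps allowed,
  scanning left to right (the literature states no counting
  convention, so ours is explicit);
* **domain layout** — 1.0 when some split point leaves 9 ± 1 cysteines
  on the β side and 11 ± 1 on the α side, degrading linearly with the
  residual deviation of the best split. The linker position itself is
  not observable from sequence alone; among equally tolerable splits
  the one closest to the exact 9/11 stoichiometry is reported.

The extreme cases the pipeline relies on (grammar-conforming proteins
score ≈ 1; proteins without cysteine structure score < 0.5) are robust
to modest re-weighting; the threshold is configuration, not biology.

## Seeded similarity search

`find_candidate_loci` replaces an external database search with exact
k-mer seeding (default k = 11) of both reference orientations against
a contig index, greedy co-linear chaining with a gap allowance of
10 kb (enough to jump any observed intron), window padding of 2 kb,
and merging of overlapping windows. A chain qualifies only if it
contains at least `min_seeds = 10` **distinct reference offsets**:
counting distinct offsets prevents one repetitive k-mer from faking a
chain, and ten of them is beyond what an isolated chance exact repeat
(~15–20 bp) can produce in random sequence, while a true exon match
contributes dozens to hundreds. A real locus at a few percent
divergence retains long exact seed runs, so recall on simulated
clusters is 1.0.

## Spliced alignment

The annotator aligns a complete reference CDS against a genomic window
with a semi-global dynamic program (full reference, free window
flanks): match +2, mismatch −3, gap −4, plus an intron move that jumps
a contig interval at a flat penalty of 12 **only** when the interval
begins `GT` and ends `AG` (GC..AG donors optionally allowed behind a
flag at an extra penalty, mirroring the rare mammalian minor splice
form). Intron length is bounded below by 60 bp inside the recurrence;
the upper bound (50 kb) is enforced by the window size handed to the
aligner — windows are gene spans plus ~2 kb flanks, far below the cap
— rather than by a monotone queue in the DP. The matrix fill is a
numba-compiled kernel (O(m·n), ~ms per window after the one-off JIT
compile).

Because an intron must start with `GT`, shifting a recovered intron by
one base would require the base after the donor to be G and T at once;
single-base boundary ambiguity is therefore impossible on unmutated
sequence, which is what makes *exact* boundary recovery a fair
expectation on noise-free synthetic data. Ties between equal-scoring
alignments break deterministically: earliest contig end, with diagonal
moves preferred over intron moves and the earliest donor kept, which
realizes the "leftmost, fewest introns" convention.

Alignment identity is matches over aligned columns (gap columns
included); models require identity ≥ 0.8. Reference coverage is the
fraction of reference positions actually placed on the contig; below
0.95 the model is "partial" — an error by default, or emitted with the
`exon_count_atypical` flag when the caller opts in (the pipeline does,
so edge-truncated genes are reported but excluded from architecture
statistics).

## Validation and isoform classification

A validated model starts with ATG, ends with TAA/TAG (TGA demotes to a
warning: the canonical MT stop is TAA/TAG, but a detection stage
should not assume its conclusion), has no internal stop, passes the
MT-likeness score, and — when three-exonic — has exon lengths inside
the observed envelopes (I: 28–31, II: 66 with 81 tolerated, III: 92 or
104–107).

Classification combines independent evidence lines by simple majority:
the 104–107 bp exon III length (Mt3's signature), the nearest
reference by K2P distance after global affine alignment (match +1,
mismatch −1, gap open −5, extend −1, via Biopython's pairwise
aligner), and optionally a clade assignment. Distance ties within 1e−9
abstain; an overall tie yields `unknown` with low confidence.
Intron-free retrocopies carry no exon-structure evidence and are
classified from distance alone (medium confidence at best).

## Distances, trees, bootstrap

K2P excludes sites with N or a gap in either sequence, computes
transition/transversion proportions P and Q over the rest, and errors
("saturated pair") when `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` instead of
returning infinity. Neighbor joining is the classic Saitou–Nei
Q-criterion agglomeration with deterministic lexicographic
tie-breaking on subtree labels; negative branch lengths (a routine NJ
artifact near zero distances) are clamped to 0 with a warning. On
additive matrices NJ provably reconstructs the generating tree; the
tests verify this for up to eight taxa and cross-check the topology
against scikit-bio's independent implementation. Bootstrap resamples
alignment columns with replacement, rebuilds the NJ tree per
replicate, and reports for each internal bipartition of the
point-estimate tree the percentage of replicates containing it
(rounded down; replicates that saturate are skipped with a warning).
Multiple sequences are put on common columns by star alignment:
pairwise alignment of each sequence to the longest one, dropping
insertions relative to that center — adequate for equal-structure
coding sequences, where indels are rare and short; it is not a general
multiple aligner.

The published analysis fits maximum-likelihood trees with external
tooling and reports their log-likelihoods; those numbers require
database downloads and an ML engine and are not targets here. The
biological claim this package reproduces is the **four-cluster
isoform structure**, verified by distance/NJ/bootstrap — the same
family of methods the original analysis uses for its starting trees.

## The simulator: what it emulates, and what it does not

`simulate_cluster_genome` writes co-oriented genes in the canonical
layout (default Mt4, Mt3, Mt2, Mt1a) on the forward strand, separated
by IGR draws and flanked by 2 kb of random sequence. All length
defaults are the observed per-species envelopes: exon I 28–31 bp
(isoform-specific), exon II 66 bp, exon III 92 bp (104–107 for Mt3,
constrained so the CDS is a codon multiple), intron ranges per isoform
(e.g. Mt2 intron I 291–297 bp; Mt4 intron I 1171–1671 bp; tandem Mt1
copies use the copy-a envelope), and IGR ranges per adjacent pair
(Mt4-Mt3 19.6–36.1 kb down to ~3 kb between Mt1 copies). One printed
range (Mt2 intron II, 205–283 bp) exceeds the individual values its
own table lists — we follow the printed summary range.

Coding sequences follow a two-level evolutionary story: one root MT
CDS (a grammar-conforming 61-aa protein — exactly 20 cysteines in
motif groups, 9 β / 11 α — reverse-translated with uniform synonymous
codons; no codon-usage table is assumed) is diverged once per isoform
at a deep per-site rate (default 0.25) and once per species at a
shallow rate (default 0.02, giving ~99 % within-isoform and ~75–80 %
between-isoform nucleotide identity, the regime in which seeds,
spliced alignment and K2P all behave like they do on real paralogs).
Divergence and the optional contig-level mutation process never touch
start/stop codons, cysteine codons (divergence) or splice
dinucleotides (mutation), and never create in-frame stops — so every
emitted gene satisfies every validator, and truth coordinates are
mutation-invariant. The isoform ancestors double as the reference CDS
set for detection (`reference_records`); free-standing synthetic
exemplars (`make_reference_set`) are available when no curated
reference FASTA is supplied.

Deliberately **not** modeled: indels, pseudogenization (frameshifts,
premature stops), codon-usage bias, GC heterogeneity, repeats or gene
conversion between Mt1 copies. Passing the recovery benchmarks
therefore shows the pipeline is correct under clean-to-moderately
-noisy substitution-only divergence; it does not certify performance
on fragmented assemblies or pseudogene-rich loci, which real
annotation must still face.

## Statistics conventions

Table summaries use the arithmetic mean and the **sample (n−1)
standard deviation**, reported to two decimals — the convention that
reproduces the published per-column summaries from the per-species
cells (the published tables mix rounding and truncation in the final
hundredth, so agreement is asserted at printed precision). Cells
printed with "±" (incompletely assembled regions) contribute their
numeric value; range cells resolve by policy (default: low value —
this affects only the one column whose printed summary is internally
inconsistent in the published table, and no headline quantity uses it);
multi-copy intron cells contribute the configured tandem copy,
default copy (a). Two transcription normalizations are applied to the
packaged tables: one obvious family-name misprint is corrected so the
family count matches the inventory's own enumeration, and the sperm
whale appears under the binomial each table prints (two synonyms are
in circulation).

## Problem sizes

The shipped benchmarks run 3 simulated species (12 genes, ~50 kb
contigs) for end-to-end recovery, 20 genes for the 2 %-noise
robustness check, 4 × 5 sequences with 100 bootstrap replicates for
the monophyly check, and n ≤ 8 additive matrices for NJ recovery —
sizes chosen so the whole suite exercises every claim in minutes on a
single CPU while keeping every check exact rather than sampled.
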