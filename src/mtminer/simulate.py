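"""Synthetic cetacean MT cluster genomes with exact ground truth.

The generator emulates the canonical cluster: co-oriented genes in the
order Mt4-Mt3-Mt2-Mt1a(-Mt1b-Mt1c), each with three exons whose lengths
follow the observed per-isoform envelopes, GT..AG introns with lengths
drawn from the observed per-isoform ranges, and intergenic regions
drawn from the observed IGR ranges.

Coding sequences follow a two-level evolutionary story mirroring the MT
gene family: a single root MT coding sequence (a protein satisfying the
structural grammar — 61–68 aa, 20 cysteines in CC/CXC/CXXC motifs with
the 9 β / 11 α domain split — reverse-translated with uniform synonymous
codons) is diverged deeply once per isoform and shallowly once per
species.  Divergence never touches the start codon, the stop codon or
cysteine codons, and never creates an in-frame stop, so every emitted
gene still satisfies the grammar; splice dinucleotides and start/stop
codons are likewise excluded from contig-level point mutations, so truth
coordinates are mutation-invariant.

Everything is a pure function of (config, seed): reruns are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .detect import ScoreConfig, score_mt_protein
from .models import ExonModel
from .sequences import SequenceRecord, translate_cds

# codons per amino acid under the standard code
_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in unambiguous_dna_by_id[1].forward_table.items():
    _BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _BY_AA:
    _BY_AA[_aa].sort()

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: non-cysteine residues drawn for filler, enriched for residues common
#: in mammalian metallothioneins (lysine/serine/glycine/alanine)
_FILLER = "KKKSSSGGGAAATTEEDDPQN"

_STOPS = ("TAA", "TAG")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

ISOFORM_ORDER = ("Mt1", "Mt2", "Mt3", "Mt4")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator (lengths in bp).

    The default ranges are the observed per-isoform envelopes: exon I
    28–31 / exon II 66 / exon III 92 (104–107 for Mt3), intron ranges
    per isoform (tandem Mt1 copies use the copy-a envelope), and IGR
    ranges per adjacent gene pair of the Mt4-Mt3-Mt2-Mt1 cluster.
    ``isoform_divergence`` and ``species_divergence`` are per-site
    substitution probabilities applied (outside protected positions)
    between the root coding sequence and each isoform ancestor, and
    between an isoform ancestor and each species copy.
    """

    seed: int = 0
    species_count: int = 3
    cluster_layout: tuple[str, ...] = ("Mt4", "Mt3", "Mt2", "Mt1a")
    exon_length_ranges: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: {
            "Mt1": ((28, 31), (66, 66), (92, 92)),
            "Mt2": ((28, 28), (66, 66), (92, 92)),
            "Mt3": ((31, 31), (66, 66), (104, 107)),
            "Mt4": ((31, 31), (66, 66), (92, 92)),
        }
    )
    intron_length_ranges: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: {
            "Mt1": ((577, 612), (344, 356)),
            "Mt2": ((291, 297), (205, 283)),
            "Mt3": ((173, 181), (803, 1098)),
            "Mt4": ((1171, 1671), (520, 1041)),
        }
    )
    igr_ranges: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=lambda: {
            ("Mt4", "Mt3"): (19583, 36109),
            ("Mt3", "Mt2"): (7129, 7571),
            ("Mt2", "Mt1a"): (2064, 5310),
            ("Mt1a", "Mt1b"): (2729, 3214),
            ("Mt1b", "Mt1c"): (3088, 3926),
        }
    )
    isoform_divergence: float = 0.25
    species_divergence: float = 0.02
    mutation_rate: float = 0.0
    intron_free_mt1_prob: float = 0.0
    flank_length: int = 2000

    def __post_init__(self) -> None:
        for ranges in (*self.exon_length_ranges.values(), *self.intron_length_ranges.values()):
            for lo, hi in ranges:
                if lo > hi:
                    raise ValueError("range low > high")
        for lo, hi in self.igr_ranges.values():
            if lo > hi:
                raise ValueError("range low > high")
        rates = (
            self.isoform_divergence,
            self.species_divergence,
            self.mutation_rate,
            self.intron_free_mt1_prob,
        )
        if not all(0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class AncestralGene:
    """Isoform-level ancestor: fixed exon lengths and coding sequence."""

    isoform: str
    exon_lengths: tuple[int, int, int]
    cds: str
    protein: str


@dataclass(frozen=True)
class TruthSet:
    """A simulated contig paired with its exact gene annotations."""

    contig: SequenceRecord
    annotations: tuple[ExonModel, ...]
    igr_draws: tuple[tuple[str, str, int], ...]
    config: SimulationConfig
    seed: int


# ---------------------------------------------------------------------------
# Protein construction

def _group_sizes(n: int, rng: np.random.Generator) -> list[int]:
    """Split n cysteines into motif groups of size 2 or 3."""
    sizes: list[int] = []
    rem = n
    while rem:
        if rem in (2, 3):
            sizes.append(rem)
            rem = 0
        elif rem == 4:
            sizes.extend((2, 2))
            rem = 0
        else:
            take = int(rng.integers(2, 4))
            sizes.append(take)
            rem -= take
    return sizes


def _place_cys(lo: int, hi: int, n: int, rng: np.random.Generator) -> list[int]:
    """Positions for n cysteines inside [lo, hi) such that every
    cysteine sits within 3 residues of another (motif membership)."""
    region = hi - lo
    for _attempt in range(100):
        sizes = _group_sizes(n, rng)
        gaps = [int(rng.integers(1, 4)) for _ in range(n - len(sizes))]
        base_span = n + sum(g - 1 for g in gaps) + 2 * (len(sizes) - 1)
        if base_span > region:
            gaps = [1] * (n - len(sizes))
            base_span = n + 2 * (len(sizes) - 1)
        slack = region - base_span
        if slack < 0:
            raise ValueError(f"region of {region} residues too small for {n} cysteines")
        extra = rng.multinomial(slack, np.full(len(sizes) + 1, 1.0 / (len(sizes) + 1)))
        positions: list[int] = []
        pos = lo + int(extra[0])
        gi = iter(gaps)
        for k, size in enumerate(sizes):
            for m in range(size):
                positions.append(pos)
                pos += next(gi) if m < size - 1 else 1
            pos += 1 + int(extra[k + 1])  # spacer (>=2 from last cysteine)
        if positions[-1] < hi:
            return positions
    raise ValueError("could not place cysteines")


def simulate_mt_protein(
    isoform: str,
    rng: np.random.Generator,
    length_aa: int | None = None,
    beta_len: int | None = None,
    score_config: ScoreConfig = ScoreConfig(),
) -> str:
    """Emit a protein satisfying the MT structural grammar.

    Exactly 20 cysteines: 9 in the N-terminal β segment and 11 in the
    C-terminal α segment, every one engaged in a CC/CXC/CXXC motif.
    ``length_aa`` defaults to a draw from the isoform's envelope
    (61–68; Mt3 runs longer to cover its longer exon III).  The emitted
    protein is checked against :func:`mtminer.detect.score_mt_protein`.
    """
    if length_aa is None:
        length_aa = int(rng.integers(66, 68)) if isoform == "Mt3" else int(rng.integers(61, 64))
    if beta_len is None:
        beta_len = length_aa // 2
    beta = _place_cys(1, beta_len, 9, rng)
    alpha = _place_cys(beta_len, length_aa, 11, rng)
    residues = [_FILLER[int(rng.integers(0, len(_FILLER)))] for _ in range(length_aa)]
    residues[0] = "M"
    for p in beta + alpha:
        residues[p] = "C"
    protein = "".join(residues)
    score = score_mt_protein(protein, score_config)
    if not score.passed:  # construction guarantees this; belt and braces
        raise AssertionError("generated protein fails the MT score")
    return protein


# ---------------------------------------------------------------------------
# Coding-sequence evolution

def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_BY_AA[aa][int(rng.integers(0, len(_BY_AA[aa])))] for aa in protein)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def diverge_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at ``rate`` while preserving the MT grammar.

    Protected: the start codon, the stop codon, and any change that
    would turn a cysteine codon non-cysteine or create an in-frame
    stop.  Proposals hitting a protected site are dropped, not
    redrawn, so the realized rate is slightly below nominal.
    """
    chars = list(cds)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        i = int(i)
        if i < 3 or i >= len(chars) - 3:
            continue
        codon_start = 3 * (i // 3)
        old_codon = "".join(chars[codon_start : codon_start + 3])
        new_base = "ACGT"[int(rng.integers(0, 4))]
        if new_base == chars[i]:
            continue
        new = list(old_codon)
        new[i - codon_start] = new_base
        new_codon = "".join(new)
        if new_codon in _STOP_CODONS:
            continue
        if old_codon in ("TGT", "TGC") and new_codon not in ("TGT", "TGC"):
            continue
        chars[i] = new_base
    return "".join(chars)


def _derive_seed(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % (2**31 - 1)


def ancestral_genes(config: SimulationConfig) -> dict[str, AncestralGene]:
    """Isoform-level ancestors shared by every simulated species.

    A single root coding sequence is built from the grammar, each
    isoform draws its exon lengths (constrained to a codon multiple,
    the stop codon bookkept inside exon III), extends the root with
    C-terminal filler to match, and diverges at
    ``config.isoform_divergence``.  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, 20731))
    root_protein = simulate_mt_protein("root", rng, length_aa=61, beta_len=31)
    root_core = _reverse_translate(root_protein, rng)  # no stop codon yet
    ancestors: dict[str, AncestralGene] = {}
    for isoform in ISOFORM_ORDER:
        ranges = config.exon_length_ranges[isoform]
        for _ in range(100):
            exon_lens = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in ranges)
            if sum(exon_lens) % 3 == 0:
                break
        else:
            raise ValueError(f"no codon-multiple exon combination for {isoform}")
        length_aa = sum(exon_lens) // 3 - 1
        if length_aa < len(root_protein):
            raise ValueError("exon draw shorter than the root protein")
        tail = "".join(
            _FILLER[int(rng.integers(0, len(_FILLER)))]
            for _ in range(length_aa - len(root_protein))
        )
        cds = root_core + _reverse_translate(tail, rng) + _STOPS[int(rng.integers(0, 2))]
        cds = diverge_cds(cds, config.isoform_divergence, rng)
        ancestors[isoform] = AncestralGene(
            isoform=isoform,
            exon_lengths=exon_lens,  # type: ignore[arg-type]
            cds=cds,
            protein=translate_cds(cds),
        )
    return ancestors


def reference_records(config: SimulationConfig) -> dict[str, list[SequenceRecord]]:
    """The isoform ancestors as reference CDS records (detection refs)."""
    return {
        isoform: [
            SequenceRecord(
                id=f"{isoform}_anc",
                residues=anc.cds,
                moltype="nucleotide",
                description=f"synthetic ancestral {isoform} CDS",
            )
        ]
        for isoform, anc in ancestral_genes(config).items()
    }


def make_reference_set(
    seed: int = 97, config: SimulationConfig | None = None
) -> dict[str, list[SequenceRecord]]:
    """Free-standing synthetic exemplar CDS per isoform.

    Built from the grammar with its own seed; used as a stand-in when
    no curated reference FASTA is supplied.  For annotating simulated
    genomes, use :func:`reference_records` of the same config instead.
    """
    return reference_records(config or SimulationConfig(seed=seed))


# ---------------------------------------------------------------------------
# Gene and genome construction

def simulate_gene(
    isoform: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    intron_free: bool | None = None,
    ancestor: AncestralGene | None = None,
) -> tuple[str, ExonModel]:
    """One synthetic MT gene: sequence plus gene-relative annotation.

    The species copy diverges from the isoform ancestor at
    ``config.species_divergence``; introns are drawn fresh (lengths
    from the configured envelope, GT..AG with uniform random interior).
    ``intron_free`` forces or suppresses the single-exon
    (retrocopy-like) form; by default Mt1 genes go intron-free with
    probability ``config.intron_free_mt1_prob``.
    """
    if ancestor is None:
        ancestor = ancestral_genes(config)[isoform]
    e1, e2, e3 = ancestor.exon_lengths
    cds = diverge_cds(ancestor.cds, config.species_divergence, rng)
    protein = translate_cds(cds)
    score = score_mt_protein(protein)
    if not score.passed:
        raise AssertionError("species copy fails the MT score")

    if intron_free is None:
        intron_free = isoform == "Mt1" and rng.random() < config.intron_free_mt1_prob

    if intron_free:
        gene_seq = cds
        exons: tuple[tuple[int, int], ...] = ((0, len(cds)),)
    else:
        intron_lens = tuple(
            int(rng.integers(lo, hi + 1)) for lo, hi in config.intron_length_ranges[isoform]
        )
        i1, i2 = intron_lens
        introns = tuple("GT" + _random_seq(ln - 4, rng) + "AG" for ln in intron_lens)
        gene_seq = cds[:e1] + introns[0] + cds[e1 : e1 + e2] + introns[1] + cds[e1 + e2 :]
        exons = (
            (0, e1),
            (e1 + i1, e1 + i1 + e2),
            (e1 + i1 + e2 + i2, e1 + i1 + e2 + i2 + e3),
        )
    model = ExonModel(
        gene_id=f"{isoform}_gene",
        contig_id="relative",
        strand="+",
        exons=exons,
        cds=cds,
        protein=protein,
        isoform=isoform,
    )
    return gene_seq, model


def _shift(
    model: ExonModel, offset: int, gene_id: str, contig_id: str, copy_label: str | None
) -> ExonModel:
    return ExonModel(
        gene_id=gene_id,
        contig_id=contig_id,
        strand=model.strand,
        exons=tuple((a + offset, b + offset) for a, b in model.exons),
        cds=model.cds,
        protein=model.protein,
        isoform=model.isoform,
        copy_label=copy_label,
    )


def simulate_cluster_genome(
    config: SimulationConfig,
    contig_id: str | None = None,
    seed: int | None = None,
    ancestors: dict[str, AncestralGene] | None = None,
) -> TruthSet:
    """Simulate one contig carrying a full MT cluster.

    Genes are placed co-oriented on the forward strand in layout order,
    separated by IGR draws and flanked by random sequence.  With
    probability ``intron_free_mt1_prob`` a dispersed intron-free Mt1
    copy lands in the downstream flank.  Point mutations (if any) are
    applied outside splice dinucleotides and start/stop codons, so the
    truth coordinates are mutation-invariant.
    """
    seed = config.seed if seed is None else seed
    contig_id = contig_id or f"synthetic_cluster_{seed}"
    if ancestors is None:
        ancestors = ancestral_genes(config)
    rng = np.random.default_rng(_derive_seed(seed, 9176))
    pieces: list[str] = [_random_seq(config.flank_length, rng)]
    pos = config.flank_length
    annotations: list[ExonModel] = []
    igr_draws: list[tuple[str, str, int]] = []

    layout = config.cluster_layout
    for idx, label in enumerate(layout):
        isoform = label[:3]
        copy_label = label[3:] or None
        gene_seq, rel = simulate_gene(
            isoform, config, rng, intron_free=False, ancestor=ancestors[isoform]
        )
        gene_id = f"{contig_id}_{label}"
        annotations.append(_shift(rel, pos, gene_id, contig_id, copy_label))
        pieces.append(gene_seq)
        pos += len(gene_seq)
        if idx + 1 < len(layout):
            nxt = layout[idx + 1]
            lo, hi = config.igr_ranges.get((label, nxt), (3000, 5000))
            igr = int(rng.integers(lo, hi + 1))
            igr_draws.append((gene_id, f"{contig_id}_{nxt}", igr))
            pieces.append(_random_seq(igr, rng))
            pos += igr

    if rng.random() < config.intron_free_mt1_prob:
        offset = int(rng.integers(2000, 4001))
        pieces.append(_random_seq(offset, rng))
        pos += offset
        gene_seq, rel = simulate_gene(
            "Mt1", config, rng, intron_free=True, ancestor=ancestors["Mt1"]
        )
        annotations.append(_shift(rel, pos, f"{contig_id}_Mt1_retro", contig_id, None))
        pieces.append(gene_seq)
        pos += len(gene_seq)

    pieces.append(_random_seq(config.flank_length, rng))
    sequence = "".join(pieces)

    if config.mutation_rate > 0:
        sequence = _mutate(sequence, annotations, config.mutation_rate, rng)

    contig = SequenceRecord(id=contig_id, residues=sequence, moltype="nucleotide")
    return TruthSet(
        contig=contig,
        annotations=tuple(annotations),
        igr_draws=tuple(igr_draws),
        config=config,
        seed=seed,
    )


def _protected_positions(annotations: list[ExonModel]) -> set[int]:
    protected: set[int] = set()
    for model in annotations:
        protected.update(range(model.start, model.start + 3))  # start codon
        protected.update(range(model.end - 3, model.end))  # stop codon
        for (_, e0), (s1, _) in zip(model.exons, model.exons[1:]):
            protected.update((e0, e0 + 1))  # GT donor
            protected.update((s1 - 2, s1 - 1))  # AG acceptor
    return protected


def _mutate(
    sequence: str,
    annotations: list[ExonModel],
    rate: float,
    rng: np.random.Generator,
) -> str:
    hits = np.flatnonzero(rng.random(len(sequence)) < rate)
    protected = _protected_positions(annotations)
    chars = list(sequence)
    for i in hits:
        i = int(i)
        if i in protected:
            continue
        options = [b for b in "ACGT" if b != chars[i]]
        chars[i] = options[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_species(config: SimulationConfig) -> list[TruthSet]:
    """One cluster genome per species, sharing the isoform ancestors."""
    ancestors = ancestral_genes(config)
    return [
        simulate_cluster_genome(
            config,
            contig_id=f"species_{i + 1}",
            seed=_derive_seed(config.seed, 51 + i),
            ancestors=ancestors,
        )
        for i in range(config.species_count)
    ]
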