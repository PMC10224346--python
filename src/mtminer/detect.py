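"""Nomination of candidate MT loci: ORF scanning, cysteine-motif
scoring and seeded similarity search.

Metallothioneins have a tight structural grammar: 61–68 residues,
cysteine fraction above 30%, cysteines arranged in Cys-Cys, Cys-X-Cys
and Cys-X-X-Cys motifs, and a two-domain layout — an N-terminal β
domain whose nine cysteines bind three metal cations and a C-terminal α
domain whose eleven cysteines bind four.  :func:`score_mt_protein`
turns those constraints into a [0, 1] score with one component per
constraint.

Database similarity search is replaced by an in-house exact k-mer seed
search with co-linear chaining (:func:`find_candidate_loci`); the gap
allowance while chaining accommodates introns so one chain can span a
whole three-exon gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequences import SequenceRecord, reverse_complement, translate_cds

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


# ---------------------------------------------------------------------------
# ORF scanning

def find_orfs(
    contig: SequenceRecord, min_len_aa: int
) -> list[tuple[tuple[int, int], str, SequenceRecord]]:
    """Scan all six frames for ORFs (ATG → stop, stop included).

    Every ATG with an in-frame downstream stop is reported (nested ORFs
    sharing a stop are all emitted).  Coordinates are contig-relative,
    0-based half-open on the forward strand; the protein excludes the
    stop.  ``min_len_aa`` filters on protein length.
    """
    if contig.moltype != "nucleotide":
        raise ValueError("contig must be nucleotide")
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    seq = contig.residues
    if seq.count("N") > len(seq) / 2:
        raise ValueError("low-complexity contig")
    results = []
    n = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            starts: list[int] = []
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon == "ATG":
                    starts.append(pos)
                elif codon in STOP_CODONS:
                    for start in starts:
                        aa_len = (pos - start) // 3
                        if aa_len >= min_len_aa:
                            interval = (start, pos + 3)
                            if strand == "-":
                                interval = (n - interval[1], n - interval[0])
                            protein = translate_cds(s[start : pos + 3])
                            results.append(
                                (
                                    interval,
                                    strand,
                                    SequenceRecord(
                                        id=f"{contig.id}_orf_{interval[0]}_{interval[1]}_{strand}",
                                        residues=protein,
                                        moltype="protein",
                                    ),
                                )
                            )
                    starts = []
    results.sort(key=lambda r: (r[0], r[1]))
    return results


# ---------------------------------------------------------------------------
# Cysteine-motif profile and MT-likeness score

def count_cys_motifs(protein: SequenceRecord | str) -> dict[str, int]:
    """Count (overlapping) CC, CXC and CXXC motifs left to right.

    X matches any residue that is not a cysteine.
    """
    p = protein.residues if isinstance(protein, SequenceRecord) else protein
    counts = {"CC": 0, "CXC": 0, "CXXC": 0}
    for i in range(len(p)):
        if p[i] != "C":
            continue
        if i + 1 < len(p) and p[i + 1] == "C":
            counts["CC"] += 1
        if i + 2 < len(p) and p[i + 1] != "C" and p[i + 2] == "C":
            counts["CXC"] += 1
        if (
            i + 3 < len(p)
            and p[i + 1] != "C"
            and p[i + 2] != "C"
            and p[i + 3] == "C"
        ):
            counts["CXXC"] += 1
    return counts


@dataclass(frozen=True)
class MtProteinProfile:
    """Structural summary of a candidate MT protein."""

    length_aa: int
    cys_count: int
    cys_fraction: float
    motif_counts: dict[str, int]
    beta_cys: int
    alpha_cys: int
    linker_index: int


@dataclass(frozen=True)
class ScoreConfig:
    """Weights and thresholds for :func:`score_mt_protein`.

    The length component peaks on ``length_core`` (the canonical 61–68
    aa span) and decays linearly to zero at ``length_halo``.  The
    domain-layout component is exact when some split point puts 9 ± tol
    cysteines on the β side and 11 ± tol on the α side.
    """

    length_core: tuple[int, int] = (61, 68)
    length_halo: tuple[int, int] = (57, 72)
    cys_fraction_target: float = 0.30
    domain_targets: tuple[int, int] = (9, 11)
    domain_tolerance: int = 1
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "length": 1.0,
            "cys_fraction": 1.0,
            "motif": 1.0,
            "domain_layout": 1.0,
        }
    )
    threshold: float = 0.75


@dataclass(frozen=True)
class MtScore:
    total: float
    components: dict[str, float]
    passed: bool
    profile: MtProteinProfile


def _motif_participation(p: str) -> set[int]:
    """Positions of cysteines participating in at least one motif."""
    members: set[int] = set()
    for i in range(len(p)):
        if p[i] != "C":
            continue
        for j in (i + 1, i + 2, i + 3):
            if j < len(p) and p[j] == "C" and all(
                p[k] != "C" for k in range(i + 1, j)
            ):
                members.add(i)
                members.add(j)
    return members


def profile_protein(protein: SequenceRecord | str, config: ScoreConfig = ScoreConfig()) -> MtProteinProfile:
    """Build the :class:`MtProteinProfile`, choosing the β/α linker as
    the split point closest to the 9/11 cysteine stoichiometry."""
    p = protein.residues if isinstance(protein, SequenceRecord) else protein
    cys_positions = [i for i, c in enumerate(p) if c == "C"]
    cys_count = len(cys_positions)
    beta_target, alpha_target = config.domain_targets
    best_split, best_key = 0, (float("inf"), float("inf"))
    for split in range(1, len(p)):
        beta = sum(1 for i in cys_positions if i < split)
        alpha = cys_count - beta
        dev = max(0, abs(beta - beta_target) - config.domain_tolerance) + max(
            0, abs(alpha - alpha_target) - config.domain_tolerance
        )
        # prefer the split closest to the exact 9/11 stoichiometry among
        # equally tolerable ones
        key = (dev, abs(beta - beta_target) + abs(alpha - alpha_target))
        if key < best_key:
            best_key, best_split = key, split
    beta = sum(1 for i in cys_positions if i < best_split)
    return MtProteinProfile(
        length_aa=len(p),
        cys_count=cys_count,
        cys_fraction=cys_count / len(p) if p else 0.0,
        motif_counts=count_cys_motifs(p),
        beta_cys=beta,
        alpha_cys=cys_count - beta,
        linker_index=best_split,
    )


def score_mt_protein(
    protein: SequenceRecord | str, config: ScoreConfig = ScoreConfig()
) -> MtScore:
    """Score a protein against the MT structural grammar.

    Components (each in [0, 1]): canonical length, cysteine fraction,
    fraction of cysteines engaged in CC/CXC/CXXC motifs, and β/α domain
    cysteine stoichiometry.  The total is the weighted mean; ``passed``
    applies the configured threshold.
    """
    p = protein.residues if isinstance(protein, SequenceRecord) else protein
    if isinstance(protein, SequenceRecord) and protein.moltype != "protein":
        raise ValueError("score_mt_protein requires a protein record")
    if len(p) < 20:
        raise ValueError("protein shorter than 20 residues")
    profile = profile_protein(p, config)

    lo, hi = config.length_core
    halo_lo, halo_hi = config.length_halo
    L = profile.length_aa
    if lo <= L <= hi:
        length_comp = 1.0
    elif halo_lo < L < lo:
        length_comp = (L - halo_lo) / (lo - halo_lo)
    elif hi < L < halo_hi:
        length_comp = (halo_hi - L) / (halo_hi - hi)
    else:
        length_comp = 0.0

    frac = profile.cys_fraction
    cys_comp = 1.0 if frac > config.cys_fraction_target else frac / config.cys_fraction_target

    if profile.cys_count:
        motif_comp = len(_motif_participation(p)) / profile.cys_count
    else:
        motif_comp = 0.0

    beta_target, alpha_target = config.domain_targets
    dev = max(0, abs(profile.beta_cys - beta_target) - config.domain_tolerance) + max(
        0, abs(profile.alpha_cys - alpha_target) - config.domain_tolerance
    )
    domain_comp = max(0.0, 1.0 - dev / 4.0)

    components = {
        "length": length_comp,
        "cys_fraction": cys_comp,
        "motif": motif_comp,
        "domain_layout": domain_comp,
    }
    wsum = sum(config.weights.values())
    total = sum(config.weights[k] * components[k] for k in components) / wsum
    return MtScore(
        total=total,
        components=components,
        passed=total >= config.threshold,
        profile=profile,
    )


# ---------------------------------------------------------------------------
# Seeded similarity search

@dataclass(frozen=True)
class SeedSearchConfig:
    k: int = 11
    min_seeds: int = 10  # distinct ref offsets; beyond any chance exact repeat
    chain_gap: int = 10_000  # bp; generous enough to jump introns
    flank: int = 2_000  # bp of padding around a chained window


@dataclass(frozen=True)
class LocusHit:
    """A candidate MT locus: a contig window supported by seed chains."""

    contig_id: str
    window: tuple[int, int]
    strand: str
    best_ref_id: str
    seed_count: int
    score: float


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _chain_matches(
    matches: list[tuple[int, int]], chain_gap: int
) -> list[list[tuple[int, int]]]:
    """Greedy co-linear chaining of (contig_pos, ref_pos) seed matches."""
    chains: list[list[tuple[int, int]]] = []
    for cpos, rpos in sorted(matches):
        placed = False
        for chain in chains:
            last_c, last_r = chain[-1]
            if 0 < cpos - last_c <= chain_gap and rpos >= last_r:
                chain.append((cpos, rpos))
                placed = True
                break
        if not placed:
            chains.append([(cpos, rpos)])
    return chains


def find_candidate_loci(
    contig: SequenceRecord,
    refs: list[SequenceRecord],
    config: SeedSearchConfig = SeedSearchConfig(),
) -> list[LocusHit]:
    """Locate windows of the contig similar to any reference CDS.

    Exact k-mer seeds between each reference (both orientations) and
    the contig are chained when co-linear within ``chain_gap`` (so a
    chain can span introns), chains with at least ``min_seeds`` seeds
    become windows padded by ``flank``, and overlapping windows are
    merged, keeping the reference with the strongest chain.  Hits are
    sorted by descending seed count.
    """
    k = config.k
    for ref in refs:
        if k > len(ref.residues):
            raise ValueError(f"k={k} larger than reference {ref.id} length")
    index = _kmer_index(contig.residues, k)
    n = len(contig.residues)
    raw_hits: list[LocusHit] = []
    for ref in refs:
        for strand, oriented in (("+", ref.residues), ("-", reverse_complement(ref.residues))):
            matches = []
            for rpos in range(len(oriented) - k + 1):
                kmer = oriented[rpos : rpos + k]
                for cpos in index.get(kmer, ()):
                    matches.append((cpos, rpos))
            for chain in _chain_matches(matches, config.chain_gap):
                # count distinct reference offsets so a repetitive k-mer
                # matching many contig positions cannot fake a chain
                distinct = len({rpos for _, rpos in chain})
                if distinct < config.min_seeds:
                    continue
                start = max(0, chain[0][0] - config.flank)
                end = min(n, chain[-1][0] + k + config.flank)
                raw_hits.append(
                    LocusHit(
                        contig_id=contig.id,
                        window=(start, end),
                        strand=strand,
                        best_ref_id=ref.id,
                        seed_count=distinct,
                        score=float(distinct),
                    )
                )
    # merge overlapping windows, keeping the strongest chain's metadata
    raw_hits.sort(key=lambda h: h.window)
    merged: list[LocusHit] = []
    for hit in raw_hits:
        if merged and hit.window[0] < merged[-1].window[1]:
            prev = merged[-1]
            best = max(prev, hit, key=lambda h: h.seed_count)
            merged[-1] = LocusHit(
                contig_id=contig.id,
                window=(prev.window[0], max(prev.window[1], hit.window[1])),
                strand=best.strand,
                best_ref_id=best.best_ref_id,
                seed_count=best.seed_count,
                score=best.score,
            )
        else:
            merged.append(hit)
    merged.sort(key=lambda h: (-h.seed_count, h.window))
    return merged
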