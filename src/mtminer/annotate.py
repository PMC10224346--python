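"""Spliced alignment of a reference MT coding sequence against a
genomic window, and derivation of the three-exon gene model.

The aligner is a semi-global dynamic program: the full reference CDS is
aligned, the window's flanks are free.  Long contig-only gaps are
scored as introns at a flat penalty, but only when the gap starts with
the donor dinucleotide GT and ends with the acceptor AG (GC..AG
optionally allowed at an extra penalty).  Because an intron must start
with GT, shifting a recovered intron by one base would need the base
after the donor to be both G and T at once — exon/intron boundaries are
therefore unambiguous on unmutated sequence, which is what makes exact
boundary recovery on synthetic truth sets possible.

The O(m·n) matrix fill is a numba-compiled kernel; the maximum intron
length is enforced by the window size handed to the aligner (windows
are gene spans plus a couple of kb of flank, far below the configured
cap) while the minimum is enforced inside the recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .models import (
    FLAG_EXON_COUNT_ATYPICAL,
    FLAG_INTERNAL_STOP,
    FLAG_NON_ATG_START,
    FLAG_TGA_STOP,
    ExonModel,
)
from .sequences import SequenceRecord, reverse_complement, translate_cds, translate_full
from .detect import ScoreConfig, score_mt_protein


class NoSplicedModelError(ValueError):
    """No spliced alignment reached the identity threshold."""


class PartialModelError(ValueError):
    """The alignment covers too little of the reference CDS."""


@dataclass(frozen=True)
class SplicedAlignParams:
    match: float = 2.0
    mismatch: float = -3.0
    gap: float = -4.0
    intron_penalty: float = 12.0  # flat cost per intron, length-free
    min_intron: int = 60
    max_intron: int = 50_000
    gc_ag_allowed: bool = False
    gc_ag_extra_penalty: float = 8.0
    min_identity: float = 0.8
    min_ref_coverage: float = 0.95


@dataclass(frozen=True)
class SplicedAlignment:
    """Blocks (exon pieces) plus introns from one spliced alignment.

    Intervals are 0-based half-open.  Contig intervals refer to the
    forward strand of the aligned window; for strand '-' the reference
    matched the reverse complement and block order in contig
    coordinates is the reverse of transcription order.
    """

    ref_id: str
    contig_id: str
    strand: str
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]  # (ref, contig)
    introns: tuple[tuple[tuple[int, int], str, str], ...]  # (contig interval, donor, acceptor)
    identity: float
    score: float
    ref_coverage: float
    ref_length: int


_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int8)


@njit(cache=False)
def _spliced_dp(ref, ctg, match, mismatch, gap, intron_pen, gc_pen, min_intron, allow_gc):
    m = ref.shape[0]
    n = ctg.shape[0]
    NEG = -1e18
    H = np.full((m + 1, n + 1), NEG)
    MOVE = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1 diag, 2 up, 3 left, 4 intron
    DONOR = np.full((m + 1, n + 1), -1, dtype=np.int64)
    for j in range(n + 1):
        H[0, j] = 0.0
    for i in range(1, m + 1):
        H[i, 0] = H[i - 1, 0] + gap
        MOVE[i, 0] = 2
    for i in range(1, m + 1):
        best_gt = NEG
        best_gt_a = -1
        best_gc = NEG
        best_gc_a = -1
        for j in range(1, n + 1):
            a = ref[i - 1]
            b = ctg[j - 1]
            if a == b and a < 4:
                h = H[i - 1, j - 1] + match
            else:
                h = H[i - 1, j - 1] + mismatch
            mv = 1
            up = H[i - 1, j] + gap
            if up > h:
                h = up
                mv = 2
            left = H[i, j - 1] + gap
            if left > h:
                h = left
                mv = 3
            if i < m:
                # admit donors whose intron would satisfy the minimum length
                da = j - min_intron
                if da >= 0 and da + 1 < n:
                    if ctg[da] == 2 and ctg[da + 1] == 3:  # G, T
                        if H[i, da] > best_gt:
                            best_gt = H[i, da]
                            best_gt_a = da
                    if allow_gc and ctg[da] == 2 and ctg[da + 1] == 1:  # G, C
                        if H[i, da] > best_gc:
                            best_gc = H[i, da]
                            best_gc_a = da
                # close an intron at an acceptor AG ending at j
                if j >= 2 and ctg[j - 2] == 0 and ctg[j - 1] == 2:  # A, G
                    cand = best_gt - intron_pen
                    cand_a = best_gt_a
                    if allow_gc and best_gc - intron_pen - gc_pen > cand:
                        cand = best_gc - intron_pen - gc_pen
                        cand_a = best_gc_a
                    if cand_a >= 0 and cand > h:
                        h = cand
                        mv = 4
                        DONOR[i, j] = cand_a
            H[i, j] = h
            MOVE[i, j] = mv
    return H, MOVE, DONOR


def spliced_align(
    ref_cds: SequenceRecord,
    window: SequenceRecord,
    params: SplicedAlignParams = SplicedAlignParams(),
    strand: str = "both",
) -> SplicedAlignment:
    """Align a complete reference CDS against a genomic window.

    Both orientations are tried unless ``strand`` pins one; the higher
    scoring orientation wins ('+' on ties).  Raises
    :class:`NoSplicedModelError` when the best alignment's identity
    falls below ``params.min_identity``.
    """
    candidates = []
    strands = ("+", "-") if strand == "both" else (strand,)
    for s in strands:
        target = window.residues if s == "+" else reverse_complement(window.residues)
        aln = _align_one(ref_cds, window.id, target, s, len(window.residues), params)
        candidates.append(aln)
    best = max(candidates, key=lambda a: (a.score, a.strand == "+"))
    if best.identity < params.min_identity:
        raise NoSplicedModelError(
            f"no spliced model: best identity {best.identity:.3f} below "
            f"{params.min_identity} for ref {ref_cds.id} in {window.id}"
        )
    return best


def _align_one(
    ref_cds: SequenceRecord,
    contig_id: str,
    target: str,
    strand: str,
    window_len: int,
    params: SplicedAlignParams,
) -> SplicedAlignment:
    ref = _encode(ref_cds.residues)
    ctg = _encode(target)
    H, MOVE, DONOR = _spliced_dp(
        ref,
        ctg,
        params.match,
        params.mismatch,
        params.gap,
        params.intron_penalty,
        params.gc_ag_extra_penalty,
        params.min_intron,
        params.gc_ag_allowed,
    )
    m, n = len(ref), len(ctg)
    final = H[m, :]
    j = int(np.argmax(final))  # first maximum -> earliest contig end on ties
    score = float(final[j])
    # traceback
    i = m
    columns: list[tuple[int, int, str]] = []  # (ref_i, ctg_j, kind)
    introns: list[tuple[int, int]] = []
    while i > 0:
        mv = MOVE[i, j]
        if mv == 0:
            break
        if mv == 1:
            columns.append((i - 1, j - 1, "diag"))
            i -= 1
            j -= 1
        elif mv == 2:
            columns.append((i - 1, -1, "up"))
            i -= 1
        elif mv == 3:
            columns.append((-1, j - 1, "left"))
            j -= 1
        else:  # intron
            donor = int(DONOR[i, j])
            introns.append((donor, j))
            j = donor
    columns.reverse()
    introns.reverse()

    # group aligned columns into blocks separated by introns
    intron_set = sorted(introns)
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = []
    cur_ref: list[int] = []
    cur_ctg: list[int] = []

    def flush() -> None:
        if cur_ref and cur_ctg:
            blocks.append(
                (
                    (min(cur_ref), max(cur_ref) + 1),
                    (min(cur_ctg), max(cur_ctg) + 1),
                )
            )
        cur_ref.clear()
        cur_ctg.clear()

    next_boundary = 0
    matches = 0
    diag_cols = 0
    aligned_cols = 0
    for ri, cj, kind in columns:
        while next_boundary < len(intron_set) and cj >= 0 and cj >= intron_set[next_boundary][1]:
            flush()
            next_boundary += 1
        aligned_cols += 1
        if kind == "diag":
            diag_cols += 1
            if ref_cds.residues[ri] == target[cj] and target[cj] != "N":
                matches += 1
            cur_ref.append(ri)
            cur_ctg.append(cj)
    flush()

    identity = matches / aligned_cols if aligned_cols else 0.0
    # reference positions actually placed on the contig (gap columns in
    # either sequence do not count as coverage)
    coverage = diag_cols / m if m else 0.0

    intron_records = tuple(
        ((a, b), target[a : a + 2], target[b - 2 : b]) for a, b in intron_set
    )
    if strand == "-":
        blocks = [
            (rint, (window_len - c1, window_len - c0)) for rint, (c0, c1) in blocks
        ][::-1]
        intron_records = tuple(
            ((window_len - b, window_len - a), don, acc)
            for (a, b), don, acc in intron_records
        )[::-1]
    return SplicedAlignment(
        ref_id=ref_cds.id,
        contig_id=contig_id,
        strand=strand,
        blocks=tuple(blocks),
        introns=intron_records,
        identity=identity,
        score=score,
        ref_coverage=coverage,
        ref_length=m,
    )


# ---------------------------------------------------------------------------
# Gene model derivation and validation

def alignment_to_gene_model(
    aln: SplicedAlignment,
    window_seq: str,
    gene_id: str,
    contig_id: str | None = None,
    window_offset: int = 0,
    params: SplicedAlignParams = SplicedAlignParams(),
    allow_partial: bool = False,
) -> ExonModel:
    """Turn a spliced alignment into an :class:`ExonModel`.

    ``window_seq`` is the forward-strand sequence the alignment's contig
    coordinates refer to; ``window_offset`` shifts the exon intervals
    into full-contig coordinates.  A reference coverage below
    ``params.min_ref_coverage`` raises :class:`PartialModelError`
    unless ``allow_partial`` is set, in which case the model is emitted
    carrying the ``exon_count_atypical`` flag.
    """
    flags = set()
    if aln.ref_coverage < params.min_ref_coverage:
        if not allow_partial:
            raise PartialModelError(
                f"partial model: ref coverage {aln.ref_coverage:.2f} below "
                f"{params.min_ref_coverage}"
            )
        flags.add(FLAG_EXON_COUNT_ATYPICAL)
    exon_intervals = tuple(sorted((c0, c1) for _, (c0, c1) in aln.blocks))
    pieces = [window_seq[a:b] for a, b in exon_intervals]
    if aln.strand == "+":
        cds = "".join(pieces)
    else:
        cds = reverse_complement("".join(pieces))
    protein = translate_cds(cds) if len(cds) >= 3 else ""
    if not cds.startswith("ATG"):
        flags.add(FLAG_NON_ATG_START)
    if cds[-3:] == "TGA":
        flags.add(FLAG_TGA_STOP)
    full = translate_full(cds)
    if "*" in full[:-1]:
        flags.add(FLAG_INTERNAL_STOP)
    if len(exon_intervals) not in (1, 3):
        flags.add(FLAG_EXON_COUNT_ATYPICAL)
    exons = tuple((a + window_offset, b + window_offset) for a, b in exon_intervals)
    return ExonModel(
        gene_id=gene_id,
        contig_id=contig_id or aln.contig_id,
        strand=aln.strand,
        exons=exons,
        cds=cds,
        protein=protein,
        flags=frozenset(flags),
    )


#: exon-length envelopes observed across the four isoforms
EXON1_ENVELOPE = (28, 31)
EXON2_ALLOWED = (66, 81)
EXON3_ALLOWED = frozenset({92, 104, 105, 106, 107})


def validate_gene_model(
    model: ExonModel, score_config: ScoreConfig = ScoreConfig()
) -> tuple[bool, list[str]]:
    """Check a gene model against the canonical MT gene structure.

    Failures are returned as diagnostics, never raised.  A TGA stop
    demotes to a warning (prefixed ``warning:``) because the canonical
    MT stop is TAA/TAG; warnings do not fail the model.
    """
    diagnostics: list[str] = []
    if not model.cds.startswith("ATG"):
        diagnostics.append("CDS does not start with ATG")
    stop = model.stop_codon
    if stop == "TGA":
        diagnostics.append("warning: TGA stop codon (canonical MT stop is TAA/TAG)")
    elif stop not in ("TAA", "TAG"):
        diagnostics.append(f"CDS does not end with a stop codon (saw {stop})")
    if FLAG_INTERNAL_STOP in model.flags or "*" in translate_full(model.cds)[:-1]:
        diagnostics.append("internal stop codon in spliced CDS")
    if len(model.cds) % 3:
        diagnostics.append("spliced CDS length not divisible by 3")
    n_exons = len(model.exons)
    if n_exons not in (1, 3):
        diagnostics.append(f"atypical exon count {n_exons}")
    if n_exons == 3:
        e1, e2, e3 = model.exon_lengths
        if not (EXON1_ENVELOPE[0] <= e1 <= EXON1_ENVELOPE[1]):
            diagnostics.append(f"exon I length {e1} outside envelope 28-31")
        if e2 not in EXON2_ALLOWED:
            diagnostics.append(f"exon II length {e2} outside envelope (66; 81 tolerated)")
        if e3 not in EXON3_ALLOWED:
            diagnostics.append(f"exon III length {e3} outside envelope (92 or 104-107)")
    try:
        score = score_mt_protein(model.protein, score_config)
        if not score.passed:
            diagnostics.append(
                f"protein fails MT-likeness score ({score.total:.2f} < {score_config.threshold})"
            )
    except ValueError as exc:
        diagnostics.append(f"protein not scorable: {exc}")
    ok = not any(not d.startswith("warning:") for d in diagnostics)
    return ok, diagnostics


__all__ = [
    "NoSplicedModelError",
    "PartialModelError",
    "SplicedAlignParams",
    "SplicedAlignment",
    "spliced_align",
    "alignment_to_gene_model",
    "validate_gene_model",
    "translate_cds",
]
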