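"""Gene-model containers shared across annotation, architecture and I/O.

Coordinate convention: every interval held in memory is 0-based,
half-open ``(start, end)`` on the forward strand of the contig.  The
GFF3 reader/writer in :mod:`mtminer.io` is the only place where the
shift to 1-based inclusive coordinates happens.
"""

from __future__ import annotations

from dataclasses import dataclass

ISOFORMS = ("Mt1", "Mt2", "Mt3", "Mt4")

#: validation / annotation flags an ExonModel may carry
FLAG_NON_ATG_START = "non_ATG_start"
FLAG_TGA_STOP = "TGA_stop"
FLAG_INTERNAL_STOP = "internal_stop"
FLAG_EXON_COUNT_ATYPICAL = "exon_count_atypical"

KNOWN_FLAGS = frozenset(
    {FLAG_NON_ATG_START, FLAG_TGA_STOP, FLAG_INTERNAL_STOP, FLAG_EXON_COUNT_ATYPICAL}
)


@dataclass
class ExonModel:
    """An annotated MT gene: up to three exons, spliced CDS and protein.

    ``exons`` are contig intervals in ascending coordinate order; for a
    minus-strand gene the transcription order is the reverse.  The gene
    span runs from the start codon through the stop codon inclusive, so
    the stop codon lies inside the last (transcription-order) exon.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: str
    protein: str
    isoform: str = "unknown"
    copy_label: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        if not exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for a, b in exons:
            if a >= b:
                raise ValueError(f"gene {self.gene_id}: empty exon interval ({a},{b})")
        if list(exons) != sorted(exons):
            raise ValueError(f"gene {self.gene_id}: exons not coordinate-sorted")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 <= e0:
                raise ValueError(f"gene {self.gene_id}: overlapping/abutting exons")
        self.exons = exons
        self.flags = frozenset(self.flags)
        unknown = self.flags - KNOWN_FLAGS
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Gene span (ATG through stop codon) as a half-open interval."""
        return (self.start, self.end)

    @property
    def intron_free(self) -> bool:
        return len(self.exons) == 1

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        """Exon lengths in transcription (5'→3') order."""
        lengths = tuple(b - a for a, b in self.exons)
        return lengths if self.strand == "+" else lengths[::-1]

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        gaps = tuple(s1 - e0 for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]))
        return gaps if self.strand == "+" else gaps[::-1]

    @property
    def start_codon(self) -> str:
        return self.cds[:3]

    @property
    def stop_codon(self) -> str:
        return self.cds[-3:]

    @property
    def label(self) -> str:
        """Isoform label with the tandem-copy suffix, e.g. ``Mt1a``."""
        return self.isoform + (self.copy_label or "")
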