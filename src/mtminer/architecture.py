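"""Cluster architecture: gene ordering, tandem Mt1 copy naming,
InterGenic Region (IGR) lengths and table summary statistics.

The IGR between two genes is the count of bases strictly between their
spans, where a span runs from the start codon through the stop codon
inclusive.  Summary statistics use the arithmetic mean and the sample
(n−1) standard deviation — the convention that reproduces the printed
summary rows of the transcribed tables from their per-species cells.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io import FixtureTable, LengthCell, load_fixture_table
from .models import ExonModel


@dataclass(frozen=True)
class ClusterArchitecture:
    contig_id: str
    genes: tuple[ExonModel, ...]  # sorted by contig coordinate
    igrs: tuple[tuple[str, str, int], ...]  # (upstream gene_id, downstream gene_id, bp)

    @property
    def architecture_string(self) -> str:
        return "-".join(g.label for g in self.genes)


@dataclass(frozen=True)
class SummaryStats:
    """Mean ± sample SD plus the min–max envelope of a length column."""

    n: int
    mean: float
    sd: float | None
    min: int
    max: int

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("min <= mean <= max violated")
        if self.sd is not None and self.sd < 0:
            raise ValueError("negative sd")


def order_genes(models: list[ExonModel]) -> ClusterArchitecture:
    """Sort gene models along the contig and name tandem Mt1 copies.

    Mt1 copies are labeled a, b, c walking outward from the copy nearest
    Mt2 (coordinate order when no Mt2 is present); a lone Mt1 keeps no
    suffix.  Overlapping gene spans raise ``inconsistent models``.  The
    input models are left untouched; the architecture carries relabeled
    copies.
    """
    if not models:
        raise ValueError("no gene models")
    contigs = {m.contig_id for m in models}
    if len(contigs) > 1:
        raise ValueError(f"models span multiple contigs: {sorted(contigs)}")
    genes = sorted((dataclasses.replace(m) for m in models), key=lambda m: m.span)
    for a, b in zip(genes, genes[1:]):
        if b.start < a.end:
            raise ValueError(
                f"inconsistent models: {a.gene_id} and {b.gene_id} overlap"
            )
    if any(g.strand != genes[0].strand for g in genes):
        warnings.warn("mixed-orientation cluster", stacklevel=2)

    mt1_idx = [i for i, g in enumerate(genes) if g.isoform == "Mt1"]
    if len(mt1_idx) == 1:
        genes[mt1_idx[0]].copy_label = None
    elif len(mt1_idx) > 1:
        mt2_idx = [i for i, g in enumerate(genes) if g.isoform == "Mt2"]
        if mt2_idx:
            anchor = mt2_idx[0]
            ordered = sorted(mt1_idx, key=lambda i: abs(i - anchor))
        else:
            ordered = mt1_idx
        for label, i in zip("abcdef", ordered):
            genes[i].copy_label = label

    arch = ClusterArchitecture(
        contig_id=genes[0].contig_id, genes=tuple(genes), igrs=()
    )
    igrs = compute_igrs(arch)
    return ClusterArchitecture(
        contig_id=arch.contig_id, genes=arch.genes, igrs=tuple(igrs)
    )


def compute_igrs(arch: ClusterArchitecture) -> list[tuple[str, str, int]]:
    """Bases strictly between consecutive gene spans (0 for abutting genes)."""
    igrs = []
    for up, down in zip(arch.genes, arch.genes[1:]):
        gap = down.start - up.end
        if gap < 0:
            raise ValueError(f"inconsistent models: {up.gene_id}/{down.gene_id} overlap")
        igrs.append((up.gene_id, down.gene_id, gap))
    return igrs


def summarize_lengths(
    cells: list[LengthCell],
    policy: str = "low",
    multi_policy: str = "a",
) -> SummaryStats:
    """Mean, sample SD and min–max over a column of length cells.

    Missing cells are skipped, approximate (``±``) cells contribute
    their numeric value, range cells resolve per ``policy`` (low /
    high / midpoint / exclude).  Mean and SD are reported to two
    decimals; SD is undefined (None) for a single value.
    """
    values = [
        v
        for cell in cells
        if (v := cell.resolve(policy=policy, multi_policy=multi_policy)) is not None
    ]
    if not values:
        raise ValueError("all cells missing")
    n = len(values)
    mean = sum(values) / n
    if n >= 2:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        sd = round(math.sqrt(var), 2)
    else:
        sd = None
    return SummaryStats(n=n, mean=round(mean, 2), sd=sd, min=min(values), max=max(values))


def modal_value(
    cells: list[LengthCell], policy: str = "low", multi_policy: str = "a"
) -> int:
    values = [
        v
        for cell in cells
        if (v := cell.resolve(policy=policy, multi_policy=multi_policy)) is not None
    ]
    if not values:
        raise ValueError("all cells missing")
    # deterministic: most common, smallest value on ties
    counts = Counter(values)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def summarize_exon_intron_tables(
    exon_table: FixtureTable | None = None,
    intron_table: FixtureTable | None = None,
    multi_policy: str = "a",
) -> pd.DataFrame:
    """Per-column summary of the exon- and intron-length fixtures.

    One row per (gene, feature) column: n, mean, sd, min, max and the
    modal value.  Multi-copy Mt1 intron cells contribute the configured
    tandem copy only (default copy a, matching the per-copy sub-columns
    of the printed summary row).
    """
    exon_table = exon_table or load_fixture_table("exon_lengths")
    intron_table = intron_table or load_fixture_table("intron_lengths")
    rows = []
    for table, feature_kind in ((exon_table, "exon"), (intron_table, "intron")):
        for column in table.columns:
            cells = table.column(column)
            stats = summarize_lengths(cells, multi_policy=multi_policy)
            rows.append(
                {
                    "column": column,
                    "feature": feature_kind,
                    "n": stats.n,
                    "mean": stats.mean,
                    "sd": stats.sd,
                    "min": stats.min,
                    "max": stats.max,
                    "mode": modal_value(cells, multi_policy=multi_policy),
                }
            )
    return pd.DataFrame(rows).set_index("column")
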