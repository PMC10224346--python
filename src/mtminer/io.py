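"""Readers and writers for FASTA, GFF3 and the packaged table fixtures.

The packaged fixtures transcribe published per-species tables of
cetacean MT genes: a species/accession inventory, intergenic-region (IGR) lengths
inside the Mt4-Mt3-Mt2-Mt1 cluster, exon lengths and intron lengths for
the four MT isoforms.  Printed summary rows (averages, min–max) are
deliberately NOT part of the fixtures — they are recomputed by
:func:`mtminer.architecture.summarize_lengths` so the statistical
conventions stay under test.

Cell dialect of the length tables: plain integers, ``±N`` (approximate,
from incompletely assembled regions), ``a–b`` ranges (en-dash or
hyphen), and multi-copy cells like ``611(a)-578(b)`` giving one value
per tandem Mt1 copy.  Comma thousands separators are accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .models import ExonModel
from .sequences import SequenceRecord, translate_cds

# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, moltype: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and record order is preserved.  An empty
    file raises ``ValueError("no records")``; a record with an empty
    sequence raises an error naming the record id.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=seq, moltype=moltype, description=desc))
    if not records:
        raise ValueError("no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3

_GFF_SOURCE = "mtminer"


def write_gff3(
    annotations: Sequence[ExonModel],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Write gene models as GFF3 (gene → mRNA → exon features).

    Internal 0-based half-open intervals are converted to the 1-based
    inclusive coordinates GFF3 requires; this function and
    :func:`read_gff3` are the only places that shift happens.  The
    spliced CDS is carried in the mRNA attributes so the file
    round-trips losslessly through :func:`read_gff3`.
    """
    lines = ["##gff-version 3"]
    for comment in header_comments:
        lines.append(f"# {comment}")
    for model in annotations:
        if contig_lengths is not None:
            clen = contig_lengths.get(model.contig_id)
            if clen is not None and model.end > clen:
                raise ValueError(
                    f"gene {model.gene_id}: exon interval exceeds contig "
                    f"{model.contig_id} length {clen}"
                )
        gid = model.gene_id
        start1, end1 = model.start + 1, model.end
        attrs = [f"ID=gene:{gid}", f"isoform={model.isoform}"]
        if model.copy_label:
            attrs.append(f"copy_label={model.copy_label}")
        if model.flags:
            attrs.append("flags=" + ",".join(sorted(model.flags)))
        lines.append(
            "\t".join(
                [model.contig_id, _GFF_SOURCE, "gene", str(start1), str(end1), ".",
                 model.strand, ".", ";".join(attrs)]
            )
        )
        lines.append(
            "\t".join(
                [model.contig_id, _GFF_SOURCE, "mRNA", str(start1), str(end1), ".",
                 model.strand, ".",
                 f"ID=mrna:{gid};Parent=gene:{gid};cds={model.cds}"]
            )
        )
        for i, (a, b) in enumerate(model.exons, start=1):
            lines.append(
                "\t".join(
                    [model.contig_id, _GFF_SOURCE, "exon", str(a + 1), str(b), ".",
                     model.strand, ".", f"ID=exon:{gid}.{i};Parent=mrna:{gid}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[ExonModel]:
    """Read gene models written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        contig, _src, ftype, start1, end1, _score, strand, _phase, attr_text = line.split("\t")
        attrs = _parse_attrs(attr_text)
        interval = (int(start1) - 1, int(end1))
        if ftype == "gene":
            gid = attrs["ID"].removeprefix("gene:")
            order.append(gid)
            genes[gid] = {
                "contig": contig,
                "strand": strand,
                "isoform": attrs.get("isoform", "unknown"),
                "copy_label": attrs.get("copy_label"),
                "flags": frozenset(
                    f for f in attrs.get("flags", "").split(",") if f
                ),
                "exons": [],
                "cds": "",
            }
        elif ftype == "mRNA":
            gid = attrs["Parent"].removeprefix("gene:")
            genes[gid]["cds"] = attrs.get("cds", "")
        elif ftype == "exon":
            gid = attrs["Parent"].removeprefix("mrna:")
            genes[gid]["exons"].append(interval)
    models = []
    for gid in order:
        g = genes[gid]
        models.append(
            ExonModel(
                gene_id=gid,
                contig_id=g["contig"],
                strand=g["strand"],
                exons=tuple(sorted(g["exons"])),
                cds=g["cds"],
                protein=translate_cds(g["cds"]) if len(g["cds"]) >= 3 else "",
                isoform=g["isoform"],
                copy_label=g["copy_label"],
                flags=g["flags"],
            )
        )
    return models


# ---------------------------------------------------------------------------
# Length-table cells

_DASHES = re.compile(r"[–—−]")  # en/em dash, minus sign
_MULTI_RE = re.compile(r"^(\d+)\(([a-z])\)(?:-(\d+)\(([a-z])\))*$")
_MULTI_PART = re.compile(r"(\d+)\(([a-z])\)")


@dataclass(frozen=True)
class LengthCell:
    """One printed cell of a length table (bp).

    ``value`` is None for a blank (missing) cell.  ``approximate`` marks
    cells printed with a ``±`` prefix.  Range cells ``a–b`` store
    ``value=a`` and ``range_high=b``.  Multi-copy cells like
    ``611(a)-578(b)`` store the labeled values in ``multi``.
    """

    value: int | None = None
    approximate: bool = False
    range_high: int | None = None
    multi: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.range_high is not None and (
            self.value is None or self.range_high < self.value
        ):
            raise ValueError("range_high must be >= value")
        if self.value is not None and self.value < 0:
            raise ValueError("negative length")

    @property
    def is_missing(self) -> bool:
        return self.value is None and self.multi is None

    def resolve(self, policy: str = "low", multi_policy: str = "a") -> int | None:
        """Collapse the cell to a single integer (or None for missing).

        ``policy`` applies to range cells: ``low``, ``high``,
        ``midpoint`` or ``exclude``.  ``multi_policy`` selects the
        tandem-copy value used from multi cells (default copy ``a``;
        unlabeled plain cells always count).
        """
        if self.multi is not None:
            by_label = dict(self.multi)
            return by_label.get(multi_policy)
        if self.value is None:
            return None
        if self.range_high is not None:
            if policy == "low":
                return self.value
            if policy == "high":
                return self.range_high
            if policy == "midpoint":
                return (self.value + self.range_high) // 2
            if policy == "exclude":
                return None
            raise ValueError(f"unknown range policy {policy!r}")
        return self.value


def parse_length_cell(text: str) -> LengthCell:
    """Parse one printed table cell into a :class:`LengthCell`."""
    raw = text
    text = _DASHES.sub("-", text.strip()).replace(",", "").replace(" ", "")
    if not text:
        return LengthCell()
    if text.startswith("±") or text.startswith("+/-"):
        body = text[1:] if text.startswith("±") else text[3:]
        if not body.isdigit():
            raise ValueError(f"unparsable length cell: {raw!r}")
        return LengthCell(value=int(body), approximate=True)
    if _MULTI_RE.match(text):
        parts = tuple((label, int(v)) for v, label in _MULTI_PART.findall(text))
        return LengthCell(multi=parts)
    if text.isdigit():
        return LengthCell(value=int(text))
    m = re.match(r"^(\d+)-(\d+)$", text)
    if m:
        low, high = int(m.group(1)), int(m.group(2))
        if high < low:
            raise ValueError(f"range cell with high < low: {raw!r}")
        return LengthCell(value=low, range_high=high)
    raise ValueError(f"unparsable length cell: {raw!r}")


def format_length_cell(cell: LengthCell) -> str:
    """Inverse of :func:`parse_length_cell`."""
    if cell.multi is not None:
        return "-".join(f"{v}({label})" for label, v in cell.multi)
    if cell.value is None:
        return ""
    if cell.approximate:
        return f"±{cell.value}"
    if cell.range_high is not None:
        return f"{cell.value}-{cell.range_high}"
    return str(cell.value)


# ---------------------------------------------------------------------------
# Packaged fixtures

IGR_COLUMNS = (
    "igr_mt4_mt3",
    "igr_mt3_mt2",
    "igr_mt2_mt1a",
    "igr_mt1a_mt1b",
    "igr_mt1b_mt1c",
)

_FIXTURE_FILES = {
    "species_inventory": "table1_species_inventory.tsv",
    "igr_lengths": "table2_igr_lengths.tsv",
    "exon_lengths": "table3_exon_lengths.tsv",
    "intron_lengths": "table4_intron_lengths.tsv",
}

_EXPECTED_CELL_COLUMNS = {
    "igr_lengths": 5,
    "exon_lengths": 12,
    "intron_lengths": 8,
}


@dataclass
class FixtureTable:
    """A transcribed per-species table.

    ``columns`` are the value-column names; ``rows`` pair each species
    (and family, where the table prints one) with its parsed cells.
    ``frame`` keeps the raw strings for tables (like the inventory)
    whose cells are not lengths.
    """

    name: str
    columns: tuple[str, ...]
    rows: list[tuple[str, str, tuple[LengthCell, ...]]]
    frame: pd.DataFrame

    def column(self, name: str) -> list[LengthCell]:
        idx = self.columns.index(name)
        return [cells[idx] for _, _, cells in self.rows]

    def row(self, species: str) -> tuple[LengthCell, ...]:
        for sp, _fam, cells in self.rows:
            if sp == species:
                return cells
        raise KeyError(species)


def load_fixture_table(name: str) -> FixtureTable:
    """Load one of the packaged fixtures by its logical name.

    Valid names: ``species_inventory``, ``igr_lengths``,
    ``exon_lengths``, ``intron_lengths``.
    """
    if name not in _FIXTURE_FILES:
        raise ValueError(f"unknown fixture name {name!r}")
    ref = resources.files("mtminer.data") / _FIXTURE_FILES[name]
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    value_cols = tuple(c for c in frame.columns if c not in ("species", "family"))
    expected = _EXPECTED_CELL_COLUMNS.get(name)
    if expected is not None and len(value_cols) != expected:
        raise ValueError(
            f"fixture {name}: expected {expected} value columns, found {len(value_cols)}"
        )
    rows: list[tuple[str, str, tuple[LengthCell, ...]]] = []
    seen: set[str] = set()
    for _, r in frame.iterrows():
        species = r["species"]
        if species in seen:
            raise ValueError(f"fixture {name}: duplicate species {species!r}")
        seen.add(species)
        family = r.get("family", "")
        if name == "species_inventory":
            cells: tuple[LengthCell, ...] = ()
        else:
            cells = tuple(parse_length_cell(r[c]) for c in value_cols)
        rows.append((species, family, cells))
    return FixtureTable(name=name, columns=value_cols, rows=rows, frame=frame)
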