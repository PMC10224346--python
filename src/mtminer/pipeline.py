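"""End-to-end orchestration: detect → annotate → validate → classify →
architecture → phylogeny, with deterministic report files.

The pipeline is a pure function of (inputs, configuration, seed):
rerunning with the same arguments produces byte-identical outputs.
Every report file carries the tool version, a configuration hash and
the seed in its comment header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (
    NoSplicedModelError,
    SplicedAlignParams,
    alignment_to_gene_model,
    spliced_align,
    validate_gene_model,
)
from .architecture import (
    ClusterArchitecture,
    order_genes,
    summarize_lengths,
)
from .detect import ScoreConfig, SeedSearchConfig, find_candidate_loci
from .io import IGR_COLUMNS, LengthCell, load_fixture_table, read_fasta, write_gff3
from .models import FLAG_EXON_COUNT_ATYPICAL, ISOFORMS, ExonModel
from .phylo import IsoformCall, bootstrap_support, classify_isoform, k2p_matrix, star_msa
from .sequences import SequenceRecord

logger = logging.getLogger("mtminer")


@dataclass(frozen=True)
class RunConfig:
    inputs: tuple[str, ...]
    refs_path: str | None = None
    outdir: str = "mtminer_out"
    seed: int = 0
    replicates: int = 100
    max_tandem_copies: int = 3
    seed_search: SeedSearchConfig = field(default_factory=SeedSearchConfig)
    align_params: SplicedAlignParams = field(default_factory=SplicedAlignParams)
    score_config: ScoreConfig = field(default_factory=ScoreConfig)


@dataclass
class AnnotatedGene:
    model: ExonModel
    call: IsoformCall
    valid: bool
    diagnostics: list[str]
    align_score: float


@dataclass
class RunReport:
    config: RunConfig
    genes: list[AnnotatedGene]
    architectures: list[ClusterArchitecture]
    tree_newick: str | None
    supports: dict[frozenset[str], int] | None
    distances: pd.DataFrame | None

    @property
    def models(self) -> list[ExonModel]:
        return [g.model for g in self.genes]


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific parameters only — file-system paths are
    excluded so equivalent runs in different directories agree."""
    params = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if k not in ("inputs", "refs_path", "outdir")
    }
    blob = repr(sorted(params.items())).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _load_refs(config: RunConfig) -> dict[str, list[SequenceRecord]]:
    if config.refs_path is None:
        from .simulate import make_reference_set

        return make_reference_set()
    refs: dict[str, list[SequenceRecord]] = {}
    for rec in read_fasta(config.refs_path):
        isoform = rec.id.split("_")[0]
        if isoform not in ISOFORMS:
            raise ValueError(
                f"reference id {rec.id!r} must start with an isoform label (Mt1..Mt4)"
            )
        refs.setdefault(isoform, []).append(rec)
    return refs


def _annotate_window(
    contig: SequenceRecord,
    window: tuple[int, int],
    refs: dict[str, list[SequenceRecord]],
    config: RunConfig,
) -> list[tuple[ExonModel, float]]:
    """Align every reference against one candidate window.

    Accepted gene regions are masked with N and the same reference is
    retried, so tandem copies inside one window are all recovered.
    """
    start, end = window
    window_seq = contig.residues[start:end]
    candidates: list[tuple[ExonModel, float]] = []
    for isoform in sorted(refs):
        for ref in refs[isoform]:
            masked = window_seq
            for _copy in range(config.max_tandem_copies):
                try:
                    aln = spliced_align(
                        ref,
                        SequenceRecord(id=f"{contig.id}:{start}-{end}", residues=masked),
                        config.align_params,
                    )
                except NoSplicedModelError:
                    break
                model = alignment_to_gene_model(
                    aln,
                    window_seq,
                    gene_id="pending",
                    contig_id=contig.id,
                    window_offset=start,
                    params=config.align_params,
                    allow_partial=True,
                )
                candidates.append((model, aln.score))
                # mask the accepted span before searching for another copy
                s, e = model.start - start, model.end - start
                masked = masked[:s] + "N" * (e - s) + masked[e:]
    return candidates


def _select_non_overlapping(
    candidates: list[tuple[ExonModel, float]]
) -> list[tuple[ExonModel, float]]:
    chosen: list[tuple[ExonModel, float]] = []
    for model, score in sorted(candidates, key=lambda c: (-c[1], c[0].span)):
        if all(
            model.end <= m.start or model.start >= m.end
            for m, _ in chosen
            if m.contig_id == model.contig_id
        ):
            chosen.append((model, score))
    chosen.sort(key=lambda c: (c[0].contig_id, c[0].span))
    return chosen


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full mining pipeline and write reports to the outdir."""
    if not config.inputs:
        raise ValueError("no input FASTA files")
    refs = _load_refs(config)
    flat_refs = [r for lst in refs.values() for r in lst]
    contigs: list[SequenceRecord] = []
    for path in config.inputs:
        contigs.extend(read_fasta(path))

    genes: list[AnnotatedGene] = []
    architectures: list[ClusterArchitecture] = []
    for contig in contigs:
        hits = find_candidate_loci(contig, flat_refs, config.seed_search)
        logger.info("stage=detect contig=%s hits=%d", contig.id, len(hits))
        candidates: list[tuple[ExonModel, float]] = []
        for hit in hits:
            candidates.extend(_annotate_window(contig, hit.window, refs, config))
        selected = _select_non_overlapping(candidates)
        contig_genes: list[AnnotatedGene] = []
        for i, (model, score) in enumerate(selected, start=1):
            model.gene_id = f"{contig.id}_g{i}"
            valid, diagnostics = validate_gene_model(model, config.score_config)
            call = classify_isoform(model, refs)
            model.isoform = call.isoform
            contig_genes.append(AnnotatedGene(model, call, valid, diagnostics, score))
        logger.info(
            "stage=annotate contig=%s genes=%d valid=%d",
            contig.id,
            len(contig_genes),
            sum(g.valid for g in contig_genes),
        )
        full = [
            g.model
            for g in contig_genes
            if g.valid and FLAG_EXON_COUNT_ATYPICAL not in g.model.flags
        ]
        if full:
            arch = order_genes(full)
            architectures.append(arch)
            copy_labels = {g.gene_id: g.copy_label for g in arch.genes}
            for g in contig_genes:
                if g.model.gene_id in copy_labels:
                    g.model.copy_label = copy_labels[g.model.gene_id]
            logger.info(
                "stage=architecture contig=%s string=%s", contig.id, arch.architecture_string
            )
        genes.extend(contig_genes)

    tree_newick = None
    supports = None
    distances = None
    phylo_models = [g.model for g in genes if g.valid]
    if len(phylo_models) >= 3:
        records = [
            SequenceRecord(id=m.gene_id, residues=m.cds, moltype="nucleotide")
            for m in phylo_models
        ]
        labels, aligned = star_msa(records)
        dm = k2p_matrix(labels, aligned)
        distances = pd.DataFrame(dm.d, index=list(dm.labels), columns=list(dm.labels))
        tree, supports = bootstrap_support(
            labels, aligned, replicates=config.replicates, seed=config.seed
        )
        tree_newick = str(tree).strip()
        logger.info("stage=phylo taxa=%d replicates=%d", len(labels), config.replicates)

    report = RunReport(
        config=config,
        genes=genes,
        architectures=architectures,
        tree_newick=tree_newick,
        supports=supports,
        distances=distances,
    )
    _write_outputs(report, contigs)
    return report


def _header(config: RunConfig) -> list[str]:
    return [
        f"mtminer {__version__} config_hash={config_hash(config)} seed={config.seed}",
    ]


def _write_outputs(report: RunReport, contigs: list[SequenceRecord]) -> None:
    outdir = Path(report.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _header(report.config)
    contig_lengths = {c.id: len(c.residues) for c in contigs}

    write_gff3(report.models, outdir / "annotations.gff3", contig_lengths, header)

    rows = []
    for g in report.genes:
        exon_lens = g.model.exon_lengths
        intron_lens = g.model.intron_lengths
        rows.append(
            {
                "gene_id": g.model.gene_id,
                "contig_id": g.model.contig_id,
                "isoform": g.model.label,
                "strand": g.model.strand,
                "start": g.model.start + 1,
                "end": g.model.end,
                "exon_lengths": ",".join(map(str, exon_lens)),
                "intron_lengths": ",".join(map(str, intron_lens)) or ".",
                "valid": g.valid,
                "confidence": g.call.confidence,
                "flags": ",".join(sorted(g.model.flags)) or ".",
                "diagnostics": "; ".join(g.diagnostics) or ".",
            }
        )
    _write_tsv(pd.DataFrame(rows), outdir / "genes.tsv", header)

    igr = summarize_run_igr(report)
    _write_tsv(igr.reset_index(), outdir / "igr.tsv", header)

    if report.distances is not None:
        _write_tsv(
            report.distances.round(6).reset_index(names="label"),
            outdir / "distances.tsv",
            header,
        )
    if report.tree_newick is not None:
        (outdir / "tree.nwk").write_text(
            "".join(f"# {line}\n" for line in header) + report.tree_newick + "\n"
        )


def _write_tsv(frame: pd.DataFrame, path: Path, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Table-style summaries

_PAIR_LABELS = (
    "Mt4-Mt3",
    "Mt3-Mt2",
    "Mt2-Mt1a",
    "Mt2-Mt1",
    "Mt1a-Mt1b",
    "Mt1b-Mt1c",
)


def summarize_run_igr(report: RunReport) -> pd.DataFrame:
    """IGR table in the layout of the per-species IGR fixture: one row
    per contig, one column per adjacent cluster pair, plus recomputed
    Average ± SD and Min–Max footer rows."""
    by_label: dict[str, dict[str, int]] = {}
    for arch in report.architectures:
        gene_by_id = {g.gene_id: g for g in arch.genes}
        row: dict[str, int] = {}
        for up_id, down_id, length in arch.igrs:
            pair = f"{gene_by_id[up_id].label}-{gene_by_id[down_id].label}"
            row[pair] = length
        by_label[arch.contig_id] = row
    observed = {pair for row in by_label.values() for pair in row}
    columns = [c for c in _PAIR_LABELS if c in observed] + sorted(
        observed - set(_PAIR_LABELS)
    )
    if not columns:
        columns = list(_PAIR_LABELS)
    frame = pd.DataFrame.from_dict(by_label, orient="index").reindex(
        columns=columns
    )
    frame.index.name = "contig"
    footer: dict[str, dict[str, str]] = {"Average ± SD (bp)": {}, "Min–Max (bp)": {}}
    for col in columns:
        values = [int(v) for v in frame[col].dropna()]
        if not values:
            footer["Average ± SD (bp)"][col] = ""
            footer["Min–Max (bp)"][col] = ""
            continue
        stats = summarize_lengths([LengthCell(value=v) for v in values])
        sd = f" ± {stats.sd}" if stats.sd is not None else ""
        footer["Average ± SD (bp)"][col] = f"{stats.mean}{sd}"
        footer["Min–Max (bp)"][col] = f"{stats.min}–{stats.max}"
    out = frame.astype("object")
    for name, row in footer.items():
        out.loc[name] = pd.Series(row)
    return out


def summarize_fixture_tables(policy: str = "low") -> dict[str, pd.DataFrame]:
    """Recompute the summary rows of the packaged per-species tables."""
    from .architecture import summarize_exon_intron_tables

    igr_table = load_fixture_table("igr_lengths")
    rows = []
    for col in IGR_COLUMNS:
        stats = summarize_lengths(igr_table.column(col), policy=policy)
        rows.append(
            {
                "column": col,
                "n": stats.n,
                "mean": stats.mean,
                "sd": stats.sd,
                "min": stats.min,
                "max": stats.max,
            }
        )
    return {
        "igr": pd.DataFrame(rows).set_index("column"),
        "exon_intron": summarize_exon_intron_tables(),
    }
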