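"""Isoform phylogeny: Kimura two-parameter distances, neighbor-joining,
bootstrap support and isoform classification.

The K2P distance separates transitions (A↔G, C↔T; proportion P) from
transversions (proportion Q):

    d = -(1/2) · ln((1 - 2P - Q) · sqrt(1 - 2Q))

Pairs outside the logarithm's domain are saturated and raise an error
rather than returning infinity.  Trees are built with the classic
Saitou–Nei neighbor-joining agglomeration on the distance matrix and
serialized through scikit-bio's ``TreeNode``; bootstrap support is the
percentage of column-resampled replicate trees containing each internal
bipartition of the point-estimate tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from skbio.tree import TreeNode

from .models import ExonModel
from .sequences import SequenceRecord


class SaturationError(ValueError):
    """Pairwise divergence too high for the K2P correction."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with row/column labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("nonzero diagonal")
        if (d < 0).any() or not np.isfinite(d).all():
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "d", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


_K2P_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _K2P_ENCODE[ord(_c)] = _i


def _enc(seq: str) -> np.ndarray:
    return _K2P_ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _k2p_from_encoded(a: np.ndarray, b: np.ndarray, pair_name: str) -> float:
    keep = (a < 4) & (b < 4)
    n = int(keep.sum())
    if n == 0:
        raise SaturationError(f"no comparable sites for pair {pair_name}")
    aa, bb = a[keep], b[keep]
    diff = aa != bb
    # A and G encode even, C and T odd: a transition keeps parity
    transitions = int((diff & ((aa % 2) == (bb % 2))).sum())
    transversions = int(diff.sum()) - transitions
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated pair {pair_name}: P={P:.3f}, Q={Q:.3f}")
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


def pairwise_k2p(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """K2P distance between two equal-length aligned sequences.

    Sites with N or a gap in either sequence are excluded pairwise.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if len(sa) != len(sb):
        raise ValueError("sequences must be aligned to equal length")
    name_a = a.id if isinstance(a, SequenceRecord) else "seq1"
    name_b = b.id if isinstance(b, SequenceRecord) else "seq2"
    return _k2p_from_encoded(_enc(sa), _enc(sb), f"({name_a}, {name_b})")


def k2p_matrix(labels: list[str], aligned: list[str]) -> DistanceMatrix:
    """All-pairs K2P distances over aligned equal-length sequences."""
    if len(labels) != len(aligned):
        raise ValueError("labels and sequences differ in length")
    enc = [_enc(s) for s in aligned]
    n = len(enc)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _k2p_from_encoded(
                enc[i], enc[j], f"({labels[i]}, {labels[j]})"
            )
    return DistanceMatrix(labels=tuple(labels), d=d)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(m: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining (Saitou–Nei Q-criterion).

    Ties in the Q-criterion break on the lexicographically smallest
    pair of subtree labels (a subtree is labeled by its smallest leaf
    name); negative branch lengths are clamped to zero with a warning.
    The returned tree is unrooted, represented with a trifurcating root.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = m.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in m.labels]
    keys: list[str] = list(m.labels)

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(f"negative branch length {x:.4g} clamped to 0", stacklevel=3)
            return 0.0
        return x

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * d[i, j] - r[i] - r[j]
                tie_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = clamp(d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2)))
        lj = clamp(d[i, j] - (d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))))
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        new_dist = np.array(
            [(d[i, t] + d[j, t] - d[i, j]) / 2.0 for t in range(k) if t not in (i, j)]
        )
        keep = [t for t in range(k) if t not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_dist
        d[:-1, -1] = new_dist
        nodes = [nodes[t] for t in keep] + [new]
        keys = [keys[t] for t in keep] + [min(keys[i], keys[j])]

    # resolve the final three subtrees around a central node
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp((dab + dac - dbc) / 2.0)
    b.length = clamp((dab + dbc - dac) / 2.0)
    c.length = clamp((dac + dbc - dab) / 2.0)
    return TreeNode(children=[a, b, c])


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is represented by the leaf set on the side NOT
    containing the lexicographically smallest leaf (a canonical form
    independent of rooting).
    """
    leaves = {t.name for t in tree.tips()}
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if anchor in clade:
            clade = frozenset(leaves - clade)
        if 2 <= len(clade) <= len(leaves) - 2:
            splits.add(clade)
    return splits


def bootstrap_support(
    labels: list[str],
    aligned: list[str],
    replicates: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], int]]:
    """NJ tree with bootstrap support on its internal edges.

    Alignment columns are resampled with replacement per replicate;
    support is the percentage (rounded down) of replicate trees
    containing each internal bipartition of the point-estimate tree.
    Replicates whose resampled matrix saturates are skipped with a
    warning.  Supports are attached as internal node names.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    L = len(aligned[0]) if aligned else 0
    if L < 2:
        raise ValueError("alignment must have at least 2 columns")
    if any(len(s) != L for s in aligned):
        raise ValueError("alignment rows differ in length")
    tree = nj_tree(k2p_matrix(labels, aligned))
    splits = tree_bipartitions(tree)
    counts: dict[frozenset[str], int] = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    effective = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        resampled = ["".join(s[c] for c in cols) for s in aligned]
        try:
            with warnings.catch_warnings():
                # replicate trees are discarded after split extraction;
                # their clamped near-zero branches are routine
                warnings.simplefilter("ignore", UserWarning)
                rep_tree = nj_tree(k2p_matrix(labels, resampled))
        except SaturationError:
            warnings.warn("bootstrap replicate skipped: saturated distances", stacklevel=2)
            continue
        effective += 1
        rep_splits = tree_bipartitions(rep_tree)
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    if effective == 0:
        raise SaturationError("every bootstrap replicate saturated")
    support = {s: int(100 * c / effective) for s, c in counts.items()}
    anchor = min(t.name for t in tree.tips())
    leaves = {t.name for t in tree.tips()}
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if anchor in clade:
            clade = frozenset(leaves - clade)
        if clade in support:
            node.name = str(support[clade])
    return tree, support


# ---------------------------------------------------------------------------
# Isoform classification

@dataclass(frozen=True)
class IsoformCall:
    gene_id: str
    isoform: str
    evidence: dict[str, object]
    confidence: str

    def __post_init__(self) -> None:
        if self.isoform == "unknown" and self.confidence != "low":
            raise ValueError("unknown isoform must have low confidence")


def _affine_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global affine-gap alignment of two coding sequences; returns the
    gapped strings (deterministic: the aligner's first optimum)."""
    aligner = _affine_aligner()
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def star_msa(records: list[SequenceRecord]) -> tuple[list[str], list[str]]:
    """Approximate multiple alignment by projection onto a center sequence.

    Every sequence is pairwise-aligned to the longest record (ties break
    on id) and its residues are projected onto the center's coordinates;
    insertions relative to the center are dropped.  Adequate for
    equal-structure coding sequences, where indels are rare and short.
    """
    if not records:
        raise ValueError("no sequences")
    center = max(records, key=lambda r: (len(r.residues), r.id))
    rows = []
    for rec in records:
        if rec.id == center.id and rec.residues == center.residues:
            rows.append(center.residues)
            continue
        gapped_center, gapped_other = align_pair(center.residues, rec.residues)
        projected = "".join(
            o for c, o in zip(gapped_center, gapped_other) if c != "-"
        )
        rows.append(projected)
    return [r.id for r in records], rows


def classify_isoform(
    model: ExonModel,
    refs: dict[str, list[SequenceRecord]],
    clade_vote: str | None = None,
) -> IsoformCall:
    """Classify a gene model as Mt1/Mt2/Mt3/Mt4.

    Evidence lines: (i) an exon III of 104–107 bp is the Mt3 length
    signature; (ii) the nearest reference CDS by K2P after pairwise
    alignment; (iii) optionally a precomputed clade assignment.  The
    majority of available evidence wins; ties and empty evidence give
    ``unknown`` with low confidence.  Intron-free (retrocopy-like)
    models carry no exon-structure evidence and rely on (ii) alone.
    """
    evidence: dict[str, object] = {}
    votes: list[str] = []

    if not model.intron_free and len(model.exons) == 3:
        e3 = model.exon_lengths[2]
        evidence["exon3_length"] = e3
        if 104 <= e3 <= 107:
            votes.append("Mt3")

    best: dict[str, float] = {}
    for isoform, ref_list in refs.items():
        dists = []
        for ref in ref_list:
            try:
                ga, gb = align_pair(model.cds, ref.residues)
                dists.append(pairwise_k2p(ga, gb))
            except (SaturationError, ValueError):
                continue
        if dists:
            best[isoform] = min(dists)
    if best:
        ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
        evidence["nearest_reference"] = ranked[0][0]
        evidence["nearest_distance"] = round(ranked[0][1], 6)
        if len(ranked) == 1 or ranked[1][1] - ranked[0][1] > 1e-9:
            votes.append(ranked[0][0])
        else:
            evidence["nearest_reference"] = "tie"

    if clade_vote is not None:
        evidence["clade"] = clade_vote
        votes.append(clade_vote)

    if not votes:
        return IsoformCall(model.gene_id, "unknown", evidence, "low")
    tally: dict[str, int] = {}
    for v in votes:
        tally[v] = tally.get(v, 0) + 1
    ranked_votes = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked_votes) > 1 and ranked_votes[0][1] == ranked_votes[1][1]:
        return IsoformCall(model.gene_id, "unknown", evidence, "low")
    winner, count = ranked_votes[0]
    confidence = "high" if count >= 2 else "medium"
    return IsoformCall(model.gene_id, winner, evidence, confidence)
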