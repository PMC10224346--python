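"""ORF scanning, cysteine-motif counting, MT scoring and seeded search."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mtminer as mt
from mtminer.sequences import reverse_complement, translate_cds

# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive re-implementations)

_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def brute_force_orfs(seq: str, min_len_aa: int):
    """Position-by-position six-frame scan, independent of find_orfs."""
    found = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for start in range(n):
            if s[start : start + 3] != "ATG":
                continue
            for stop in range(start + 3, n - 2, 3):
                codon = s[stop : stop + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if (stop - start) // 3 >= min_len_aa:
                        iv = (start, stop + 3)
                        if strand == "-":
                            iv = (n - iv[1], n - iv[0])
                        found.add((iv, strand))
                    break
    return found


def brute_force_motifs(p: str):
    counts = {"CC": 0, "CXC": 0, "CXXC": 0}
    for i in range(len(p) - 1):
        if p[i] == "C" and p[i + 1] == "C":
            counts["CC"] += 1
    for i in range(len(p) - 2):
        if p[i] == "C" and p[i + 1] != "C" and p[i + 2] == "C":
            counts["CXC"] += 1
    for i in range(len(p) - 3):
        if p[i] == "C" and p[i + 1] != "C" and p[i + 2] != "C" and p[i + 3] == "C":
            counts["CXXC"] += 1
    return counts


# ---------------------------------------------------------------------------
# find_orfs

class TestFindOrfs:
    def test_minimal_orf(self):
        contig = mt.SequenceRecord(id="c", residues="ATGTGTTAA")
        ((interval, strand, protein),) = mt.find_orfs(contig, min_len_aa=2)
        assert interval == (0, 9) and strand == "+"
        assert protein.residues == "MC"

    def test_reverse_complement_strand_symmetry(self):
        fwd = mt.SequenceRecord(id="c", residues="ATGTGTTAA")
        rev = mt.SequenceRecord(id="c", residues=reverse_complement(fwd.residues))
        ((interval, strand, protein),) = mt.find_orfs(rev, min_len_aa=2)
        assert strand == "-" and interval == (0, 9)
        assert protein.residues == "MC"

    def test_matches_brute_force_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        contig = mt.SequenceRecord(id="c", residues=seq)
        got = {(iv, s) for iv, s, _ in mt.find_orfs(contig, min_len_aa=10)}
        want = {
            (iv, s)
            for iv, s in brute_force_orfs(seq, 10)
        }
        # find_orfs reports every nested ATG; the naive oracle only the
        # outermost per stop, so oracle results must be a subset and all
        # extra calls must share a stop with an oracle call
        assert want <= got
        for iv, s in got - want:
            assert any(
                s == s2 and (iv[1] == iv2[1] if s == "+" else iv[0] == iv2[0])
                for iv2, s2 in want
            )

    def test_translations_match_standard_code(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        for iv, strand, protein in mt.find_orfs(mt.SequenceRecord(id="c", residues=seq), 5):
            sub = seq[iv[0] : iv[1]]
            if strand == "-":
                sub = reverse_complement(sub)
            expected = ""
            for i in range(0, len(sub) - 3, 3):
                expected += _CODONS[sub[i : i + 3]]
            assert protein.residues == expected

    def test_low_complexity_contig_rejected(self):
        contig = mt.SequenceRecord(id="c", residues="N" * 60 + "ACGT" * 10)
        with pytest.raises(ValueError, match="low-complexity"):
            mt.find_orfs(contig, min_len_aa=2)


# ---------------------------------------------------------------------------
# motif counting and scoring

class TestCysMotifs:
    def test_no_cysteines(self):
        assert mt.count_cys_motifs("AAAA") == {"CC": 0, "CXC": 0, "CXXC": 0}

    def test_overlapping_cc_runs(self):
        assert mt.count_cys_motifs("CCC") == {"CC": 2, "CXC": 0, "CXXC": 0}

    def test_example_against_brute_force(self):
        assert mt.count_cys_motifs("CACGGC") == brute_force_motifs("CACGGC")

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.text(alphabet="CAKS", min_size=0, max_size=40))
    def test_matches_brute_force(self, p):
        assert mt.count_cys_motifs(p) == brute_force_motifs(p)


def _canonical_mt_protein() -> str:
    """61 aa, 20 Cys in motifs, 9 cysteines before the midpoint."""
    beta = "MDPNCSCATGGSCTCAGSCKCKECKCTSCK"  # 9 C in 30 aa
    alpha = "KSCCSCCPVGCAKCAQGCICKGASDKCSCCA"  # 11 C in 31 aa
    assert beta.count("C") == 9 and alpha.count("C") == 11
    return beta + alpha


class TestScoreMtProtein:
    def test_canonical_protein_passes(self):
        protein = _canonical_mt_protein()
        score = mt.score_mt_protein(protein)
        assert score.passed
        assert score.profile.cys_count == 20
        assert score.profile.cys_fraction > 0.30
        assert (score.profile.beta_cys, score.profile.alpha_cys) == (9, 11)

    def test_poly_alanine_fails(self):
        score = mt.score_mt_protein("A" * 61)
        assert score.components["cys_fraction"] == 0.0
        assert not score.passed

    def test_length_component_decays_outside_halo(self):
        protein = _canonical_mt_protein()
        long = protein + "G" * 20  # 81 aa, outside the 57-72 halo
        assert mt.score_mt_protein(long).components["length"] == 0.0

    def test_record_description_is_ignored(self):
        protein = _canonical_mt_protein()
        a = mt.SequenceRecord(id="p", residues=protein, moltype="protein")
        b = mt.SequenceRecord(
            id="p", residues=protein, moltype="protein", description="other text"
        )
        assert mt.score_mt_protein(a) == mt.score_mt_protein(b)

    def test_motif_participation_monotonicity(self):
        # scattered lone cysteines -> low motif component; pairing them up
        # (other components held roughly fixed) must not lower the score
        scattered = ("C" + "A" * 4) * 12 + "A"  # 61 aa, 12 isolated C
        paired = ("CC" + "A" * 8) * 6 + "A"  # 61 aa, 12 C in 6 CC pairs
        s0 = mt.score_mt_protein(scattered)
        s1 = mt.score_mt_protein(paired)
        assert s0.components["motif"] == 0.0
        assert s1.components["motif"] == 1.0
        assert s1.total >= s0.total

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError):
            mt.score_mt_protein("MC")


# ---------------------------------------------------------------------------
# seeded search

class TestFindCandidateLoci:
    def test_exact_copy_found(self, rng, study_refs):
        ref = study_refs["Mt2"][0]
        left = "".join(rng.choice(list("ACGT"), size=3000))
        right = "".join(rng.choice(list("ACGT"), size=3000))
        contig = mt.SequenceRecord(id="c", residues=left + ref.residues + right)
        hits = mt.find_candidate_loci(contig, [ref])
        assert len(hits) == 1
        (hit,) = hits
        assert hit.window[0] <= 3000 and hit.window[1] >= 3000 + len(ref.residues)
        assert hit.strand == "+" and hit.best_ref_id == ref.id

    def test_split_copy_chains_across_insert(self, rng, study_refs):
        ref = study_refs["Mt2"][0]
        insert = "".join(rng.choice(list("ACGT"), size=500))
        body = ref.residues[:94] + insert + ref.residues[94:]
        left = "".join(rng.choice(list("ACGT"), size=2000))
        contig = mt.SequenceRecord(id="c", residues=left + body + left[::-1])
        hits = mt.find_candidate_loci(contig, [ref])
        assert len(hits) == 1
        (hit,) = hits
        assert hit.window[0] <= 2000
        assert hit.window[1] >= 2000 + len(body)

    def test_reverse_strand_copy_found(self, rng, study_refs):
        ref = study_refs["Mt3"][0]
        left = "".join(rng.choice(list("ACGT"), size=2000))
        contig = mt.SequenceRecord(
            id="c", residues=left + reverse_complement(ref.residues) + left[::-1]
        )
        (hit,) = mt.find_candidate_loci(contig, [ref])
        assert hit.strand == "-"

    def test_random_contigs_yield_no_hits(self, study_refs):
        refs = [r for lst in study_refs.values() for r in lst]
        for seed in range(20):
            r = np.random.default_rng(seed)
            contig = mt.SequenceRecord(
                id=f"rand{seed}", residues="".join(r.choice(list("ACGT"), size=10_000))
            )
            assert mt.find_candidate_loci(contig, refs) == []

    def test_k_larger_than_ref_rejected(self):
        ref = mt.SequenceRecord(id="Mt1_tiny", residues="ATGTGTTAA")
        contig = mt.SequenceRecord(id="c", residues="ACGT" * 100)
        with pytest.raises(ValueError, match="larger than reference"):
            mt.find_candidate_loci(contig, [ref], mt.SeedSearchConfig(k=50))

    def test_simulated_truth_genes_always_covered(self, study, study_refs):
        """Recall 1.0: every ground-truth gene lies inside some window."""
        refs = [r for lst in study_refs.values() for r in lst]
        for truth in study:
            hits = mt.find_candidate_loci(truth.contig, refs)
            for model in truth.annotations:
                assert any(
                    h.window[0] <= model.start and h.window[1] >= model.end
                    for h in hits
                ), f"{model.gene_id} not covered"
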