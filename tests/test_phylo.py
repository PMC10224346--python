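"""K2P distances, neighbor joining, bootstrap support and isoform calls."""

from __future__ import annotations

import math

import numpy as np
import pytest
import skbio

import mtminer as mt
from mtminer.phylo import tree_bipartitions
from mtminer.sequences import SequenceRecord


# ---------------------------------------------------------------------------
# K2P

class TestPairwiseK2p:
    def test_identical_sequences(self):
        assert mt.pairwise_k2p("ACGTACGTAC", "ACGTACGTAC") == 0.0

    def test_closed_form_one_transition_one_transversion(self):
        # length 10, one A->G transition, one A->C transversion
        a = "AAAAAAAAAA"
        b = "GCAAAAAAAA"
        expected = -0.5 * math.log(0.7) - 0.25 * math.log(0.8)
        assert mt.pairwise_k2p(a, b) == pytest.approx(expected, rel=1e-12)

    def test_saturation_raises(self):
        # P = 0.5, Q = 0: 1 - 2P - Q = 0
        a = "AAGGCCTTAA"
        b = "GGAACCTTAA"  # hand-check: 4 transitions in 10 -> P=0.4 fine
        a = "AAAAAAAAAA"
        b = "GGGGGAAAAA"  # 5 transitions / 10 -> P = 0.5
        with pytest.raises(mt.SaturationError, match="saturated"):
            mt.pairwise_k2p(a, b)

    def test_gap_and_n_sites_excluded(self):
        # the gapped/N columns carry the only differences
        a = "ACGTAC-TNA"
        b = "ACGTACCTGA"
        assert mt.pairwise_k2p(a, b) == 0.0

    def test_symmetry_and_length_check(self):
        a, b = "ACGTACGTAC", "ACGTACGTTC"
        assert mt.pairwise_k2p(a, b) == mt.pairwise_k2p(b, a)
        with pytest.raises(ValueError, match="equal length"):
            mt.pairwise_k2p("ACGT", "ACGTA")

    def test_error_names_the_pair(self):
        a = SequenceRecord(id="seqA", residues="AAAAAAAAAA")
        b = SequenceRecord(id="seqB", residues="GGGGGAAAAA")
        with pytest.raises(mt.SaturationError, match="seqA.*seqB"):
            mt.pairwise_k2p(a, b)

    def test_monotone_in_transition_proportion(self):
        base = "A" * 50
        prev = -1.0
        for k in range(0, 12):
            other = "G" * k + "A" * (50 - k)
            d = mt.pairwise_k2p(base, other)
            assert d > prev
            prev = d


# ---------------------------------------------------------------------------
# Neighbor joining

def _leaf_distances(tree: skbio.TreeNode) -> dict[tuple[str, str], float]:
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


def _random_additive_matrix(n: int, rng) -> tuple[mt.DistanceMatrix, set[frozenset[str]]]:
    """Distances from a random binary tree with positive branch lengths."""
    labels = [f"t{i}" for i in range(n)]
    nodes = [skbio.TreeNode(name=l) for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent = skbio.TreeNode(children=[b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    nodes[0].length = float(rng.uniform(0.05, 1.0))
    nodes[1].length = 0.0
    tree = skbio.TreeNode(children=nodes)
    d = np.zeros((n, n))
    dist = _leaf_distances(tree)
    for (a, b), v in dist.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return mt.DistanceMatrix(labels=tuple(labels), d=d), tree_bipartitions(tree)


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = mt.nj_tree(mt.DistanceMatrix(labels=("a", "b", "c"), d=d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ValueError, match="at least 3"):
            mt.nj_tree(mt.DistanceMatrix(labels=("a", "b"), d=d))

    def test_four_taxon_additive_recovery(self, rng):
        dm, true_splits = _random_additive_matrix(4, rng)
        tree = mt.nj_tree(dm)
        assert tree_bipartitions(tree) == true_splits
        recovered = _leaf_distances(tree)
        for pair, v in recovered.items():
            assert v == pytest.approx(dm[pair], abs=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_recovery_up_to_eight_taxa(self, n):
        """NJ is exact on additive matrices (oracle property), and the
        topology agrees with scikit-bio's independent NJ."""
        for seed in range(5):
            rng = np.random.default_rng(1000 * n + seed)
            dm, true_splits = _random_additive_matrix(n, rng)
            tree = mt.nj_tree(dm)
            assert tree_bipartitions(tree) == true_splits
            recovered = _leaf_distances(tree)
            for pair, v in recovered.items():
                assert v == pytest.approx(dm[pair], abs=1e-9)
            skbio_tree = skbio.tree.nj(
                skbio.DistanceMatrix(dm.d, ids=list(dm.labels))
            )
            assert tree_bipartitions(skbio_tree) == true_splits

    def test_negative_branch_clamped_with_warning(self):
        d = np.array(
            [
                [0.0, 0.1, 0.6, 0.6],
                [0.1, 0.0, 0.11, 0.6],
                [0.6, 0.11, 0.0, 0.1],
                [0.6, 0.6, 0.1, 0.0],
            ]
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = mt.nj_tree(mt.DistanceMatrix(labels=("a", "b", "c", "d"), d=d))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


# ---------------------------------------------------------------------------
# Bootstrap

def _four_isoform_alignment(study_config, n_per_group=5):
    """Aligned CDSs: four deeply diverged isoform groups, shallow
    within-group divergence (strong phylogenetic signal)."""
    from mtminer.simulate import ancestral_genes, diverge_cds

    ancestors = ancestral_genes(study_config)
    rng = np.random.default_rng(study_config.seed + 1)
    records = []
    for isoform, anc in ancestors.items():
        for i in range(n_per_group):
            cds = diverge_cds(anc.cds, study_config.species_divergence, rng)
            records.append(
                SequenceRecord(id=f"{isoform}_s{i}", residues=cds)
            )
    return mt.star_msa(records)


class TestBootstrapSupport:
    def test_unanimous_alignment_gives_full_support(self):
        labels = ["a", "b", "c", "d"]
        aligned = [
            "AAAAAAAAAAAA",
            "AAAAAAAAAAAA",
            "GGAAAAAAAAAA",
            "GGAAAAAAAAAA",
        ]
        _, support = mt.bootstrap_support(labels, aligned, replicates=25, seed=0)
        assert support == {frozenset({"c", "d"}): 100}

    def test_supports_stay_in_range_across_seeds(self, study_config):
        labels, aligned = _four_isoform_alignment(study_config, n_per_group=2)
        for seed in range(10):
            _, support = mt.bootstrap_support(labels, aligned, replicates=20, seed=seed)
            assert all(0 <= v <= 100 for v in support.values())

    def test_deterministic_under_fixed_seed(self, study_config):
        labels, aligned = _four_isoform_alignment(study_config, n_per_group=2)
        r1 = mt.bootstrap_support(labels, aligned, replicates=30, seed=5)
        r2 = mt.bootstrap_support(labels, aligned, replicates=30, seed=5)
        assert r1[1] == r2[1]
        assert str(r1[0]) == str(r2[0])

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError, match="2 columns"):
            mt.bootstrap_support(["a", "b", "c"], ["A", "A", "T"], replicates=5, seed=0)

    def test_four_isoform_groups_strongly_supported(self, study_config):
        labels, aligned = _four_isoform_alignment(study_config)
        tree, support = mt.bootstrap_support(labels, aligned, replicates=100, seed=42)
        splits = tree_bipartitions(tree)
        leaves = set(labels)
        for isoform in ("Mt1", "Mt2", "Mt3", "Mt4"):
            group = frozenset(l for l in labels if l.startswith(isoform))
            split = group if min(leaves) not in group else frozenset(leaves - group)
            assert split in splits, f"{isoform} not monophyletic"
            assert support[split] >= 95


# ---------------------------------------------------------------------------
# Isoform classification

class TestClassifyIsoform:
    def test_three_exon_mt3_high_confidence(self, study, study_refs):
        truth = study[0]
        target = next(m for m in truth.annotations if m.isoform == "Mt3")
        call = mt.classify_isoform(target, study_refs)
        assert call.isoform == "Mt3"
        assert call.confidence == "high"
        assert call.evidence["exon3_length"] in (104, 107)
        assert call.evidence["nearest_reference"] == "Mt3"

    def test_intron_free_model_single_evidence_line(self, study_config, study_refs, rng):
        _, model = mt.simulate_gene("Mt1", study_config, rng, intron_free=True)
        call = mt.classify_isoform(model, study_refs)
        assert call.isoform == "Mt1"
        assert call.confidence == "medium"
        assert "exon3_length" not in call.evidence

    def test_equidistant_references_give_unknown(self, study, study_refs):
        target = next(m for m in study[0].annotations if m.isoform == "Mt1")
        same_ref = study_refs["Mt1"][0]
        ambiguous = {
            "Mt1": [same_ref],
            "Mt2": [SequenceRecord(id="Mt2_same", residues=same_ref.residues)],
        }
        call = mt.classify_isoform(target, ambiguous)
        assert call.isoform == "unknown"
        assert call.confidence == "low"

    def test_simulator_labels_recovered(self, study, study_refs):
        """Classification matches the simulator's isoform for every gene."""
        for truth in study:
            for model in truth.annotations:
                call = mt.classify_isoform(model, study_refs)
                assert call.isoform == model.isoform
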