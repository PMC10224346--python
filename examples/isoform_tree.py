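"""Four-isoform phylogeny: K2P distances, NJ tree, bootstrap support.

Builds coding sequences for five species per isoform (deep divergence
between isoforms, shallow within), computes the Kimura two-parameter
distance matrix and a neighbor-joining tree, and bootstraps the
alignment columns.
"""

import numpy as np

import mtminer as mt
from mtminer.phylo import tree_bipartitions
from mtminer.simulate import ancestral_genes, diverge_cds

config = mt.SimulationConfig(seed=12)
ancestors = ancestral_genes(config)
rng = np.random.default_rng(99)

records = [
    mt.SequenceRecord(
        id=f"{isoform}_sp{i}",
        residues=diverge_cds(anc.cds, config.species_divergence, rng),
    )
    for isoform, anc in ancestors.items()
    for i in range(5)
]
labels, aligned = mt.star_msa(records)
dm = mt.k2p_matrix(labels, aligned)
print(f"K2P distances: within-isoform ~{dm[('Mt1_sp0', 'Mt1_sp1')]:.3f}, "
      f"between-isoform ~{dm[('Mt1_sp0', 'Mt3_sp0')]:.3f}")

tree, support = mt.bootstrap_support(labels, aligned, replicates=100, seed=0)
splits = tree_bipartitions(tree)
leaves = set(labels)
anchor = min(leaves)
print("\nbootstrap support of the isoform clades (100 replicates):")
for isoform in ("Mt1", "Mt2", "Mt3", "Mt4"):
    group = frozenset(l for l in labels if l.startswith(isoform))
    split = group if anchor not in group else frozenset(leaves - group)
    print(f"  {isoform}: {'monophyletic' if split in splits else 'NOT monophyletic'},"
          f" support {support.get(split, 0)}")

print("\nNewick (support values on internal nodes):")
print(str(tree).strip())

# With ~25x deeper between-isoform than within-isoform divergence the
# four isoform clades are recovered as monophyletic with near-100
# bootstrap support, mirroring the four-cluster structure of the MT
# gene family.
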