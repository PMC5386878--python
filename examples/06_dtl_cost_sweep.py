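"""DTL reconciliation and the transfer-cost sweep.

Reconciles 100 moderately discordant gene trees against their species tree
under duplication/transfer/loss parsimony and sweeps the transfer cost from
3 (the usual default) to 30.
"""

from lgt_audit import dtl, synthdata

species = synthdata.simulate_species_tree(8, seed=4)
gene_trees = [synthdata.simulate_gene_tree(species, 1 + s % 2, seed=s)
              for s in range(100)]

rec = dtl.reconcile(gene_trees[0], species)
print(f"first tree: min cost {rec.min_cost:.0f} "
      f"(D={rec.n_duplications}, T={rec.n_transfers}, L={rec.n_losses})")

sweep = dtl.cost_sweep(gene_trees, species, transfer_costs=range(3, 31, 3))
print("\ntransfer cost -> % of trees with >= 1 transfer")
for row in sweep.itertuples(index=False):
    print(f"  {int(row.transfer_cost):2d} -> {100 * row.fraction_with_transfer:5.1f}%")
print("At the default cost nearly every discordant tree is 'explained' by a "
      "transfer; raising the cost collapses the calls - the inverse-like "
      "sensitivity that makes default-cost DTL predictions unreliable.")
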