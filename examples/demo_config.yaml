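# Demo audit: 8 species, 60 single-copy genes each, 10 planted transfers
# from the most distant species into the reference. Runs in about a minute.
n_species: 8
genes_per_species: 60
n_lgt_events: 10
discordance_rearrangements: 1
base_gc3: 0.50
gc3_spread: 0.06
codon_bias_strength: 1.0
n_sites: 400
n_aic_controls: 10
transfer_cost_min: 3
transfer_cost_max: 30
transfer_cost_step: 3
seed: 0
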