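# Methods

This note documents the models, parameter choices, and numerical conventions
behind `lgt_audit`, and what the synthetic experiments do and do not show.

## The synthetic study system

All experiments run on generated data with known ground truth. The generator
is first-class, tested code, and its defaults define the study conditions.

**Species tree.** A pure-birth (Yule) process with rate 1: lineages split
uniformly at random with exponential waiting times, and all tips end at the
final event time, giving an ultrametric rooted binary tree with positive
branch lengths (in expected-event units; stages that need substitution-scale
lengths multiply by `branch_scale`, default 0.1).

**Gene trees.** Each single-copy gene tree starts as the species tree and
receives a configurable number of random subtree-prune-and-regraft moves
(`discordance_rearrangements`, default 1). A single knob reproduces the full
spectrum of observed gene-tree/species-tree discordance — it does not model
the *causes* (incomplete lineage sorting, estimation error, paralogy), only
the topological effect, which is all the downstream statistics see.
Bootstrap-style supports (default 100, optional uniform noise) are written
on internal edges.

**Coding sequences.** Genes are codon-resampled: lengths are normal (mean
300, sd 80 codons, floored at 10, start and stop included), the first codon
is ATG, the last a uniform stop (TAA/TAG/TGA), and interior codons are drawn
amino-acid-uniform, then codon-conditional on a per-species usage table.
Within each synonymous family the codon probability is a softmax over
`bias·[preferred codon] + θ·[third base is G or C]`; the preferred codon per
family is a species-level trait (keyed by `usage_tag`, so close relatives
can share preferences), and θ is solved by bisection so the expected GC3
equals `gc3_target`. Because only sense codons are sampled, no internal
in-frame stop can occur. GC3 targets outside the achievable range (the
single-codon families Met/Trp pin part of GC3; the range is roughly
[0.10, 0.97]) raise an explicit infeasibility error. Under uniform usage
(bias 0, `gc3_target = uniform_usage_gc3() ≈ 0.542`) the pooled usage
attains Wright's ENC maximum of 61, a closed-form anchor used in testing.

**Planted transfers.** An LGT event from donor D to recipient R in family f
replaces R's CDS by D's ortholog (`sequence_swap`), prunes R's leaf and
regrafts it as sister to D's leaf (`leaf_regraft`), or both (the default;
the real mechanism does both at once). One truth record per event.

**Alignments.** Site-independent evolution under JC69 or HKY85 from a root
draw at equilibrium, with optional continuous-gamma rate multipliers.
Transition matrices come from the symmetrised eigendecomposition of the
normalised generator; branch lengths are expected substitutions per site.

**Hit tables.** True ortholog pairs appear as mutual hits with E-values
log-uniform in [1e-50, 1e-10]; noise adds one-way hits at least a decade
worse, so decoys can never displace a true best hit. This makes the
noise-free RBBH round-trip exact by construction — the test of the *caller*
is the decoy-rejection property, not the recovery.

**Randomness.** Every generator draws from a named substream of a single
seed (crc32-keyed `SeedSequence` spawn keys), so outputs are byte-stable and
adding a generator never perturbs the others.

## Composition metrics

- **GC / GC3**: fraction of G+C over unambiguous bases; GC3 over third codon
  positions. N is excluded from numerator and denominator.
- **CAI**: geometric mean of relative adaptiveness `w_c`, computed in log
  space; stop codons and the single-codon families (Met, Trp) are excluded,
  and the empty product returns 1. The reference usage defaults to the
  pooled usage of the same species' input gene set (self-contained and
  reproducible; a highly-expressed reference set can be supplied instead).
  Zero-count reference codons receive pseudo-count 0.5 before forming `w`.
- **ENC**: Wright's estimator with the 6-fold families (Leu, Ser, Arg) kept
  whole. Families seen fewer than twice, or with non-positive homozygosity,
  are skipped; a degeneracy class with no usable family borrows the mean
  homozygosity of the observed classes; the value is clamped at 61 (finite
  samples of uniform usage give F̂ slightly below 1/k and would otherwise
  exceed the analytic maximum). Genes where no family is observed twice have
  no defined ENC and are excluded from profiling with a warning.
- **Tetranucleotides**: overlapping 4-mers on the coding strand only, genes
  (not genomic windows) as the unit; windows containing N are dropped; not
  strand-symmetrised. The discriminative selector ranks 4-mers by absolute
  standardised mean difference; a zero-pooled-sd 4-mer with differing means
  separates perfectly and ranks first.
- **Tail outliers**: per tail, `floor(α·n)` genes by rank (ties broken by
  id), with the strictness rule that a flagged gene must lie strictly inside
  its tail relative to the opposite tail boundary — a constant sample flags
  nothing.

## Overlap and clustering

The percentage overlap of two metric distributions is histogram
intersection: `100 · Σ_b min(f_a(b), f_b(b))` on one Freedman–Diaconis grid
spanning the pooled range. It is exactly symmetric, exactly 100 for
identical samples (integer arithmetic), 0 for disjoint supports, and
invariant under common affine rescaling. Histogram intersection
underestimates the true overlap at small n (the minimum of two noisy
proportions is biased down by a few points at n ≈ 100); validation is
against the analytic Gaussian overlap `2Φ(−δ/2)` at large n, not against any
published table computed on real data with an unrecoverable estimator.

Clustering asks whether any substantial group of genes stands apart
compositionally. Features (GC, GC3, CAI, ENC, 256 tetranucleotide
frequencies) are z-scored per column; constant columns are dropped.
Mean-shift bandwidth is the mean distance to the ⌈0.3·n⌉-th nearest
neighbour. Kernel mode-seeking in this many dimensions reliably leaves
satellite modes of a handful of outlying genes around one dominant mode, so
modes holding fewer than 5% of genes are absorbed into the nearest
substantial mode before counting — without this rule the cluster count
measures sample noise, not structure. DBSCAN's `eps`, when not given, comes
from the k-distance heuristic (90th percentile of the distance to the
`min_samples`-th neighbour, inflated 1.5×). The tetranucleotide block can be
truncated to the 32 highest-variance 4-mers for speed (off by default).

## Orthology

Best hits keep, per query, the subject with the smallest E-value at an
inclusive E ≤ 1e-5 ceiling, collapsing multiple HSPs per query–subject pair
first; ties break by higher bitscore, then lexicographic subject id (the tie
rule is a determinism choice, not biology). A pair is orthologous iff it is
the best hit in both directions. Groups anchor on a reference species;
conflicting assignments raise rather than silently overwrite, and groups
with fewer than 4 species are flagged as too small for topology tests.

## Tree statistics

All distances operate on unrooted non-trivial bipartitions after restricting
both trees to their shared leaf set (equivalent to pruning first, and
order-independent). `max_RF` is the sum of the two restricted trees'
non-trivial split counts, which handles polytomies and asymmetric collapse
gracefully; two star trees are at distance 0. Rooting on a shared outgroup
does not change unrooted splits, so the outgroup argument is validated but
cannot alter the distance. Support filtering contracts internal edges with
support below 75 (inclusive keep at 75) and refuses trees without supports.
Polytomies resolve deterministically into zero-length cherries by sorted
child order; a seeded random order exists to expose sensitivity to the
arbitrary resolution. The supertree stand-in is the extended majority-rule
consensus; its bootstrap follows the resample-gene-trees-with-replacement
scheme, support being the percentage of replicate consensus trees containing
the branch. The RFn null shuffles each gene tree's leaf labels, preserving
shape and branch lengths, hence the gene-tree size distribution.

## The constrained-topology AIC test

Likelihood is Felsenstein pruning over unique site patterns with per-node
rescaling; JC69 and HKY85 are used throughout (nucleotide models keep every
quantity checkable in closed form; the test logic is model-agnostic).
Branch lengths are optimised coordinate-wise (bounded Brent per branch,
bounds [1e-8, 10], post-order sweep order, kappa likewise for HKY85) until
the lnL gain per sweep is below 1e-6 or 50 sweeps. Each gene is fitted on
its unconstrained topology (supplied, or neighbour-joining from JC-corrected
distances — no likelihood topology search is performed) and on the species
topology pruned to its taxa; `ΔAIC = AIC_constrained − AIC_unconstrained`
with `AIC = 2k − 2 lnL`, k counting branch lengths plus model parameters.
The verdict threshold is ΔAIC > 10, the conventional strong-evidence bound;
the number of internal branches of the pruned species topology is reported
as the comparison's degrees-of-freedom bookkeeping but is deliberately not
converted into a p-value. The calibration experiment reports type-I error on
congruent genes and power on one-regraft genes with Jeffreys 95% intervals;
at desk scale (6 species, 500 sites, branch scale 0.1) type-I error is ~0
and power is partial, dropping further at shorter sequences — the low-power
regime this test is known for.

## DTL reconciliation

The undated duplication–transfer–loss parsimony model (the cited tools'
default mode): `c(g, s)` is the cost of gene subtree g with its event on
species node s, computed with an enter-subtree table charging one loss per
skipped species edge and an outside table for transfer landings on
incomparable nodes. Time-consistency of transfers is not enforced. Default
costs are duplication 2, transfer 3, loss 1; speciation is free. One optimal
scenario is reconstructed by backtracking that prefers speciation >
duplication > transfer at equal cost, then the lowest species-node index —
the most conservative optimum with respect to transfer calls.
`min_cost = 2D + 3T + L` is verified exactly on every reconstruction.
Whether *every* optimum needs a transfer is answered by
`min_transfers_among_optima`, a perturbation rerun with the transfer cost
raised by ε = 1e-6 (exact whenever ε times the maximal transfer count is
below the spacing of achievable costs, true for integer schemes). The cost
sweep reports, per transfer cost in 3…30, the fraction of trees whose
reported optimum contains a transfer.

## Pipeline and problem sizes

The audit chains simulate → composition → overlap/cluster → RBBH → tree
statistics → AIC test → DTL sweep → truth evaluation. Every threshold is a
named config key with the audit's standard default (E ≤ 1e-5, support ≥ 75,
tails 2.5%, transfer costs 3–30, ΔAIC 10). The manifest records the config
hash, seed, stage order, and SHA-256 of every output, and contains no
timestamps, so identical config+seed runs are byte-identical; `--resume`
reloads existing stage outputs and recomputes only downstream stages.

Default experiment sizes are chosen as desk-scale versions of a genome
study: 8 species × 200 genes for the library default, 60 genes per species
in the demo configuration, 200 replicates for the AIC calibration, 500
random instances for the DTL cross-validation suite, and 50 seeded runs for
the clustering reproduction. These sizes give stable Monte-Carlo estimates
(binomial s.e. ≤ ~3.5 points) while keeping the whole suite in minutes.

## Limitations

- The generator has no indels, introns, rate heterogeneity across genes,
  coalescent/ILS model, or genome spatial structure (isochores, repeats) —
  so passing tests show the *methods* behave as designed, not that real
  fungal genomes are this clean. In particular, composition-based detection
  is *easier* here than in real data (no AT-rich isochores to confound it),
  which strengthens, rather than weakens, the negative result on its power.
- Nucleotide models stand in for protein-model inference; conclusions about
  the AIC test's calibration transfer because the test logic never inspects
  the model beyond its likelihood.
- The supertree is a consensus stand-in, not an SPR-distance optimiser; only
  the bootstrap-support procedure around it is exercised.
- `has_transfer` reports one deterministic optimum; co-optimal scenario
  space is summarised only through the minimum transfer count.
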