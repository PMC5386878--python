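import numpy as np
import pytest

from _oracles import random_binary_tree, rf_graph
from lgt_audit import synthdata as sd
from lgt_audit import treecmp as tc
from lgt_audit.errors import InvalidArgumentError
from lgt_audit.treeio import leaf_labels, tree_from_newick, tree_to_newick


def nwk(s):
    return tree_from_newick(s)


class TestCollapseLowSupport:
    def test_high_supports_leave_tree_unchanged(self):
        t = nwk("((a:1,b:1)100:1,(c:1,d:1)100:1);")
        out = tc.collapse_low_support(t, 75)
        assert tc.normalized_rf(out, t) == 0.0

    def test_all_low_supports_give_star(self):
        t = nwk("((a:1,b:1)50:1,((c:1,d:1)50:1,e:1)50:1);")
        out = tc.collapse_low_support(t, 75)
        assert tc.nontrivial_splits(out) == set()

    def test_threshold_is_inclusive(self):
        t = nwk("((a:1,b:1)75:1,((c:1,d:1)74:1,e:1)75:1);")
        out = tc.collapse_low_support(t, 75)
        # edges at exactly 75 retained, the 74 edge (split c|d) contracted
        assert tc.nontrivial_splits(t) == {frozenset("cde"), frozenset("cd")}
        assert tc.nontrivial_splits(out) == {frozenset("cde")}

    def test_missing_support_raises(self):
        t = nwk("((a:1,b:1):1,(c:1,d:1)90:1);")
        with pytest.raises(InvalidArgumentError):
            tc.collapse_low_support(t, 75)

    def test_leaf_set_never_changes(self):
        t = nwk("((a:1,b:1)10:1,((c:1,d:1)99:1,e:1)10:1);")
        out = tc.collapse_low_support(t, 75)
        assert leaf_labels(out) == leaf_labels(t)


class TestResolvePolytomies:
    def test_binary_input_is_noop(self):
        t = nwk("((a:1,b:1):1,(c:1,d:1):1);")
        out = tc.resolve_polytomies(t)
        assert tc.normalized_rf(out, t) == 0.0

    def test_star_tree_becomes_binary(self):
        star = nwk("(a:1,b:1,c:1,d:1);")
        out = tc.resolve_polytomies(star)
        internal = [n for n in out.preorder_internal_node_iter()]
        assert all(len(n.child_nodes()) == 2 for n in internal)
        assert len(internal) == 3  # root + 2 added nodes on 4 leaves

    def test_deterministic_and_idempotent(self):
        star = nwk("(a:1,b:1,c:1,e:1,d:1);")
        once = tc.resolve_polytomies(star)
        twice = tc.resolve_polytomies(tc.resolve_polytomies(star))
        assert tree_to_newick(once) == tree_to_newick(twice)

    def test_positively_supported_splits_preserved(self):
        t = nwk("((a:1,b:1)90:1,(c:1,d:1)40:1,e:1);")
        resolved = tc.resolve_polytomies(t)
        assert tc.nontrivial_splits(t) <= tc.nontrivial_splits(resolved)


class TestNormalizedRf:
    def test_identical_trees_zero(self, species8):
        assert tc.normalized_rf(species8, species8) == 0.0

    def test_conflicting_quartets_give_one(self, quartet_trees):
        t1, t2 = quartet_trees
        assert tc.normalized_rf(t1, t2) == 1.0

    def test_random_pairs_match_graph_oracle(self, rng):
        labels = [f"t{i}" for i in range(8)]
        for _ in range(200):
            a = random_binary_tree(labels, rng)
            b = random_binary_tree(labels, rng)
            rf, max_rf = tc.robinson_foulds(a, b)
            orf, omax = rf_graph(a, b)
            assert (rf, max_rf) == (orf, omax)

    def test_pseudo_metric_properties(self, rng):
        labels = [f"t{i}" for i in range(7)]
        for _ in range(40):
            a, b, c = (random_binary_tree(labels, rng) for _ in range(3))
            ab, _ = tc.robinson_foulds(a, b)
            ba, _ = tc.robinson_foulds(b, a)
            assert ab == ba
            ac, _ = tc.robinson_foulds(a, c)
            cb, _ = tc.robinson_foulds(c, b)
            assert ab <= ac + cb

    def test_pruning_to_shared_leaves_is_order_independent(self, rng):
        a = random_binary_tree([f"t{i}" for i in range(10)], rng)
        b = random_binary_tree([f"t{i}" for i in range(3, 13)], rng)
        assert tc.normalized_rf(a, b) == tc.normalized_rf(b, a)

    def test_too_few_shared_leaves_rejected(self):
        a = nwk("((a:1,b:1):1,(c:1,x:1):1);")
        b = nwk("((a:1,b:1):1,(y:1,z:1):1);")
        with pytest.raises(InvalidArgumentError):
            tc.normalized_rf(a, b)

    def test_outgroup_must_be_shared(self, quartet_trees):
        t1, t2 = quartet_trees
        with pytest.raises(InvalidArgumentError):
            tc.normalized_rf(t1, t2, outgroup="zzz")


class TestBipartitionFrequencies:
    def test_identical_gene_trees_give_100_everywhere(self, species8):
        freqs = tc.bipartition_frequencies(species8, [species8] * 5)
        assert freqs and all(v == 100.0 for v in freqs.values())

    def test_direct_count(self):
        sp = nwk("((a:1,b:1):1,(c:1,d:1):1);")
        match = nwk("((a:1,b:1):1,(c:1,d:1):1);")
        differ = nwk("((a:1,c:1):1,(b:1,d:1):1);")
        freqs = tc.bipartition_frequencies(sp, [match, match, differ, differ])
        assert set(freqs.values()) == {50.0}

    def test_mean_frequency_decreases_with_discordance(self, species8):
        means = []
        for k in (0, 2, 5):
            trees = [sd.simulate_gene_tree(species8, k, seed=s) for s in range(40)]
            freqs = tc.bipartition_frequencies(species8, trees)
            means.append(np.mean(list(freqs.values())))
        assert means[0] == 100.0 and means[0] > means[1] > means[2]

    def test_empty_gene_tree_list_rejected(self, species8):
        with pytest.raises(InvalidArgumentError):
            tc.bipartition_frequencies(species8, [])


class TestExactMatchFraction:
    def test_all_identical(self, species8):
        assert tc.exact_match_fraction([species8] * 4, species8) == 1.0

    def test_none_identical(self, species8):
        trees = [sd.simulate_gene_tree(species8, 3, seed=s) for s in range(5)]
        fracs = tc.exact_match_fraction(trees, species8)
        assert fracs <= 0.2

    def test_planted_half_and_half(self, species8):
        concordant = [sd.simulate_gene_tree(species8, 0, seed=s) for s in range(20)]
        discordant = []
        for s in range(100, 200):
            t = sd.simulate_gene_tree(species8, 3, seed=s)
            if tc.normalized_rf(t, species8) > 0:
                discordant.append(t)
            if len(discordant) == 20:
                break
        frac = tc.exact_match_fraction(concordant + discordant, species8)
        assert frac == pytest.approx(0.5)


class TestSupertreeBootstrap:
    def test_identical_gene_trees_give_full_support(self, species8):
        trees = [species8] * 12
        consensus = tc.supertree_bootstrap(trees, n_replicates=25, seed=1)
        assert tc.normalized_rf(consensus, species8) == 0.0
        supports = [float(n.label) for n in consensus.preorder_internal_node_iter()
                    if n.parent_node is not None and n.label]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_binary_valued(self, species8):
        trees = [sd.simulate_gene_tree(species8, 1, seed=s) for s in range(12)]
        consensus = tc.supertree_bootstrap(trees, n_replicates=1, seed=3)
        supports = {float(n.label) for n in consensus.preorder_internal_node_iter()
                    if n.parent_node is not None and n.label}
        assert supports <= {0.0, 100.0}

    def test_concordant_majority_recovers_species_branches(self, species8):
        trees = [species8] * 40 + [sd.simulate_gene_tree(species8, 2, seed=s)
                                   for s in range(10)]
        consensus = tc.supertree_bootstrap(trees, n_replicates=50, seed=5)
        assert tc.normalized_rf(consensus, species8) == 0.0
        supports = [float(n.label) for n in consensus.preorder_internal_node_iter()
                    if n.parent_node is not None and n.label]
        assert np.mean(supports) > 90

    def test_too_few_trees_rejected(self, species8):
        with pytest.raises(InvalidArgumentError):
            tc.supertree_bootstrap([species8] * 5, n_replicates=10, seed=0)


class TestRfNull:
    def test_null_sample_reproducible_and_sized(self, species8):
        trees = [sd.simulate_gene_tree(species8, 1, seed=s) for s in range(10)]
        a = tc.rf_null_distribution(trees, species8, n_shuffles=2, seed=9)
        b = tc.rf_null_distribution(trees, species8, n_shuffles=2, seed=9)
        assert np.array_equal(a, b)
        assert a.shape == (20,)

    def test_null_mean_exceeds_observed_for_concordant_trees(self, species8):
        trees = [sd.simulate_gene_tree(species8, 1, seed=s) for s in range(25)]
        observed = np.mean([tc.normalized_rf(t, species8) for t in trees])
        null = tc.rf_null_distribution(trees, species8, n_shuffles=2, seed=1)
        assert null.mean() > observed
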