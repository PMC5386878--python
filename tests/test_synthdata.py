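import math

import numpy as np
import pytest

from lgt_audit import composition as comp
from lgt_audit import synthdata as sd
from lgt_audit import treecmp
from lgt_audit.errors import InfeasibleCompositionError, InvalidArgumentError
from lgt_audit.models import jc69
from lgt_audit.treeio import leaf_labels, tree_from_newick, tree_to_newick


class TestSpeciesTree:
    def test_node_counts_and_positive_lengths(self):
        tree = sd.simulate_species_tree(3, seed=1)
        assert len(tree.leaf_nodes()) == 3
        assert len(tree.internal_nodes()) == 2
        tree = sd.simulate_species_tree(12, seed=1)
        assert len(tree.leaf_nodes()) == 12
        assert len(tree.internal_nodes()) == 11
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length > 0

    def test_determinism_under_fixed_seed(self):
        a = tree_to_newick(sd.simulate_species_tree(8, seed=1))
        b = tree_to_newick(sd.simulate_species_tree(8, seed=1))
        assert a == b

    def test_different_seeds_usually_differ(self):
        n_distinct = 0
        for s in range(30):
            a = sd.simulate_species_tree(8, seed=2 * s)
            b = sd.simulate_species_tree(8, seed=2 * s + 1)
            if treecmp.normalized_rf(a, b) > 0:
                n_distinct += 1
        assert n_distinct >= 27

    def test_too_few_species_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sd.simulate_species_tree(2, seed=0)


class TestGeneTree:
    def test_zero_moves_identical_topology(self, species8):
        gene = sd.simulate_gene_tree(species8, 0, seed=5)
        assert treecmp.normalized_rf(gene, species8) == 0.0
        assert leaf_labels(gene) == leaf_labels(species8)

    def test_one_move_creates_discordance_almost_always(self, species8):
        n_discordant = sum(
            treecmp.normalized_rf(sd.simulate_gene_tree(species8, 1, seed=s), species8) > 0
            for s in range(100)
        )
        assert n_discordant >= 90

    def test_mean_discordance_monotone_in_moves(self, species8):
        means = []
        for k in (0, 1, 3, 5):
            vals = [
                treecmp.normalized_rf(sd.simulate_gene_tree(species8, k, seed=s), species8)
                for s in range(60)
            ]
            means.append(np.mean(vals))
        assert means == sorted(means)
        assert means[0] == 0.0 and means[-1] > means[1]

    def test_supports_written_on_internal_edges(self, species8):
        gene = sd.simulate_gene_tree(species8, 1, seed=2, support=90, support_noise=20)
        for node in gene.preorder_internal_node_iter():
            if node.parent_node is not None:
                assert 70 <= float(node.label) <= 90


class TestCodingSequences:
    def test_construction_constraints(self):
        cfg = sd.SimulationConfig(genes_per_species=50, length_distribution=(60, 15))
        seqs = sd.simulate_coding_sequences(cfg, "spX", seed=0)
        stops = {"TAA", "TAG", "TGA"}
        for s in seqs:
            assert len(s.seq) % 3 == 0 and len(s.seq) >= 30
            assert s.seq.startswith("ATG")
            assert s.seq[-3:] in stops
            interior = [s.seq[i:i + 3] for i in range(3, len(s.seq) - 3, 3)]
            assert not (set(interior) & stops)

    def test_gc3_converges_to_target(self):
        cfg = sd.SimulationConfig(genes_per_species=1500, gc3_target=0.5,
                                  length_distribution=(150, 30))
        seqs = sd.simulate_coding_sequences(cfg, "spX", seed=7)
        mean_gc3 = np.mean([comp.gc3(s.seq) for s in seqs])
        assert 0.47 <= mean_gc3 <= 0.53

    def test_infeasible_target_raises(self):
        with pytest.raises(InfeasibleCompositionError):
            sd.build_codon_usage(0.01, 0.0, seed=0)

    def test_unbiased_usage_attains_enc_maximum(self):
        cfg = sd.SimulationConfig(genes_per_species=150,
                                  gc3_target=sd.uniform_usage_gc3(),
                                  codon_bias_strength=0.0)
        seqs = sd.simulate_coding_sequences(cfg, "spX", seed=1)
        pooled_enc = comp.enc("".join(s.seq for s in seqs))
        assert pooled_enc == pytest.approx(61.0, abs=0.5)

    def test_determinism(self):
        cfg = sd.SimulationConfig(genes_per_species=10)
        a = sd.simulate_coding_sequences(cfg, "spX", seed=3)
        b = sd.simulate_coding_sequences(cfg, "spX", seed=3)
        assert [s.seq for s in a] == [s.seq for s in b]


class TestRandomize:
    def test_length_and_terminal_codons_kept(self):
        seq = comp.CodingSequence("g", "sp", "ATG" + "GCT" * 40 + "TGA")
        out = sd.randomize_sequence(seq, seed=1)
        assert len(out.seq) == len(seq.seq)
        assert out.seq.startswith("ATG") and out.seq.endswith("TGA")

    def test_interior_bases_uniform(self):
        seq = "ATG" + "GCA" * 3000 + "TAA"
        out = sd.randomize_sequence(seq, seed=5)
        interior = out[3:-3]
        freqs = {b: interior.count(b) / len(interior) for b in "ACGT"}
        for b in "ACGT":
            assert freqs[b] == pytest.approx(0.25, abs=0.02)

    def test_gc_of_randomized_sequence_near_half(self):
        values = [
            comp.gc_content(sd.randomize_sequence("ATG" + "AAA" * 998 + "TAA", seed=s))
            for s in range(50)
        ]
        assert np.mean(values) == pytest.approx(0.5, abs=0.02)

    def test_missing_stop_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sd.randomize_sequence("ATGGCTGCA", seed=0)


class TestPlantLgt:
    @pytest.fixture
    def dataset(self, species8):
        cfg = sd.SimulationConfig(n_species=8, genes_per_species=15, seed=5)
        names = [sd.species_label(i) for i in range(8)]
        per_sp = {
            sp: sd.simulate_coding_sequences(cfg, sp, seed=5) for sp in names
        }
        fams = [f"fam{i:03d}" for i in range(15)]
        sequences = {f: {sp: per_sp[sp][i] for sp in names} for i, f in enumerate(fams)}
        trees = {f: sd.simulate_gene_tree(species8, 1, seed=i) for i, f in enumerate(fams)}
        return sequences, trees

    def test_regraft_mode_makes_recipient_donor_cherry(self, dataset):
        sequences, trees = dataset
        planted = sd.plant_lgt(sequences, trees, "sp08", "sp01", 5,
                               mode="leaf_regraft", seed=1)
        for rec in planted.records:
            tree = planted.gene_trees[rec.family_id]
            leaf = next(lf for lf in tree.leaf_node_iter()
                        if lf.taxon.label == "sp01")
            cherry = {l.taxon.label for l in leaf.parent_node.leaf_iter()}
            assert cherry == {"sp01", "sp08"}

    def test_swap_mode_copies_donor_sequence(self, dataset):
        sequences, trees = dataset
        planted = sd.plant_lgt(sequences, trees, "sp08", "sp01", 5,
                               mode="sequence_swap", seed=1)
        for rec in planted.records:
            fam = rec.family_id
            assert planted.sequences[fam]["sp01"].seq == planted.sequences[fam]["sp08"].seq
            assert planted.sequences[fam]["sp01"].id == sequences[fam]["sp01"].id

    def test_truth_record_count_and_distinct_genes(self, dataset):
        sequences, trees = dataset
        planted = sd.plant_lgt(sequences, trees, "sp08", "sp01", 10, seed=2)
        assert len(planted.records) == 10
        assert len({r.gene_id for r in planted.records}) == 10

    def test_too_many_events_rejected(self, dataset):
        sequences, trees = dataset
        with pytest.raises(InvalidArgumentError):
            sd.plant_lgt(sequences, trees, "sp08", "sp01", 16, seed=0)

    def test_unmodified_families_untouched(self, dataset):
        sequences, trees = dataset
        planted = sd.plant_lgt(sequences, trees, "sp08", "sp01", 3, seed=4)
        touched = {r.family_id for r in planted.records}
        for fam in sequences:
            if fam not in touched:
                assert planted.sequences[fam]["sp01"].seq == sequences[fam]["sp01"].seq


class TestEvolveAlignment:
    def test_zero_branch_lengths_give_identical_rows(self):
        tree = tree_from_newick("((a:0,b:0):0,(c:0,d:0):0);")
        aln = sd.evolve_alignment(tree, 200, seed=1)
        assert len(set(aln.values())) == 1

    def test_two_taxon_jc_mismatch_fraction(self):
        d = 0.1
        tree = tree_from_newick(f"(a:{d / 2},b:{d / 2});")
        aln = sd.evolve_alignment(tree, 100_000, model=jc69(), seed=2)
        mismatch = np.mean([x != y for x, y in zip(aln["a"], aln["b"])])
        expected = 0.75 * (1 - math.exp(-4 * d / 3))
        assert mismatch == pytest.approx(expected, abs=0.005)

    def test_determinism(self, species8):
        a = sd.evolve_alignment(species8, 100, seed=9)
        b = sd.evolve_alignment(species8, 100, seed=9)
        assert a == b

    def test_missing_branch_length_rejected(self):
        tree = tree_from_newick("((a:1,b:1),(c:1,d:1):1);")
        with pytest.raises(InvalidArgumentError):
            sd.evolve_alignment(tree, 10, seed=0)


class TestHitTable:
    def test_empty_truth_gives_empty_table(self):
        assert len(sd.generate_hit_table([], seed=0)) == 0

    def test_true_pairs_pass_threshold(self):
        table = sd.generate_hit_table([("a1", "b1")], seed=1)
        assert (table.evalue <= 1e-5).all()

    def test_invalid_noise_rate(self):
        with pytest.raises(InvalidArgumentError):
            sd.generate_hit_table([("a", "b")], noise_rate=1.0)


class TestShuffleLeaves:
    def test_label_multiset_and_lengths_preserved(self, species8):
        shuffled = sd.shuffle_tree_leaves(species8, seed=3)
        assert leaf_labels(shuffled) == leaf_labels(species8)
        orig = sorted(n.edge.length for n in species8.preorder_node_iter()
                      if n.parent_node is not None)
        new = sorted(n.edge.length for n in shuffled.preorder_node_iter()
                     if n.parent_node is not None)
        assert np.allclose(orig, new)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sd.shuffle_tree_leaves(tree_from_newick("((a:1,b:1):1,c:1);"), seed=0)

    def test_caterpillar_shuffles_near_null_maximum(self):
        newick = "(" * 19 + "t01:1," + ",".join(f"t{i:02d}:1)" + ":1" for i in range(2, 20))
        newick += f",t20:1);"
        cat = tree_from_newick(newick)
        assert len(cat.leaf_nodes()) == 20
        vals = [
            treecmp.normalized_rf(sd.shuffle_tree_leaves(cat, seed=s), cat)
            for s in range(300)
        ]
        assert np.mean(vals) > 0.8


def test_fasta_writer_wraps_at_60(tmp_path):
    seq = comp.CodingSequence("g1", "sp", "ATG" + "GCT" * 60 + "TAA")
    path = tmp_path / "out.fasta"
    sd.write_fasta([seq], path)
    lines = path.read_text().splitlines()
    assert lines[0] == ">g1"
    assert all(len(l) <= 60 for l in lines[1:])
    back = comp.read_fasta(path, "sp")
    assert back[0].seq == seq.seq
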