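import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import enc_spreadsheet
from lgt_audit import composition as comp
from lgt_audit._codons import SENSE_CODONS, SYNONYMOUS_FAMILIES, TETRANUCLEOTIDES
from lgt_audit.errors import (
    DegenerateInputError,
    FrameError,
    InvalidArgumentError,
    UndefinedMetricError,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=120)


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 0.5), ("GGCC", 1.0), ("ATGGCCTAA", 4 / 9), ("NNGC", 1.0), ("AANN", 0.0)],
)
def test_gc_content_hand_counts(seq, expected):
    assert comp.gc_content(seq) == pytest.approx(expected)


def test_gc_content_errors():
    with pytest.raises(InvalidArgumentError):
        comp.gc_content("")
    with pytest.raises(UndefinedMetricError):
        comp.gc_content("NNNN")


@pytest.mark.parametrize(
    "seq,expected",
    [("ATG", 1.0), ("ATGAAAGGG", 2 / 3), ("AAAAATTTT", 0.0), ("GCGGCG", 1.0)],
)
def test_gc3_hand_counts(seq, expected):
    assert comp.gc3(seq) == pytest.approx(expected)


def test_gc3_requires_frame():
    with pytest.raises(FrameError):
        comp.gc3("ATGA")


class TestCai:
    def test_all_preferred_codons_give_one(self):
        # reference in which GCT (Ala) and AAA (Lys) dominate their families
        table = comp.CodonUsageTable({"GCT": 10, "GCC": 2, "AAA": 8, "AAG": 1})
        assert comp.cai("GCTAAA" * 5, table) == pytest.approx(1.0)

    def test_met_trp_only_returns_one_by_convention(self):
        table = comp.CodonUsageTable({"GCT": 1})
        assert comp.cai("ATGTGGATGTGG", table) == pytest.approx(1.0)

    def test_toy_gene_matches_log_domain_hand_computation(self):
        # printed toy usage: Ala GCT:3 GCC:1, Lys AAA:4 AAG:1, Phe TTT:2 TTC:2
        table = comp.CodonUsageTable({"GCT": 3, "GCC": 1, "AAA": 4, "AAG": 1,
                                      "TTT": 2, "TTC": 2})
        # gene: ATG GCT GCC AAA TTT TAA -> countable w: 1, 1/3, 1, 1
        expected = math.exp((math.log(1) + math.log(1 / 3) + math.log(1) + math.log(1)) / 4)
        assert comp.cai("ATGGCTGCCAAATTTTAA", table) == pytest.approx(expected)

    def test_empty_reference_rejected(self):
        with pytest.raises(InvalidArgumentError):
            comp.CodonUsageTable({})

    def test_zero_count_codons_get_positive_weight(self):
        table = comp.CodonUsageTable({"GCT": 10})
        assert all(w > 0 for w in table.weights.values())
        assert table.weights["GCC"] == pytest.approx(0.5 / 10)


class TestEnc:
    def test_uniform_synonymous_usage_attains_maximum(self):
        assert comp.enc("".join(SENSE_CODONS) * 50) == 61.0

    def test_one_codon_per_amino_acid_attains_minimum(self):
        seq = "".join(fam[0] for fam in SYNONYMOUS_FAMILIES.values()) * 5
        assert comp.enc(seq) == pytest.approx(20.0)

    def test_toy_gene_matches_spreadsheet_recomputation(self, rng):
        codons = rng.choice(np.array(SENSE_CODONS, dtype=object), size=60)
        seq = "".join(codons)
        assert comp.enc(seq) == pytest.approx(enc_spreadsheet(seq), abs=1e-12)

    def test_bounds_on_random_genes(self, rng):
        for _ in range(20):
            codons = rng.choice(np.array(SENSE_CODONS, dtype=object),
                                size=int(rng.integers(20, 200)))
            value = comp.enc("".join(codons))
            assert 20.0 <= value <= 61.0


def test_cai_and_enc_invariant_to_codon_reordering(rng):
    codons = list(rng.choice(np.array(SENSE_CODONS, dtype=object), size=80))
    table = comp.CodonUsageTable.from_sequences(["".join(codons)])
    shuffled = list(codons)
    rng.shuffle(shuffled)
    a, b = "".join(codons), "".join(shuffled)
    assert comp.cai(a, table) == pytest.approx(comp.cai(b, table))
    assert comp.enc(a) == pytest.approx(comp.enc(b))


class TestTetranucleotides:
    def test_single_window(self):
        vec = comp.tetranucleotide_frequencies("AAAA")
        assert vec[0] == 1.0 and vec.sum() == 1.0

    def test_two_identical_windows(self):
        vec = comp.tetranucleotide_frequencies("AAAAA")
        assert vec[0] == 1.0

    def test_exhaustive_single_4mer_inputs(self):
        for i, tetra in enumerate(TETRANUCLEOTIDES):
            vec = comp.tetranucleotide_frequencies(tetra)
            assert vec[i] == 1.0 and vec.sum() == 1.0

    @given(DNA.filter(lambda s: len(s) >= 4))
    @settings(max_examples=50, deadline=None)
    def test_normalisation_property(self, seq):
        assert comp.tetranucleotide_frequencies(seq).sum() == pytest.approx(1.0, abs=1e-9)

    def test_n_windows_dropped(self):
        vec = comp.tetranucleotide_frequencies("AAAANCCCC")
        assert vec.sum() == pytest.approx(1.0)
        assert vec[0] == pytest.approx(0.5)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            comp.tetranucleotide_frequencies("ACG")


class TestTetraSelection:
    def test_constant_4mer_always_selected_first(self, rng):
        mat = rng.uniform(0, 1, size=(20, 256))
        mat /= mat.sum(axis=1, keepdims=True)
        mat[:, 37] = 0.004  # engineered zero-variance column
        assert comp.select_low_variance_tetranucs(mat, 1) == [TETRANUCLEOTIDES[37]]

    def test_k_256_returns_everything(self, rng):
        mat = rng.uniform(0, 1, size=(5, 256))
        assert sorted(comp.select_low_variance_tetranucs(mat, 256)) == sorted(TETRANUCLEOTIDES)

    def test_matches_brute_force_variance_sort(self, rng):
        mat = rng.uniform(0, 1, size=(30, 256))
        got = comp.select_low_variance_tetranucs(mat, 10)
        order = sorted(range(256), key=lambda i: (mat[:, i].var(ddof=1), TETRANUCLEOTIDES[i]))
        assert got == [TETRANUCLEOTIDES[i] for i in order[:10]]

    def test_discriminative_identical_sets_lexicographic(self, rng):
        mat = rng.uniform(0, 1, size=(10, 256))
        got = comp.select_discriminative_tetranucs(mat, mat.copy(), 3)
        assert got == list(TETRANUCLEOTIDES[:3])

    def test_discriminative_engineered_difference_ranks_first(self, rng):
        a = rng.uniform(0, 1, size=(15, 256))
        b = a + rng.normal(0, 1e-4, size=(15, 256))
        b[:, 0] += 0.5  # sets differ essentially only in AAAA
        assert comp.select_discriminative_tetranucs(a, b, 1) == ["AAAA"]

    def test_discriminative_degenerate_error(self):
        mat = np.full((5, 256), 1 / 256)
        with pytest.raises(DegenerateInputError):
            comp.select_discriminative_tetranucs(mat, mat.copy(), 1)


class TestTailOutliers:
    def test_exact_counts_per_tail(self, rng):
        values = {f"g{i:04d}": float(v) for i, v in enumerate(rng.normal(size=1000))}
        flagged = comp.flag_tail_outliers(values, alpha=0.025)
        assert len(flagged) == 50  # floor(0.025 * 1000) per tail

    def test_constant_sample_flags_nothing(self):
        values = {f"g{i}": 1.0 for i in range(100)}
        assert comp.flag_tail_outliers(values) == []

    def test_matches_sort_and_slice_oracle(self, rng):
        values = {f"g{i:03d}": float(v) for i, v in enumerate(rng.normal(size=200))}
        flagged = set(comp.flag_tail_outliers(values, alpha=0.025))
        ranked = sorted(values, key=lambda k: values[k])
        expected = set(ranked[:5]) | set(ranked[-5:])
        assert flagged == expected

    @pytest.mark.parametrize("alpha", [0.0, 0.5, -0.1, 1.0])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(InvalidArgumentError):
            comp.flag_tail_outliers({f"g{i}": float(i) for i in range(100)}, alpha=alpha)


def test_compute_profiles_excludes_bad_genes(caplog):
    seqs = [
        comp.CodingSequence("good", "sp", "ATG" + "GCT" * 2 + "AAA" * 2 + "TTT" * 2 + "TAA"),
        comp.CodingSequence("frame", "sp", "ATGGCTAAATA"),
        comp.CodingSequence("ns", "sp", "ATGNNNNNNTAA"),
    ]
    profiles = comp.compute_profiles(seqs)
    assert [p.gene_id for p in profiles] == ["good"]


def test_profile_table_round_trip(tmp_path, two_species_profiles):
    profiles, _ = two_species_profiles
    path = tmp_path / "profiles.tsv"
    comp.write_profile_table(profiles[:10], path)
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    assert list(frame.columns[:6]) == ["gene_id", "species", "gc", "gc3", "cai", "enc"]
    assert frame.shape == (10, 6 + 256)
    assert frame["gc"].iloc[0] == pytest.approx(profiles[0].gc)
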