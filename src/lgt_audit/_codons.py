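"""Standard genetic code tables used by the composition metrics and simulators."""

from __future__ import annotations

import itertools

NUCLEOTIDES = "ACGT"

#: Standard genetic code, 64 codons -> one-letter amino acid, '*' = stop.
GENETIC_CODE: dict[str, str] = {}
_AA_BY_BLOCK = (
    # (first, second, thirds, aa)
    ("T", "T", "TC", "F"), ("T", "T", "AG", "L"),
    ("T", "C", "TCAG", "S"),
    ("T", "A", "TC", "Y"), ("T", "A", "AG", "*"),
    ("T", "G", "TC", "C"), ("T", "G", "A", "*"), ("T", "G", "G", "W"),
    ("C", "T", "TCAG", "L"),
    ("C", "C", "TCAG", "P"),
    ("C", "A", "TC", "H"), ("C", "A", "AG", "Q"),
    ("C", "G", "TCAG", "R"),
    ("A", "T", "TCA", "I"), ("A", "T", "G", "M"),
    ("A", "C", "TCAG", "T"),
    ("A", "A", "TC", "N"), ("A", "A", "AG", "K"),
    ("A", "G", "TC", "S"), ("A", "G", "AG", "R"),
    ("G", "T", "TCAG", "V"),
    ("G", "C", "TCAG", "A"),
    ("G", "A", "TC", "D"), ("G", "A", "AG", "E"),
    ("G", "G", "TCAG", "G"),
)
for _b1, _b2, _thirds, _aa in _AA_BY_BLOCK:
    for _b3 in _thirds:
        GENETIC_CODE[_b1 + _b2 + _b3] = _aa

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if GENETIC_CODE[c] != "*"
)
assert len(SENSE_CODONS) == 61

#: amino acid -> tuple of synonymous sense codons (sorted)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa = GENETIC_CODE[_codon]
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
for _aa in SYNONYMOUS_FAMILIES:
    SYNONYMOUS_FAMILIES[_aa] = tuple(
        sorted(c for c in SENSE_CODONS if GENETIC_CODE[c] == _aa)
    )

#: degeneracy class (2, 3, 4, 6) -> amino acids; single-codon families excluded
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _codons in SYNONYMOUS_FAMILIES.items():
    DEGENERACY_CLASSES.setdefault(len(_codons), ())
for _k in list(DEGENERACY_CLASSES):
    DEGENERACY_CLASSES[_k] = tuple(
        sorted(a for a, cs in SYNONYMOUS_FAMILIES.items() if len(cs) == _k)
    )

SINGLE_CODON_AMINO_ACIDS: tuple[str, ...] = DEGENERACY_CLASSES.get(1, ())  # M, W

#: all 256 tetranucleotides in lexicographic order
TETRANUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(NUCLEOTIDES, repeat=4)
)
TETRA_INDEX: dict[str, int] = {t: i for i, t in enumerate(TETRANUCLEOTIDES)}


def codons_of(seq: str) -> list[str]:
    """Split an in-frame sequence into codons (no frame validation here)."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
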