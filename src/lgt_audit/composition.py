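"""Per-gene nucleotide composition metrics and simple composition-based flags.

Implements the four classic codon-level statistics used to screen for
laterally transferred genes — GC content, GC content at third codon positions
(GC3), the Codon Adaptation Index (CAI, Sharp & Li style geometric mean of
relative adaptiveness values) and Wright's Effective Number of Codons (ENC) —
plus overlapping tetranucleotide frequency vectors, selection of
low-variance / discriminative tetranucleotides, and two-tailed outlier
flagging of a metric distribution.

All metrics operate on coding sequences (CDS) given on the coding strand.
``N`` bases are tolerated: they are excluded from GC counts, codons containing
``N`` are skipped by CAI/ENC, and 4-mer windows containing ``N`` are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._codons import (
    DEGENERACY_CLASSES,
    GENETIC_CODE,
    SENSE_CODONS,
    SINGLE_CODON_AMINO_ACIDS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    TETRA_INDEX,
    TETRANUCLEOTIDES,
    codons_of,
)
from .errors import (
    DegenerateInputError,
    FrameError,
    InvalidArgumentError,
    UndefinedMetricError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CodingSequence",
    "CodonUsageTable",
    "CompositionProfile",
    "gc_content",
    "gc3",
    "cai",
    "enc",
    "tetranucleotide_frequencies",
    "select_low_variance_tetranucs",
    "select_discriminative_tetranucs",
    "flag_tail_outliers",
    "compute_profiles",
    "profiles_to_frame",
    "read_fasta",
    "write_profile_table",
]

#: maximum tolerated fraction of N before a gene is excluded from profiling
MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class CodingSequence:
    """A single CDS: identifier, species tag, and nucleotide string over ACGTN."""

    id: str
    species: str
    seq: str

    def __post_init__(self):
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise InvalidArgumentError(
                f"{self.id}: sequence contains non-ACGTN characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


def gc_content(seq: str) -> float:
    """Fraction of G+C among unambiguous bases; N excluded from both counts."""
    seq = seq.upper()
    if not seq:
        raise InvalidArgumentError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    total = gc + seq.count("A") + seq.count("T")
    if total == 0:
        raise UndefinedMetricError("GC content undefined: no unambiguous bases")
    return gc / total


def gc3(seq: str) -> float:
    """GC fraction over third codon positions (positions 3, 6, 9, ...)."""
    seq = seq.upper()
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a positive multiple of 3")
    thirds = seq[2::3]
    return gc_content(thirds)


class CodonUsageTable:
    """Relative codon usage of a reference gene set.

    Stores counts ``n_c`` for the 61 sense codons and exposes relative
    adaptiveness ``w_c = n_c / max(n over synonyms)``. Codons never observed in
    the reference receive a pseudo-count (default 0.5) before the ratio is
    formed, so every ``w_c`` is strictly positive.
    """

    def __init__(self, counts: Mapping[str, float], pseudo_count: float = 0.5):
        if not counts or all(v == 0 for v in counts.values()):
            raise InvalidArgumentError("empty codon usage reference")
        self.pseudo_count = float(pseudo_count)
        self.counts: dict[str, float] = {c: 0.0 for c in SENSE_CODONS}
        n_zero = 0
        for codon, n in counts.items():
            codon = codon.upper()
            if codon in self.counts:
                self.counts[codon] = float(n)
        self.weights: dict[str, float] = {}
        for codons in SYNONYMOUS_FAMILIES.values():
            adj = {c: self.counts[c] if self.counts[c] > 0 else self.pseudo_count
                   for c in codons}
            n_zero += sum(1 for c in codons if self.counts[c] == 0)
            top = max(adj.values())
            for c in codons:
                self.weights[c] = adj[c] / top
        if n_zero:
            logger.debug(
                "codon usage reference: %d zero-count codons given pseudo-count %g",
                n_zero, self.pseudo_count,
            )

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[CodingSequence | str], pseudo_count: float = 0.5
    ) -> "CodonUsageTable":
        """Pool codon counts over a gene set (stop codons ignored)."""
        counts: dict[str, float] = {c: 0.0 for c in SENSE_CODONS}
        for s in seqs:
            raw = s.seq if isinstance(s, CodingSequence) else str(s)
            for codon in codons_of(raw.upper()):
                if codon in counts:
                    counts[codon] += 1.0
        return cls(counts, pseudo_count=pseudo_count)


def cai(seq: str, reference: CodonUsageTable) -> float:
    """Codon Adaptation Index: geometric mean of relative adaptiveness.

    Stop codons and the single-codon families (Met, Trp) are excluded, as are
    codons containing N. If no countable codon remains, 1.0 is returned by
    convention (the empty geometric mean).
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    log_sum = 0.0
    n = 0
    for codon in codons_of(seq):
        aa = GENETIC_CODE.get(codon)
        if aa is None or aa == "*" or aa in SINGLE_CODON_AMINO_ACIDS:
            continue
        log_sum += math.log(reference.weights[codon])
        n += 1
    if n == 0:
        return 1.0
    return math.exp(log_sum / n)


def _family_homozygosity(counts: Sequence[float]) -> float | None:
    """Wright's F-hat = (n * sum(p_i^2) - 1) / (n - 1); None if n < 2."""
    n = sum(counts)
    if n < 2:
        return None
    p = [c / n for c in counts]
    return (n * sum(x * x for x in p) - 1.0) / (n - 1.0)


def enc(seq: str) -> float:
    """Wright's Effective Number of Codons, in [20, 61].

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where Fk is the mean codon
    homozygosity of the amino-acid families with degeneracy k. Families
    observed fewer than 2 times, or with non-positive homozygosity, are
    skipped; a degeneracy class with no usable family borrows the average
    homozygosity of the observed classes. The result is clamped at 61.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    codon_counts: dict[str, int] = {}
    for codon in codons_of(seq):
        if codon in GENETIC_CODE and GENETIC_CODE[codon] != "*":
            codon_counts[codon] = codon_counts.get(codon, 0) + 1

    class_f: dict[int, list[float]] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        if k == 1:
            continue
        for aa in aas:
            fam = SYNONYMOUS_FAMILIES[aa]
            f_hat = _family_homozygosity([codon_counts.get(c, 0) for c in fam])
            if f_hat is not None and f_hat > 0:
                class_f.setdefault(k, []).append(f_hat)

    means = {k: sum(v) / len(v) for k, v in class_f.items()}
    if not means:
        raise UndefinedMetricError("ENC undefined: no amino-acid family observed twice")
    overall = sum(means.values()) / len(means)

    n_families = {2: 9, 3: 1, 4: 5, 6: 3}
    value = 2.0  # Met + Trp
    for k, n_fam in n_families.items():
        value += n_fam / means.get(k, overall)
    return min(value, 61.0)


def tetranucleotide_frequencies(seq: str) -> np.ndarray:
    """Overlapping 4-mer frequencies (256-vector, lexicographic order).

    Windows containing N are dropped; the remaining counts are normalised to
    sum to 1.
    """
    seq = seq.upper()
    if len(seq) < 4:
        raise InvalidArgumentError("sequence shorter than 4 nt")
    counts = np.zeros(256, dtype=float)
    for i in range(len(seq) - 3):
        idx = TETRA_INDEX.get(seq[i : i + 4])
        if idx is not None:
            counts[idx] += 1.0
    total = counts.sum()
    if total == 0:
        raise UndefinedMetricError("no N-free 4-mer window in sequence")
    return counts / total


@dataclass
class CompositionProfile:
    """The per-gene metric vector used throughout the composition analyses."""

    gene_id: str
    species: str
    gc: float
    gc3: float
    cai: float
    enc: float
    tetra: np.ndarray = field(repr=False)


def compute_profiles(
    seqs: Sequence[CodingSequence],
    reference: CodonUsageTable | None = None,
) -> list[CompositionProfile]:
    """Profile every gene in a set.

    The CAI reference defaults to codon usage pooled over the whole input set
    (per species this is the species' own genome-wide usage). Genes that are
    out of frame, shorter than 6 nt, or more than 10% N are excluded with a
    logged warning.
    """
    usable = []
    for s in seqs:
        if len(s.seq) < 6 or len(s.seq) % 3 != 0:
            logger.warning("excluding %s: length %d not usable for codon metrics",
                           s.id, len(s.seq))
            continue
        if s.seq.count("N") / len(s.seq) >= MAX_N_FRACTION:
            logger.warning("excluding %s: N fraction >= %.0f%%", s.id,
                           100 * MAX_N_FRACTION)
            continue
        usable.append(s)
    if not usable:
        return []
    if reference is None:
        reference = CodonUsageTable.from_sequences(usable)
    profiles = []
    for s in usable:
        try:
            profiles.append(
                CompositionProfile(
                    gene_id=s.id,
                    species=s.species,
                    gc=gc_content(s.seq),
                    gc3=gc3(s.seq),
                    cai=cai(s.seq, reference),
                    enc=enc(s.seq),
                    tetra=tetranucleotide_frequencies(s.seq),
                )
            )
        except UndefinedMetricError as exc:
            logger.warning("excluding %s: %s", s.id, exc)
    return profiles


def profiles_to_frame(profiles: Sequence[CompositionProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame: gene_id, species, gc, gc3, cai, enc, 256 tetra columns."""
    rows = {
        "gene_id": [p.gene_id for p in profiles],
        "species": [p.species for p in profiles],
        "gc": [p.gc for p in profiles],
        "gc3": [p.gc3 for p in profiles],
        "cai": [p.cai for p in profiles],
        "enc": [p.enc for p in profiles],
    }
    tetra = np.vstack([p.tetra for p in profiles]) if profiles else np.zeros((0, 256))
    return pd.concat(
        [pd.DataFrame(rows), pd.DataFrame(tetra, columns=list(TETRANUCLEOTIDES))],
        axis=1,
    )


def write_profile_table(profiles: Sequence[CompositionProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_fasta(path, species: str) -> list[CodingSequence]:
    """Read a multi-FASTA of coding sequences, tagging each with a species."""
    return [
        CodingSequence(id=rec.id, species=species, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def _tetra_matrix(profiles: Sequence[CompositionProfile] | np.ndarray) -> np.ndarray:
    if isinstance(profiles, np.ndarray):
        mat = np.asarray(profiles, dtype=float)
    else:
        mat = np.vstack([p.tetra for p in profiles])
    if mat.ndim != 2 or mat.shape[1] != 256:
        raise InvalidArgumentError("expected an (n, 256) tetranucleotide matrix")
    return mat


def select_low_variance_tetranucs(
    profiles: Sequence[CompositionProfile] | np.ndarray, k: int
) -> list[str]:
    """The k tetranucleotides with smallest across-gene frequency variance.

    Ties are broken lexicographically (the column order is lexicographic and
    the sort is stable).
    """
    mat = _tetra_matrix(profiles)
    if mat.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 profiles")
    if not 1 <= k <= 256:
        raise InvalidArgumentError(f"k={k} out of range [1, 256]")
    variances = mat.var(axis=0, ddof=1)
    order = np.argsort(variances, kind="stable")
    return [TETRANUCLEOTIDES[i] for i in order[:k]]


def select_discriminative_tetranucs(
    profiles_a: Sequence[CompositionProfile] | np.ndarray,
    profiles_b: Sequence[CompositionProfile] | np.ndarray,
    k: int,
) -> list[str]:
    """The k tetranucleotides best separating two gene sets.

    Score = |mean_a - mean_b| / pooled sd (absolute standardised mean
    difference); a 4-mer with zero pooled sd but differing means separates the
    sets perfectly and ranks first. Ties are broken lexicographically.
    """
    a = _tetra_matrix(profiles_a)
    b = _tetra_matrix(profiles_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise InvalidArgumentError("both profile sets must be non-empty")
    if not 1 <= k <= 256:
        raise InvalidArgumentError(f"k={k} out of range [1, 256]")
    na, nb = a.shape[0], b.shape[0]
    var_a = a.var(axis=0, ddof=1) if na > 1 else np.zeros(256)
    var_b = b.var(axis=0, ddof=1) if nb > 1 else np.zeros(256)
    dof = max(na + nb - 2, 1)
    pooled_sd = np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / dof)
    diff = np.abs(a.mean(axis=0) - b.mean(axis=0))
    if np.all(pooled_sd == 0) and np.all(diff == 0):
        raise DegenerateInputError("all tetranucleotides have zero pooled sd and zero difference")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(pooled_sd > 0, diff / np.where(pooled_sd > 0, pooled_sd, 1.0),
                         np.where(diff > 0, np.inf, 0.0))
    order = np.argsort(-score, kind="stable")
    return [TETRANUCLEOTIDES[i] for i in order[:k]]


def flag_tail_outliers(values: Mapping[str, float], alpha: float = 0.025) -> list[str]:
    """Flag ids whose value lies in either empirical alpha-tail.

    Per tail, floor(alpha * n) items are taken by rank (ties at a boundary are
    broken by id); an item is only flagged if its value is strictly inside the
    tail relative to the opposite tail boundary, so a constant sample flags
    nothing.
    """
    if not 0 < alpha < 0.5:
        raise InvalidArgumentError(f"alpha={alpha} outside (0, 0.5)")
    n = len(values)
    m = math.floor(alpha * n)
    if n < math.ceil(1 / alpha):
        raise InvalidArgumentError(
            f"need at least {math.ceil(1 / alpha)} values for alpha={alpha}, got {n}"
        )
    items = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
    if m == 0:
        return []
    upper_boundary = items[n - m][1]  # smallest value of the upper-tail block
    lower_boundary = items[m - 1][1]  # largest value of the lower-tail block
    low = [gid for gid, v in items[:m] if v < upper_boundary]
    high_sorted = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    high = [gid for gid, v in high_sorted[:m] if v > lower_boundary]
    return sorted(set(low) | set(high))
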