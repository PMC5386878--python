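"""Reciprocal Best Blast Hit (RBBH) orthology calling.

Consumes pairwise similarity searches in the common 12-column tab-separated
dialect (qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
sstart, send, evalue, bitscore), keeps per query the best hit at or below an
E-value ceiling (default 1e-5, inclusive), and accepts an ortholog pair only
when the two genes are each other's best hit. Reference-anchored ortholog
groups are then assembled from the per-species RBBH maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, HitTableParseError, InvalidArgumentError

__all__ = [
    "HIT_COLUMNS",
    "HitRecord",
    "OrthologGroup",
    "parse_hit_table",
    "best_hits",
    "reciprocal_best_hits",
    "build_groups",
]

HIT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit (one HSP row)."""

    query: str
    subject: str
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not self.query or not self.subject:
            raise InvalidArgumentError("hit with empty query or subject id")
        if self.evalue < 0:
            raise InvalidArgumentError(f"negative E-value {self.evalue}")


def parse_hit_table(path_or_lines) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit file into HitRecords.

    Malformed rows raise :class:`HitTableParseError` carrying the 1-based line
    number. Comment lines starting with '#' and blank lines are skipped.
    """
    if isinstance(path_or_lines, (list, tuple)):
        lines = list(path_or_lines)
    else:
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    records = []
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(HIT_COLUMNS):
            raise HitTableParseError(
                f"expected {len(HIT_COLUMNS)} tab-separated fields, got {len(parts)}", i
            )
        try:
            records.append(
                HitRecord(
                    query=parts[0],
                    subject=parts[1],
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            )
        except (ValueError, InvalidArgumentError) as exc:
            raise HitTableParseError(str(exc), i) from exc
    return records


def _as_records(hits) -> list[HitRecord]:
    if isinstance(hits, pd.DataFrame):
        missing = [c for c in ("qseqid", "sseqid", "evalue", "bitscore")
                   if c not in hits.columns]
        if missing:
            raise InvalidArgumentError(f"hit frame lacks columns {missing}")
        return [
            HitRecord(query=str(r.qseqid), subject=str(r.sseqid),
                      evalue=float(r.evalue), bitscore=float(r.bitscore))
            for r in hits.itertuples(index=False)
        ]
    return list(hits)


def best_hits(
    hits: Iterable[HitRecord] | pd.DataFrame,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> dict[str, str]:
    """Best subject per query among hits with E-value <= evalue_max (inclusive).

    Multiple HSPs for the same query-subject pair are collapsed to their best
    row first. Ranking: smallest E-value, then highest bitscore, then
    lexicographically smallest subject id. Queries with no passing hit are
    dropped.
    """
    collapsed: dict[tuple[str, str], HitRecord] = {}
    for rec in _as_records(hits):
        if rec.evalue > evalue_max:
            continue
        key = (rec.query, rec.subject)
        prev = collapsed.get(key)
        if prev is None or (rec.evalue, -rec.bitscore) < (prev.evalue, -prev.bitscore):
            collapsed[key] = rec
    best: dict[str, HitRecord] = {}
    for rec in collapsed.values():
        prev = best.get(rec.query)
        if prev is None or (rec.evalue, -rec.bitscore, rec.subject) < (
            prev.evalue, -prev.bitscore, prev.subject
        ):
            best[rec.query] = rec
    return {q: r.subject for q, r in sorted(best.items())}


def reciprocal_best_hits(
    best_a_to_b: Mapping[str, str], best_b_to_a: Mapping[str, str]
) -> list[tuple[str, str]]:
    """Pairs (g1, g2) with best_a_to_b[g1] == g2 and best_b_to_a[g2] == g1, sorted by g1."""
    pairs = [
        (g1, g2)
        for g1, g2 in best_a_to_b.items()
        if best_b_to_a.get(g2) == g1
    ]
    return sorted(pairs)


@dataclass
class OrthologGroup:
    """Orthologs of one reference gene: species -> gene id (reference included)."""

    reference_gene: str
    members: dict[str, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def too_small_for_tree(self) -> bool:
        """Groups with fewer than 4 species cannot support a topology test."""
        return self.size < 4


def build_groups(
    reference_species: str,
    pairwise_rbbh_maps: Mapping[str, Sequence[tuple[str, str]]],
) -> list[OrthologGroup]:
    """Assemble reference-anchored ortholog groups from per-species RBBH pairs.

    ``pairwise_rbbh_maps`` maps each other species to its RBBH pair list, each
    pair ordered (reference gene, other-species gene). A reference gene or
    partner gene appearing in two conflicting pairs for the same species raises
    a consistency error.
    """
    groups: dict[str, OrthologGroup] = {}
    for species, pairs in pairwise_rbbh_maps.items():
        if species == reference_species:
            raise InvalidArgumentError("comparison species equals the reference species")
        seen_partner: dict[str, str] = {}
        for ref_gene, other_gene in pairs:
            grp = groups.setdefault(
                ref_gene,
                OrthologGroup(reference_gene=ref_gene,
                              members={reference_species: ref_gene}),
            )
            if species in grp.members and grp.members[species] != other_gene:
                raise ConsistencyError(
                    f"{ref_gene}: conflicting {species} partners "
                    f"{grp.members[species]} vs {other_gene}"
                )
            if seen_partner.get(other_gene, ref_gene) != ref_gene:
                raise ConsistencyError(
                    f"{species}:{other_gene} assigned to two reference genes"
                )
            seen_partner[other_gene] = ref_gene
            grp.members[species] = other_gene
    return [groups[g] for g in sorted(groups)]
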