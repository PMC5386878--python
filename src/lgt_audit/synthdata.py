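"""Synthetic genomes, trees, and hit tables with known ground truth.

Everything the audit pipeline consumes can be generated here: a Yule species
tree; gene trees derived from it by a controllable number of random
prune-and-regraft moves (the single knob for gene-tree/species-tree
discordance); per-species coding sequences with a controllable length
distribution, GC3 target, and codon-usage bias (codon resampling from a
per-species usage table with a softmax concentration on one preferred codon
per amino-acid family); planted lateral-transfer events (sequence
replacement and/or leaf regraft, with truth records); random ORF-like
sequences that keep only the start and stop codons; site-independent
alignment evolution under the reversible nucleotide models; and noisy
reciprocal-hit tables in the 12-column tabular dialect.

All randomness flows from a single seed through named substreams, so adding
one generator never perturbs the draws of another, and a fixed configuration
reproduces byte-identical FASTA/Newick/TSV outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._codons import SENSE_CODONS, STOP_CODONS, SYNONYMOUS_FAMILIES
from ._rng import substream
from .composition import CodingSequence
from .errors import InfeasibleCompositionError, InvalidArgumentError
from .models import SubstitutionModel, jc69
from .orthology import HIT_COLUMNS
from .treeio import clone_tree, leaf_labels

__all__ = [
    "SimulationConfig",
    "LgtTruthRecord",
    "PlantedLgt",
    "simulate_species_tree",
    "simulate_gene_tree",
    "build_codon_usage",
    "simulate_coding_sequences",
    "randomize_sequence",
    "plant_lgt",
    "evolve_alignment",
    "generate_hit_table",
    "shuffle_tree_leaves",
    "write_fasta",
    "write_hit_table",
]

_AA_LIST = tuple(sorted(SYNONYMOUS_FAMILIES))  # 20 amino acids
_GC3_FLAG = {c: 1.0 if c[2] in "GC" else 0.0 for c in SENSE_CODONS}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for one synthetic dataset.

    ``length_distribution`` is the (mean, sd) of CDS length in codons
    (start and stop included; minimum 10). ``codon_bias_strength`` is the
    softmax concentration placed on one preferred codon per family (0 =
    uniform synonymous usage). ``discordance_rearrangements`` is the number of
    random prune-and-regraft moves applied to each gene tree.
    """

    n_species: int = 8
    genes_per_species: int = 200
    length_distribution: tuple[float, float] = (300.0, 80.0)
    gc3_target: float = 0.5
    codon_bias_strength: float = 1.0
    discordance_rearrangements: int = 1
    n_lgt_events: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 0 or self.genes_per_species < 0:
            raise InvalidArgumentError("counts must be >= 0")
        if not 0.0 <= self.gc3_target <= 1.0:
            raise InvalidArgumentError("gc3_target must be in [0, 1]")
        if self.codon_bias_strength < 0:
            raise InvalidArgumentError("codon_bias_strength must be >= 0")
        if self.discordance_rearrangements < 0 or self.n_lgt_events < 0:
            raise InvalidArgumentError("counts must be >= 0")


@dataclass(frozen=True)
class LgtTruthRecord:
    """Ground truth for one planted transfer event."""

    gene_id: str
    donor_species: str
    recipient_species: str
    mode: str  # sequence_swap | leaf_regraft | both
    family_id: str = ""

    def __post_init__(self):
        if self.donor_species == self.recipient_species:
            raise InvalidArgumentError("donor and recipient species must differ")
        if self.mode not in ("sequence_swap", "leaf_regraft", "both"):
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")


class PlantedLgt(NamedTuple):
    sequences: dict[str, dict[str, CodingSequence]]
    gene_trees: dict[str, dendropy.Tree]
    records: list[LgtTruthRecord]


# ---------------------------------------------------------------------------
# trees


def species_label(i: int) -> str:
    return f"sp{i + 1:02d}"


def simulate_species_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Rooted binary ultrametric tree under a pure-birth (Yule) process, rate 1.

    Leaves are labelled sp01..spNN in left-to-right order; all branch lengths
    are positive. n_species leaves, n_species - 1 internal nodes.
    """
    if n_species < 3:
        raise InvalidArgumentError("need at least 3 species")
    rng = substream(seed, "species_tree")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.birth_time = 0.0
    tips = [root.new_child(), root.new_child()]
    t = 0.0
    for tip in tips:
        tip.birth_time = None
    while len(tips) < n_species:
        t += rng.exponential(1.0 / len(tips))
        i = int(rng.integers(len(tips)))
        node = tips.pop(i)
        node.birth_time = t
        tips.extend([node.new_child(), node.new_child()])
    t_end = t + rng.exponential(1.0 / len(tips))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_t = node.parent_node.birth_time
        own_t = t_end if node.is_leaf() else node.birth_time
        node.edge.length = own_t - parent_t
    for k, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.require_taxon(label=species_label(k))
    return tree


def _random_spr(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One random prune-and-regraft move, in place.

    Prunes a random subtree whose grandparent exists (so the root never needs
    re-seeding) and regrafts it into a random remaining edge, splitting that
    edge's length at a random point.
    """
    candidates = [
        n for n in tree.preorder_node_iter()
        if n.parent_node is not None and n.parent_node.parent_node is not None
    ]
    if not candidates:
        return
    prune = candidates[int(rng.integers(len(candidates)))]
    parent = prune.parent_node
    grand = parent.parent_node
    parent.remove_child(prune)
    sib = parent.child_nodes()[0]
    parent.remove_child(sib)
    grand.remove_child(parent)
    sib.edge.length = (sib.edge.length or 0.0) + (parent.edge.length or 0.0)
    grand.add_child(sib)
    targets = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    b = targets[int(rng.integers(len(targets)))]
    bp = b.parent_node
    frac = float(rng.uniform(0.2, 0.8))
    b_len = b.edge.length or 1.0
    bp.remove_child(b)
    mid = bp.new_child(edge_length=b_len * (1.0 - frac))
    b.edge.length = b_len * frac
    mid.add_child(b)
    mid.add_child(prune)


def simulate_gene_tree(
    species_tree: dendropy.Tree,
    discordance_rearrangements: int = 0,
    seed: int = 0,
    support: float = 100.0,
    support_noise: float = 0.0,
) -> dendropy.Tree:
    """A gene tree for one single-copy gene: the species tree plus random regrafts.

    Applies exactly ``discordance_rearrangements`` random prune-and-regraft
    moves, then writes a support value (default 100, minus uniform noise up to
    ``support_noise``) on every internal edge.
    """
    if discordance_rearrangements < 0:
        raise InvalidArgumentError("rearrangement count must be >= 0")
    rng = substream(seed, "gene_tree")
    tree = clone_tree(species_tree)
    for _ in range(int(discordance_rearrangements)):
        _random_spr(tree, rng)
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        value = support - float(rng.uniform(0.0, support_noise)) if support_noise else support
        node.label = "%g" % value
    return tree


def shuffle_tree_leaves(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Permute the leaf labels uniformly at random; shape and lengths unchanged."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 4:
        raise InvalidArgumentError("need at least 4 leaves to shuffle")
    rng = substream(seed, "shuffle_leaves")
    out = clone_tree(tree)
    out_leaves = sorted(out.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    labels = [lf.taxon.label for lf in out_leaves]
    perm = rng.permutation(len(labels))
    for leaf, j in zip(out_leaves, perm):
        leaf.taxon.label = labels[int(j)]
    return out


# ---------------------------------------------------------------------------
# sequences


def uniform_usage_gc3() -> float:
    """Expected GC3 under uniform synonymous usage and uniform amino acids.

    Not 0.5: the Ile family offers only one G/C-ending codon in three, and
    Met/Trp are fixed at G. Requesting this target leaves every family's
    usage uniform (zero GC3 shaping), which is the condition under which
    pooled usage attains Wright's ENC maximum of 61.
    """
    per_aa = [
        float(np.mean([_GC3_FLAG[c] for c in fam]))
        for fam in SYNONYMOUS_FAMILIES.values()
    ]
    return float(np.mean(per_aa))


def build_codon_usage(
    gc3_target: float,
    codon_bias_strength: float,
    seed: int = 0,
    species_tag: str = "",
) -> dict[str, float]:
    """Per-codon sampling probabilities (within-family) for one species.

    Within each synonymous family, p(codon) is a softmax over
    ``bias * [codon is the species' preferred codon] + theta * [3rd base is G/C]``,
    where theta is solved by bisection so that the expected GC3 over uniformly
    drawn amino acids equals ``gc3_target``. The preferred codon of each
    family is drawn per species. Raises if the target is infeasible (the
    single-codon families Met and Trp pin part of GC3).
    """
    if not 0.0 <= gc3_target <= 1.0:
        raise InvalidArgumentError("gc3_target must be in [0, 1]")
    rng = substream(seed, f"codon_usage:{species_tag}")
    preferred = {
        aa: fam[int(rng.integers(len(fam)))]
        for aa, fam in SYNONYMOUS_FAMILIES.items()
    }

    def family_probs(theta: float) -> dict[str, float]:
        probs: dict[str, float] = {}
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            logits = np.array([
                codon_bias_strength * (c == preferred[aa]) + theta * _GC3_FLAG[c]
                for c in fam
            ])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            for c, p in zip(fam, w):
                probs[c] = float(p)
        return probs

    def expected_gc3(theta: float) -> float:
        probs = family_probs(theta)
        per_aa = [
            sum(probs[c] * _GC3_FLAG[c] for c in fam)
            for fam in SYNONYMOUS_FAMILIES.values()
        ]
        return float(np.mean(per_aa))

    lo, hi = -40.0, 40.0
    if not expected_gc3(lo) - 1e-9 <= gc3_target <= expected_gc3(hi) + 1e-9:
        raise InfeasibleCompositionError(
            f"gc3_target={gc3_target} infeasible; achievable range is "
            f"[{expected_gc3(lo):.3f}, {expected_gc3(hi):.3f}]"
        )
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if expected_gc3(mid) < gc3_target:
            lo = mid
        else:
            hi = mid
    return family_probs((lo + hi) / 2.0)


def simulate_coding_sequences(
    config: SimulationConfig,
    species_tag: str,
    seed: int = 0,
    n_genes: int | None = None,
    usage_tag: str | None = None,
) -> list[CodingSequence]:
    """ORF-like coding sequences for one species.

    Each gene starts with ATG, ends with a uniform stop codon, contains no
    internal in-frame stop (only sense codons are sampled), and has length
    (in codons, start and stop included) drawn from the configured normal
    distribution, floored at 10. Interior codons are drawn amino-acid-uniform
    and codon-conditional from the species' usage table, so the realised mean
    GC3 converges to ``gc3_target``. Preferred codons are a species-level
    trait keyed by ``usage_tag`` (default: the species tag); giving two
    species the same usage tag models close relatives with conserved codon
    preferences.
    """
    n = config.genes_per_species if n_genes is None else int(n_genes)
    usage = build_codon_usage(
        config.gc3_target, config.codon_bias_strength,
        seed=config.seed, species_tag=usage_tag or species_tag,
    )
    rng = substream(seed, f"coding_sequences:{species_tag}")
    mean, sd = config.length_distribution
    lengths = np.maximum(np.rint(rng.normal(mean, sd, size=n)).astype(int), 10)
    n_interior = lengths - 2
    total = int(n_interior.sum())

    aa_idx = rng.integers(0, len(_AA_LIST), size=total)
    codon_pool = np.empty(total, dtype=object)
    for a, aa in enumerate(_AA_LIST):
        mask = aa_idx == a
        count = int(mask.sum())
        if count == 0:
            continue
        fam = SYNONYMOUS_FAMILIES[aa]
        p = np.array([usage[c] for c in fam])
        codon_pool[mask] = rng.choice(np.array(fam, dtype=object), size=count, p=p)
    stops = rng.choice(np.array(STOP_CODONS, dtype=object), size=n)

    out: list[CodingSequence] = []
    offset = 0
    for i in range(n):
        k = int(n_interior[i])
        body = "".join(codon_pool[offset : offset + k])
        offset += k
        out.append(
            CodingSequence(
                id=f"{species_tag}_g{i + 1:04d}",
                species=species_tag,
                seq="ATG" + body + str(stops[i]),
            )
        )
    return out


def randomize_sequence(seq: CodingSequence | str, seed: int = 0):
    """Uniform-random interior with the start and stop codons retained.

    The output has the input's length, begins with ATG, ends with the input's
    stop codon, and every interior base is i.i.d. uniform over ACGT (interior
    in-frame stops may occur, as in a random open reading frame check).
    """
    raw = seq.seq if isinstance(seq, CodingSequence) else str(seq).upper()
    if len(raw) < 6 or len(raw) % 3 != 0:
        raise InvalidArgumentError("sequence must be >= 6 nt and a multiple of 3")
    if raw[-3:] not in STOP_CODONS:
        raise InvalidArgumentError(f"sequence does not end with a stop codon ({raw[-3:]})")
    rng = substream(seed, "randomize_sequence")
    interior = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=len(raw) - 6)])
    new = "ATG" + interior + raw[-3:]
    if isinstance(seq, CodingSequence):
        return CodingSequence(id=seq.id, species=seq.species, seq=new)
    return new


# ---------------------------------------------------------------------------
# planted transfers


def plant_lgt(
    sequences: Mapping[str, Mapping[str, CodingSequence]],
    gene_trees: Mapping[str, dendropy.Tree],
    donor: str,
    recipient: str,
    n_events: int,
    mode: str = "both",
    seed: int = 0,
) -> PlantedLgt:
    """Plant ``n_events`` transfer events from donor to recipient.

    ``sequences`` maps ortholog family id -> species -> CDS; ``gene_trees``
    maps family id -> gene tree with species-labelled leaves. For
    ``sequence_swap`` the recipient's CDS is replaced by the donor's ortholog
    sequence (keeping the recipient's gene id); for ``leaf_regraft`` the
    recipient leaf is pruned and regrafted as sister to the donor leaf;
    ``both`` does both. Returns modified copies plus one truth record per
    event.
    """
    if donor == recipient:
        raise InvalidArgumentError("donor and recipient must differ")
    if mode not in ("sequence_swap", "leaf_regraft", "both"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    eligible = sorted(
        fam for fam, by_sp in sequences.items()
        if donor in by_sp and recipient in by_sp
        and (mode == "sequence_swap" or
             (fam in gene_trees
              and {donor, recipient} <= leaf_labels(gene_trees[fam])))
    )
    if n_events > len(eligible):
        raise InvalidArgumentError(
            f"{n_events} events requested but only {len(eligible)} orthologous "
            f"families carry both {donor} and {recipient}"
        )
    rng = substream(seed, "plant_lgt")
    chosen = sorted(rng.choice(len(eligible), size=n_events, replace=False).tolist())
    chosen_fams = [eligible[i] for i in chosen]

    new_sequences = {fam: dict(by_sp) for fam, by_sp in sequences.items()}
    new_trees = {fam: clone_tree(t) for fam, t in gene_trees.items()}
    records: list[LgtTruthRecord] = []
    for fam in chosen_fams:
        rec_seq = new_sequences[fam][recipient]
        if mode in ("sequence_swap", "both"):
            new_sequences[fam][recipient] = CodingSequence(
                id=rec_seq.id, species=recipient,
                seq=new_sequences[fam][donor].seq,
            )
        if mode in ("leaf_regraft", "both"):
            _regraft_as_sister(new_trees[fam], recipient, donor)
        records.append(
            LgtTruthRecord(
                gene_id=rec_seq.id, donor_species=donor,
                recipient_species=recipient, mode=mode, family_id=fam,
            )
        )
    return PlantedLgt(new_sequences, new_trees, records)


def _regraft_as_sister(tree: dendropy.Tree, moving_label: str, anchor_label: str) -> None:
    """Prune leaf ``moving_label`` and reattach it as sister of ``anchor_label``."""
    moving = anchor = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == moving_label:
            moving = lf
        elif lf.taxon.label == anchor_label:
            anchor = lf
    if moving is None or anchor is None:
        raise InvalidArgumentError(
            f"leaf {moving_label!r} or {anchor_label!r} absent from gene tree"
        )
    parent = moving.parent_node
    grand = parent.parent_node
    parent.remove_child(moving)
    sib = parent.child_nodes()[0]
    parent.remove_child(sib)
    if grand is None:
        # parent was the root: the sibling becomes the new root
        sib.edge.length = None
        tree.seed_node = sib
    else:
        grand.remove_child(parent)
        sib.edge.length = (sib.edge.length or 0.0) + (parent.edge.length or 0.0)
        grand.add_child(sib)
    ap = anchor.parent_node
    a_len = anchor.edge.length or 1.0
    ap.remove_child(anchor)
    mid = ap.new_child(edge_length=a_len / 2.0)
    mid.label = "100"  # the planted cherry is certain by construction
    anchor.edge.length = a_len / 2.0
    mid.add_child(anchor)
    moving.edge.length = a_len / 2.0
    mid.add_child(moving)


# ---------------------------------------------------------------------------
# alignments


def evolve_alignment(
    tree: dendropy.Tree,
    n_sites: int,
    model: SubstitutionModel | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Simulate an ungapped alignment on a tree, site-independently.

    The root state is drawn from the model's equilibrium frequencies and
    evolved down every branch with the model's transition matrices; with a
    gamma-shaped model, each site carries an i.i.d. gamma(shape, 1/shape) rate
    multiplier. Returns leaf label -> sequence.
    """
    if n_sites < 1:
        raise InvalidArgumentError("n_sites must be >= 1")
    model = model or jc69()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise InvalidArgumentError("tree has a branch without a length")
    rng = substream(seed, "evolve_alignment")
    rates = (
        rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=n_sites)
        if model.gamma_shape is not None else None
    )
    states: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.choice(4, size=n_sites, p=model.pi)
    }
    eigval, right, left = model._decomp
    out: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            parent_states = states[id(node.parent_node)]
            t = float(node.edge.length)
            child = np.empty(n_sites, dtype=np.int64)
            u = rng.random(n_sites)
            if rates is None:
                p = model.transition_matrix(t)
                cum = p.cumsum(axis=1)
                cum[:, -1] = 1.0
                for s in range(4):
                    mask = parent_states == s
                    if mask.any():
                        child[mask] = np.searchsorted(cum[s], u[mask], side="right")
            else:
                expo = np.exp(np.outer(rates * t, eigval))  # (sites, 4)
                for s in range(4):
                    mask = parent_states == s
                    if mask.any():
                        probs = (expo[mask] * right[s][None, :]) @ left
                        probs = np.clip(probs, 0.0, None)
                        probs /= probs.sum(axis=1, keepdims=True)
                        cum = probs.cumsum(axis=1)
                        cum[:, -1] = 1.0
                        child[mask] = (u[mask][:, None] > cum).sum(axis=1)
            child = np.clip(child, 0, 3)
            states[id(node)] = child
            if node.is_leaf():
                out[node.taxon.label] = "".join(bases[child])
    return out


# ---------------------------------------------------------------------------
# hit tables


def generate_hit_table(
    ortholog_truth: Sequence[tuple[str, str]],
    evalue_range: tuple[float, float] = (1e-50, 1e-10),
    noise_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A 12-column hit table realising a planted ortholog truth set.

    Every true pair appears as mutual best hits with an E-value drawn
    log-uniformly from ``evalue_range`` (well below the 1e-5 acceptance
    ceiling). ``noise_rate`` adds ``round(noise_rate * n_pairs)`` spurious
    one-way hits with E-values above the truth range, which are therefore
    never reciprocal best hits.
    """
    if not 0.0 <= noise_rate < 1.0:
        raise InvalidArgumentError("noise_rate must be in [0, 1)")
    lo, hi = evalue_range
    if not 0 < lo <= hi:
        raise InvalidArgumentError("evalue_range must be positive and ordered")
    rng = substream(seed, "hit_table")
    rows: list[dict] = []

    def add_row(q, s, evalue):
        length = int(rng.integers(200, 2000))
        pident = float(rng.uniform(75.0, 100.0))
        rows.append({
            "qseqid": q, "sseqid": s, "pident": round(pident, 2),
            "length": length, "mismatch": int(length * (100 - pident) / 100),
            "gapopen": int(rng.integers(0, 5)), "qstart": 1, "qend": length,
            "sstart": 1, "send": length, "evalue": float(evalue),
            "bitscore": round(max(30.0, -10.0 * math.log10(max(evalue, 1e-180))
                                  + float(rng.normal(50, 5))), 1),
        })

    for a, b in ortholog_truth:
        e_ab = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))
        e_ba = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))
        add_row(a, b, e_ab)
        add_row(b, a, e_ba)

    n_noise = round(noise_rate * len(ortholog_truth))
    if n_noise and ortholog_truth:
        a_side = sorted({a for a, _ in ortholog_truth})
        b_side = sorted({b for _, b in ortholog_truth})
        partner = {a: b for a, b in ortholog_truth}
        partner.update({b: a for a, b in ortholog_truth})
        for _ in range(n_noise):
            q = a_side[int(rng.integers(len(a_side)))]
            choices = [s for s in b_side if s != partner.get(q)]
            if not choices:
                continue
            s = choices[int(rng.integers(len(choices)))]
            # worse than any true hit: spurious and one-way by construction
            lo_e = math.log10(hi) + 1.0
            add_row(q, s, 10.0 ** rng.uniform(lo_e, max(lo_e + 1.0, -5.0)))
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


# ---------------------------------------------------------------------------
# writers


def write_fasta(seqs: Sequence[CodingSequence], path, wrap: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), wrap):
                fh.write(s.seq[i : i + wrap] + "\n")


def write_hit_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
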