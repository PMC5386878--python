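"""End-to-end audit: simulate -> composition -> overlap/cluster -> RBBH ->
tree comparison -> AIC test -> DTL sweep -> truth evaluation.

A run is driven by a flat key/value config (YAML mapping); every threshold of
the audit (E-value ceiling, support cutoff, tail fraction, transfer-cost
range, dAIC) is a named key with the audit's standard default. Outputs are
plain text (FASTA, Newick, TSV, JSON); a run manifest records the config
hash, seed, stage order, and a SHA-256 digest of every output file, so two
runs with the same config and seed produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, dtl, orthology, popcompare, synthdata, toplik, treecmp
from ._rng import substream
from .errors import InvalidArgumentError
from .models import jc69
from .treeio import clone_tree, read_tree, tree_from_newick, tree_to_newick, write_tree

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "RunManifest", "load_config", "run_audit",
           "evaluate_against_truth"]

TOOL_VERSION = "lgt-audit 0.1.0"

#: every audit threshold is a config key; defaults are the audit's standard values
DEFAULT_CONFIG: dict = {
    "n_species": 8,
    "genes_per_species": 200,
    "length_mean": 300.0,
    "length_sd": 80.0,
    "base_gc3": 0.50,
    "gc3_spread": 0.06,          # per-species GC3 targets span base +/- spread/2
    "codon_bias_strength": 1.0,
    "discordance_rearrangements": 1,
    "n_lgt_events": 10,
    "lgt_mode": "both",
    "seed": 0,
    "evalue_max": 1e-5,          # RBBH acceptance ceiling (inclusive)
    "hit_noise_rate": 0.1,
    "support_min": 75.0,         # bootstrap filter for tree distances
    "tail_alpha": 0.025,         # two-sided composition outlier tails
    "transfer_cost_min": 3,
    "transfer_cost_max": 30,
    "transfer_cost_step": 3,
    "delta_aic": 10.0,
    "n_aic_controls": 10,        # congruent families tested alongside planted ones
    "n_sites": 500,
    "branch_scale": 0.1,
    "null_shuffles": 1,
    "dbscan_eps": None,          # None = k-distance heuristic
    "dbscan_min_samples": 5,
}


@dataclass
class RunManifest:
    """Reproducibility record of one audit run."""

    config_hash: str
    seed: int
    tool_version: str
    stages: list[str] = field(default_factory=list)
    digests: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def load_config(source) -> dict:
    """Merge a YAML mapping (path or dict) over the defaults; reject unknown keys."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = dict(source)
    else:
        import yaml

        user = yaml.safe_load(Path(source).read_text()) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_config(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=float).encode()
    ).hexdigest()


def _species_gc3(cfg: dict, i: int) -> float:
    n = cfg["n_species"]
    frac = i / (n - 1) if n > 1 else 0.5
    return cfg["base_gc3"] + cfg["gc3_spread"] * (frac - 0.5)


def _family_id(i: int) -> str:
    return f"fam{i + 1:04d}"


def run_audit(config=None, out_dir="audit_out", resume: bool = False) -> RunManifest:
    """Run every audit stage in dependency order; returns the run manifest.

    With ``resume=True``, a stage whose output files already exist is loaded
    from disk instead of recomputed, so deleting one intermediate regenerates
    only that stage and the ones downstream of it.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config_hash=_digest_config(cfg), seed=seed,
                           tool_version=TOOL_VERSION)
    summary: dict = {}
    species_names = [synthdata.species_label(i) for i in range(cfg["n_species"])]
    reference = species_names[0]
    donor = species_names[-1]
    n_genes = int(cfg["genes_per_species"])
    families = [_family_id(i) for i in range(n_genes)]

    def record(stage: str, *paths: Path):
        manifest.stages.append(stage)
        for p in paths:
            manifest.digests[str(p.relative_to(out))] = _sha256(p)

    # ---------------------------------------------------------------- simulate
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    sp_path = sim_dir / "species_tree.nwk"
    gt_path = sim_dir / "gene_trees.tsv"
    truth_path = sim_dir / "lgt_truth.tsv"
    fasta_paths = {sp: sim_dir / f"{sp}.fasta" for sp in species_names}
    hits_dir = sim_dir / "hits"
    hits_dir.mkdir(exist_ok=True)
    sim_outputs = [sp_path, gt_path, truth_path, *fasta_paths.values()]

    base_cfg = synthdata.SimulationConfig(
        n_species=int(cfg["n_species"]),
        genes_per_species=n_genes,
        length_distribution=(float(cfg["length_mean"]), float(cfg["length_sd"])),
        gc3_target=float(cfg["base_gc3"]),
        codon_bias_strength=float(cfg["codon_bias_strength"]),
        discordance_rearrangements=int(cfg["discordance_rearrangements"]),
        n_lgt_events=int(cfg["n_lgt_events"]),
        seed=seed,
    )

    if resume and all(p.exists() for p in sim_outputs):
        species_tree = read_tree(sp_path)
        gt_frame = pd.read_csv(gt_path, sep="\t")
        gene_trees = {
            r.family: tree_from_newick(r.newick)
            for r in gt_frame.itertuples(index=False)
        }
        seqs_by_species = {
            sp: composition.read_fasta(fasta_paths[sp], sp) for sp in species_names
        }
        sequences = {
            fam: {sp: seqs_by_species[sp][i] for sp in species_names}
            for i, fam in enumerate(families)
        }
        truth_frame = pd.read_csv(truth_path, sep="\t")
        truth = [
            synthdata.LgtTruthRecord(
                gene_id=r.gene_id, donor_species=r.donor_species,
                recipient_species=r.recipient_species, mode=r.mode,
                family_id=r.family_id,
            )
            for r in truth_frame.itertuples(index=False)
        ]
        logger.info("simulate: reused existing outputs")
    else:
        species_tree = synthdata.simulate_species_tree(cfg["n_species"], seed=seed)
        write_tree(species_tree, sp_path)
        gene_trees = {}
        tree_rng = substream(seed, "pipeline:gene_trees")
        for fam in families:
            gene_trees[fam] = synthdata.simulate_gene_tree(
                species_tree, cfg["discordance_rearrangements"],
                seed=int(tree_rng.integers(0, 2**31 - 1)),
            )
        seqs_by_species = {}
        for i, sp in enumerate(species_names):
            sp_cfg = dataclasses.replace(base_cfg, gc3_target=_species_gc3(cfg, i))
            seqs_by_species[sp] = synthdata.simulate_coding_sequences(
                sp_cfg, sp, seed=seed
            )
        sequences = {
            fam: {sp: seqs_by_species[sp][i] for sp in species_names}
            for i, fam in enumerate(families)
        }
        planted = synthdata.plant_lgt(
            sequences, gene_trees, donor=donor, recipient=reference,
            n_events=int(cfg["n_lgt_events"]), mode=cfg["lgt_mode"], seed=seed,
        )
        sequences, gene_trees, truth = planted
        seqs_by_species = {
            sp: [sequences[fam][sp] for fam in families] for sp in species_names
        }
        for sp in species_names:
            synthdata.write_fasta(seqs_by_species[sp], fasta_paths[sp])
        pd.DataFrame(
            [{"family": fam, "newick": tree_to_newick(t)}
             for fam, t in gene_trees.items()]
        ).to_csv(gt_path, sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(r) for r in truth]).to_csv(
            truth_path, sep="\t", index=False
        )
    # hit tables (cheap; always regenerated deterministically)
    hit_paths = []
    hit_rng = substream(seed, "pipeline:hits")
    hit_tables = {}
    for sp in species_names[1:]:
        pairs = [
            (sequences[fam][reference].id, sequences[fam][sp].id) for fam in families
        ]
        table = synthdata.generate_hit_table(
            pairs, noise_rate=float(cfg["hit_noise_rate"]),
            seed=int(hit_rng.integers(0, 2**31 - 1)),
        )
        p = hits_dir / f"{reference}_{sp}.tsv"
        synthdata.write_hit_table(table, p)
        hit_tables[sp] = table
        hit_paths.append(p)
    record("simulate", *sim_outputs, *hit_paths)

    # ------------------------------------------------------------- composition
    comp_dir = out / "composition"
    comp_dir.mkdir(exist_ok=True)
    profiles_by_species = {}
    comp_paths = []
    for sp in species_names:
        profs = composition.compute_profiles(seqs_by_species[sp])
        profiles_by_species[sp] = profs
        p = comp_dir / f"{sp}.tsv"
        composition.write_profile_table(profs, p)
        comp_paths.append(p)
    ref_profiles = profiles_by_species[reference]
    flagged: set[str] = set()
    alpha = float(cfg["tail_alpha"])
    if len(ref_profiles) * alpha >= 1:
        for metric in ("gc", "gc3", "cai", "enc"):
            values = {p.gene_id: getattr(p, metric) for p in ref_profiles}
            flagged |= set(composition.flag_tail_outliers(values, alpha))
    else:
        logger.warning("too few genes for %.1f%% tail flagging; skipping", 100 * alpha)
    outlier_path = comp_dir / "tail_outliers.tsv"
    pd.DataFrame({"gene_id": sorted(flagged)}).to_csv(outlier_path, sep="\t", index=False)
    comp_paths.append(outlier_path)
    record("composition", *comp_paths)
    summary["n_tail_outliers"] = len(flagged)

    # ------------------------------------------------------- overlap / cluster
    pop_dir = out / "popcompare"
    pop_dir.mkdir(exist_ok=True)
    ref_usage = composition.CodonUsageTable.from_sequences(seqs_by_species[reference])
    rand_rng = substream(seed, "pipeline:random_seqs")
    random_seqs = [
        synthdata.randomize_sequence(s, seed=int(rand_rng.integers(0, 2**31 - 1)))
        for s in seqs_by_species[reference]
    ]
    random_profiles = composition.compute_profiles(random_seqs, reference=ref_usage)
    others = {sp: profiles_by_species[sp] for sp in species_names[1:]}
    others["Random"] = random_profiles
    overlap = popcompare.overlap_table(
        ref_profiles, others, exclude_from_median=("Random",)
    )
    overlap_path = pop_dir / "overlap.tsv"
    overlap.to_csv(overlap_path, sep="\t", float_format="%.6g")
    features = popcompare.feature_matrix(ref_profiles)
    ms = popcompare.cluster_mode_seeking(features)
    db = popcompare.cluster_density(
        features,
        eps=None if cfg["dbscan_eps"] is None else float(cfg["dbscan_eps"]),
        min_samples=int(cfg["dbscan_min_samples"]),
    )
    cluster_path = pop_dir / "clusters.tsv"
    pd.DataFrame({
        "gene_id": [p.gene_id for p in ref_profiles],
        "modeseek_label": ms.labels,
        "density_label": db.labels,
    }).to_csv(cluster_path, sep="\t", index=False)
    record("popcompare", overlap_path, cluster_path)
    summary["overlap_median"] = {
        m: float(overlap.loc["Median", m]) for m in overlap.columns
    }
    summary["n_clusters_modeseek"] = ms.n_clusters
    summary["n_clusters_density"] = db.n_clusters
    # clustering-based flags: genes outside the dominant cluster (or noise)
    cluster_flagged: set[str] = set()
    for labels in (ms.labels, db.labels):
        values, counts = np.unique(labels[labels >= 0], return_counts=True)
        majority = int(values[counts.argmax()]) if values.size else 0
        for p, lab in zip(ref_profiles, labels):
            if lab != majority:
                cluster_flagged.add(p.gene_id)

    # ---------------------------------------------------------------- orthology
    orth_dir = out / "orthology"
    orth_dir.mkdir(exist_ok=True)
    rbbh_by_species = {}
    for sp in species_names[1:]:
        table = hit_tables[sp]
        ab = table[table.qseqid.str.startswith(reference + "_")]
        ba = table[table.qseqid.str.startswith(sp + "_")]
        best_ab = orthology.best_hits(ab, evalue_max=float(cfg["evalue_max"]))
        best_ba = orthology.best_hits(ba, evalue_max=float(cfg["evalue_max"]))
        rbbh_by_species[sp] = orthology.reciprocal_best_hits(best_ab, best_ba)
    groups = orthology.build_groups(reference, rbbh_by_species)
    groups_path = orth_dir / "groups.tsv"
    pd.DataFrame([
        {"reference_gene": g.reference_gene, "size": g.size,
         "members": ";".join(f"{sp}:{gid}" for sp, gid in sorted(g.members.items()))}
        for g in groups
    ]).to_csv(groups_path, sep="\t", index=False)
    record("orthology", groups_path)
    truth_pairs = {
        (sequences[fam][reference].id, sequences[fam][sp].id)
        for fam in families for sp in species_names[1:]
    }
    found_pairs = {
        (a, b) for sp, pairs in rbbh_by_species.items() for a, b in pairs
    }
    summary["rbbh_recall"] = len(found_pairs & truth_pairs) / len(truth_pairs)
    summary["rbbh_false_pairs"] = len(found_pairs - truth_pairs)

    # ----------------------------------------------------------------- treecmp
    tree_dir = out / "treecmp"
    tree_dir.mkdir(exist_ok=True)
    filtered = {}
    for fam, gt in gene_trees.items():
        collapsed = treecmp.collapse_low_support(gt, float(cfg["support_min"]))
        filtered[fam] = treecmp.resolve_polytomies(collapsed)
    rfn = {
        fam: treecmp.normalized_rf(t, species_tree) for fam, t in filtered.items()
    }
    manifest_path = tree_dir / "trees_manifest.tsv"
    pd.DataFrame([
        {"tree_id": fam, "n_leaves": len(species_names), "rfn": rfn[fam]}
        for fam in families
    ]).to_csv(manifest_path, sep="\t", index=False, float_format="%.6g")
    null_sample = treecmp.rf_null_distribution(
        list(filtered.values()), species_tree,
        n_shuffles=int(cfg["null_shuffles"]), seed=seed,
    )
    null_path = tree_dir / "null_rfn.tsv"
    pd.DataFrame({"rfn": null_sample}).to_csv(
        null_path, sep="\t", index=False, float_format="%.6g"
    )
    record("treecmp", manifest_path, null_path)
    summary["mean_rfn"] = float(np.mean(list(rfn.values())))
    summary["null_mean_rfn"] = float(null_sample.mean())
    summary["exact_match_fraction"] = treecmp.exact_match_fraction(
        list(filtered.values()), species_tree
    )

    # ---------------------------------------------------------------- AIC test
    aic_dir = out / "toplik"
    aic_dir.mkdir(exist_ok=True)
    planted_fams = sorted({r.family_id for r in truth})
    control_fams = [f for f in families if f not in planted_fams]
    control_fams = control_fams[: int(cfg["n_aic_controls"])]
    aic_fams = planted_fams + control_fams
    aln_rng = substream(seed, "pipeline:alignments")
    aic_rows = []
    aic_flagged: set[str] = set()
    for fam in aic_fams:
        topo = clone_tree(gene_trees[fam])
        for node in topo.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = (node.edge.length or 1.0) * float(cfg["branch_scale"])
        aln = synthdata.evolve_alignment(
            topo, int(cfg["n_sites"]), model=jc69(),
            seed=int(aln_rng.integers(0, 2**31 - 1)),
        )
        unconstrained = toplik.estimate_topology_nj(aln)
        cmp = toplik.constrained_test(
            aln, unconstrained, species_tree, model=jc69(),
            delta_threshold=float(cfg["delta_aic"]), tol=1e-4,
        )
        aic_rows.append({
            "family": fam,
            "planted": fam in planted_fams,
            "lnl_unconstrained": cmp.lnl_unconstrained,
            "lnl_constrained": cmp.lnl_constrained,
            "delta_aic": cmp.delta_aic,
            "internal_branches": cmp.internal_branch_count,
            "verdict": cmp.verdict,
        })
        if cmp.verdict == "candidate_lgt":
            aic_flagged.add(fam)
    aic_path = aic_dir / "aic_comparisons.tsv"
    pd.DataFrame(aic_rows).to_csv(aic_path, sep="\t", index=False,
                                  float_format="%.6g")
    record("toplik", aic_path)
    summary["aic_candidates"] = len(aic_flagged)
    summary["aic_tested"] = len(aic_fams)

    # --------------------------------------------------------------------- DTL
    dtl_dir = out / "dtl"
    dtl_dir.mkdir(exist_ok=True)
    costs = list(range(int(cfg["transfer_cost_min"]), int(cfg["transfer_cost_max"]) + 1,
                       int(cfg["transfer_cost_step"])))
    sweep = dtl.cost_sweep(list(filtered.values()), species_tree, transfer_costs=costs)
    sweep_path = dtl_dir / "transfer_cost_sweep.tsv"
    sweep.to_csv(sweep_path, sep="\t", index=False, float_format="%.6g")
    dtl_flagged = {
        fam for fam in families
        if dtl.has_transfer(dtl.reconcile(filtered[fam], species_tree))
    }
    per_tree_path = dtl_dir / "per_tree.tsv"
    pd.DataFrame({
        "family": families,
        "has_transfer": [fam in dtl_flagged for fam in families],
    }).to_csv(per_tree_path, sep="\t", index=False)
    record("dtl", sweep_path, per_tree_path)
    summary["dtl_fraction_at_min_cost"] = float(
        sweep.fraction_with_transfer.iloc[0]
    )
    summary["dtl_fraction_at_max_cost"] = float(
        sweep.fraction_with_transfer.iloc[-1]
    )

    # ------------------------------------------------------------- evaluation
    truth_gene_ids = {r.gene_id for r in truth}
    fam_of_gene = {
        sequences[fam][reference].id: fam for fam in families
    }
    detections = {
        "composition_tail": flagged,
        "clustering": cluster_flagged,
        "aic_test": {sequences[f][reference].id for f in aic_flagged},
        "dtl": {sequences[f][reference].id for f in dtl_flagged},
    }
    considered = {
        "composition_tail": set(fam_of_gene),
        "clustering": set(fam_of_gene),
        "aic_test": {sequences[f][reference].id for f in aic_fams},
        "dtl": set(fam_of_gene),
    }
    detection = evaluate_against_truth(detections, truth_gene_ids, considered)
    detect_path = out / "detection.tsv"
    detection.to_csv(detect_path, sep="\t", index=False, float_format="%.6g")
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    record("evaluate", detect_path, summary_path)

    manifest_file = out / "manifest.json"
    manifest_file.write_text(manifest.to_json() + "\n")
    return manifest


def evaluate_against_truth(
    detections: dict[str, set[str]],
    truth_gene_ids: set[str],
    considered: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-method detection bookkeeping against the planted truth.

    ``detections`` maps method name -> set of flagged gene ids; ``considered``
    optionally restricts, per method, the universe of genes the method
    actually examined (truth outside it is not counted against the method).
    Returns tp/fp/fn with precision and recall per method.
    """
    rows = []
    for method, flags in detections.items():
        universe = considered.get(method) if considered else None
        truth_here = truth_gene_ids & universe if universe is not None else truth_gene_ids
        tp = len(flags & truth_here)
        fp = len(flags - truth_here)
        fn = len(truth_here - flags)
        rows.append({
            "method": method,
            "n_flagged": len(flags),
            "tp": tp, "fp": fp, "fn": fn,
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
        })
    return pd.DataFrame(rows)
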