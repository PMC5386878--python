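"""Gene-tree / species-tree topology statistics.

Covers the tree-hygiene and distance steps of a phylogenetic LGT audit:
contracting poorly supported edges (default: keep bootstrap >= 75%),
resolving the resulting polytomies, the normalised Robinson–Foulds distance
(RFn in [0, 1]; 0 = identical topologies), per-node bipartition frequencies
of a species tree across a gene-tree set, the exact-topology-match fraction,
a bootstrap-resampled consensus supertree, and the leaf-shuffle RFn null.

All distances are computed on unrooted, non-trivial bipartitions after
restricting both trees to their shared leaf set; this equals pruning both
trees to the shared leaves first and is independent of the order of pruning.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from ._rng import substream
from .errors import InvalidArgumentError
from .treeio import clone_tree, get_support, leaf_labels, tree_from_newick

__all__ = [
    "nontrivial_splits",
    "collapse_low_support",
    "resolve_polytomies",
    "normalized_rf",
    "robinson_foulds",
    "bipartition_frequencies",
    "exact_match_fraction",
    "supertree_bootstrap",
    "majority_rule_consensus",
    "rf_null_distribution",
]

SUPPORT_THRESHOLD_DEFAULT = 75.0


def _canonical(side: set[str], full: frozenset[str]) -> frozenset[str]:
    """Canonical representation of a split: the side lacking the reference leaf."""
    ref = min(full)
    return frozenset(side) if ref not in side else full - frozenset(side)


def nontrivial_splits(
    tree: dendropy.Tree, restrict: set[str] | None = None
) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions of a tree, optionally leaf-restricted.

    Each internal edge induces a split; after restriction to ``restrict`` a
    split is kept only if both sides retain >= 2 leaves. Splits are returned
    as the canonical side (the one lacking the lexicographically smallest
    leaf), so set operations compare topologies directly.
    """
    all_leaves = leaf_labels(tree)
    full = frozenset(all_leaves if restrict is None else (all_leaves & restrict))
    if len(full) < 4:
        return set()
    splits: set[frozenset[str]] = set()
    below: dict[int, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            below[id(node)] = {lab} if lab in full else set()
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= below[id(ch)]
            below[id(node)] = acc
            if node.parent_node is not None:  # internal edge above this node
                side = acc
                if 2 <= len(side) <= len(full) - 2:
                    splits.add(_canonical(side, full))
    return splits


def collapse_low_support(
    tree: dendropy.Tree, threshold: float = SUPPORT_THRESHOLD_DEFAULT
) -> dendropy.Tree:
    """Contract every internal edge whose support is below ``threshold``.

    Supports are read from internal-node labels; the comparison is inclusive
    (support exactly at the threshold is retained). An internal edge without a
    support raises: silent pass-through would disguise unsupported topology as
    supported.
    """
    out = clone_tree(tree)
    to_collapse = []
    for node in out.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        support = get_support(node)
        if support is None:
            raise InvalidArgumentError(
                "internal edge without a support value; cannot apply support filter"
            )
        if support < threshold:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.collapse()
    return out


def _min_leaf(node: dendropy.Node) -> str:
    return min(leaf.taxon.label for leaf in node.leaf_iter())


def resolve_polytomies(
    tree: dendropy.Tree, seed: int = 0, random_order: bool = False
) -> dendropy.Tree:
    """Resolve every polytomy into zero-length cherries.

    Default resolution is deterministic: at each polytomy the children are
    ordered by their smallest descendant leaf label and combined pairwise.
    ``random_order=True`` shuffles the child order with the given seed instead
    (for sensitivity checks on the arbitrary resolution).
    """
    out = clone_tree(tree)
    rng = substream(seed, "resolve_polytomies") if random_order else None
    for node in list(out.postorder_internal_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            children = sorted(children, key=_min_leaf)
            if rng is not None:
                order = rng.permutation(len(children))
                children = [children[i] for i in order]
            a, b = children[0], children[1]
            node.remove_child(a)
            node.remove_child(b)
            joint = node.new_child(edge_length=0.0)
            joint.add_child(a)
            joint.add_child(b)
            children = node.child_nodes()
    return out


def _shared_leaves(tree_a, tree_b, minimum: int = 4) -> frozenset[str]:
    shared = leaf_labels(tree_a) & leaf_labels(tree_b)
    if len(shared) < minimum:
        raise InvalidArgumentError(
            f"trees share only {len(shared)} leaves; need >= {minimum}"
        )
    return frozenset(shared)


def robinson_foulds(
    tree_a: dendropy.Tree, tree_b: dendropy.Tree
) -> tuple[int, int]:
    """(RF, max_RF) on the shared leaf set.

    RF is the size of the symmetric difference of the non-trivial split sets;
    max_RF is the total number of non-trivial splits in the two restricted
    trees, so RF / max_RF is in [0, 1].
    """
    shared = _shared_leaves(tree_a, tree_b)
    sa = nontrivial_splits(tree_a, set(shared))
    sb = nontrivial_splits(tree_b, set(shared))
    return len(sa ^ sb), len(sa) + len(sb)


def normalized_rf(
    tree_a: dendropy.Tree, tree_b: dendropy.Tree, outgroup: str | None = None
) -> float:
    """Normalised Robinson–Foulds distance in [0, 1]; 0 iff identical topologies.

    The distance is computed on unrooted bipartitions, which rooting both
    trees on a shared outgroup (the convention for rooted comparisons) leaves
    unchanged; ``outgroup``, when given, is only validated to be present in
    both trees.
    """
    if outgroup is not None:
        for t, name in ((tree_a, "first"), (tree_b, "second")):
            if outgroup not in leaf_labels(t):
                raise InvalidArgumentError(f"outgroup {outgroup!r} absent from {name} tree")
    rf, max_rf = robinson_foulds(tree_a, tree_b)
    return rf / max_rf if max_rf else 0.0


def bipartition_frequencies(
    species_tree: dendropy.Tree, gene_trees: Sequence[dendropy.Tree]
) -> dict[frozenset[str], float]:
    """Percent of gene trees containing each species-tree bipartition.

    For each internal species-tree edge, a gene tree is *applicable* if, after
    restriction to the shared leaves, both sides of the bipartition retain at
    least one leaf; the bipartition is *present* if its restriction appears in
    the gene tree (a restriction trivial on one side is present by
    definition). Keys are the canonical split sides on the full species leaf
    set.
    """
    if not gene_trees:
        raise InvalidArgumentError("empty gene-tree list")
    sp_leaves = frozenset(leaf_labels(species_tree))
    sp_splits = nontrivial_splits(species_tree)
    gene_info = []
    for gt in gene_trees:
        gl = leaf_labels(gt) & sp_leaves
        gene_info.append((gl, nontrivial_splits(gt, set(gl))))
    result: dict[frozenset[str], float] = {}
    for split in sp_splits:
        other = sp_leaves - split
        applicable = present = 0
        for gl, gsplits in gene_info:
            s_in = split & gl
            o_in = other & gl
            if not s_in or not o_in:
                continue
            applicable += 1
            if min(len(s_in), len(o_in)) < 2:
                present += 1  # trivial after restriction: in every tree
            else:
                canon = _canonical(set(s_in), frozenset(gl))
                if canon in gsplits:
                    present += 1
        result[split] = 100.0 * present / applicable if applicable else float("nan")
    return result


def exact_match_fraction(
    gene_trees: Sequence[dendropy.Tree], species_tree: dendropy.Tree
) -> float:
    """Fraction of gene trees with RFn = 0 against the species tree."""
    if not gene_trees:
        raise InvalidArgumentError("empty gene-tree list")
    matches = sum(1 for gt in gene_trees if normalized_rf(gt, species_tree) == 0.0)
    return matches / len(gene_trees)


def _tree_from_splits(
    leaves: frozenset[str], splits: Iterable[frozenset[str]]
) -> dendropy.Tree:
    """Build the (unique) tree displaying a compatible, laminar split family."""
    splits = sorted(set(splits), key=lambda s: (-len(s), sorted(s)))
    # parent of each split = smallest strictly containing split (or the root)
    children: dict[frozenset[str] | None, list[frozenset[str]]] = {None: []}
    parent_of: dict[frozenset[str], frozenset[str] | None] = {}
    for i, s in enumerate(splits):
        parent = None
        for t in splits[:i]:
            if s < t and (parent is None or len(t) < len(parent)):
                parent = t
        parent_of[s] = parent
        children.setdefault(s, [])
        children[parent].append(s)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def grow(node: dendropy.Node, group: frozenset[str] | None, members: frozenset[str]):
        covered: set[str] = set()
        for sub in children.get(group, []):
            child = node.new_child(edge_length=1.0)
            grow(child, sub, sub)
            covered |= set(sub)
        for leaf_name in sorted(members - covered):
            leaf = node.new_child(edge_length=1.0)
            leaf.taxon = taxa.require_taxon(label=leaf_name)

    grow(tree.seed_node, None, leaves)
    return tree


def majority_rule_consensus(gene_trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Majority-rule consensus over the common leaf set (splits in > 50% of trees)."""
    if not gene_trees:
        raise InvalidArgumentError("empty gene-tree list")
    common = frozenset.intersection(*(frozenset(leaf_labels(t)) for t in gene_trees))
    if len(common) < 4:
        raise InvalidArgumentError("fewer than 4 leaves common to all gene trees")
    counts: dict[frozenset[str], int] = {}
    for t in gene_trees:
        for s in nontrivial_splits(t, set(common)):
            counts[s] = counts.get(s, 0) + 1
    majority = [s for s, c in counts.items() if c > len(gene_trees) / 2]
    return _tree_from_splits(common, majority)


def supertree_bootstrap(
    gene_trees: Sequence[dendropy.Tree],
    n_replicates: int = 500,
    seed: int = 0,
) -> dendropy.Tree:
    """Consensus supertree with bootstrap supports from gene-tree resampling.

    The supertree stand-in is the majority-rule consensus of all gene trees.
    For each replicate the gene trees are resampled with replacement and the
    replicate's consensus recomputed; each branch's support is the percentage
    of replicate supertrees containing that branch, written into the internal
    node labels.
    """
    if len(gene_trees) < 10:
        raise InvalidArgumentError("need at least 10 gene trees")
    if n_replicates < 1:
        raise InvalidArgumentError("need at least 1 replicate")
    rng = substream(seed, "supertree_bootstrap")
    main = majority_rule_consensus(gene_trees)
    main_splits = nontrivial_splits(main)
    hits = {s: 0 for s in main_splits}
    n = len(gene_trees)
    common = frozenset(leaf_labels(main))
    # precompute per-tree split sets on the common leaf set
    per_tree = [nontrivial_splits(t, set(common)) for t in gene_trees]
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        counts: dict[frozenset[str], int] = {}
        for i in idx:
            for s in per_tree[i]:
                counts[s] = counts.get(s, 0) + 1
        for s in main_splits:
            if counts.get(s, 0) > n / 2:
                hits[s] += 1
    full = frozenset(leaf_labels(main))
    below: dict[int, set[str]] = {}
    for node in main.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = {node.taxon.label}
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= below[id(ch)]
            below[id(node)] = acc
            if node.parent_node is not None and 2 <= len(acc) <= len(full) - 2:
                canon = _canonical(acc, full)
                node.label = "%g" % (100.0 * hits[canon] / n_replicates)
    return main


def rf_null_distribution(
    gene_trees: Sequence[dendropy.Tree],
    species_tree: dendropy.Tree,
    n_shuffles: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Leaf-shuffle null of RFn: shuffle each gene tree's leaves, record RFn.

    Returns the pooled null sample (length = n_shuffles * n_trees), matching
    the observed gene-tree size distribution by construction.
    """
    from .synthdata import shuffle_tree_leaves  # local import: avoids a cycle

    rng = substream(seed, "rf_null")
    out = []
    for _ in range(int(n_shuffles)):
        for gt in gene_trees:
            shuffled = shuffle_tree_leaves(gt, seed=int(rng.integers(0, 2**31 - 1)))
            out.append(normalized_rf(shuffled, species_tree))
    return np.asarray(out)
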