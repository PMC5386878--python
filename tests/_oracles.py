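"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the library:
- Robinson–Foulds splits via graph edge removal (networkx connected components)
- DTL minimum cost via direct recursion over the event definitions
- tree likelihood via exhaustive summation over internal-state assignments
- ENC via a spreadsheet-style per-family recomputation
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import networkx as nx
import numpy as np


# ---------------------------------------------------------------- RF splits


def rf_splits_graph(tree, restrict=None):
    """Non-trivial splits of a dendropy tree by deleting each internal edge
    of the tree graph and reading off the connected components."""
    graph = nx.Graph()
    leaves = set()
    internal_edges = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            graph.add_edge(id(node), id(child))
            if not child.is_leaf():
                internal_edges.append((id(node), id(child)))
        if node.is_leaf():
            leaves.add(node.taxon.label)
            graph.add_edge(id(node), node.taxon.label)
    full = frozenset(leaves if restrict is None else leaves & restrict)
    if len(full) < 4:
        return set(), full
    ref = min(full)
    splits = set()
    for u, v in internal_edges:
        graph.remove_edge(u, v)
        comp = nx.node_connected_component(graph, v)
        graph.add_edge(u, v)
        side = frozenset(x for x in comp if isinstance(x, str)) & full
        if 2 <= len(side) <= len(full) - 2:
            splits.add(side if ref not in side else full - side)
    return splits, full


def rf_graph(tree_a, tree_b):
    """(RF, max_RF) on the shared leaf set via the graph-component oracle."""
    la = {lf.taxon.label for lf in tree_a.leaf_node_iter()}
    lb = {lf.taxon.label for lf in tree_b.leaf_node_iter()}
    shared = la & lb
    sa, _ = rf_splits_graph(tree_a, shared)
    sb, _ = rf_splits_graph(tree_b, shared)
    return len(sa ^ sb), len(sa) + len(sb)


# -------------------------------------------------------------- DTL oracle


def dtl_min_cost(gene_tree, species_tree, leaf_map, dup, transfer, loss,
                 allow_transfer=True):
    """Minimum DTL cost by direct recursion over the event definitions.

    Speciation sends the two gene children into the two species child
    subtrees (losses per skipped edge); duplication keeps both in the current
    subtree; transfer moves one child to any incomparable species node.
    ``allow_transfer=False`` gives the duplication-loss-only optimum.
    """
    s_nodes = list(species_tree.postorder_node_iter())
    s_idx = {id(n): i for i, n in enumerate(s_nodes)}
    n_s = len(s_nodes)
    desc = [[False] * n_s for _ in range(n_s)]
    dist = [[0] * n_s for _ in range(n_s)]
    for i, n in enumerate(s_nodes):
        desc[i][i] = True
        for ch in n.child_nodes():
            ci = s_idx[id(ch)]
            for j in range(n_s):
                if desc[ci][j]:
                    desc[i][j] = True
                    dist[i][j] = dist[ci][j] + 1
    s_children = [[s_idx[id(c)] for c in n.child_nodes()] for n in s_nodes]
    comparable = [[desc[i][j] or desc[j][i] for j in range(n_s)] for i in range(n_s)]
    leaf_of = {n.taxon.label: i for i, n in enumerate(s_nodes) if n.is_leaf()}

    g_nodes = list(gene_tree.postorder_node_iter())
    g_idx = {id(n): i for i, n in enumerate(g_nodes)}
    g_children = [[g_idx[id(c)] for c in n.child_nodes()] for n in g_nodes]
    g_leaf = {
        i: leaf_of[leaf_map(n.taxon.label)]
        for i, n in enumerate(g_nodes) if n.is_leaf()
    }

    @lru_cache(maxsize=None)
    def cost(g, s):
        kids = g_children[g]
        if not kids:
            return 0.0 if g_leaf[g] == s else math.inf
        g1, g2 = kids
        best = math.inf
        if s_children[s]:
            left, right = s_children[s]
            for a, b in ((g1, g2), (g2, g1)):
                for s1 in range(n_s):
                    if not desc[left][s1]:
                        continue
                    for s2 in range(n_s):
                        if not desc[right][s2]:
                            continue
                        best = min(best, loss * (dist[left][s1] + dist[right][s2])
                                   + cost(a, s1) + cost(b, s2))
        for s1 in range(n_s):
            if not desc[s][s1]:
                continue
            for s2 in range(n_s):
                if not desc[s][s2]:
                    continue
                best = min(best, dup + loss * (dist[s][s1] + dist[s][s2])
                           + cost(g1, s1) + cost(g2, s2))
        if allow_transfer:
            for a, b in ((g1, g2), (g2, g1)):
                for s1 in range(n_s):
                    if not desc[s][s1]:
                        continue
                    for s2 in range(n_s):
                        if comparable[s][s2]:
                            continue
                        best = min(best, transfer + loss * dist[s][s1]
                                   + cost(a, s1) + cost(b, s2))
        return best

    root = len(g_nodes) - 1
    return min(cost(root, s) for s in range(n_s))


# ------------------------------------------------------- likelihood oracle


def loglik_state_sum(alignment, tree, model):
    """Tree log-likelihood by exhaustive summation over internal states."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    n_sites = len(next(iter(alignment.values())))
    char_state = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    p_cache = {}

    def pmat(t):
        if t not in p_cache:
            p_cache[t] = model.transition_matrix(t)
        return p_cache[t]

    for site in range(n_sites):
        site_lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assign)}
            for lf in leaves:
                states[id(lf)] = char_state[alignment[lf.taxon.label][site]]
            prob = model.pi[states[id(tree.seed_node)]]
            for node in nodes:
                if node.parent_node is not None:
                    p = pmat(float(node.edge.length))
                    prob *= p[states[id(node.parent_node)], states[id(node)]]
            site_lik += prob
        total += math.log(site_lik)
    return total


# -------------------------------------------------------------- ENC oracle


_CODE = None


def enc_spreadsheet(seq):
    """Wright's ENC recomputed family-by-family, spreadsheet style."""
    global _CODE
    if _CODE is None:
        from lgt_audit._codons import GENETIC_CODE

        _CODE = GENETIC_CODE
    counts = {}
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if _CODE.get(codon, "*") != "*":
            counts[codon] = counts.get(codon, 0) + 1
    families = {}
    for codon, aa in _CODE.items():
        if aa != "*":
            families.setdefault(aa, []).append(codon)
    f_by_class = {}
    for aa, codons in families.items():
        k = len(codons)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f_hat = (n * sum_p2 - 1) / (n - 1)
        if f_hat > 0:
            f_by_class.setdefault(k, []).append(f_hat)
    means = {k: sum(v) / len(v) for k, v in f_by_class.items()}
    fallback = sum(means.values()) / len(means)
    enc = 2.0
    for k, n_fam in ((2, 9), (3, 1), (4, 5), (6, 3)):
        enc += n_fam / means.get(k, fallback)
    return min(enc, 61.0)


# ---------------------------------------------------------------- helpers


def random_binary_tree(labels, rng):
    """Uniform-ish random rooted binary tree over the given leaf labels (dendropy)."""
    import dendropy

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    labels = list(labels)
    rng.shuffle(labels)
    nodes = []
    for lab in labels:
        leaf = dendropy.Node(edge_length=float(rng.uniform(0.1, 1.0)))
        leaf.taxon = taxa.require_taxon(label=lab)
        nodes.append(leaf)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node(edge_length=float(rng.uniform(0.1, 1.0)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    for n in nodes:
        tree.seed_node.add_child(n)
    return tree
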