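"""Newick tree reading/writing shared by the simulators and tree statistics.

Trees are dendropy ``Tree`` objects. Bootstrap-style support values live in
``node.label`` of internal nodes (the conventional Newick internal-node-label
slot), as percentages in [0, 100].
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import dendropy

from .errors import InvalidArgumentError

__all__ = [
    "tree_from_newick",
    "tree_to_newick",
    "read_tree",
    "write_tree",
    "read_trees",
    "clone_tree",
    "leaf_labels",
    "get_support",
]


def tree_from_newick(newick: str) -> dendropy.Tree:
    """Parse one Newick string; internal node labels are kept as labels, not taxa."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """One-line Newick with internal-node labels (supports) and branch lengths."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def read_tree(path) -> dendropy.Tree:
    return tree_from_newick(Path(path).read_text())


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def read_trees(paths: Iterable) -> list[dendropy.Tree]:
    return [read_tree(p) for p in paths]


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep copy with a fresh taxon namespace (safe to relabel)."""
    return tree_from_newick(tree_to_newick(tree))


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def get_support(node: dendropy.Node) -> float | None:
    """Support of the edge above an internal node, parsed from its label."""
    if node.label is None or node.label == "":
        return None
    try:
        return float(node.label)
    except ValueError as exc:
        raise InvalidArgumentError(
            f"internal node label {node.label!r} is not a numeric support"
        ) from exc
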