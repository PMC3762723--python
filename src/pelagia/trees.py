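"""Shared chronogram helpers on top of dendropy.

A chronogram is a :class:`dendropy.Tree` whose branch lengths are durations
in My; node ages (Ma before present) are derived assuming the tips are
extant (age 0) unless the tree is non-ultrametric, in which case ages are
measured from the deepest tip.
"""

from __future__ import annotations

import dendropy

__all__ = [
    "read_chronogram",
    "ensure_node_labels",
    "node_ages",
    "tree_to_graph",
]


def read_chronogram(source: str) -> dendropy.Tree:
    """Read a Newick chronogram from a path or a literal Newick string."""
    if source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        with open(source) as fh:
            tree = dendropy.Tree.get(file=fh, schema="newick")
    tree.is_rooted = True
    return tree


def ensure_node_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign stable labels to every node in place.

    Leaves are labelled by their taxon; unlabelled internal nodes get
    ``nd<k>`` in preorder, so labels are reproducible for a given topology.
    """
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label if node.taxon else node.label
        elif not node.label:
            node.label = f"nd{k}"
        if not node.is_leaf():
            k += 1
    return tree


def node_ages(tree: dendropy.Tree) -> dict[str, float]:
    """Ages (Ma) of all nodes, keyed by node label.

    The deepest leaf defines age zero's offset: for an ultrametric tree all
    tips get age 0 and internal ages equal the height above the tips.
    """
    ensure_node_labels(tree)
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    total = max(depths[lf] for lf in tree.leaf_node_iter())
    return {node.label: total - d for node, d in depths.items()}


def tree_to_graph(tree: dendropy.Tree) -> tuple[dict, list, list]:
    """Undirected adjacency view of a tree.

    Returns ``(adjacency, leaf_labels, internal_labels)`` where adjacency
    maps each node label to a list of ``(neighbour_label, branch_length)``.
    Branch lengths must be non-negative; ``None`` lengths count as zero.
    """
    ensure_node_labels(tree)
    adj: dict[str, list[tuple[str, float]]] = {}
    leaves, internals = [], []
    for node in tree.preorder_node_iter():
        adj.setdefault(node.label, [])
        (leaves if node.is_leaf() else internals).append(node.label)
        for child in node.child_nodes():
            length = child.edge.length or 0.0
            if length < 0:
                raise ValueError(f"negative branch length on edge to {child.label!r}")
            adj[node.label].append((child.label, length))
            adj.setdefault(child.label, []).append((node.label, length))
    return adj, leaves, internals
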