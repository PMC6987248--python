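"""Shared rooted-tree helpers built on dendropy.

Conventions used across the package:

* A *chronogram* is a rooted ultrametric tree whose edge lengths are in
  millions of years (My); every node additionally carries ``node.age``
  (time before present, tips at 0).
* A *phylogram* is the same topology with edge lengths in expected
  substitutions per site.

Trees are passed around as :class:`dendropy.Tree` objects; functions here
take care of age bookkeeping, ultrametricity checks and bipartition keys.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

__all__ = [
    "read_tree",
    "write_newick",
    "parse_newick",
    "set_ages_from_edge_lengths",
    "set_edge_lengths_from_ages",
    "is_ultrametric",
    "leaf_labels",
    "clade_key",
    "bipartition_keys",
    "clone_tree",
    "mrca",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree."""
    return dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")


def read_tree(path: str) -> dendropy.Tree:
    """Read a rooted tree from a newick file."""
    return dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialize ``tree`` as newick; write to ``path`` when given.

    Output is deterministic for a fixed tree (dendropy preserves child
    order), so identical simulations yield bit-identical files.
    """
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep-copy a tree, keeping the taxon namespace shared."""
    return tree.clone(depth=1)


def set_ages_from_edge_lengths(tree: dendropy.Tree) -> None:
    """Populate ``node.age`` assuming the tree is an ultrametric chronogram.

    Ages are computed as (root depth of deepest tip) minus the node's own
    depth, so tips land at ~0 even with floating-point jitter.
    """
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    height = max(depths[leaf] for leaf in tree.leaf_node_iter())
    for node, depth in depths.items():
        node.age = height - depth


def set_edge_lengths_from_ages(tree: dendropy.Tree) -> None:
    """Set every edge length to parent age minus child age (time units)."""
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    """True if all root-to-tip path lengths agree to ``rel_tol`` × root age."""
    depths = []
    stack = [(tree.seed_node, 0.0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf():
            depths.append(d)
        for child in node.child_nodes():
            stack.append((child, d + (child.edge.length or 0.0)))
    if not depths:
        return True
    span = max(depths) - min(depths)
    scale = max(depths) or 1.0
    return span <= rel_tol * scale


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def clade_key(node: dendropy.Node) -> frozenset[str]:
    """Bipartition key for a node: the frozen set of its descendant tip labels.

    Keys are invariant under child-order rotations, which is how bootstrap
    chronograms are matched node-by-node to the point-estimate tree.
    """
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def bipartition_keys(tree: dendropy.Tree, internal_only: bool = True) -> dict[frozenset[str], dendropy.Node]:
    keys = {}
    for node in tree.preorder_node_iter():
        if internal_only and node.is_leaf():
            continue
        keys[clade_key(node)] = node
    return keys


def mrca(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the given tip labels."""
    labels = list(labels)
    want = set(labels)
    found = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon.label in want}
    missing = want - found
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    if len(want) == 1:
        (label,) = want
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
    node = tree.mrca(taxon_labels=labels)
    if node is None:
        raise ValueError(f"no MRCA found for {sorted(want)}")
    return node
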