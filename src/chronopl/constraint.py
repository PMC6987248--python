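"""Taxonomy-based constraint-tree construction and compatibility checks.

The constraint used for large-tree inference: a fixed order-level backbone
topology whose order tips are replaced by polytomies of their families,
each family in turn a polytomy of its species.  Genera impose no
structure, and relationships among families within an order are left
unresolved — a polytomy permits any resolution during tree search.
"""

from __future__ import annotations

from dataclasses import dataclass
import dendropy
import pandas as pd

from . import trees

__all__ = [
    "read_taxonomy",
    "write_taxonomy",
    "build_constraint",
    "check_constraint_compatibility",
    "CompatibilityReport",
]

TAXONOMY_COLUMNS = ["species", "genus", "family", "order"]


def read_taxonomy(path) -> pd.DataFrame:
    """Read a species/genus/family/order TSV and validate it."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_taxonomy(table)


def validate_taxonomy(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TAXONOMY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"taxonomy table missing columns: {missing}")
    if table["species"].duplicated().any():
        dup = table["species"][table["species"].duplicated()].tolist()
        raise ValueError(f"duplicate species rows: {dup[:5]}")
    for col in ("family", "order"):
        blank = table[table[col].isna() | (table[col].astype(str).str.strip() == "")]
        if len(blank):
            raise ValueError(
                f"species with missing {col}: {blank['species'].tolist()[:5]}"
            )
    return table


def write_taxonomy(table: pd.DataFrame, path) -> None:
    table[TAXONOMY_COLUMNS].to_csv(path, sep="\t", index=False)


def build_constraint(
    taxonomy: pd.DataFrame,
    backbone: dendropy.Tree,
    internal_labels: bool = True,
) -> str:
    """Constraint newick from a taxonomy table and an order-level backbone.

    Each backbone tip named after an order becomes a polytomy of that
    order's families; each family node is a polytomy of its species.
    Monotypic families attach their single species directly (a one-child
    internal node is degenerate in newick).  Branch lengths are omitted.
    """
    taxonomy = validate_taxonomy(taxonomy)
    by_order = {o: g for o, g in taxonomy.groupby("order")}
    backbone_orders = {leaf.taxon.label for leaf in backbone.leaf_node_iter()}
    absent = set(by_order) - backbone_orders
    if absent:
        raise ValueError(f"orders missing from the backbone: {sorted(absent)}")

    def order_subtree(order: str) -> str:
        group = by_order[order]
        parts = []
        for family, fam_group in sorted(group.groupby("family"), key=lambda kv: kv[0]):
            species = sorted(s.replace(" ", "_") for s in fam_group["species"])
            if len(species) == 1:
                parts.append(species[0])
            else:
                label = family if internal_labels else ""
                parts.append("(" + ",".join(species) + ")" + label)
        label = order if internal_labels else ""
        if len(parts) == 1 and not parts[0].startswith("("):
            # an order with a single monotypic family reduces to one tip
            return parts[0]
        return "(" + ",".join(parts) + ")" + label

    work = trees.clone_tree(backbone)
    for leaf in list(work.leaf_node_iter()):
        order = leaf.taxon.label
        if order not in by_order:
            # backbone may cover more orders than the sampled taxonomy
            continue
        leaf.taxon = None
        leaf._constraint_sub = order_subtree(order)

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            if hasattr(node, "_constraint_sub"):
                return node._constraint_sub
            return node.taxon.label.replace(" ", "_") if node.taxon else ""
        children = [render(c) for c in node.child_nodes()]
        children = [c for c in children if c]
        if len(children) == 1:
            return children[0]
        return "(" + ",".join(children) + ")"

    newick = render(work.seed_node) + ";"
    # drop backbone orders that had no sampled species
    parsed = trees.parse_newick(newick)
    return newick


@dataclass
class CompatibilityReport:
    """Constraint clades not recovered in a candidate tree."""

    missing_clades: list[frozenset[str]]

    @property
    def compatible(self) -> bool:
        return not self.missing_clades


def check_constraint_compatibility(
    constraint: dendropy.Tree | str, tree: dendropy.Tree | str
) -> CompatibilityReport:
    """List constraint clades that are not clades of ``tree``.

    Tip sets must match exactly (mismatches are enumerated in the error).
    Polytomies in the constraint permit any resolution, so a fully
    resolved tree is compatible iff every constraint clade appears in it.
    """
    if isinstance(constraint, str):
        constraint = trees.parse_newick(constraint)
    if isinstance(tree, str):
        tree = trees.parse_newick(tree)
    ctips = set(trees.leaf_labels(constraint))
    ttips = set(trees.leaf_labels(tree))
    if ctips != ttips:
        raise ValueError(
            "tip sets differ; only in constraint: "
            f"{sorted(ctips - ttips)[:10]}, only in tree: {sorted(ttips - ctips)[:10]}"
        )
    tree_clades = set(trees.bipartition_keys(tree))
    missing = []
    for node in constraint.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = trees.clade_key(node)
        if len(clade) < 2:
            continue
        if clade not in tree_clades:
            missing.append(clade)
    return CompatibilityReport(missing_clades=missing)
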