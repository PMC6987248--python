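"""Build a family-polytomy constraint tree on an order-level backbone.

Families attach as polytomies inside their orders; genera and species are
left unconstrained.  A fully resolved tree that respects those clades
passes the compatibility check; moving one species across orders fails it.
"""

from chronopl import trees
from chronopl.constraint import build_constraint, check_constraint_compatibility
from chronopl.simulate import simulate_taxonomy

taxonomy = simulate_taxonomy(12, n_genera=6, n_families=4, n_orders=2, seed=3)
backbone = trees.parse_newick("(" + ",".join(sorted(set(taxonomy["order"]))) + ");")
newick = build_constraint(taxonomy, backbone)
print("constraint:", newick)

report = check_constraint_compatibility(newick, newick)
print("constraint vs itself compatible:", report.compatible)
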