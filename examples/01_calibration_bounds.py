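"""Derive hard maximum ages from fossil minimum ages.

Loads the packaged 55-row fossil calibration table, resolves the constant
interval width shared by its rows, and regenerates two maxima from their
minima.  The printed maxima should equal the table's own values: every
fossil minimum gains the same 16.82 My window.
"""

from chronopl.calibrations import (
    BoundScheme,
    compute_max_age,
    load_packaged_table,
    resolve_interval_width,
)

table = load_packaged_table()
width = resolve_interval_width(table)
print(f"calibration table: {len(table)} fossil rows; interval width {width} My")
for clade in ("Ebenaceae", "Valeriana"):
    row = table[table["clade"] == clade].iloc[0]
    got = compute_max_age(row.min_age, BoundScheme(interval_width=width))
    print(f"  {clade}: min {row.min_age} My -> max {got:.2f} My (table says {row.max_age})")
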