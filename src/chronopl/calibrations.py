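"""Fossil calibration handling: hard min/max bounds and dating configs.

Each fossil gives a hard *minimum* age for its calibrated node (crown or
stem).  Hard *maximum* ages are derived from the minimum by a fixed bound
scheme: a log-normal tail rule (offset = fossil minimum, mean 1.0, sd 1.0
on the log scale, 95% upper boundary) that in the published calibration
table resolves to a constant interval width of 16.82 My added to every
minimum.  The constant-width mode is the default because it reproduces the
published table exactly; the analytic log-normal mode is available for
comparison.  The angiosperm root itself is constrained to [180, 220] My.
"""

from __future__ import annotations

import importlib.resources
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from scipy.stats import norm

from . import trees

__all__ = [
    "CalibrationPoint",
    "BoundScheme",
    "RootConstraint",
    "compute_max_age",
    "resolve_interval_width",
    "read_calibration_table",
    "write_calibration_table",
    "load_packaged_table",
    "packaged_calibration_points",
    "map_to_node",
    "emit_dating_config",
]

TABLE_COLUMNS = ["clade", "fossil", "period", "locality", "min_age", "max_age", "crown_stem"]


@dataclass(frozen=True)
class CalibrationPoint:
    """A named clade with hard fossil age bounds.

    ``taxa`` lists species that define the clade in a target tree: the crown
    node is their MRCA, the stem node is that node's parent.
    """

    clade_label: str
    min_age: float
    max_age: float
    placement: str  # "crown" or "stem"
    taxa: tuple[str, ...] = ()
    fossil_name: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.min_age < self.max_age):
            raise ValueError(
                f"{self.clade_label}: require 0 < min_age < max_age, "
                f"got [{self.min_age}, {self.max_age}]"
            )
        if self.placement not in ("crown", "stem"):
            raise ValueError(f"{self.clade_label}: unknown placement {self.placement!r}")


@dataclass
class BoundScheme:
    """How a hard maximum age is derived from a fossil minimum age.

    mode="constant": max = min + interval_width (the published table's rule).
    mode="analytic": max = min + exp(log_mean + z(quantile) * log_sd).
    """

    mode: str = "constant"
    interval_width: float = 16.82
    log_mean: float = 1.0
    log_sd: float = 1.0
    quantile_level: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "analytic"):
            raise ValueError(f"unknown bound scheme mode {self.mode!r}")
        if self.mode == "constant" and self.interval_width < 15:
            raise ValueError("interval_width must be at least 15 My")


@dataclass(frozen=True)
class RootConstraint:
    """Hard bounds on the root (angiosperm crown) age, My."""

    min_age: float = 180.0
    max_age: float = 220.0


def compute_max_age(min_age: float, scheme: BoundScheme | None = None) -> float:
    """Hard maximum age derived from a fossil minimum age."""
    if min_age <= 0:
        raise ValueError(f"min_age must be positive, got {min_age}")
    scheme = scheme or BoundScheme()
    if scheme.mode == "constant":
        return min_age + scheme.interval_width
    import math

    z = norm.ppf(scheme.quantile_level)
    return min_age + math.exp(scheme.log_mean + z * scheme.log_sd)


def resolve_interval_width(table: pd.DataFrame) -> float:
    """Resolve the constant interval width from a calibration table.

    Returns the modal value of max_age − min_age rounded to 2 decimals
    (rows whose maxima are printed at reduced precision are out-voted).
    """
    diffs = (table["max_age"] - table["min_age"]).round(2)
    width, _count = Counter(diffs).most_common(1)[0]
    return float(width)


def read_calibration_table(path) -> pd.DataFrame:
    """Read a TSV calibration table (clade/fossil/period/locality/min/max/cr-st)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"calibration table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("calibration table has no rows")
    bad = table[table["min_age"] >= table["max_age"]]
    if len(bad):
        raise ValueError(f"rows with min_age >= max_age: {bad['clade'].tolist()}")
    tokens = set(table["crown_stem"])
    unknown = tokens - {"cr.", "st.", "crown", "stem"}
    if unknown:
        raise ValueError(f"unknown crown/stem tokens: {sorted(unknown)}")
    dup = table["clade"][table["clade"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate clade labels: {sorted(set(dup))}")
    return table


def write_calibration_table(points: Sequence[CalibrationPoint], path) -> None:
    rows = [
        {
            "clade": p.clade_label,
            "fossil": p.fossil_name,
            "period": "",
            "locality": "",
            "min_age": p.min_age,
            "max_age": p.max_age,
            "crown_stem": "cr." if p.placement == "crown" else "st.",
        }
        for p in points
    ]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_packaged_table() -> pd.DataFrame:
    """The transcribed 55-row fossil calibration table shipped with the package."""
    with importlib.resources.files("chronopl.data").joinpath("fossil_calibrations.tsv").open() as fh:
        return read_calibration_table(fh)


def _placement(token: str) -> str:
    return "crown" if token in ("cr.", "crown") else "stem"


def table_to_points(
    table: pd.DataFrame, clade_taxa: dict[str, Sequence[str]] | None = None
) -> list[CalibrationPoint]:
    """Turn table rows into CalibrationPoints, attaching defining taxa if given."""
    clade_taxa = clade_taxa or {}
    return [
        CalibrationPoint(
            clade_label=row.clade,
            fossil_name=row.fossil,
            min_age=float(row.min_age),
            max_age=float(row.max_age),
            placement=_placement(row.crown_stem),
            taxa=tuple(clade_taxa.get(row.clade, ())),
        )
        for row in table.itertuples()
    ]


def packaged_calibration_points() -> list[CalibrationPoint]:
    return table_to_points(load_packaged_table())


def map_to_node(tree: dendropy.Tree, cal: CalibrationPoint) -> dendropy.Node:
    """Node calibrated by ``cal``: MRCA of its taxa (crown) or its parent (stem).

    A warning is emitted when the taxa are not monophyletic in the tree; the
    MRCA is still returned, mirroring how fixed clade definitions behave on
    an arbitrary user tree.
    """
    if not cal.taxa:
        raise ValueError(f"{cal.clade_label}: no defining taxa attached")
    node = trees.mrca(tree, cal.taxa)
    spanned = {leaf.taxon.label for leaf in node.leaf_iter()}
    if spanned != set(cal.taxa):
        warnings.warn(
            f"{cal.clade_label}: taxa not monophyletic; MRCA spans "
            f"{len(spanned)} tips",
            stacklevel=2,
        )
    if cal.placement == "stem":
        if node.parent_node is None:
            raise ValueError(f"{cal.clade_label}: stem of the root is undefined")
        node = node.parent_node
    return node


def emit_dating_config(
    tree_path: str,
    calibrations: Sequence[CalibrationPoint],
    root: RootConstraint | None = None,
    smoothing: float = 0.0033,
    n_sites: int = 4968,
    out_path: str | None = None,
) -> str:
    """Emit a treePL-dialect dating configuration.

    One ``mrca``/``min``/``max`` triple per calibration (sorted by clade
    label for byte-determinism), plus the root constraint, smoothing value
    and alignment length.
    """
    root = root or RootConstraint()
    lines = [f"treefile = {tree_path}", f"numsites = {n_sites}", f"smooth = {smoothing}"]
    lines += [
        "mrca = root ALL",
        f"min = root {_fmt(root.min_age)}",
        f"max = root {_fmt(root.max_age)}",
    ]
    for cal in sorted(calibrations, key=lambda c: c.clade_label):
        if not cal.taxa:
            raise ValueError(f"{cal.clade_label}: calibration not mapped to taxa")
        name = cal.clade_label.replace(" ", "_")
        lines.append(f"mrca = {name} " + " ".join(cal.taxa))
        lines.append(f"min = {name} {_fmt(cal.min_age)}")
        lines.append(f"max = {name} {_fmt(cal.max_age)}")
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write(text)
    return text


def dating_config_json(
    tree_path: str,
    calibrations: Sequence[CalibrationPoint],
    root: RootConstraint | None = None,
    smoothing: float = 0.0033,
    n_sites: int = 4968,
) -> str:
    """JSON mirror of :func:`emit_dating_config` (same content, same order)."""
    import json

    root = root or RootConstraint()
    payload = {
        "treefile": tree_path,
        "numsites": n_sites,
        "smooth": smoothing,
        "root": {"min": root.min_age, "max": root.max_age},
        "calibrations": [
            {
                "clade": cal.clade_label,
                "min": cal.min_age,
                "max": cal.max_age,
                "placement": cal.placement,
                "taxa": list(cal.taxa),
            }
            for cal in sorted(calibrations, key=lambda c: c.clade_label)
        ],
    }
    return json.dumps(payload, indent=2)


def _fmt(x: float) -> str:
    return f"{x:g}"
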