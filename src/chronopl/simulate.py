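"""Synthetic data generation for every stage of the dating pipeline.

The generator produces calibrated chronograms with known truth so that the
penalized-likelihood machinery can be tested end to end offline:

* ultrametric chronograms from a constant-rate birth–death process
  conditioned on the number of extant tips (simple retry conditioning);
* autocorrelated log-normal (geometric Brownian) substitution rates along
  edges, with drift −sd²/2 so the expected rate is constant along paths —
  the rate-variation regime penalized likelihood smooths toward;
* phylograms with edge lengths rate × duration, optionally with Poisson
  substitution-count noise at a stated alignment length;
* fossil-style calibration windows guaranteed to contain the true node age;
* bootstrap pseudo-replicate phylograms on the fixed topology.

Time is in millions of years (My); branch lengths in substitutions/site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import trees
from .calibrations import CalibrationPoint
from .dating import Chronogram, Phylogram

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_chronogram",
    "simulate_rates",
    "chronogram_to_phylogram",
    "sample_calibrations",
    "make_bootstrap_phylograms",
    "simulate_truth",
    "simulate_taxonomy",
    "simulate_sequences",
    "random_coding_sequence",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults emulate the empirical setting the pipeline targets: a two-locus
    plastid supermatrix of 4,968 aligned sites, rates around 5×10⁻⁴
    substitutions/site/My, and moderate lineage-wise rate heterogeneity.
    """

    n_tips: int = 100
    birth_rate: float = 0.02  # speciation events / lineage / My (crown ages ~200-250 My)
    death_rate: float = 0.005
    root_rate: float = 2e-3  # substitutions / site / My (fast plastid marker scale)
    rate_log_sd: float = 0.2  # per-edge log-scale jitter of the GBM rate walk
    n_sites: int = 4968
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")
        if not (self.birth_rate > self.death_rate >= 0):
            raise ValueError("require birth_rate > death_rate >= 0")
        if self.root_rate <= 0:
            raise ValueError("root_rate must be positive")
        if self.rate_log_sd < 0:
            raise ValueError("rate_log_sd must be non-negative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")


@dataclass
class SimulatedTruth:
    """A complete synthetic dataset with its generating truth."""

    chronogram: Chronogram
    edge_rates: dict[dendropy.Node, float]
    phylogram: Phylogram
    calibrations: list[CalibrationPoint] = field(default_factory=list)


def _rng(seed: int, stage: int) -> np.random.Generator:
    # independent streams per pipeline stage, all derived from one user seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


class _Lineage:
    __slots__ = ("birth", "end", "children")

    def __init__(self, birth: float):
        self.birth = birth
        self.end: float | None = None
        self.children: list["_Lineage"] = []


def _grow_birth_death(config: SimulationConfig, rng: np.random.Generator):
    """One forward pass; returns (root lineages, stop time) or None on extinction.

    The process starts from the crown (two lineages) and is cut at the moment
    the first event *after* the standing diversity reaches n_tips would
    occur; extinct subtrees are pruned afterwards.
    """
    t = 0.0
    left, right = _Lineage(0.0), _Lineage(0.0)
    active = [left, right]
    total_rate = config.birth_rate + config.death_rate
    while True:
        t += rng.exponential(1.0 / (total_rate * len(active)))
        if len(active) == config.n_tips:
            for lin in active:
                lin.end = t
            return (left, right), t
        if rng.random() < config.birth_rate / total_rate:
            lin = active.pop(rng.integers(len(active)))
            lin.end = t
            lin.children = [_Lineage(t), _Lineage(t)]
            active.extend(lin.children)
        else:
            lin = active.pop(rng.integers(len(active)))
            lin.end = t
            if not active:
                return None


def _to_dendropy(roots, stop_time: float, n_tips: int) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    counter = [0]

    def build(lin: _Lineage) -> dendropy.Node | None:
        # reconstructed tree: drop extinct subtrees, splice through unary nodes
        if not lin.children:
            if lin.end < stop_time - 1e-12:  # died before the present
                return None
            node = dendropy.Node()
            node.age = 0.0
            return node
        kids = [build(c) for c in lin.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = dendropy.Node()
        node.age = stop_time - lin.end
        for k in kids:
            node.add_child(k)
        return node

    root_nodes = [build(r) for r in roots]
    root_nodes = [r for r in root_nodes if r is not None]
    if len(root_nodes) == 2:
        root = dendropy.Node()
        root.age = stop_time
        root.add_child(root_nodes[0])
        root.add_child(root_nodes[1])
    else:
        root = root_nodes[0]
    tree.seed_node = root
    for leaf in tree.leaf_node_iter():
        counter[0] += 1
        leaf.taxon = taxa.require_taxon(label=f"t{counter[0]}")
    if len(tree.leaf_nodes()) != n_tips:
        raise RuntimeError("lost tips while pruning extinct lineages")
    trees.set_edge_lengths_from_ages(tree)
    return tree


def simulate_chronogram(config: SimulationConfig, max_retries: int = 1000) -> Chronogram:
    """Rooted binary ultrametric tree with ``config.n_tips`` extant tips.

    Simulation that goes extinct before reaching ``n_tips`` is retried with a
    fresh internal draw; after ``max_retries`` failures an error is raised.
    """
    rng = _rng(config.seed, 1)
    for _ in range(max_retries):
        grown = _grow_birth_death(config, rng)
        if grown is None:
            continue
        roots, stop_time = grown
        tree = _to_dendropy(roots, stop_time, config.n_tips)
        return Chronogram(tree)
    raise RuntimeError(
        f"birth-death simulation went extinct {max_retries} times before "
        f"reaching {config.n_tips} tips"
    )


def simulate_rates(
    chrono: Chronogram, config: SimulationConfig
) -> dict[dendropy.Node, float]:
    """Autocorrelated log-normal edge rates, keyed by the edge's child node.

    Child rate = parent rate × exp(N(−sd²/2, sd)); edges off the root start
    the walk from ``config.root_rate``.  The −sd²/2 drift keeps E[rate]
    constant along every root-to-tip path.
    """
    rng = _rng(config.seed, 2)
    sd = config.rate_log_sd
    rates: dict[dendropy.Node, float] = {}
    for node in chrono.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_rate = rates.get(node.parent_node, config.root_rate)
        if sd == 0:
            rates[node] = parent_rate
        else:
            rates[node] = parent_rate * float(np.exp(rng.normal(-0.5 * sd * sd, sd)))
    return rates


def chronogram_to_phylogram(
    chrono: Chronogram,
    rates: dict[dendropy.Node, float],
    config: SimulationConfig,
) -> Phylogram:
    """Phylogram with edge lengths rate × duration (± Poisson noise).

    With ``poisson_noise`` on, each edge length is drawn as
    Poisson(rate × duration × n_sites) / n_sites.
    """
    rng = _rng(config.seed, 3)
    tree = trees.clone_tree(chrono.tree)
    orig_nodes = list(chrono.tree.preorder_node_iter())
    copy_nodes = list(tree.preorder_node_iter())
    for orig, node in zip(orig_nodes, copy_nodes):
        if node.parent_node is None:
            continue
        if orig not in rates:
            raise KeyError(f"no rate for edge above node {trees.clade_key(orig)}")
        duration = orig.parent_node.age - orig.age
        expected = rates[orig] * duration
        if config.poisson_noise:
            node.edge.length = float(rng.poisson(expected * config.n_sites)) / config.n_sites
        else:
            node.edge.length = expected
        node.age = None
    return Phylogram(tree, n_sites=config.n_sites)


def sample_calibrations(
    truth: Chronogram, k: int, width: float = 16.82, seed: int = 0
) -> list[CalibrationPoint]:
    """Fossil-style calibration windows on ``k`` distinct internal nodes.

    The root is always among them, with a window containing the true root
    age.  Each minimum age is drawn uniformly in (0, true age]; the maximum
    is minimum + ``width``; draws are repeated until the window contains the
    truth (the maximum side is not guaranteed by construction).
    """
    rng = _rng(seed, 4)
    internals = [n for n in truth.tree.preorder_node_iter() if not n.is_leaf()]
    if k > len(internals):
        raise ValueError(f"k={k} exceeds number of internal nodes ({len(internals)})")
    root = truth.tree.seed_node
    others = [n for n in internals if n is not root]
    chosen = [root]
    if k > 1:
        idx = rng.choice(len(others), size=k - 1, replace=False)
        chosen += [others[i] for i in sorted(idx)]
    points = []
    for i, node in enumerate(chosen):
        age = node.age
        for _ in range(10000):
            lo = float(rng.uniform(0.0, age))
            if lo > 0 and lo + width >= age:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("failed to draw a truth-containing window")
        taxa = tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))
        label = "root" if node is root else f"clade_{i:03d}"
        points.append(
            CalibrationPoint(
                clade_label=label,
                min_age=lo,
                max_age=lo + width,
                placement="crown",
                taxa=taxa,
            )
        )
    return points


def make_bootstrap_phylograms(
    phylo: Phylogram, n_reps: int, seed: int = 0
) -> list[Phylogram]:
    """Pseudo-replicate phylograms on the same topology.

    A site-resampling surrogate: every edge length is redrawn as
    Poisson(length × n_sites) / n_sites, mimicking the sampling noise of a
    bootstrap re-estimate with the topology held fixed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = _rng(seed, 5)
    n = phylo.n_sites
    lengths = np.array(
        [node.edge.length or 0.0 for node in phylo.tree.preorder_node_iter() if node.parent_node],
        dtype=float,
    )
    reps = []
    for _ in range(n_reps):
        drawn = rng.poisson(lengths * n) / n
        tree = trees.clone_tree(phylo.tree)
        it = iter(drawn)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = float(next(it))
        reps.append(Phylogram(tree, n_sites=n))
    return reps


def simulate_truth(config: SimulationConfig, n_calibrations: int = 10, cal_width: float = 16.82) -> SimulatedTruth:
    """Convenience wrapper: chronogram + rates + phylogram + calibrations."""
    chrono = simulate_chronogram(config)
    rates = simulate_rates(chrono, config)
    phylo = chronogram_to_phylogram(chrono, rates, config)
    n_internal = len([n for n in chrono.tree.preorder_node_iter() if not n.is_leaf()])
    cals = sample_calibrations(chrono, min(n_calibrations, n_internal), width=cal_width, seed=config.seed)
    return SimulatedTruth(chronogram=chrono, edge_rates=rates, phylogram=phylo, calibrations=cals)


# ---------------------------------------------------------------------------
# taxonomy and sequence fixtures for the QC and constraint-tree stages


def simulate_taxonomy(
    n_species: int,
    n_genera: int | None = None,
    n_families: int | None = None,
    n_orders: int = 3,
    seed: int = 0,
):
    """Random species → genus → family → order table (pandas DataFrame)."""
    import pandas as pd

    rng = _rng(seed, 6)
    n_genera = n_genera or max(2, n_species // 3)
    n_families = n_families or max(2, n_genera // 2)
    orders = [f"Order{i + 1}" for i in range(n_orders)]
    families = [f"Famil{chr(ord('a') + i % 26)}aceae{i // 26 or ''}" for i in range(n_families)]
    fam_order = {f: orders[int(rng.integers(n_orders))] for f in families}
    # guarantee every order has at least one family
    for i, o in enumerate(orders):
        fam_order[families[i % n_families]] = o
    genera = [f"Gen{i + 1:03d}" for i in range(n_genera)]
    gen_family = {g: families[int(rng.integers(n_families))] for g in genera}
    rows = []
    for i in range(n_species):
        genus = genera[i % n_genera]
        species = f"{genus} sp{i + 1:04d}"
        family = gen_family[genus]
        rows.append({"species": species, "genus": genus, "family": family, "order": fam_order[family]})
    return pd.DataFrame(rows)


_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))


def random_coding_sequence(n_codons: int, rng: np.random.Generator, start: bool = True) -> str:
    """Random in-frame coding sequence with no internal stop codons."""
    codons = []
    if start:
        codons.append("ATG")
    while len(codons) < n_codons:
        codon = "".join(_BASES[rng.integers(4, size=3)])
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def _mutate(seq: str, frac: float, rng: np.random.Generator, preserve_frame: bool = False) -> str:
    arr = np.array(list(seq))
    n_mut = rng.binomial(len(arr), frac)
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    arr[pos] = _BASES[rng.integers(4, size=n_mut)]
    out = "".join(arr)
    if preserve_frame:  # repair any in-frame stop codons the mutations created
        codons = [out[i : i + 3] for i in range(0, len(out) - 2, 3)]
        codons = ["TAC" if c in _STOPS else c for c in codons]
        out = "".join(codons) + out[len(codons) * 3 :]
    return out


def simulate_sequences(
    taxonomy,
    marker: str = "rbcL",
    n_codons: int = 200,
    family_divergence: float = 0.12,
    species_divergence: float = 0.02,
    seed: int = 0,
):
    """Species-labelled coding sequences with family-level similarity structure.

    Each family gets an ancestral stop-free coding sequence derived from one
    marker ancestor; species sequences are light mutations of their family
    ancestor (frame preserved), so that similarity searches recover family
    membership.  Returns a list of qc.TaxonRecord.
    """
    from .qc import TaxonRecord

    rng = _rng(seed, 7)
    ancestor = random_coding_sequence(n_codons, rng)
    fam_seq = {
        fam: _mutate(ancestor, family_divergence, rng, preserve_frame=True)
        for fam in sorted(set(taxonomy["family"]))
    }
    records = []
    for i, row in enumerate(taxonomy.itertuples()):
        seq = _mutate(fam_seq[row.family], species_divergence, rng, preserve_frame=True)
        records.append(
            TaxonRecord(
                species_name=row.species,
                marker=marker,
                accession=f"SYN{i + 1:05d}",
                sequence=seq,
            )
        )
    return records
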