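"""Smoothing-parameter selection by cross-validation.

Two schemes:

* :func:`cv_score` / :func:`run_cv` — terminal-pruning cross-validation:
  drop a terminal, re-date the reduced tree at smoothing λ, predict the
  dropped terminal's substitution count from the rate of the edge it
  attached to, and score the prediction error (chi-square by default).
* :func:`subsampled_cv` — the replicate scheme for trees too large to
  cross-validate whole: many replicates each keeping a small random
  fraction of the species, a full grid cross-validation per replicate, and
  the modal best-λ across replicates as the selected smoothing value.

λ multiplies a squared-rate penalty, so its useful magnitude scales with
(mean substitution count)/(rate scale)²; grids should be chosen at the
scale of the data at hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import trees
from .calibrations import CalibrationPoint, RootConstraint
from .dating import Phylogram, PLProblem, _Index, _solve

__all__ = ["smoothing_grid", "cv_score", "run_cv", "subsampled_cv", "CVResult", "SubsampledCVResult"]

logger = logging.getLogger(__name__)


def smoothing_grid(cvstart: float = 10.0, cvstop: float = 0.0001, cvmultstep: float = 0.9) -> list[float]:
    """Geometric λ grid: cvstart · cvmultstep^k down to cvstop (inclusive)."""
    if not (0 < cvmultstep < 1):
        raise ValueError("cvmultstep must be in (0, 1)")
    if cvstop > cvstart:
        raise ValueError("cvstop must not exceed cvstart")
    grid = []
    value = cvstart
    while value >= cvstop * (1 - 1e-12):
        grid.append(value)
        value *= cvmultstep
    return grid


@dataclass
class CVResult:
    """Grid cross-validation outcome: per-λ scores and the arg-min."""

    grid: list[float]
    scores: list[float]
    best: float

    def as_rows(self):
        return list(zip(self.grid, self.scores))


@dataclass
class SubsampledCVResult:
    """Replicate-subsampling outcome: per-replicate optima and the mode."""

    n_replicates: int
    keep_fraction: float
    grid: list[float]
    best_per_replicate: list[float]
    proportions: dict[float, float]
    modal: float


def _calibration_spans(tree, calibrations):
    """Per calibration, the tip sets of the calibrated crown node's children.

    Used to decide whether a calibration survives tip pruning: the window
    still belongs to the same node only if kept taxa remain in at least two
    of these child clades; otherwise the restricted MRCA would be a
    strictly shallower node and the window is dropped, not remapped.
    """
    spans = []
    for cal in calibrations:
        crown = trees.mrca(tree, cal.taxa)
        spans.append([trees.clade_key(c) for c in crown.child_nodes()])
    return spans


def _restrict_calibrations(
    calibrations: Sequence[CalibrationPoint],
    kept: set[str],
    spans: Sequence[Sequence[frozenset[str]]] | None = None,
) -> tuple[list[CalibrationPoint], bool]:
    """Intersect calibration taxa with the kept tip set.

    Returns (surviving calibrations, all_survived flag).  A calibration
    survives only if its kept taxa still span at least two children of the
    originally calibrated node (see :func:`_calibration_spans`); windows
    that no longer identify their node are dropped rather than remapped.
    """
    out = []
    ok = True
    for i, cal in enumerate(calibrations):
        taxa = tuple(t for t in cal.taxa if t in kept)
        if len(taxa) < 2:
            ok = False
            continue
        if spans is not None:
            covered = sum(1 for clade in spans[i] if clade & kept)
            if covered < 2:
                ok = False
                continue
        out.append(
            CalibrationPoint(
                clade_label=cal.clade_label,
                min_age=cal.min_age,
                max_age=cal.max_age,
                placement=cal.placement,
                taxa=taxa,
                fossil_name=cal.fossil_name,
            )
        )
    return out, ok


def _reduced_problems(phylo, calibrations, root, labels):
    """Per-terminal reduced phylograms with prediction bookkeeping."""
    tree = phylo.tree
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    tasks = []
    all_labels = set(leaves)
    spans = _calibration_spans(tree, calibrations)
    for label in labels:
        leaf = leaves[label]
        parent = leaf.parent_node
        if parent.parent_node is None:
            logger.info("cv: terminal %s is a child of the root; skipped", label)
            continue
        siblings = [c for c in parent.child_nodes() if c is not leaf]
        if len(siblings) != 1:
            logger.info("cv: terminal %s sits in a polytomy; skipped", label)
            continue
        sib = siblings[0]
        kept = all_labels - {label}
        cals, ok = _restrict_calibrations(calibrations, kept, spans)
        if not ok:
            logger.info("cv: pruning %s disconnects a calibration; skipped", label)
            continue
        reduced = trees.clone_tree(tree)
        reduced.prune_taxa_with_labels([label], suppress_unifurcations=True)
        l_gp = parent.edge.length or 0.0
        l_ps = sib.edge.length or 0.0
        frac = l_gp / (l_gp + l_ps) if (l_gp + l_ps) > 0 else 0.5
        tasks.append(
            {
                "label": label,
                "observed": round((leaf.edge.length or 0.0) * phylo.n_sites),
                "sib_key": trees.clade_key(sib),
                "frac": frac,
                "problem_tree": Phylogram(reduced, n_sites=phylo.n_sites),
                "calibrations": cals,
            }
        )
    return tasks


def _index_task(task, root: RootConstraint):
    """Attach the reduced-tree index and prediction-edge position to a task."""
    problem = PLProblem(task["problem_tree"], task["calibrations"], root, smoothing=1.0)
    idx = _Index(task["problem_tree"], problem.node_bounds())
    pos = None
    for i, node in enumerate(idx.nodes):
        if i > 0 and trees.clade_key(node) == task["sib_key"]:
            pos = i
            break
    if pos is None:
        raise RuntimeError(f"prediction edge not found for terminal {task['label']}")
    task["idx"] = idx
    task["sib_pos"] = pos
    return task


def _predict_error(task, u, rho, n_sites: int, error: str) -> float:
    idx = task["idx"]
    pos = task["sib_pos"]
    a, _, _ = idx.ages_from_u(u)
    age_top = a[idx.int_pos[idx.parent[pos]]]
    age_bot = 0.0 if idx.is_leaf[pos] else a[idx.int_pos[pos]]
    attach_age = age_top - task["frac"] * (age_top - age_bot)
    expected = float(np.exp(rho[pos - 1])) * attach_age * n_sites
    obs = task["observed"]
    if error == "squared":
        return (obs - expected) ** 2
    return (obs - expected) ** 2 / max(expected, 1e-12)


def _sample_terminals(phylo, n_terminals, seed):
    labels = sorted(trees.leaf_labels(phylo.tree))
    if n_terminals is None:
        n_terminals = min(len(labels), 50)
    if n_terminals > len(labels):
        raise ValueError("n_terminals exceeds the tip count")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    idx = rng.choice(len(labels), size=n_terminals, replace=False)
    return [labels[i] for i in sorted(idx)]


def cv_score(
    phylo: Phylogram,
    lam: float,
    calibrations: Sequence[CalibrationPoint] = (),
    root: RootConstraint | None = None,
    n_terminals: int | None = None,
    seed: int = 0,
    n_starts: int = 1,
    error: str = "chi2",
) -> float:
    """Mean terminal-pruning prediction error at smoothing λ.

    For each sampled terminal: prune it, date the reduced tree at λ under
    the surviving calibrations, place the terminal's attachment point on
    the merged edge at its original length fraction, predict the terminal's
    substitution count as rate × attachment age × n_sites, and score
    (observed − expected)²/expected (chi-square flavour; ``error="squared"``
    switches to plain squared error).  Deterministic for a fixed seed.
    """
    root = root or RootConstraint()
    labels = _sample_terminals(phylo, n_terminals, seed)
    tasks = _reduced_problems(phylo, calibrations, root, labels)
    if not tasks:
        raise ValueError("no usable terminals for cross-validation")
    errs = []
    for task in tasks:
        _index_task(task, root)
        _, u, rho = _solve(task["idx"], lam, n_starts, seed, maxiter=300, ftol=1e-9)
        errs.append(_predict_error(task, u, rho, phylo.n_sites, error))
    return float(np.mean(errs))


def run_cv(
    phylo: Phylogram,
    grid: Sequence[float],
    calibrations: Sequence[CalibrationPoint] = (),
    root: RootConstraint | None = None,
    n_terminals: int | None = None,
    seed: int = 0,
    n_starts: int = 1,
    error: str = "chi2",
) -> CVResult:
    """Cross-validate over a λ grid, reusing the per-terminal reduced trees.

    Fits are warm-started from the previous λ's solution on the same
    reduced tree, which makes a dense grid affordable.
    """
    root = root or RootConstraint()
    grid = list(grid)
    if not grid:
        raise ValueError("empty smoothing grid")
    labels = _sample_terminals(phylo, n_terminals, seed)
    tasks = _reduced_problems(phylo, calibrations, root, labels)
    if not tasks:
        raise ValueError("no usable terminals for cross-validation")
    for task in tasks:
        _index_task(task, root)
    scores = []
    warm = [None] * len(tasks)
    for lam in grid:
        errs = []
        for i, task in enumerate(tasks):
            _, u, rho = _solve(task["idx"], lam, n_starts, seed, init=warm[i], maxiter=300, ftol=1e-9)
            warm[i] = (u, rho)
            errs.append(_predict_error(task, u, rho, phylo.n_sites, error))
        scores.append(float(np.mean(errs)))
    best = grid[int(np.argmin(scores))]
    return CVResult(grid=grid, scores=scores, best=best)


def subsampled_cv(
    phylo: Phylogram,
    calibrations: Sequence[CalibrationPoint] = (),
    root: RootConstraint | None = None,
    n_replicates: int = 500,
    keep_fraction: float = 0.10,
    grid: Sequence[float] | None = None,
    seed: int = 0,
    n_terminals: int | None = None,
    n_starts: int = 1,
    error: str = "chi2",
) -> SubsampledCVResult:
    """Replicate-subsampling smoothing selection for large trees.

    Each replicate keeps ``keep_fraction`` of the species chosen uniformly
    without replacement (90% pruned at the default), restricts the
    phylogram and the calibrations to the kept set, runs the grid
    cross-validation, and records its best λ.  The selected value is the
    mode of the per-replicate optima; ties break toward smaller λ.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    root = root or RootConstraint()
    grid = list(grid) if grid is not None else smoothing_grid()
    labels = sorted(trees.leaf_labels(phylo.tree))
    n_keep = int(round(keep_fraction * len(labels)))
    if n_keep < 4:
        raise ValueError("keep_fraction leaves fewer than 4 tips per replicate")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    root_child_clades = [trees.clade_key(c) for c in phylo.tree.seed_node.child_nodes()]
    spans = _calibration_spans(phylo.tree, calibrations)
    best_per_rep = []
    for rep in range(n_replicates):
        idx = rng.choice(len(labels), size=n_keep, replace=False)
        kept = {labels[i] for i in idx}
        sub = trees.clone_tree(phylo.tree)
        sub.retain_taxa_with_labels(sorted(kept))
        cals, _ = _restrict_calibrations(calibrations, kept, spans)
        # the replicate's root is the original root only if tips survive on
        # both sides; otherwise the original minimum does not apply to it
        if all(kept & clade for clade in root_child_clades):
            sub_root = root
        else:
            sub_root = RootConstraint(min_age=1e-6, max_age=root.max_age)
        sub_phylo = Phylogram(sub, n_sites=phylo.n_sites)
        result = run_cv(
            sub_phylo,
            grid,
            cals,
            sub_root,
            n_terminals=n_terminals,
            seed=int(rng.integers(2**31 - 1)),
            n_starts=n_starts,
            error=error,
        )
        best_per_rep.append(result.best)
    counts = {lam: 0 for lam in grid}
    for b in best_per_rep:
        counts[b] += 1
    proportions = {lam: c / n_replicates for lam, c in counts.items()}
    top = max(proportions.values())
    modal = min(lam for lam, p in proportions.items() if p == top)
    return SubsampledCVResult(
        n_replicates=n_replicates,
        keep_fraction=keep_fraction,
        grid=grid,
        best_per_replicate=best_per_rep,
        proportions=proportions,
        modal=modal,
    )
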