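"""End-to-end pipeline orchestration over a single config file.

The pipeline composes the package's stages — synthetic-data generation (or
user inputs), sequence QC, constraint building, calibration emission,
optional subsampled cross-validation, penalized-likelihood dating,
bootstrap dating and confidence-interval annotation — and writes a
machine-readable run manifest (inputs, version, seeds, parameters,
artifact checksums).  Every text artifact starts with a header comment
naming the tool version, the config hash and the seed.

Config format: INI (key = value) with sections [run], [simulate], [qc],
[cv], [dating], [bootstrap], [ci]; all values have defaults, so an empty
config runs the full synthetic demo.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__, trees
from .calibrations import RootConstraint, dating_config_json, emit_dating_config
from .ci import date_replicates, summarize, write_annotated_nexus, write_interval_table
from .constraint import build_constraint
from .cv import smoothing_grid, subsampled_cv
from .dating import PLProblem, date_tree
from .qc import Checklist, run_qc, write_fasta
from .simulate import (
    SimulationConfig,
    make_bootstrap_phylograms,
    simulate_sequences,
    simulate_taxonomy,
    simulate_truth,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "chronopl_run"
    seed: int = 0
    # simulate
    n_tips: int = 60
    n_calibrations: int = 8
    # qc
    qc_species: int = 24
    # cv ("smoothing = cv" switches it on)
    smoothing: str = "2e8"
    cv_replicates: int = 8
    cv_keep_fraction: float = 0.25
    cv_grid_start: float = 1e10
    cv_grid_stop: float = 1e4
    cv_grid_step: float = 0.1
    cv_terminals: int = 6
    # bootstrap / ci
    bootstrap_replicates: int = 30
    ci_level: float = 0.95

    @property
    def config_hash(self) -> str:
        # hash the scientific settings only, not where the artifacts land
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        text = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    parser = configparser.ConfigParser()
    parser.read(str(path))
    cfg = PipelineConfig()

    def get(section, key, cast, attr):
        if parser.has_option(section, key):
            setattr(cfg, attr, cast(parser.get(section, key)))

    get("run", "out_dir", str, "out_dir")
    get("run", "seed", int, "seed")
    get("simulate", "n_tips", int, "n_tips")
    get("simulate", "n_calibrations", int, "n_calibrations")
    get("qc", "species", int, "qc_species")
    get("dating", "smoothing", str, "smoothing")
    get("cv", "replicates", int, "cv_replicates")
    get("cv", "keep_fraction", float, "cv_keep_fraction")
    get("cv", "grid_start", float, "cv_grid_start")
    get("cv", "grid_stop", float, "cv_grid_stop")
    get("cv", "grid_step", float, "cv_grid_step")
    get("cv", "terminals", int, "cv_terminals")
    get("bootstrap", "replicates", int, "bootstrap_replicates")
    get("ci", "level", float, "ci_level")
    return cfg


def _header(cfg: PipelineConfig) -> str:
    return f"chronopl {__version__} config={cfg.config_hash} seed={cfg.seed}"


def _write_text(path: Path, text: str, cfg: PipelineConfig, comment: str = "#") -> None:
    if comment == "[":
        header = f"[{_header(cfg)}]\n"
    else:
        header = f"{comment} {_header(cfg)}\n"
    path.write_text(header + text)


def _prepend_header(path: Path, cfg: PipelineConfig, comment: str = "#") -> None:
    text = path.read_text()
    if comment == "[":
        path.write_text(f"[{_header(cfg)}]\n" + text)
    else:
        path.write_text(f"{comment} {_header(cfg)}\n" + text)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to the out dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dict(cfg.__dict__),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "stages": {},
        "artifacts": {},
    }

    # -- stage: simulate -----------------------------------------------------
    sim_cfg = SimulationConfig(n_tips=cfg.n_tips, seed=cfg.seed)
    truth = simulate_truth(sim_cfg, n_calibrations=cfg.n_calibrations)
    root_cal = truth.calibrations[0]
    cals = truth.calibrations[1:]
    root = RootConstraint(root_cal.min_age, root_cal.max_age)
    _write_text(out / "phylogram.nwk", trees.write_newick(truth.phylogram.tree), cfg, "[")
    _write_text(out / "true_chronogram.nwk", trees.write_newick(truth.chronogram.tree), cfg, "[")
    manifest["stages"]["simulate"] = {"n_tips": cfg.n_tips, "root_age": truth.chronogram.root_age}

    # -- stage: qc -----------------------------------------------------------
    taxonomy = simulate_taxonomy(cfg.qc_species, seed=cfg.seed)
    records = simulate_sequences(taxonomy, seed=cfg.seed)
    fam_of = dict(zip(taxonomy["species"], taxonomy["family"]))
    checklist = Checklist.from_names("both", taxonomy["species"])
    kept, report = run_qc(records, records, fam_of, checklist, checklist)
    report.write(out / "qc_report.tsv")
    _prepend_header(out / "qc_report.tsv", cfg)
    write_fasta(kept, out / "qc_kept.fasta")
    _prepend_header(out / "qc_kept.fasta", cfg, ";")
    manifest["stages"]["qc"] = {"input": len(records), "kept": len(kept)}

    # -- stage: constraint ---------------------------------------------------
    orders = sorted(set(taxonomy["order"]))
    backbone = trees.parse_newick("(" + ",".join(orders) + ");")
    constraint = build_constraint(taxonomy, backbone)
    _write_text(out / "constraint.nwk", constraint + "\n", cfg, "[")
    manifest["stages"]["constraint"] = {"orders": len(orders)}

    # -- stage: calibrations -------------------------------------------------
    config_text = emit_dating_config(
        "phylogram.nwk", cals, root, smoothing=0.0, n_sites=sim_cfg.n_sites
    )
    _write_text(out / "dating_config.txt", config_text, cfg)
    (out / "dating_config.json").write_text(
        dating_config_json("phylogram.nwk", cals, root, smoothing=0.0, n_sites=sim_cfg.n_sites)
    )

    # -- stage: cv (optional) ------------------------------------------------
    grid = smoothing_grid(cfg.cv_grid_start, cfg.cv_grid_stop, cfg.cv_grid_step)
    if cfg.smoothing.strip().lower() == "cv":
        cv_res = subsampled_cv(
            truth.phylogram,
            cals,
            root,
            n_replicates=cfg.cv_replicates,
            keep_fraction=cfg.cv_keep_fraction,
            grid=grid,
            seed=cfg.seed,
            n_terminals=cfg.cv_terminals,
        )
        lam = cv_res.modal
        manifest["stages"]["cv"] = {
            "modal_smoothing": lam,
            "proportion": cv_res.proportions[lam],
            "grid": grid,
        }
    else:
        lam = float(cfg.smoothing)
        manifest["stages"]["cv"] = {"skipped": True, "smoothing": lam}

    # -- stage: dating -------------------------------------------------------
    problem = PLProblem(truth.phylogram, cals, root, smoothing=lam)
    fit = date_tree(problem, n_starts=3, seed=cfg.seed)
    _write_text(out / "chronogram.nwk", trees.write_newick(fit.chronogram.tree), cfg, "[")
    rates_rows = "edge_clade\trate\n" + "".join(
        f"{';'.join(sorted(trees.clade_key(n)))}\t{r:.8g}\n" for n, r in fit.rates.items()
    )
    _write_text(out / "rates.tsv", rates_rows, cfg)
    manifest["stages"]["dating"] = {
        "smoothing": lam,
        "objective": fit.objective,
        "root_age": fit.chronogram.root_age,
    }

    # -- stage: bootstrap + ci ----------------------------------------------
    reps = make_bootstrap_phylograms(truth.phylogram, cfg.bootstrap_replicates, seed=cfg.seed)
    chronos = date_replicates(reps, problem, n_starts=1, seed=cfg.seed, warm_from=fit)
    ann = summarize(chronos, level=cfg.ci_level, point_estimate=fit.chronogram)
    write_annotated_nexus(ann, out / "annotated_chronogram.nex")
    _prepend_header(out / "annotated_chronogram.nex", cfg, "[")
    write_interval_table(ann, out / "node_intervals.tsv")
    _prepend_header(out / "node_intervals.tsv", cfg)
    manifest["stages"]["ci"] = {
        "replicates_dated": len(chronos),
        "level": cfg.ci_level,
    }

    for artifact in sorted(out.iterdir()):
        if artifact.name != "manifest.json":
            manifest["artifacts"][artifact.name] = _checksum(artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
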