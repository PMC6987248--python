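"""Synthetic-data generator: distributional oracles and invariants."""

import numpy as np
import pytest

from chronopl import trees
from chronopl.simulate import (
    SimulationConfig,
    chronogram_to_phylogram,
    make_bootstrap_phylograms,
    sample_calibrations,
    simulate_chronogram,
    simulate_rates,
    simulate_taxonomy,
    simulate_truth,
)


def _independent_yule_root_ages(n_tips, birth, n_reps, rng):
    """Separately coded Yule oracle with the same stopping convention:

    two crown lineages, exponential waits at total rate k·birth, stop at
    the first event after standing diversity reaches n_tips.
    """
    ages = np.empty(n_reps)
    for i in range(n_reps):
        t, k = 0.0, 2
        while k < n_tips:
            t += rng.exponential(1.0 / (birth * k))
            k += 1
        t += rng.exponential(1.0 / (birth * k))
        ages[i] = t
    return ages


class TestChronogram:
    def test_two_tips_single_internal_node(self):
        chrono = simulate_chronogram(SimulationConfig(n_tips=2, seed=1))
        internals = [n for n in chrono.tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internals) == 1
        for leaf in chrono.tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(chrono.root_age)

    def test_binary_tree_node_arithmetic(self):
        chrono = simulate_chronogram(SimulationConfig(n_tips=1000, seed=3))
        internals = [n for n in chrono.tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internals) == 999

    def test_ultrametric_and_ordered(self):
        chrono = simulate_chronogram(SimulationConfig(n_tips=64, seed=5))
        assert trees.is_ultrametric(chrono.tree)
        for node in chrono.tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.parent_node.age > node.age

    def test_pure_birth_mean_root_age_matches_yule_oracle(self):
        n_reps = 1000
        cfg = lambda s: SimulationConfig(n_tips=64, birth_rate=1.0, death_rate=0.0, seed=s)
        sim_ages = np.array(
            [simulate_chronogram(cfg(s)).root_age for s in range(n_reps)]
        )
        oracle = _independent_yule_root_ages(64, 1.0, n_reps, np.random.default_rng(999))
        se = np.sqrt(sim_ages.var() / n_reps + oracle.var() / n_reps)
        assert abs(sim_ages.mean() - oracle.mean()) < 3 * se

    def test_seed_determinism_bit_identical_newick(self):
        a = simulate_chronogram(SimulationConfig(n_tips=20, seed=7))
        b = simulate_chronogram(SimulationConfig(n_tips=20, seed=7))
        assert trees.write_newick(a.tree) == trees.write_newick(b.tree)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_tips=1)
        with pytest.raises(ValueError):
            SimulationConfig(birth_rate=0.01, death_rate=0.02)


class TestRates:
    def test_zero_sd_gives_constant_rates(self):
        cfg = SimulationConfig(n_tips=16, rate_log_sd=0.0, seed=2)
        chrono = simulate_chronogram(cfg)
        rates = simulate_rates(chrono, cfg)
        assert all(r == cfg.root_rate for r in rates.values())

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_tips=16, rate_log_sd=0.3, seed=2)
        chrono = simulate_chronogram(cfg)
        r1 = simulate_rates(chrono, cfg)
        r2 = simulate_rates(chrono, cfg)
        assert list(r1.values()) == list(r2.values())

    def test_log_rate_step_mean_matches_drift(self):
        # E[log(child/parent)] = -sd^2/2 = -0.045 at sd = 0.3
        cfg = SimulationConfig(n_tips=5000, rate_log_sd=0.3, birth_rate=1.0, seed=4)
        chrono = simulate_chronogram(cfg)
        rates = simulate_rates(chrono, cfg)
        steps = []
        for node, r in rates.items():
            parent_rate = rates.get(node.parent_node, cfg.root_rate)
            steps.append(np.log(r / parent_rate))
        steps = np.asarray(steps)
        assert len(steps) >= 9000
        se = steps.std() / np.sqrt(len(steps))
        assert abs(steps.mean() - (-0.045)) < 3 * se


class TestPhylogram:
    def test_noiseless_length_is_rate_times_duration(self):
        cfg = SimulationConfig(n_tips=12, poisson_noise=False, seed=6)
        chrono = simulate_chronogram(cfg)
        rates = simulate_rates(chrono, cfg)
        phylo = chronogram_to_phylogram(chrono, rates, cfg)
        for orig, node in zip(
            chrono.tree.preorder_node_iter(), phylo.tree.preorder_node_iter()
        ):
            if orig.parent_node is None:
                continue
            expect = rates[orig] * (orig.parent_node.age - orig.age)
            assert node.edge.length == pytest.approx(expect, abs=1e-15)

    def test_noiseless_roundtrip_recovers_durations(self):
        cfg = SimulationConfig(n_tips=12, rate_log_sd=0.0, poisson_noise=False, seed=6)
        chrono = simulate_chronogram(cfg)
        rates = simulate_rates(chrono, cfg)
        phylo = chronogram_to_phylogram(chrono, rates, cfg)
        for orig, node in zip(
            chrono.tree.preorder_node_iter(), phylo.tree.preorder_node_iter()
        ):
            if orig.parent_node is not None:
                duration = orig.parent_node.age - orig.age
                assert node.edge.length / cfg.root_rate == pytest.approx(duration)

    def test_missing_rate_names_edge(self):
        cfg = SimulationConfig(n_tips=6, seed=1)
        chrono = simulate_chronogram(cfg)
        rates = simulate_rates(chrono, cfg)
        rates.pop(next(iter(rates)))
        with pytest.raises(KeyError):
            chronogram_to_phylogram(chrono, rates, cfg)

    def test_poisson_noise_mean(self):
        # an edge of expectation 0.02 (10 My at rate 0.002, 4,968 sites)
        chrono = simulate_chronogram(SimulationConfig(n_tips=2, birth_rate=1.0, seed=123))
        chrono.tree.seed_node.age = 10.0
        for leaf in chrono.tree.leaf_node_iter():
            leaf.age = 0.0
        rates = {n: 0.002 for n in chrono.tree.preorder_node_iter() if n.parent_node}
        draws = []
        for seed in range(1000):
            cfg = SimulationConfig(
                n_tips=2, birth_rate=1.0, root_rate=0.002, n_sites=4968,
                poisson_noise=True, seed=seed,
            )
            phylo = chronogram_to_phylogram(chrono, rates, cfg)
            draws.append(next(iter(phylo.tree.leaf_node_iter())).edge.length)
        draws = np.asarray(draws)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.02) < 3 * se

    def test_topology_preserved_across_pipeline(self):
        truth = simulate_truth(SimulationConfig(n_tips=25, seed=9), n_calibrations=5)
        keys = set(trees.bipartition_keys(truth.chronogram.tree))
        assert set(trees.bipartition_keys(truth.phylogram.tree)) == keys
        reps = make_bootstrap_phylograms(truth.phylogram, 3, seed=1)
        for rep in reps:
            assert set(trees.bipartition_keys(rep.tree)) == keys


class TestCalibrationSampling:
    def test_all_internal_nodes_calibratable(self):
        cfg = SimulationConfig(n_tips=10, seed=3)
        chrono = simulate_chronogram(cfg)
        cals = sample_calibrations(chrono, k=9, seed=1)
        assert len(cals) == 9
        assert len({c.taxa for c in cals}) == 9

    def test_width_is_constant_offset(self):
        chrono = simulate_chronogram(SimulationConfig(n_tips=10, seed=3))
        for cal in sample_calibrations(chrono, k=5, width=16.82, seed=2):
            assert cal.max_age - cal.min_age == pytest.approx(16.82)

    def test_windows_contain_truth(self):
        chrono = simulate_chronogram(SimulationConfig(n_tips=40, seed=8))
        ages = chrono.ages_by_clade()
        for cal in sample_calibrations(chrono, k=20, seed=5):
            truth_age = ages[frozenset(cal.taxa)]
            assert cal.min_age <= truth_age <= cal.max_age

    def test_deterministic_and_root_included(self):
        chrono = simulate_chronogram(SimulationConfig(n_tips=10, seed=3))
        a = sample_calibrations(chrono, k=4, seed=9)
        b = sample_calibrations(chrono, k=4, seed=9)
        assert [(c.clade_label, c.min_age) for c in a] == [(c.clade_label, c.min_age) for c in b]
        assert set(a[0].taxa) == set(trees.leaf_labels(chrono.tree))

    def test_k_too_large_rejected(self):
        chrono = simulate_chronogram(SimulationConfig(n_tips=5, seed=3))
        with pytest.raises(ValueError):
            sample_calibrations(chrono, k=5, seed=1)


class TestBootstrap:
    def test_replicate_count(self):
        truth = simulate_truth(SimulationConfig(n_tips=8, seed=2), n_calibrations=2)
        assert len(make_bootstrap_phylograms(truth.phylogram, 1000, seed=0)) == 1000

    def test_large_n_sites_limit_recovers_lengths(self):
        cfg = SimulationConfig(n_tips=10, n_sites=10**8, poisson_noise=False, seed=4)
        truth = simulate_truth(cfg, n_calibrations=2)
        rep = make_bootstrap_phylograms(truth.phylogram, 1, seed=1)[0]
        for orig, node in zip(
            truth.phylogram.tree.preorder_node_iter(), rep.tree.preorder_node_iter()
        ):
            if orig.parent_node is not None:
                assert node.edge.length == pytest.approx(orig.edge.length, abs=1e-3)

    def test_zero_lengths_stay_zero(self):
        truth = simulate_truth(SimulationConfig(n_tips=6, seed=2), n_calibrations=2)
        for node in truth.phylogram.tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 0.0
        rep = make_bootstrap_phylograms(truth.phylogram, 2, seed=3)[0]
        assert all(
            (n.edge.length or 0.0) == 0.0
            for n in rep.tree.preorder_node_iter()
            if n.parent_node
        )


def test_taxonomy_table_shape():
    tab = simulate_taxonomy(30, n_orders=3, seed=1)
    assert list(tab.columns) == ["species", "genus", "family", "order"]
    assert len(tab) == 30
    assert tab["species"].is_unique
    assert set(tab["order"]) == {"Order1", "Order2", "Order3"}
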