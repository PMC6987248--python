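import logging

import pytest

from chronopl import PLProblem, RootConstraint, date_tree
from chronopl.simulate import SimulationConfig, simulate_truth

logging.getLogger("chronopl").setLevel(logging.ERROR)

# smoothing at the synthetic scale: the penalty multiplies squared rate
# differences, so a useful lambda is ~(mean substitution count)/(rate)^2
LAM = 2e8


@pytest.fixture(scope="session")
def small_truth():
    """A 30-tip synthetic dataset with known ages, rates and calibrations."""
    cfg = SimulationConfig(n_tips=30, seed=42)
    return simulate_truth(cfg, n_calibrations=6)


@pytest.fixture(scope="session")
def small_fit(small_truth):
    rc = small_truth.calibrations[0]
    problem = PLProblem(
        small_truth.phylogram,
        small_truth.calibrations[1:],
        RootConstraint(rc.min_age, rc.max_age),
        smoothing=LAM,
    )
    return problem, date_tree(problem, n_starts=2, seed=0)
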