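"""Choose the smoothing parameter by subsampled cross-validation.

On clock-like data, heavier smoothing predicts pruned terminals better, so
the replicate mode should land on the largest grid values.  Each replicate
keeps 25% of the species, cross-validates the grid, and votes; the modal
value is the selected smoothing.
"""

from chronopl import RootConstraint
from chronopl.cv import smoothing_grid, subsampled_cv
from chronopl.simulate import SimulationConfig, simulate_truth

truth = simulate_truth(SimulationConfig(n_tips=80, rate_log_sd=0.0, seed=2), n_calibrations=6)
rc = truth.calibrations[0]
grid = smoothing_grid(1e10, 1e5, 0.1)
res = subsampled_cv(
    truth.phylogram, truth.calibrations[1:], RootConstraint(rc.min_age, rc.max_age),
    n_replicates=6, keep_fraction=0.25, grid=grid, seed=2, n_terminals=6,
)
for lam, prop in res.proportions.items():
    if prop:
        print(f"smoothing {lam:10.3g}: chosen by {prop:.0%} of replicates")
print(f"modal smoothing: {res.modal:g}")
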