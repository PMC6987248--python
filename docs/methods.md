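# Methods

## The model

`chronopl` estimates divergence times on a fixed rooted topology by
penalized likelihood.  The data are the edge lengths of a phylogram in
expected substitutions per site together with the alignment length
`n_sites`; each edge k is summarized by a substitution count
`x_k = round(length_k × n_sites)` modelled as Poisson with mean
`r_k · t_k · n_sites`, where `r_k` is the edge's substitution rate
(substitutions/site/My) and `t_k` its duration implied by the node ages.
Rate variation is smoothed by the autocorrelation penalty

    Φ(r) = Σ_{non-root edges} (r_k − r_parent(k))²  +  Var(root-child rates)

and ages and rates jointly minimize

    −Σ_k log Poisson(x_k ; r_k t_k n)  +  λ · Φ(r)

subject to hard minimum/maximum age windows on calibrated nodes, a hard
root window ([180, 220] My by default, the angiosperm-crown setting), and
parent-older-than-child ordering.  Zero-count edges contribute only their
mean to the objective; the `log x!` constant is kept so the likelihood
term is the exact Poisson log-pmf.

### The smoothing parameter λ

λ multiplies squared *raw-rate* differences, so it is dimensional: its
useful magnitude is of order (mean substitution count)/(rate scale)².  At
the synthetic defaults below (rates ~2×10⁻³/site/My, counts of tens to
hundreds) that is λ ≈ 10⁷–10⁹; on data expressed in relative time units
with rates of order one it is λ ≈ 1–10⁶.  Cross-validation grids should
therefore be placed at the scale of the data at hand; the classic
`smoothing_grid()` defaults (10 → 0.0001, step 0.9, 110 values) are kept
for config emission and for workflows whose inputs are pre-scaled.

### Optimization

Feasibility is guaranteed by construction.  Each internal node's age is a
height fraction `u ∈ [0,1]` interpolating between the node's *effective
minimum* (its own hard minimum joined with every descendant's, computed
once by a postorder pass) and the smaller of its parent's age and its own
hard maximum; an infeasible system (a descendant minimum above an
ancestor maximum) is detected at this stage and reported with the
offending node.  Rates are optimized in log space.  The objective and its
analytic gradient (chain rule through the height-fraction recursion) are
evaluated in O(edges); L-BFGS-B with `ftol 1e-14`, `gtol 1e-9` and a
fixed-seed multi-start (5 starts by default: one mid-window/empirical-rate
start plus seeded perturbations) makes fits deterministic for a given
seed.  Bootstrap-replicate fits warm-start from the point estimate and
use a looser `ftol 1e-9`.  A fully pinned system (min = max everywhere)
bypasses the age search exactly.

### A known, deliberate property: attraction to maximum bounds

The Poisson likelihood is exactly invariant under the joint rescaling
`r → r/c`, `t → c·t`, while Φ strictly decreases as rates shrink; the
optimum therefore slides along this flat ridge until calibration maxima
bind.  Calibrated nodes tend to sit near their hard maximum ages — a
recognized behaviour of penalized-likelihood dating under hard windows,
not an implementation artifact (the optimizer's solution has a far better
objective than the generating truth).  Consequences measured by the test
suite: node-age recovery error is dominated by the calibration-window
width (~half-window upward bias), and bootstrap confidence intervals —
which share the calibrations across replicates and only capture
count-resampling noise — undercover true ages (mean per-node coverage
~0.45 at the 30-dataset benchmark; the corresponding suite check is
expected to fail and documents this limitation rather than masking it).

## Cross-validation

*Terminal pruning* (`cv_score`, `run_cv`): a sampled terminal is pruned,
the reduced tree is re-dated at λ (calibrations that no longer identify
their node are dropped, not remapped — a window survives only if its
remaining taxa span ≥2 children of the originally calibrated node), and
the terminal's count is predicted as rate × attachment age × n_sites,
with the attachment point placed on the merged edge at the terminal's
original length fraction.  The default score is the chi-square flavour
`(obs − exp)²/exp` (squared error available).  Terminals attached to the
root, in polytomies, or whose pruning disconnects a calibration are
skipped and logged.  By default `min(tips, 50)` terminals are sampled per
evaluation.  `run_cv` builds each reduced problem once and warm-starts
along the grid.

*Subsampled replicates* (`subsampled_cv`): for trees too large to
cross-validate whole, 500 replicates (default) each keep a uniform 10% of
the species; each replicate runs the grid cross-validation and votes for
its best λ; the modal λ is selected, ties breaking toward the smaller
(less smoothing, conservative).  If a replicate's subtree root is not the
original root, the root window's minimum is not applied to it (only the
maximum remains valid for an interior node).

## The clock test

`clock_test` is a chi-square likelihood-ratio test comparing the
saturated per-edge Poisson fit (one mean per edge) against the
single-rate Langley–Fitch fit (one rate plus free ultrametric ages, the
root age pinned to remove the unidentifiable scale).  The degrees of
freedom are the identifiable-parameter difference, #edges − #internal
nodes (= #tips − 1 on a binary rooted tree); simulation under the clock
gives a rejection rate of ~0.06 at α = 0.05 at 5,000 sites, and strong
rate heterogeneity (per-edge log-sd 0.5) is rejected at p < 0.001
essentially always.

## Confidence intervals

Bootstrap pseudo-replicates redraw each edge count as
Poisson(length × n_sites) — a site-resampling surrogate on the fixed
topology, mirroring a workflow in which replicate trees share the
ML topology.  Each replicate is dated under identical calibrations and
λ; per-node age samples (matched by tip-set bipartition, so child-order
rotations are harmless) are summarized as equal-tailed empirical
quantiles with linear (type-7) interpolation.  Equal-tailed quantiles are
the default because bootstrap samples are frequentist; an HPD option
exists for comparison with posterior annotators.  Interval width is
non-decreasing in the level, and permuting replicates changes nothing.

## The synthetic-data generator

The generator emulates the study conditions at desk scale; defaults:

| parameter | default | rationale |
|---|---|---|
| `birth_rate` | 0.02 /lineage/My | crown ages ~200–250 My at 100 tips, matching the 180–220 My root window |
| `death_rate` | 0.005 /lineage/My | modest turnover (ε = 0.25) |
| `root_rate` | 2×10⁻³ subs/site/My | fast plastid (matK-like) marker scale |
| `rate_log_sd` | 0.2 | per-edge log-normal jitter; chosen for test power, not measured realism |
| `n_sites` | 4,968 | the two-marker supermatrix alignment length |
| calibration width | 16.82 My | the constant fossil min→max interval |

Trees come from a constant-rate birth–death process started at the crown
(two lineages) and cut at the first event after standing diversity
reaches `n_tips`; runs that go extinct first are retried (bounded at
1,000).  Rates follow geometric Brownian motion with drift −sd²/2 so the
expected rate is constant along paths — exactly the autocorrelation the
penalty smooths toward.  Calibration windows draw the minimum uniformly
below the true age and redraw until minimum + width covers the truth, so
every window contains the true age by construction.  The sequence
generator produces family-structured, stop-free coding sequences for the
QC stage only; it does not simulate alignments under a substitution
model, alignment error, or the database-mining process itself — so
passing QC tests demonstrate the decision rules, not performance on real
GenBank data.

## Sequence QC

The similarity screen is an offline surrogate for a megablast check:
candidates must share an exact `word_size`-mer (default 8) with the
record, at most `max_hits` (250) candidates are examined, edlib infix
alignments are scored (+1/−2) and converted to an E-value-like quantity
(Karlin–Altschul form; threshold 0.0005), and the verdict asks whether
the best hit's family matches the record's claimed family.  "Best
quality" is operationalized as the lowest ambiguity fraction — the only
quality signal recoverable from sequence text.  "Multiple ambiguities"
uses a configurable fraction threshold (default 0.01) with a literal
two-ambiguity guard for short sequences.  Conflicting duplicates (same
name, >5% p-distance) remove the species entirely.  The frame screen
translates with the plastid/bacterial genetic code (table 11), locating
the matK ORF by a stop-free scan; an internal stop, a collapsed ORF, or
translated identity to a same-family reference below 0.7 drops the
record.  The chain is conservative (kept + dropped = input), idempotent
and order-independent.

## Problem sizes used by the test suite

Oracle and arithmetic checks run on 6-tip to 12-tip instances; recovery
and calibration suites use 10–100 tips with 20–500 replicates (50
datasets for the heterogeneity benchmark, 500 simulations for the
clock-test calibration, 30 datasets × 100 bootstrap replicates for the
coverage benchmark, 20 replicates on a 200-tip tree for the reduced
subsampled-CV benchmark).  These sizes are the package's chosen
benchmark conditions and complete on a single CPU core.

## Known limitations

* The maximum-bound attraction and the resulting CI undercoverage
  described above.
* The bootstrap surrogate resamples branch counts, not alignment sites;
  it understates uncertainty relative to full re-estimation.
* The QC similarity screen is panel-based: it can only flag mislabels
  the reference panel can expose.
* The constraint builder leaves within-order family relationships fully
  unresolved by design; no branch lengths are emitted.
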