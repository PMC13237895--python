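# Methods

This note documents the model implemented by `lhsdrive`, the defaults it
ships, what the synthetic generators emulate, and the numerical and
design choices a maintainer should know about.

## Instrument scoring

Ratings are integers 0–4 over eight domains, three raters per project
and period. The scoring pipeline is **normalize → average over raters →
weight-sum**: `s = r/4`, `S_d = (s_A + s_H + s_C)/3`,
`CTI = Σ w_d S_d`. The arithmetic mean over the three raters is the
adopted aggregation; scoring is monotone in every rating and attains 0
and 1 exactly at all-0 and all-4 sheets.

Default weights (balanced drivetrain) are
D1 .16, D2 .10, D3 .12, D4 .10, D5 .16, D6 .12, D7 .12, D8 .12. The
equity-forward preset raises D8 to 0.20 and removes the 0.08 difference
from the D2–D4 pool proportionally (×0.75), giving
D2 .075, D3 .09, D4 .075; all other weights unchanged. Weights are fixed
per scoring run; per-period weight variation is deliberately not
supported.

Maturity bands are left-closed (`[0,.25) [.25,.50) [.50,.70) [.70,.85)`)
with the top band closed at 1.0, so the unit interval is partitioned
with no gaps or overlaps.

Inter-rater reliability is weighted Cohen's κ on the 5-category ordinal
scale, quadratic weights by default (conventional for ordinal rubrics),
linear selectable. κ is a 0/0 when both raters are constant; the package
raises `UndefinedStatisticError` rather than returning 0, and the
reliability report records such cells as NaN. "Major discrepancy" is
operationalized as any (project, domain) where the raw ratings spread
max − min ≥ 2; flagged domains are listed for consensus review, never
auto-resolved.

## Drivetrain

Transmission `T(M) = 1/(1+e^{−a(M−m0)})` and friction reduction
`R(M) = r_max M^η/(M^η+c^η)` are strictly increasing with the exact
identities `T(m0) = 1/2` and `R(c) = r_max/2`. The wheel drive
`f_j = v_max,j E_j T/(E_j T + F_j(1−R))` uses engine power `E` and
contextual friction `F` in arbitrary common resource units — only their
ratio matters — and lies strictly inside `(0, v_max,j)`.

The spillover matrix `K` has rows receiving and columns influencing, in
the fixed axis order (clinical, education, research, governance).
Coupled velocities solve the linear system `(I−K)v = f` (LU solve, not
explicit inversion; a truncated Neumann series serves as a test-only
oracle). Validity requires nonnegative entries, zero diagonal, and
spectral radius ρ(K) < 1; every consumer of a coupling matrix enforces
this. With K ≥ 0 and f ≥ 0, v ≥ f elementwise (amplification), strictly
where a directed positive-spillover path exists. One call is one
evaluation period; longitudinal sequencing is left to callers.

Four coupling entries are model constants taken from the framework's
published narrative: governance→clinical 0.18, governance→education
0.10, governance→research 0.10, clinical→research 0.12. The remaining
off-diagonal cells are free calibration choices of this package, each
kept ≤ 0.10 (see `data/default_config.yaml`), reflecting the qualitative
pattern that education and research produce modest, broadly distributed
spillovers.

## Efficiency indices and typology

`TEI-G = ‖v‖_W/‖f‖_W` with the weighted Euclidean norm
`‖x‖_W = √(Σ α_j x_j²)` by default; a weighted 1-norm is selectable
(`norm: l1`), under which TEI-G reduces to the ratio of weighted mean
velocities. The norm weights are taken equal to the mission weights α
(equal by default). `TEI-B = min_j v_j / Σ α_j v_j ∈ (0,1]`, equal to 1
iff all velocities coincide. `TEI = TEI-G × TEI-B`.

Typology over (TEI-G, TEI-B): Fragmented (low/low), Emerging (high
G/low B), Functional (low G/high B), Fully Integrated (high/high). Cuts
are either fixed values or cohort medians (`median-split`, the default
for cohort analyses); a value exactly at a cut classifies as "high".
Percentile scaling against 5th/95th anchors is affine and returns
out-of-range values unclamped with a flag, so extreme performance stays
visible.

Milestone attribution distributes each of eight canonical milestone
latencies over the four wheels through a row-stochastic 8×4 weight
matrix; row-stochasticity makes the attribution conserve total latency
exactly. The combining rule (weighted latency allocation) is the
minimal faithful reading of interpretation weights.

## Economics

`N_j = max(0, b0_j + b1_j v_j)` (expected counts, reported as reals so
correlations stay smooth), `R_j = ρ0 + ρ1 v_j + ρ2 N_j`,
`E_j = κ0 + κ1 v_j + κ_p·PDCA_p + κ_d·PDCA_d + κ_i·PDCA_i` with unit
PDCA intensities by default. These linear forms are the simplest ones
consistent with parameterized revenue/cost functions and a monotone
ROI–velocity relationship. Global ROI is the ratio of summed revenue to
summed expense; because that differs from the mean of per-unit ratios
for heterogeneous portfolios, the Monte Carlo summary emits both
(`global_roi` and `mean_roi`). ROI is scale-invariant under a common
rescaling of all dollar coefficients. Currency is abstract dollars, no
discounting.

## Simulation

Per project: `M ~ Beta(shape1, shape2)`; per wheel,
`E, F ~ LogNormal(log_mean, log_sd)`. Per Monte Carlo iteration: the
five transmission/friction constants are drawn from uniform ranges and
the coupling matrix is scaled by a stochastic factor; a draw whose
spectral radius would reach 1 is rescaled onto ρ = 0.95 and flagged
(stability enforcement, not rejection), so no iteration ever runs an
unstable coupling. Within an iteration the computation is deterministic
given the draws; variability across iterations reflects parameter
uncertainty, summarized by cross-iteration means, SDs, medians and
2.5th–97.5th percentile simulation intervals. With one iteration the SD
is reported as NaN and the intervals collapse to the point.

Randomness: one master seed spawns per-iteration child streams via
`numpy.random.SeedSequence`, keyed by iteration index, so results are
independent of execution order and byte-identical across runs.

**Default conditions.** The shipped configuration represents a
mid-maturity portfolio: CTI ~ Beta(3.1, 2.8) (mean ≈ 0.53, SD ≈ 0.19,
spanning all five maturity bands), unit-median log-normal resources with
log-SD 0.30 (moderate institutional heterogeneity), velocity ceilings
(1.33, 1.05, 1.34, 1.11) month⁻¹, hyperparameter ranges a ∈ [6, 14],
m0 ∈ [0.4, 0.6], r_max ∈ [0.4, 0.7], η ∈ [1.5, 3], c ∈ [0.35, 0.65],
coupling scale ∈ [0.7, 1.3], and economics scaled so that a ~25-project
organization turns over roughly $2.9M revenue against $1.4M expense per
period. These choices were calibrated once so that the default sweep
reproduces the reference operating neighbourhood of the framework —
mean CTI ≈ 0.52, mean cycle velocities ≈ 0.75/0.59/0.73/0.60 month⁻¹,
system weighted velocity ≈ 0.67, global ROI ≈ 2 — and then frozen; they
are calibration aids, not empirical estimates. Portfolio size defaults
to a rounded Normal(25, 3) per iteration (constant sizes, e.g. 1,000,
are configurable).

**What the generator does not emulate.** Projects are exchangeable and
cross-sectionally independent: no longitudinal CTI trajectories, no
within-organization correlation beyond shared iteration-level
hyperparameters, no missing ratings, no rater drift, and rater noise in
the fixture generator is symmetric. Passing tests therefore demonstrate
internal consistency and directional behaviour of the model, not
validity against any real institution's data.

## Statistical reporting

Pearson correlation matrices flag zero-variance variables as NaN rather
than 0. State comparisons report per-state n, median and
linearly-interpolated (25th, 75th) percentiles with a Kruskal–Wallis
test (standard tie correction, chi-square approximation — group sizes
in simulated cohorts are large). The global ROI model is an OLS fit of
ROI on CTI, TEI and the mission-weighted mean velocity, with adjusted
R² and per-predictor VIFs; perfectly collinear predictor sets are
rejected by name. The fitted CTI coefficient conditional on TEI and
Vmean can be negative even though the marginal CTI–ROI association is
strongly positive; this is a conditioning artifact (TEI and Vmean
mediate the CTI signal), not a causal claim. The regression runs on
project-level records by default; iteration-level granularity is
available by fitting on the per-iteration table.

## Problem sizes

The default test suite runs the full property checks (1,000 random
stable couplings for the Neumann cross-check, 500 parameter draws for
the transmission/friction identities) and a 100-iteration × 200-project
directional sweep; the acceptance script runs the full 500-iteration
default sweep (~12,500 project records). These sizes give stable
summary statistics while keeping a complete run in the tens of seconds
on one CPU.

## Known limitations

- The coupling is the static fixed point of the linear spillover
  system; there are no continuous-time dynamics and no feedback from
  outcomes to CTI within a run.
- Stage-sensitivity estimation (how individual milestone stages respond
  to CTI) and fitting the model to real institutional data are out of
  scope, as are dashboards and data-provenance integrations.
- Free coupling entries, economic coefficients and sampling
  distributions are calibration choices, not estimates; conclusions
  that depend on their exact values should be re-derived under
  user-supplied configurations.
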