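# Methods

## Population model

The model tracks five compartments — cancer stem cells (CSC), two
progenitor levels (PC1, PC2), terminal cells (TC) and dead cells (DC) — as
real-valued population sizes. Thirteen phenotypic parameters control it:
the symmetric-division probability `P_sy` (dimensionless, in [0, 1]),
proliferation rates `omega_CSC`, `omega_PC` (1/time), differentiation
rates `eta_1..eta_3` (1/time), de-differentiation `gamma_PC` (1/time),
death rates `delta_1..delta_3` (1/time), lysis `delta_4` (1/time), and the
feedback intensities `h_CSC`, `h_PC` (1/cells). The tumor bulk suppresses
both proliferation rates through `omega / (1 + h*N_TC)`, applied to every
occurrence of the rate. The system is autonomous; time enters the
right-hand-side contract only for solver compatibility.

A PC1 division is modeled as symmetric-differentiative: one PC1 leaves its
compartment (`-W_P*N_PC1`) and two PC2 cells appear (`+2*W_P*N_PC1`), the
reading consistent with the loss term in the PC1 balance. Both PC levels
die at the common progenitor death rate `delta_2`, and all death fluxes
accumulate in DC, giving exact mass balance when lysis and proliferation
are switched off (a unit test asserts this).

### Analytic structure

The origin `E0` is always an equilibrium. For `gamma_PC = 0` its leading
eigenvalue is `P_sy*omega_CSC - eta_1 - delta_1`, so `E0` destabilizes at
the invasion boundary `P* = (eta_1 + delta_1)/omega_CSC`, where a positive
branch `E1` exchanges stability with it (transcritical). With
`gamma_PC > 0` the CSC and PC1 compartments couple at the origin and the
true threshold drops below the closed form (progenitor de-differentiation
rescues a sub-critical stem-cell pool); `invasion_threshold` therefore
attaches a warning whenever `gamma_PC > 0` and the numerical scan is the
authority for the exact crossing. At the shipped baselines the closed form
gives 0.025 and the exact crossing is 0.0142.

For some admissible parameter sets the positive branch also loses
stability at large `P_sy` through a Hopf point, leaving a limit cycle as
the attractor. The branch scan therefore seeds the nontrivial branch just
above the detected destabilization of `E0` — where the new branch is born
as the attractor — and continues it outward in both directions.

## Baseline calibration

The original baseline table for this model lives in supplementary material
that is not reproduced here, so the shipped defaults are the package's own
calibration. They were chosen, once, to satisfy every constraint stated
with the model: `(eta_1 + delta_1)/omega_CSC = 0.025` exactly
(eta_1 = 0.015, delta_1 = 0.01, omega_CSC = 1); an initial state of 1e5
cells mimicking a subcutaneous injection, with TC the largest and CSC the
smallest subpopulation (100 / 2000 / 7900 / 80000 / 10000); relaxation to
equilibrium within the standard 200-time-unit horizon; a dominant
sensitivity of every output to `P_sy` (median |PRCC| 0.94–0.98 at
n = 1000) with `omega_CSC` around 0.8; and a no-growth-to-growth switch in
`P_sy` that is monotone across the four partition levels with every
top-level sample growing. Terminal-cell turnover `delta_3 = 0.1` and lysis
`delta_4 = 0.3` make the initial bulk's imprint wash out within the first
quarter of the horizon — with much slower clearance the early TC/DC
variation is dominated by the sampled decay rates acting on the shared
initial state, which no proliferation parameter can influence at early
times. The feedback `h = 1e-3` per cell places the positive equilibrium in
the 1e4–1e6-cell range.

These defaults are a documented choice, not ground truth; `CSCParameters`
says so in its docstring, and the shipped `population.yaml` carries the
same values.

## Sampling

Latin hypercube designs stratify each parameter into `n` equal-probability
subintervals sampled exactly once, position uniform inside each stratum,
with the stratum order permuted independently per column. One master seed
spawns per-column substreams (`numpy` `SeedSequence`), so adding a
parameter leaves the other columns' draws unchanged, and identical
(specs, n, seed) reproduce the design bit-for-bit. Uniform intervals come
from explicit bounds or `baseline*(1 ± v/100)`; normal columns stratify by
inverse CDF with `sd` given explicitly or as `baseline*v/100`, truncated
only when explicit bounds are also present. A negative resolved lower
bound on a parameter flagged non-negative is clipped at zero and logged.
Whether out-of-domain draws should instead be re-sampled is not specified
by the methodology; clipping is this package's documented choice.

## Integration

`scipy.integrate.solve_ivp` with LSODA, `rtol = 1e-8`, `atol = 1e-10` by
default (configurable); the analytic Jacobian is supplied for the
population model. Integration failures — step-size collapse, divergence,
state overflow beyond 1e15 — are data, not crashes: each ensemble row
carries a success flag plus a reason, downstream statistics use the
surviving rows listwise, and more than 50 % failures aborts with advice to
review tolerances and ranges.

## PRCC

All columns are rank-transformed (ties averaged). For parameter `j`, the
ranks of `x_j` and of the output are residualized on the ranks of the
other `k−1` parameters plus an intercept via QR least squares, and the
PRCC is the Pearson correlation of the residuals. A cross-check against
the Spearman-correlation-matrix inverse is part of the test suite.
Significance uses `t = r*sqrt((n−2−p)/(1−r²))` with `p = k−1` conditioning
variables and `n−2−p` degrees of freedom, two-sided, `alpha = 0.01` by
default and no multiple-testing correction (optional Bonferroni in the
config); the per-time critical magnitude `t_crit/sqrt(t_crit²+dof)` bounds
the shaded non-significance band in the plots. Outputs that are constant
across samples at a time point (the shared initial state at t = 0) yield
NaN markers there, not errors. All grid times are analyzed by default; a
stride option subsamples.

## Levels and figures

`partition_range` cuts a range into `r` equal-width intervals, first
closed on both ends, the rest left-open right-closed, so every in-range
value maps to exactly one level and boundary values belong to the lower
level. Internal boundaries keep full float precision; legends print them
rounded half-up to two decimals (published tables of such partitions
truncate instead, so a boundary of exactly x.xx5 can print one unit
higher here). Colors default to black/blue/red/green for `r = 4`, a
resampled viridis palette otherwise. Derived combinations over design
columns accept identifiers, numbers, `+ - *` and parentheses only.
Figures carry JSON sidecars (partition bounds, per-level counts, clipped
point counts) so their content is machine-checkable; on log axes,
non-positive values are clipped to a configurable floor (default 1e-3
cells) and counted.

## Bifurcation scan

Equilibria come from damped Newton on the analytic (or finite-difference)
Jacobian, residual tolerance 1e-10 relative to the state scale, with a
deterministic nudge off saddle points of the residual norm where the
Newton step degenerates. The one-parameter scan polishes the trivial
branch at every grid value, seeds the nontrivial branch by integrating the
default initial state in chunks until near-stationary, and continues both
branches with a secant predictor (which follows a branch through a
transcritical crossing onto its unstable side instead of collapsing onto
the intersecting branch). Sign changes of the trivial branch's leading
eigenvalue are refined by bisection to 1e-6 in the parameter; the
stability exchange is verified on the nearest points where the two
branches are numerically distinct, since coincident points carry no
information. Grid-scan plus bisection was chosen over pseudo-arclength
continuation deliberately: for one-parameter transcritical structure it is
sufficient and far easier to validate. Leading real parts within 1e-9 of
zero are labeled marginal rather than forced into either class.

## What the tests show — and what they do not

The synthetic experiments reproduce the published study conditions:
n = 1000 samples, ±50 % uniform variation (the symmetric-division
probability on its full [0, 1] range), 200 output times on [0, 200],
r = 4 levels, alpha = 0.01; the switching experiment is scaled to n = 200
as specified for it, and the transcritical consistency check uses 20
random de-differentiation-free parameter sets on a 41-point scan. A run is
classified "no growth" when its final stem-cell count falls below the
initial inoculum (100 cells); with the invasion boundary pinned at 0.025,
asymptotic extinction is confined to the lowest partition level, so the
published level-wise switching picture is asserted in its monotone form
(fractions strictly decreasing from level 1, zero in the top level, every
top-level sample on the positive branch). All inputs are generated by the
package's own sampler and fixture models; nothing here validates the
biology of the rate values themselves, measurement noise, or stochastic
demographic effects — passing tests show the workflow's statistics and
numerics are correct on models with known structure, not that the CSC
model describes any particular tumor.

## Known limitations

- The closed-form invasion boundary ignores `gamma_PC`; the scan is the
  authority when de-differentiation is active.
- Limit cycles are detected only indirectly (a stable branch turning
  unstable); there is no Hopf normal-form analysis or cycle continuation.
- Sampling is independent per parameter; correlated designs and
  variance-based indices (Sobol, eFAST) are out of scope.
- The level partition is uniform; adaptive partitions are not implemented.
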