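# Methods

## Scope

`crownforge` models individual-tree crown width (CW, m) in a stem-mapped,
multi-species secondary stand as a function of stem diameter at breast
height (D, cm), tree height (TH, m), height to crown base (HCB, m) and a
plot-level competition index (CI), with tree species as a random effect.
The package covers the whole chain: stand ingestion and plot gridding,
competition indices with spatial edge correction, candidate allometric
model selection, covariate-generalized models, nonlinear mixed-effects
estimation with residual variance functions, model evaluation, and a
synthetic stand generator used for end-to-end and parameter-recovery
testing.

## Stand model and plot covariates

A stand is a 120 x 140 m rectangle (configurable) in local Cartesian
meters, gridded into 20 x 20 m plots: half-open cells `[k*20, (k+1)*20)`
with the outermost row/column closed, so every tree falls in exactly one
of the 42 cells. Trees below the 1 cm DBH marking threshold are invalid
input; trees with 1 <= DBH < 5 cm are saplings, DBH >= 5 cm adults.
Species are collapsed to six groups (the five most numerous species plus
"Others"); the name-to-group table is configuration.

Plot covariates: density DEN = count / 0.04 ha; MTH the mean height; MDH
and MDD the mean height and diameter of the *dominant* trees; SHN the
Shannon diversity (natural log) of species-group stem proportions.
"Dominant" has no universal field definition; the package's default is
the 4 largest-DBH trees per 20 x 20 m plot (the 100 stems/ha convention),
ties broken by tree id, configurable via `DominantRule`.

The calibration/validation split is a seeded random partition of
non-empty plots (80/20 by default, `round(fraction * n_plots)` to
calibration); trees of one plot are never separated, and the seed is
recorded in every derived artifact.

## Competition indices

Distance-independent, per plot: SD (sum of DBH), SDD (sum of dominant
DBH), SRD (sum of DBH / MDD), SBA (sum of basal area, m^2). Distance-
dependent indices sum the Hegyi index of every subject tree of the plot,

    HG_i = sum_j D_j / (D_i * (L_ij + 1)),

with D in cm and the inter-tree distance L in m; the +1 m offset keeps
the term finite for coincident stems. Competitors are either all trees
within a 5 m radius (SHGR; the boundary is closed, distance = 5 m counts)
or exactly four trees, the nearest within each Cartesian quadrant around
the subject, quadrants half-open in angle (SHGN). An empty quadrant is
filled by the overall next-nearest unused tree so the competitor count
stays four; all distance ties break deterministically by tree id.
Subjects are always original-plot trees; competitors may come from
anywhere in the stand or from its translated images.

Edge correction is by translation: conceptually the stand is tiled with
8 shifted copies of itself. The implementation uses the equivalent
minimum-image (torus) distance, which is exact whenever the search radius
is below half the smaller stand dimension (5 m << 60 m); the explicit
3 x 3 tiling is retained as a selectable mode and serves as the oracle in
the test suite, where both paths are required to agree to 1e-10 for every
subject tree of a full-size stand.

## Crown-width model forms

Twelve classical CW-D shapes (linear, power, monomolecular, Hossfeld,
compound/growth/exponential — three parameterizations of the same curve —
quadratic, Richards, two logistics, Weibull) are fitted by nonlinear
least squares with analytic parameter gradients and documented
self-starting rules (log-log regression for the power form, linear
algebra for the linear/quadratic forms, logit/monomolecular
linearizations for the saturating forms). The linear forms are solved
exactly by ordinary least squares. Non-convergence is a reported state,
never an exception; ranking tables always carry all twelve rows, ordered
by calibration AIC with non-converged forms last.

The generalized form multiplies the power law by a linear covariate
bracket:

    CW = (phi1 + phi3*CI + phi4*TH + phi5*HCB) * D^phi2 + eps,

with CI either SRD (spatially non-explicit) or SHGN (spatially explicit)
— two separate models, selected by `ci_kind`, not a ratio. The covariate
slopes keep the sign the data give them (competition slopes come out
negative: more crowding, narrower crowns).

## Mixed-effects estimation

Species group i contributes a random vector b_i ~ N(0, psi) added to a
chosen subset of the parameters (for the generalized form, any of the 31
non-empty subsets of {phi1..phi5}); residuals are independent
N(0, sigma^2 * lambda(D)) with lambda one of: constant, power D^delta,
exponential exp(delta*D), or constant-plus-power (c + D^delta)^2 (the
same convention as R nlme's varConstPower).

Estimation alternates two steps:

1. **Penalized nonlinear least squares** — with variance parameters
   fixed, (beta, b_1..b_m) jointly minimize
   `sum (y - f)^2 / lambda + sigma^2 sum b_i' psi^-1 b_i`
   (Levenberg-Marquardt-type trust region with analytic Jacobians).
2. **Linearized maximum likelihood** — the model is linearized about the
   current estimates and the resulting linear mixed model's ML criterion
   is maximized over the relative covariance psi/sigma^2 (log-Cholesky
   parameterized, guaranteeing positive semi-definiteness) and the
   variance-function parameters, with beta and sigma^2 profiled out
   analytically. Likelihood and its analytic gradient use the Woodbury
   identity, so only q x q factorizations occur per group.

The objective is plain maximum likelihood, not REML, so AIC values are
comparable across fixed-effects specifications; `p` in AIC counts every
estimated quantity (fixed effects, distinct psi entries, sigma^2,
variance-function parameters). Convergence is declared when the relative
log-likelihood change falls below 1e-6 (at most 200 outer iterations); a
sustained plateau (three iterations improving by less than `stall_tol`)
is also treated as converged because the inner optimizations stop at
finite precision. BLUPs are the posterior modes of the group effects from
the final penalized step; predictions run in population mode (random
effects zero) or group mode (BLUPs added, with a logged fallback to
population for species unseen in fitting).

Numerical safeguards: the profiled-ML surface in (psi, delta) can carry a
spurious basin at very large psi when the initial linearization is crude;
the first linearized step therefore restarts the optimizer once from a
near-zero covariance with a moment-matched variance exponent (a
log-residual regression on log D) and keeps the better optimum. A
singular relative-covariance factor is ridge-stabilized and flagged. The
engine was cross-checked against an independent reference implementation
(R `nlme`, ML, power variance): fixed effects agree to four decimals on
study-scale synthetic data, and one test in the suite repeats a smaller
version of that comparison.

The exhaustive structure search fits all subset-by-variance-kind
combinations, skips non-converged fits, and returns the minimum-AIC
model plus the full report. The search uses a lighter convergence control
(40 outer iterations, plateau tolerance 0.05) because over-parameterized
structures crawl along a flat likelihood; the sacrificed fraction of a
log-likelihood unit is far below the AIC gaps that decide the selection.

## Evaluation

Fit statistics: AIC = -2 ln L + 2p; adjusted
R_a^2 = 1 - (n-1)/(n-p-1) * RSS/TSS; RMSE; MAE; MAPE as a fraction (no
x100), undefined when an observed value is zero. The n > p + 1 guard is
waived for p = 0 so pure error summaries work on any sample. Standardized
residuals divide by the modeled standard deviation
(sigma * sqrt(lambda(D)) for variance-function models). Crown-width
curves trace predictions over a DBH grid at six levels of one covariate
(defaults: CI in {10..210}, TH in {1..26}, HCB in {0..25}; held values
TH = 25, CI = 45, HCB = 4). The cross-index regression is ordinary least
squares of SHGN on SRD across plots — the empirical basis for replacing
the spatially explicit index by the distance-free one.

Validation-set statistics default to population-mode predictions from the
calibration-fitted model; group-mode (BLUP) prediction is available
explicitly.

## Synthetic stand generator

The generator emulates a dense, young, six-species secondary stand on
120 x 140 m with ~2,800 stems:

* **Positions** — parent-offspring cluster process by default (40
  parents, 10 m Gaussian dispersal, torus-wrapped). This reproduces the
  strong between-plot density variation of such stands (per-plot DEN sd
  ~ 810 stems/ha around a ~1,700 mean); it is what gives the plot-level
  competition indices realistic spread and makes the SRD-SHGN regression
  informative (r^2 ~ 0.9). A homogeneous Poisson option exists but makes
  every plot statistically identical. The clustering also stresses the
  edge correction.
* **DBH** — lognormal(mu = 1.714, sigma = 0.531) truncated to
  [1, 46.3] cm, moment-matched to a 6.39 cm mean and 3.65 cm SD.
* **Height** — TH = 2.60 * D^0.56 + N(0, 1.2), clipped to [1.5, 21.3] m
  (target mean 7.36 m).
* **Crown base** — HCB = fraction * TH with fraction ~ Beta(2.77, 3.13),
  which guarantees 0 < HCB < TH (target mean 3.46 m).
* **Crown width** — the generalized-form mean with species effects
  (u2, u5) ~ N(0, psi) on the exponent and crown-base slope,
  psi = [[0.002, -0.001], [-0.001, 0.0005]] (note: exactly singular,
  correlation -1; a 1e-15 ridge precedes the Cholesky draw), plus
  heteroscedastic noise N(0, 0.713 * D^-2.722), floored at 0.1 m.
  Fixed effects default to (1.41, 0.410, -0.003, 0.057, -0.022) with
  CI = SHGN; the intercept was moment-matched so mean generated CW lands
  at ~2.64 m under this generator's own SHGN distribution, which runs
  higher than field-measured competition sums at the same density.

Two deliberate departures from a literal field stand: CW is generated
directly rather than as the mean of two perpendicular crown diameters,
and the drawn species effects are **centered to zero sample mean** across
the six groups (configurable). With only six groups, the fixed effect of
a random parameter is otherwise confounded with the sample mean of six
Gaussian draws — an irreducible error of ~40% of phi5's magnitude that no
estimator can remove (verified against R nlme, which lands on the same
shifted estimates) — so centering is what makes fixed-effect recovery a
meaningful benchmark. Consequently, passing recovery tests demonstrate
estimation quality *given identifiable effects*, not robustness to
group-mean sampling noise; with real data and few groups, fixed effects
of random parameters carry that extra uncertainty.

The generator does not emulate: measurement error in coordinates or
dimensions, interspecific differences in the D-TH-HCB allometries,
spatial autocorrelation of tree size, or temporal dynamics.

## Problem sizes and tolerances in the test suite

The suite exercises full-size stands (2,800 trees) for the edge-
correction equivalence, 50-tree stands (100 seeds) for the brute-force
Hegyi oracle, and 20 replicates of n = 2,000 six-species stands for
parameter recovery and structure selection (median absolute relative
fixed-effect error <= 10%; true-subset superset selected in >= 80% of
replicates). Exact identities are asserted at 1e-10, noise-free NLS
recovery at 1e-6, the degenerate psi = 0 mixed-vs-pooled equivalence at
1e-4 (homoscedastic noise, constant variance kind, since pooled NLS is
unweighted).

## Known limitations

* Species is the only grouping level; plot-level or nested random
  effects are out of scope.
* The linearized-ML AIC is comparable within this package but may differ
  from other software by a parameter-counting constant; structure
  selection is invariant to that.
* psi is weakly identified with six groups (its diagonal is typically
  recovered only within tens of percent); fixed effects and the variance
  exponent are the well-identified quantities.
* MAPE is dominated by small crowns and is reported as a fraction.
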