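# Methods

## The simulated uniformity trial

A uniformity trial observes a response on every cart of a zone with no
treatments applied; overlaying dummy treatments on such data is the
standard way to compare candidate designs on realistic background
variation.  The generator emulates the final-day total projected shoot
area (thousand pixels) of single wheat plants on a conveyor zone of 3
lanes x 24 positions.

Cell expectation:

    mu(l, p) = [ m_z + beta_pos (p - p_bar) + a_l ] * s_l

where `m_z` is the zone mean, `beta_pos` the linear position-trend slope
on centered scores (so `m_z` is the prediction at the centre of a lane),
`a_l` an additive lane effect, and `s_l = shade_penalty` for shaded lanes
(1 otherwise).  Noise is Gaussian with per-zone standard deviation and,
optionally, stationary AR1 correlation along positions within a lane
(variance held at the nominal value; lag-k correlation rho^k).

Defaults and why:

| parameter | default | units | rationale |
|---|---|---|---|
| zone_mean | 71.62 | thousand pixels | typical final-day bench-zone mean |
| zone_sd | 20.2 | thousand pixels | back-computed from a 28.2% CV at that mean |
| pos_slope | 0.5 | per position step | an 11.5-unit west->east span over a lane; keeps the expected whole-zone CV near 28.6%, inside the observed 20-30% band.  No published magnitude exists for this slope; this is a calibration choice made once |
| lane_effects | 0 | thousand pixels | bands of 3 adjacent lanes are homogeneous in practice |
| shade_penalty | 1 (0.85 in shaded scenarios) | — | shading reduces growth roughly proportionally; 0.85 reproduces the observed depression of shaded-zone means |
| ar1_rho | 0 | — | local spatial correlation is weak at best in this setting; available for sensitivity studies |

Distributional form is the package's own choice: the mixed-model analysis
assumes Gaussian residuals, so the generator uses them too.  What the
generator does *not* emulate: multivariate responses (height, density),
the greenhouse pre-phase and its covariate relationship with the final
response, curvilinear (spline-shaped) trends, and time-varying microclimate.
Passing tests therefore demonstrate correctness of the framework's
machinery under the stated variance structure, not robustness of any
design recommendation to features outside it.

## Relocation tactics

Seventy-two plants start in a band of 3 lanes x 24 positions and are
imaged at 14 uniformly spaced time points (the real Monday/Wednesday/Friday
calendar is not modelled).  `half_lane` advances each plant one half-lane
slot per move through the 16-slot cycle over lanes 4-11: west half -> east
half of the same lane (p -> p+12), east half -> west half of the next lane
(p -> p-12), wrapping from lane 11 east to lane 4 west as intact groups of
12.  The per-cart mapping within a half is order-preserving, which is the
natural reading of a belt moving intact groups.  `next_lane` advances one
whole lane per move through lanes 12-24, position unchanged.

Exposure counts are tallied over the 14 occupancy time points.  Growth
increments accrue over the 13 intervals *between* imagings, using the cell
occupied at the interval start: over a 13-lane cycle this makes every
next-lane plant accumulate each lane's microclimate exactly once, so a
pure lane trend is nullified exactly — the mechanism by which whole-lane
relocation equalizes north-south exposure, and the reason shade exposure
equals the number of shaded lanes for every plant.  Half-lane relocation,
by contrast, preserves within-group east-west order, so plants are *not*
equalized with respect to a position trend even though each spends 7 of 14
time points in each half; its residual inequality survives in the
deterministic simulation.

Growth is multiplicative on the log scale: each interval adds
`rate * m(cell)` to log-area, where `m(cell)` is the cell expectation
divided by the surface mean, plus optional Gaussian log-noise.  This is the
simplest mechanism that produces tactic-specific divergence of growth
curves while staying positive.

## Designs and optimizers

All generators are seeded and record provenance.  Replicates of resolved
designs are side-by-side vertical slices of the layout (e.g. two 3x12 or
three 3x8 slices of the 3x24 zone).

Incomplete-block and row-column designs are built by a first-improvement
interchange scan (20 000 swap proposals by default, a handful of restarts)
on cheap balance objectives: the sum of squared pairwise treatment
concurrences across blocks, and the sum of squared treatment-by-row and
treatment-by-column occurrence counts.  These standard surrogates for
direct A-optimization are verified against brute-force enumeration on all
instances small enough to enumerate (see the test suite).  Trend-free
construction minimizes Q, the sum over treatments of squared totals of
centered linear position scores; scores are centered per block when blocks
are present (supporting the equal-slopes-between-blocks analysis), else on
the whole layout.  Q = 0 is declared trend-free, anything else nearly
trend-free.  Swaps update Q in O(1), so regeneration inside the
Monte-Carlo loop is cheap.

Restricted randomization of optimized designs applies exactly the moves
that preserve their structure: whole-layout position reversal with
probability 1/2, a random lane permutation, and permutation of block
contents among congruent block slots (within replicates, or across them
when blocks coincide with replicates).  All three preserve Q.  CRDs and
complete-block designs are simply re-randomized within their structure,
and trend-free designs may instead be regenerated by a fresh optimizer run,
which varies the design beyond label swapping.

## Mixed-model fitting

The model is y ~ N(X beta, sigma2_e (I + sum_k gamma_k Z_k Z_k')) with
variance ratios gamma_k >= 0.  The REML log-likelihood is profiled over
beta and sigma2_e and maximized over gamma by L-BFGS-B under nonnegativity
bounds (tolerance 1e-8 on the log-likelihood, 200 iterations), from
several starts.  The closed-form balanced-ANOVA solution (expected mean
squares computed from sequential orthogonal projections) is evaluated as
an additional candidate; on balanced data it is the exact REML optimum and
therefore wins on likelihood, which is why the package reproduces
hand-computed ANOVA estimators to machine precision there, including the
truncation-at-zero cases.  A single residual variance is fitted per
dataset (heterogeneous zone variances exist only in the generator), and
no AR1 residual or spline terms are fitted.

Treatments are coded one-hot, so the GLS covariance block for treatments
is directly the prediction-variance matrix; with random block terms the
predictions combine intra- and inter-block information.  Blocks are random
in incomplete-block and row-column analyses and fixed in complete-block
analyses (equivalent there by orthogonality).  Error degrees of freedom
are the containment-type residual df, N - rank([X Z]).  Kenward-Roger
adjustments are deliberately not implemented: the criteria compared here
are ratios in which df enter only through the F-quantile factor, and the
containment df is exact for the orthogonal designs (e.g. d = 36 for the
CRD with v = 36, r = 2; d = 35 for the RCBD).  For non-orthogonal fits it
is an approximation, and reported as such.

REML likelihood-ratio tests for a variance component use
max(0, 2 * delta-loglik) against chi2_1, with the p-value halved when the
component is constrained nonnegative (the 50:50 chi2_0/chi2_1 boundary
mixture); a zero statistic gives p = 0.5.

## Efficiency criteria

Relative precision of a blocking arrangement is 100 x (sample variance of
all observations) / (REML residual variance under the arrangement).  The
no-blocking error variance is by definition the plain sample variance
(n - 1 divisor) of the zone's 72 observations.

AP = F(1, d; 1 - alpha) x (mean variance of all pairwise treatment
prediction differences), alpha = 0.05.  RE_PDA = 100 x AP_CRD / AP_PDA.
AP_CRD always uses the closed form 2 s^2 / r with d = N - v.  The exact
RCBD value uses the randomization expectation of the error mean square:
within each block the treatment labels are exchangeable under
randomization, so the treatment and error lines of the within-block
stratum have equal expected mean squares, and E[MS_error] equals the
pooled within-block mean square of the null analysis; hence
AP_RCBD = F(1, (v-1)(b-1); 0.95) * 2 MS_within / r.

Monte-Carlo AP re-randomizes (or regenerates) the design each draw,
refits the mixed model — variance components re-estimated every time, as
each randomization is a genuine reanalysis — and averages the mean
pairwise-difference variance and the error df over draws.  One root seed
spawns independent per-iteration substreams, so results are reproducible
and order-independent.  Non-converged fits are dropped and counted; more
than 1% failures aborts the run.  Reference sample sizes are 5000
randomizations (1000 for trend-free designs); the bundled tests and the
default CLI run use a few hundred, which this package's own timing
experiments show is ample for MC standard errors below one RE percentage
point on 72-cart zones.

## Numerical and design choices

- Coordinates are 1-based, lanes south->north, positions west->east.
- Interchange optimizers accept the first strictly improving swap in a
  seeded random scan; ties are never accepted, so Q and the balance
  objectives are non-increasing and runs are reproducible.
- Degenerate inputs: constant data yields all-zero components (no
  optimizer call); a zero residual variance in relative precision is
  flagged as infinite precision; groups with zero mean get an undefined CV
  flag rather than being dropped; over-parameterized fixed structures and
  per-block-slope models without at least two blocks raise an
  inestimability error.
- Unequal per-block trend slopes are estimable only with >= 2 blocks
  (three for the 3x8 nearly-trend-free menu entries); the
  equal-slopes analysis is the default for two-block trend-free designs.

## Limitations

- The containment df understates the effective df of non-orthogonal
  mixed analyses relative to Kenward-Roger style adjustments; RE values
  for the incomplete-block entries are correspondingly conservative.
- The interchange optimizers guarantee optimality only where brute force
  confirms it (tiny instances); on the 72-cart menu they deliver designs
  with the required structural properties and Q = 0 where attainable, but
  not certified global optima.
- Simulated designs' RE values describe the generator's variance
  structure; they are not predictions for any particular greenhouse
  without recalibrating the generator to local uniformity data.
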