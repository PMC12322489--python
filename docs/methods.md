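# Methods

`cpforage` implements the analysis chain used to study bimodal central-place
foraging in chick-rearing colonial seabirds: GPS tracks are segmented into
foraging trips, per-individual maximum foraging ranges are tested for
bimodality, body-condition metrics are linked to foraging decisions through
Bayesian random-intercept models, and a zooplankton dry-biomass index
summarises prey availability. A synthetic-study generator reproduces the
statistical structure the analysis assumes, so every stage is testable
without field data.

## Trip segmentation

Fixes are greedily subsampled to a standard cadence (default 10 min: keep the
first fix, then every fix at least the interval after the last kept one; no
interpolation). A foraging trip is a maximal run of consecutive fixes farther
than 0.2 km (haversine, sphere radius 6371.0 km) from the colony, qualifying
when the elapsed time from its first to its last above-threshold fix is at
least 50 min. Elapsed time, not fix count, is used so the rule is robust to
the raw 2–10-min cadence. Colony-attendance fixes are not part of trips. A
trip is complete when the fix immediately after the run is back within
0.2 km of the colony; otherwise the track was truncated mid-trip (battery
failure).

Two filters follow. Trips with strictly more than 50% of fixes inside a land
polygon are discarded (non-foraging excursions: bathing, nest-material
collection). Truncated trips are retained only when the final fix lies
within 25% of the trip's maximum range from the colony, i.e. the bird had
covered at least 75% of the return leg. The alternative reading of that
rule — cumulative path length at least 75% of twice the maximum range — is
not used; the final-fix reading matches "returned towards the colony" and is
monotone in how much of the return was observed.

Inside/outside-fjord classification is binary: a trip is `outside` iff at
least one fix falls strictly outside the fjord ring; fixes exactly on the
ring count as inside, since remaining within the boundary is the reference
behaviour. Polygon membership is evaluated in the raw lon/lat plane, which
is exact for the synthetic rectangular geometry and an acceptable
approximation for study-scale polygons; real coastlines would warrant a
projected CRS.

For the bimodality analysis, one value per individual and year is used: the
maximum range over all retained trips of the bird's first deployment that
year (repeat deployments would pseudo-replicate individuals).

## Dip statistic and mode locations

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and the class of unimodal CDFs (convex below the mode, concave above it,
an atom allowed at the mode). The implementation works on the staircase
geometry directly. A fast pass computes, per candidate mode placement, the
greatest-convex-minorant / least-concave-majorant deviations of the two
branches, which gives a lower bound on the dip. That bound ignores how the
branches join at the mode: when the mode sits in a gap between data values,
the convex branch must leave its last point no flatter than its final
internal slope, and the concave branch must be entered no flatter than its
first internal slope, all while staying inside the tube. An exact
feasibility sweep — propagating the convex region of achievable (end slope,
end value) states of each branch and testing the join in closed form —
verifies the bound, and bisection finds the exact dip when the join binds.
The result matches a brute-force linear-programming minimiser over
piecewise-linear unimodal CDFs to 1e-9 (tests/oracles.py); the join
conditions matter, e.g. two well-separated tight clusters of distinct values
have dip near 0.25, not the per-branch bound.

p-values are Monte-Carlo: the null table holds dips of `n_null` (default
10 000) Uniform(0,1) samples of the same size, and
p = (1 + #{D* >= D}) / (n_null + 1). Tables are cached per (n, n_null,
seed), so resampling procedures at a fixed sample size are cheap. The
uniform null is the classical calibration for the dip test; the rejection
rate at alpha = 0.05 measures 0.048 over 2000 replicates at n = 20.

Mode locations use the critical bandwidth: the smallest Gaussian-KDE
bandwidth (bisection to 1e-3) at which the density on a 512-point grid over
0–200 km has at most k modes. The window avoids spurious modes in the long
right tail of range distributions, and grid endpoints never count as modes.
The mode count k is tied to the dip decision (k = 2 if the dip p-value is
below 0.05, else k = 1); the linkage between the two procedures is a design
choice — the source analyses report one mode for non-significant years and
two otherwise without stating a rule.

The one-trip-per-individual resampling check redraws, 999 times, one trip
per bird and recomputes the dip p-value, yielding a p-value distribution
that guards the bimodality decision against unequal trip counts. Because a
numeric summary is needed for testing, the proportion of resampled p-values
below 0.05 is reported alongside the full vector.

## Condition metrics

Body condition is size-corrected mass: the residual of a pooled OLS
regression of capture mass (g) on head-bill length (mm), fitted across all
years and colonies (a single slope, matching the single reported
relationship); per-year fits are available by subsetting. Relative body-mass
change is (recapture − capture)/capture. Sex, when molecular assignment is
missing, uses the 90.5 mm head-bill cutoff (female at or below it).

The outside-trip proportion per year is the trip-count-weighted mean of
per-bird proportions, which is identically the pooled outside/total trip
ratio; its CI resamples birds (proportion and weight jointly) with
replacement, 999 iterations, percentile bounds.

## Hierarchical models

All four models share fixed effects plus a per-bird random intercept:

- M1 (gaussian): log maximum range per trip ~ year + colony, treatment
  contrasts with 2016 and colony OBS as references; fitted separately to
  inside- and outside-fjord trip subsets. Predictions are back-transformed
  by exponentiating the linear-predictor draws; the median of the
  exponentiated draws is the median response on the km scale.
- M2 (Bernoulli-logit): trip outside the fjord (0 inside / 1 outside) ~ year
  + colony.
- M3 (Bernoulli-logit): first trip after capture outside ~ body condition +
  per-year indicators + colony.
- M4 (gaussian): relative body-mass change per bird ~ outside-trip
  proportion + per-year indicators + colony.

As printed, M3/M4 carry an intercept alongside all three year indicators,
which is over-parameterised; the intercept column is dropped so the
indicators are cell means. Priors are auto-scaled weakly-informative:
beta ~ N(0, 2.5 sd(y)/sd(x)) (gaussian) or N(0, 2.5/sd(x)) (logit), residual
sd ~ Exponential(1/sd(y)), random-intercept sd half-normal with scale
2.5 sd(y) (or 2.5 for logit). The exact auto-scaling constants of common
applied-Bayes defaults are conventions, mimicked rather than reproduced.

Sampling is a custom Metropolis-within-Gibbs engine (no external PPL). The
gaussian sampler is collapsed: random intercepts are integrated out
analytically per group (within/between decomposition of the marginal
covariance, numerically stable as sigma -> 0), beta is drawn from its
conjugate GLS conditional, and (log sigma, log tau) move by adaptive
random-walk Metropolis on the marginal posterior; intercepts are then drawn
exactly from their conditional for storage. Collapsing matters because M3/M4
have one observation per bird, where a centred Gibbs sampler barely moves
across the variance split. The Bernoulli sampler uses the non-centred
parameterisation u = tau z with component-wise adaptive Metropolis for beta,
a vectorised per-group step for z, slice-sampled tau in both the non-centred
and centred parameterisations (interweaving), and likelihood-invariant
translation moves along the beta <-> intercepts ridge. Proposal scales adapt
only during warmup.

Defaults are five chains of 6000 iterations with 3000 warmup — a 10x
reduction of the headline five-chain 60 000/30 000 protocol — chosen to pass
the same convergence gates (split R-hat < 1.1, bulk ESS > 1000 for every
reported parameter, computed with ArviZ) at desk-scale runtimes; the full
protocol is one `MCMCSettings` away. An interval-excludes-zero rule flags
evidence for contrasts, and posterior predictive checks compare observed
mean/sd/min/max (proportion for binary models) against 200 replicated data
sets via tail probabilities.

## Zooplankton index

Per station and year, species abundances (ind m^-3) are averaged over depth
strata — unweighted, as the source procedure states strata averaging without
weights; a thickness-weighted variant exists behind a flag — multiplied by
per-species individual dry masses (mg) and summed. The yearly fjord-level
index is the station mean, with a 999-iteration percentile bootstrap over
stations. The diet species list and dry masses are inputs, not constants.

## Synthetic studies

The generator emulates the study design: two colonies inside a rectangular
fjord of ca. 230 km^2 at 79 N that opens west onto the open sea, flanked by
land strips; three "years"; 12 birds per colony-year (72 deployments, ~370
retained trips — the study's scale); trip counts from a rounded
normal(5.3, 3.3) clipped to 1–16; year-specific outside-trip probabilities
0.07/0.02/0.31 entering on the logit scale with bird intercepts (sd 1.5),
the intercept corrected so the year value is the population-average
probability; trip ranges lognormal per type with a bird-level log-scale
intercept; durations = commute at 30 km/h plus lognormal on-patch time
(range–duration correlation ~0.8); capture masses from the condition
regression (slope 5.96 g/mm); mass changes from the M4 model (slope 0.054,
year levels −0.02/−0.08/−0.03, residual sd 0.04, bird sd 0.01); masses
rounded to 5 g and head-bill to 1 mm as in the field protocol; battery
truncation of the final trip in 8% of deployments; occasional on-land
excursion trips rendered over the land strip.

Tracks are schematic out-and-back paths: a triangular distance profile with
a 0.25 km floor so every trip fix clears the attendance radius, an apex at
the exact template range, and colony fixes between trips. In clean mode (no
truncation, no land trips, 10-min cadence) segmentation recovers the
generated trips exactly, which the round-trip tests assert.

Unprinted spreads are generator calibrations: the outside-range log-sd
(0.12) and bird range log-sd (0.10) are set so the per-individual maximum
range distribution reproduces the printed bimodality pattern — the
bimodal-year config rejects unimodality in ~90% of seeds, the low-outside
year in well under 20% — mirroring the reported D = 0.15 (p < 0.001) versus
non-significant years. The recovery experiments in
`cpforage.validation` parameterise their lognormal mixture components by
their density modes (median = mode * exp(sigma^2)), because the printed 2018
quantities are mode locations; parameterising by medians would build a ~6%
offset into the generating truth that a correct mode estimator would
faithfully report.

What the generator does not emulate: real movement (no area-restricted
search or tortuosity), real coastline geometry, within-season trends,
observation error in positions, or diet composition. Passing tests
demonstrate that the estimators recover what this structure generates; they
do not validate behavioural realism.

## Numerical choices and limitations

- Dip: exact to the LP oracle at 1e-9; bisection tolerance 1e-10 counts.
- Monte-Carlo p-values are discrete (minimum 1/(n_null+1)); resampling
  reuses one null table per sample size and seed.
- Critical bandwidth bisection tolerance 1e-3 km; modes are grid positions
  (0.39 km resolution over 0–200 km).
- Degenerate inputs raise: all-identical samples (KDE scale undefined),
  fewer than 3 values for the dip, zero head-bill variance, single-chain
  diagnostics.
- MCMC is random-walk based: posteriors with strong separation (a year with
  almost no outside trips) rely on the weakly-informative priors for
  identification, as the source analyses do.
- The weighted-proportion bootstrap resamples birds, not trips, so its CI
  reflects between-bird variation only.
- Problem sizes in tests and recovery runs (e.g. 200 birds for the
  mass-change refit, 2000 values for mode recovery, 10x-reduced MCMC run
  lengths) are the package's default desk-scale settings; all are
  configurable upward.
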