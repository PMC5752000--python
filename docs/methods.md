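# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of the package.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design being modelled

The package targets a robust-design live-trapping study of two sympatric
small mammals: a marked, generalist rodent ("mouse") and an unmarked
insectivore ("shrew").  Each trapping grid is a rectangular lattice of
live traps at 25-m spacing (7 × 6 by default, 42 traps, within the 40–52
traps-per-grid range of such designs).  Trapping runs for three primary
sessions per year, each of five consecutive nights; the population is
treated as closed within a primary session except for trap mortality.

## Synthetic-data generator

The generator (`nichecomp.simulate`) is first-class, tested code; its
defaults are the study conditions under which all recovery properties are
asserted.

**Density model.**  The shrew latent follows the auto-regressive
competition structure on the standardized scale:

    z_t = b_lag · z_(t−1) + α · m_t + β · h + σ · ε,

with m_t the mouse standardized latent (i.i.d. standard normal per
grid × session), h standardized habitat covariates (two ordination axes
and elevation), and ε standard normal.  The lag coefficient is derived
from the unit-variance budget b_lag = √(1 − α² − Σβ² − σ²), so Var(z_t)=1
and α is *exactly* the coefficient a standardized regression estimates —
raw densities are affine in the latents (mean + sd·z, truncated at zero
with truncations counted), and within-year sample standardization is
affine-invariant.  Without this calibration, re-standardizing a response
whose variance exceeds one attenuates the slope and breaks interval
coverage.  Defaults: α = −0.9, σ = 0.3, β = 0, 21 grids.  Year-level
multipliers on the mean densities (mouse 1.0/1.3/0.35, shrew 1.0/0.9/1.4)
emulate a peak-then-crash mouse trajectory with shrew release; they shift
within-year means only and therefore do not perturb α.

**Detection.**  Each individual present in a session is caught on a night
with probability `p_night` (defaults: mice 0.25, shrews 0.10 — fixture
choices, since per-night detection is rarely printed in field studies).
A capture is assigned to the trap nearest the individual's perturbed
position (activity center + isotropic Gaussian, σ = 25 m; centers uniform
over the trap rectangle plus a 50-m margin).  We deliberately do *not*
gate capture on proximity to a trap: `p_night` is the marginal per-night
capture probability and absorbs spatial availability.  This keeps the
certain-detection limit exact (p = 1 ⇒ every alive individual appears
every night ⇒ MNKA equals true N), which is the anchor the estimator
tests rely on; the cost is that trap-assignment geometry and detection
are independent.  Movement σ = 25 m yields MMDM values of a few tens of
meters, the field-realistic scale.

**Mortality.**  Each capture is independently fatal with a per-species
probability (defaults: mice 0.11, matching the ~6–14 % trap-mortality
range typical for mice; shrews 0.35, reflecting their much higher trap
mortality).  Dead individuals produce no further records.  No natural
mortality occurs within a primary session, matching the closed-population
assumption.  Trap saturation (one animal per trap-night) is not modelled.

**Isotopes.**  Consumer signatures are computed by the
concentration-dependent mixing identity from known source proportions,
plus the species' discrimination offsets (mice +1.0 ‰ δ¹³C, +3.0 ‰ δ¹⁵N;
shrews +1.3 ‰, +2.5 ‰) and isotropic Gaussian noise.  Individual mice
draw their proportions from a Dirichlet around the habitat mean
(concentration 10), giving them the larger signature variance; shrews use
the habitat-mean proportions with small noise, so they are solved on
population means and mice per individual — the asymmetry the pipeline
enforces.

**Determinism.**  One global integer seed; every stochastic operation
derives a child stream from (seed, op-name, keys) via CRC-hashed entropy,
so stages are reproducible independently and in any order.

What the generator does **not** emulate: demographic birth/death/
immigration processes, trap saturation, spatially explicit detection
(distance-dependent capture), weather or predation covariates, and
measurement error in habitat ordination axes.  Passing recovery tests
therefore certify the estimators under these idealized conditions, not
robustness to their violation in real data.

## Abundance estimation

**M0 profile likelihood.**  Within a session the likelihood over (N, p)
is L ∝ [N!/(N−n)!] p^d (1−p)^(E−d) with exposure E = Σ observed
exposures + (N−n)T; trap deaths censor an individual's exposure at the
death occasion.  p is profiled out analytically (p̂ = d/E); N is
maximized continuously (gamma-function relaxation) by bounded scalar
minimization.  The 95 % interval is the profile-likelihood set at the
χ²₁(0.95)/2 = 1.92 log-likelihood cutoff, which remains stable at small
n where Wald intervals fail.  Degenerate cases: saturated detection
(d = nT) returns N̂ = n flagged as boundary; no recaptures (d = n) makes
the profile asymptotically flat, so the fit is flagged unidentified and
the pipeline falls back to inflating the distinct-id count by the
configured per-session detection probability.  A time-varying (Mt)
estimator solving 1 − n/N = Π(1 − nⱼ/N) is provided; at T = 2 it is the
Lincoln–Petersen estimator, used as an analytic cross-check.

**Horvitz–Thompson for the unmarked species.**  p* is interpreted as the
per-primary-session (five-night aggregate) probability of being caught at
least once; `per_session_detection` converts a per-night value via
1 − (1−p)⁵.  MNKA for the unmarked species counts live-capture *events*
(identity being unknowable without marks), which biases high when
individuals are re-caught — a documented caveat.  Zero-capture sessions
return N̂ = 0 with a rule-of-three upper bound 3/p*.

**Geometry.**  The effective trapping area is the Euclidean buffer of the
trap-array bounding rectangle, A + P·r + πr² (rounded corners), with
r = 50 m by default or MMDM/2 on request.  MMDM takes, per individual
with ≥ 2 captures, the maximum distance between *consecutive* captures,
then averages over individuals.

## Competition regression

Candidate sets: all 15 non-empty subsets of {mouse density, NMDS1, NMDS2,
elevation} (regressive) and the same 16 subsets including the empty one
with the previous-session shrew term always added (auto-regressive).
Auto-regressive response rows are sessions 2–3 with the lag from the same
grid and year (no cross-winter lag).  Standardization is within year,
pooling all grids and sessions of that year per species; covariates are
standardized too so coefficients are comparable (α is unaffected).
Fits are ordinary least squares (Gaussian GLM with identity link) with
log-likelihood under σ̂² = RSS/n; k counts the intercept, slopes and the
residual variance; AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).  Ranking sorts by
AICc; among models with ΔAICc ≤ 2 ("considerable support") the fewest-
parameter model wins, ties broken by higher R², then lower AICc.
Observations are not weighted by abundance-estimate precision.  Rows with
missing densities are dropped pairwise with a logged count.

## Diet mixing

The concentration-dependent mass balance is linear in the proportions:
for each element e, Σᵢ pᵢ c_{e,i}(δ_{e,i} − δ_mix,e) = 0, plus Σpᵢ = 1
and pᵢ ≥ 0.  With three sources the 3 × 3 system has a unique solution
(ill-conditioned when corrected sources are collinear; infeasible when
the mixture lies outside the corrected triangle).  With s ≥ 4 sources the
feasible set is a polytope of dimension s − 3; its vertices are the basic
feasible solutions over all C(s,3) support triples.  Uniform sampling:
segments (s = 4) by a uniform parameter between the extreme vertices;
higher-dimensional faces by Delaunay triangulation in affine coordinates
with simplices drawn proportionally to volume (default 10,000 samples,
seeded).  Reported means satisfy mass balance to < 10⁻⁶ ‰ because the
constraints are linear and the polytope convex.  With equal
concentrations the solver reduces exactly to plain dual-isotope linear
mixing.  A note on oracles: a brute-force simplex-grid check (keep grid
points whose implied mixture matches within a tolerance) weights points
by the local tolerance-band thickness, which varies with the
concentration contrast among sources; with moderate contrast the grid
mean and the uniform-polytope mean agree to ≈ 0.01.

The dietary-overlap criterion flags a source when the shrew population
mean exceeds the threshold (default 0.2, strict inequality) and a
positive percentage of individual mice exceed it; with no feasible mouse
solutions the mouse side is undefined and a warning is raised.

The KNN randomization test uses k = 3 and 999 permutations by default
(neither is standardized in the literature); the statistic is the mean
fraction of each point's k nearest neighbors (Euclidean in δ-space, self
excluded, distance ties broken by smallest index) sharing its label, and
the p-value is (1 + #{permuted ≥ observed})/(n_perm + 1).  Exhaustive
enumeration over label assignments is available for small inputs.

## Isotopic niches

The kernel utilization density is a Gaussian product-kernel KDE with
per-axis normal-reference bandwidths 1.06 σ n^(−1/5) (scalable by a
configurable multiplier), evaluated on a 256 × 256 grid padded three
bandwidths beyond the data range and renormalized to unit cell-sum.  The
density threshold for a mass level is found by sorting cell probabilities
and accumulating to the requested mass; contours are extracted by
marching squares on a zero-padded surface (so edge-touching regions
close), polygons assembled with nested contours as holes, areas by
polygon area in ‰², intersections by polygon clipping (shapely).
Grid-resolution refinement 200 → 400 changes Gaussian-fixture areas by
< 2 %.  The subsampling control redraws both clouds without replacement
at the smaller period's sample sizes (5 replicates by default) and
reports mean and a normal-approximation 95 % CI of the mean.

## Energetics

Shrew FMR scales linearly from a reference species (default 90 kJ/day at
8.2 g — a config constant, as reference FMRs are rarely printed); mouse
FMR is used unscaled (default 30 kJ/day) with an optional mass-specific
flag for sensitivity analysis.  Community totals use session-3 abundance
point estimates (the within-year maximum); an option would propagate
abundance intervals by endpoint arithmetic.  Compensation is
100 · E_t / E_ref per habitat and reference year.

## Problem sizes and defaults

The default pipeline runs 21 grids × 3 years × 3 sessions (≈ 10,000
capture records, 189 closed-population fits), isotope clouds of 280/231
(period A) and 21/64 (period B) mice/shrews, and five subsampling
replicates — a full run takes a few seconds on one CPU.  Recovery
benchmarks use 500 replicates for the closed-population estimator, 200
for competition-coefficient coverage and selection, and 200 null
replicates at 999 permutations for test calibration; these sizes give
Monte-Carlo standard errors comfortably below the asserted margins.

## Known limitations

- Between-session survival/recruitment is not estimated (no open-
  population likelihood); abundance is within-session only.
- MNKA-as-live-captures overcounts re-caught unmarked individuals.
- The M0 model assumes homogeneous detection; individual heterogeneity
  would bias N̂ downward and is not simulated.
- The polytope sampler is exact for segments but relies on triangulation
  for s ≥ 5; degenerate (lower-dimensional) faces are handled by rank
  detection, not by exact face lattices.
- KDE niches inflate areas by O(h²) smoothing (≈ 4–7 % on Gaussian
  fixtures at n = 2000), which cancels in overlap *ratios* only
  approximately.
- The energetics account ignores thermoregulatory seasonality and
  digestibility differences among diet items.
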