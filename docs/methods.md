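# Methods

## The analysis model

The pipeline treats a highway as a linear feature with per-100 m verge
attributes (width in m, grade class below/flat/above relative to the
surrounding terrain, % herbaceous and % tree-and-shrub cover) and hourly
traffic counts split into light vehicles (classes 1–2) and trucks
(classes 3–5).  Telemetry is nocturnal: 30-min fixes from dusk to dawn
with a triangulation error of roughly 200 m, which motivates buffering
every location by the mean error radius before describing it.

Four binary-response comparisons share one statistical engine:

| comparison | response 1 | response 0 |
|---|---|---|
| habitat selection | independent used location | random point in the 100 % isopleth |
| directionality | TOW segment | AWA segment |
| crossing sites | crossing chainage | uniform random chainage |
| crossing vs road-kill | crossing chainage | registry kill chainage |

Each is a binomial GLMM with a logit link and a per-individual Gaussian
random intercept (the registry comparison has no individual identity on
the kill side and collapses to plain logistic regression, with σ free to
shrink to zero).  Candidate models are compared by AIC; the supported set
(ΔAIC ≤ 2) is averaged with zero substitution and the unconditional-
variance SE formula.  Estimation is ML, not REML-like, because the AIC
comparisons span different fixed effects.  AIC counts the random-intercept
variance as one parameter (k = fixed effects incl. intercept + 1).

### GLMM fitting

The marginal likelihood integrates the random intercept out per group.
Two modes are implemented: the Laplace approximation (default; posterior
mode by per-group Newton iterations, all groups vectorized) and adaptive
Gauss–Hermite quadrature centered and scaled at the mode (≥ 10 nodes; the
high-accuracy mode, machine-exact against direct numerical integration on
small fixtures).  Laplace carries an O(1/m) bias on m-observation groups
— about 0.01 log-likelihood units at m = 10 — so the quadrature mode is
the reference whenever a tolerance below that is needed.  The optimizer
is L-BFGS-B over (β, σ) with σ ≥ 0; fixed effects are standardized
internally and back-transformed, and Wald covariance comes from a
finite-difference observed information matrix (the σ row is dropped when
σ sits on the boundary, or when the caller fixes it).  `fix_sigma=0`
collapses the model to ordinary logistic regression exactly.

Forward selection starts at the null model, enters the AIC-best variable
per step, and enforces the collinearity screen: two variables with
|Pearson r| > 0.5 never share a model; the one correlating better with
the response survives a collision.  Under AIC a spurious variable clears
the entry bar with probability ≈ 0.16, so "recovery" of a planted truth
means both true terms are selected, not that nothing else is.

### Residual spatial autocorrelation

A distance-binned Moran correlogram with a permutation envelope replaces
spline-based alternatives: pairwise products of centered residuals are
averaged per distance bin (bins span up to half the maximum pairwise
distance) and scaled by the residual variance.  The envelope is
simultaneous across bins — a studentized max-deviation (sup-t) band over
199 permutations — so an iid residual field stays entirely inside with
probability ≈ 0.95.

## Home ranges

k-NNCH/LoCoH: for each location, the convex hull of it and its k−1
nearest neighbors (k = 20 by default); hulls are sorted by area ascending
(small local hulls mark densely used terrain; ties broken by point index
for determinism) and unioned in that order until ≥ q % of locations fall
in the closed union — boundary points count as covered.  Exact duplicate
coordinates are jittered by 1e-6 m for hull robustness.  With k = n the
100 % isopleth equals the MCP.

The incremental-area stability check declares a home range stable when
the cumulative-MCP area grows by less than 5 % over the trailing half of
the series (never fewer than 10 additions).  A trailing block that scales
with n is essential: an unbounded random walk roughly doubles its
cumulative hull area per doubling of fixes, while a resident's saturates,
so a fixed-width trailing window would eventually pass any drifter.

## Habitat-selection design

Locations are thinned to serial independence by increasing the sampling
interval (keep every m-th fix) until the Schoener ratio t²/r² enters
(1.6, 2.4); if no m ≤ n/10 reaches the band the closest m is used with a
warning.  Available points are rejection-sampled uniformly in the 100 %
isopleth, one per used location.  Used rows read traffic at their own
hour; available rows draw traffic (with replacement, per individual,
seeded) from the individual's thinned-out fixes, falling back to the used
pool when nothing was discarded.  The interaction column is the exact
row-wise product d_highway × traffic.

Candidate sets are frozen: 14 habitat models in three families
(road-related / landscape / combined), 5 within-home-range directionality
models over starting distance and traffic by class, 11 near-highway
directionality models (segments starting within 2× the error radius),
14 (owl) / 15 (marten) crossing-site models, 11 crossing-vs-roadkill
models.  Every published winning structure is a member of its family;
the full memberships are in the candidate functions themselves.

## The simulator

The generator emulates the study conditions, not a generic ecosystem:

- **Landscape** (`make_landscape`): a gently meandering west–east highway
  across a 20 × 10 km extent; verge attributes per 100 m drawn from the
  published covariate ranges (width 2–20 m, herbs 15–99 %, trees/shrubs
  26–76 %, grade classes 25/50/25 %); streams and minor roads crossing
  roughly north–south; circular habitat patches tagged cropland (owl
  habitat) or forest (marten habitat); passages every ~2 km; buildings
  cluster around the urban centers as villages, with a minority of
  isolated farmsteads (a uniform scatter of buildings would give the
  building-distance covariate far more within-home-range texture than
  the km-scale fields of the real landscape).
- **Traffic** (`make_traffic`): hourly Poisson counts whose means follow a
  diurnal shape (evening peak fading to a pre-dawn minimum, commuter
  peaks by day), scaled so the 18:00–06:00 block carries the configured
  night share of the AADT (defaults 13 949 and 5 536 veh/day).  A
  mean-one lognormal nightly factor (log-SD 0.5) adds weekday/weekend
  structure; each factor covers one dusk-to-dawn block.  Within-night plus
  between-night variation reproduces the several-hundred-fold range of
  traffic volumes observed at real fix times; a flat night profile would
  leave the distance × traffic interaction without variance to act on.
- **Movement** (`simulate_individual`): discrete-choice step selection,
  24 candidate steps per 30-min interval during a 19:00–07:00 activity
  window (12 h → 24 fixes/night).  Candidate scores combine
  traffic-scaled highway avoidance `β_avoid · traffic · exp(−d/1000 m)`,
  stream attraction, proximity-scaled suitable-verge attraction,
  directional persistence, and a home-center attraction
  `−|x−home|²/(2·600 m²)` that makes individuals residents (home ranges
  must stabilize for the incremental-area and isopleth machinery to be
  exercised).  Defaults (β_avoid = −0.025, step scale 350 m) are
  calibrated once so that the planted avoidance expresses the effect
  size the analysis reports (a distance × traffic interaction with a
  Wald z of several units at the study's sample sizes) and crossing rates of ~0.2–0.7 per activity day for
  residents captured within 1.5 km of the road — and are not adjusted per
  analysis.
- **Crossings and kills**: a chosen step that intersects the highway is
  realized as a crossing with probability logistic(cross_logit +
  grade_effect); a refused crossing re-samples among same-side candidates
  (the animal turns back at the exclusion fencing).  Each realized
  crossing kills with probability `kill_prob`, truncating the trajectory;
  nightly censoring emulates disappearance.
- **Telemetry error** (`add_telemetry_error`): isotropic radial error with
  a Gamma-distributed radius moment-matched to the configured mean ± SD
  (196 ± 124 m owl, 182 ± 155 m marten).  A Rayleigh radius cannot match
  an arbitrary mean/SD pair — its ratio is fixed — so the Gamma family is
  used instead.

What the simulator does **not** emulate: territorial interactions,
day-roost relocations, GPS-style autocorrelated error, seasonal habitat
change, carcass detectability.  Passing recovery tests therefore show the
estimators are consistent under the stated movement model, not that field
data meet its assumptions.

## Numerical and design choices

- Geographic (lon/lat-looking) coordinates are rejected, never silently
  projected; all geometry assumes planar meters.
- Traffic lookups floor timestamps to the hour.
- The grade threshold is ±20 **degrees** by default (configurable); a ±20
  radian threshold is geometrically impossible.
- A grade class absent from a landscape yields a distance equal to the
  highway length — an explicit "farther than anything on this road" —
  rather than infinity, keeping design matrices finite.
- Crossing times are the midpoint of the bounding fixes; crossing-model
  traffic is read at that hour.  Random highway sites are uniform in
  chainage, one per crossing, inheriting the crossing's individual and
  hour so the design stays balanced within individuals.
- Directionality ties (equal start/end distance within 1e-9 m) are
  excluded and counted; a binary response admits no third class.
- Disappeared individuals contribute tracking time up to their last fix
  in both risk scenarios; the upper scenario counts them as kills.
- The mortality extrapolation takes the roadside strip width as an
  explicit argument: the published owl and marten extrapolations are not
  reproducible with a single consistent width, so no default is claimed.
- Every stochastic stage derives its seed from the master seed and the
  stage name (SHA-256), making pipeline reruns bytewise identical.

## Problem sizes used by the test suite

The recovery suites run at the scale the analysis targets: 6 individuals
× 90 nights (≈ 2 160 raw fixes each, thinned to ≈ 250 independent
locations) for the 50-replicate habitat-model competition; pooled
simulations with ≥ 1 000 (kill_prob 0.02) and ≥ 2 000 (0.005) crossings
for per-crossing risk recovery; n = 2 000 with 8 groups for the
100-replicate forward-selection check.  Property suites use 100 random
fixtures each.  These sizes are the package's definition of "study
scale"; larger runs only sharpen the same checks.

## Known limitations

- The Laplace mode's small-group bias (~1e-2 logLik at 10-observation
  groups) is inherited by AIC differences; competitions among models
  fitted to the same data are unaffected to first order.
- LoCoH isopleth construction is O(n²) in the worst case (union +
  coverage recount per hull); fine for telemetry-scale n (≤ a few
  thousand).
- The crossing detector sees only chords between consecutive fixes: two
  crossings inside one 30-min interval (out-and-back) are invisible, as
  in any fix-based study design.
- `fit_crossing_vs_roadkill` reads registry-site traffic at 23:00 of the
  kill date because registries record dates, not clock times.
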