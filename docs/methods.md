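# Methods

This note documents the models and procedures implemented in `refugia`: what
is computed, under which assumptions, with which defaults, and where the
genuinely open design choices were resolved.

## 1. The screening procedure

The unit of analysis is the pair (species, protected area).  Inputs per
species are a *current* and a *future* habitat-suitability surface on a
regular recording grid (10 km "hectad" cells by default, scores in [0, 1]),
a set of occupied hectads from the baseline recording period, and a table of
preferred land-cover classes.  Protected areas (PAs) are arbitrary polygons.

1. **Habitat refinement.** A coarse cell keeps its suitability score iff at
   least one fine land-cover cell inside it carries one of the species'
   preferred classes; otherwise the score is set to 0.  Scores are never
   increased.
2. **Threshold.** The species' suitability threshold `tau` is the 10th
   percentile (configurable) of the refined *current* suitability at its
   occupied cells, using linear interpolation between closest order
   statistics — zero-based position `(n-1)·p/100`, the numpy/R type-7
   default.  The same `tau` is applied to both periods.
3. **Zonal extraction.** For each PA and period we take the maximum score
   over all cells whose half-open footprint intersects the polygon with
   positive area.  A PA far smaller than one cell therefore inherits its
   cell's score; contact along a shared boundary only does not count.  This
   any-intersection rule is deliberate: most British PAs are much smaller
   than one hectad, and a cell-centre rule would drop them.
4. **Classification.**  With `occ` = "the polygon intersects at least one
   occupied cell":

   | occ | max_current >= tau | max_future >= tau | status  |
   |-----|--------------------|-------------------|---------|
   | yes | (ignored)          | yes               | in situ refugium |
   | yes | (ignored)          | no                | at risk |
   | no  | yes                | yes               | ex situ refugium |
   | no  | otherwise          |                   | none    |

   Occupancy overrides modelled current suitability: presence is itself
   evidence the site is currently suitable.  This is the only reading under
   which `occupied = at_risk + in_situ` holds exactly per species, as it
   does in every row of the published count table this package's arithmetic
   is checked against.
5. **Summaries.**  Per-species counts with % at risk to 1 decimal; column
   averages computed from *unrounded* per-species percentages, then rounded;
   the ex situ share of refugia and the pooled retention (100 × total
   in situ / total occupied) to the nearest integer; the mean per-species
   retention to 1 decimal.

All comparisons downstream of `tau` are order-based, so any strictly
increasing transform of the scores leaves every classification unchanged
whenever the percentile lands on an order statistic (the interpolated case
commutes only approximately; the test suite pins the exact case).

Missing scores (`NaN`) are excluded from percentiles and maxima; a PA whose
intersecting cells are all missing is excluded from classification for that
species and logged.

## 2. PA covariates and design matrix

Six predictors per PA: centroid northing and easting (planar metres,
standing in for latitude and longitude), polygon area, mean elevation,
elevational range (max − min) and habitat count (number of distinct
land-cover classes), the last three measured over fine-grid cells
intersecting the polygon under the same positive-area rule.  Mean elevation,
elevational range and area are log-transformed with fixed +1 offsets (1 m,
1 m, 1 m²) so flat, sea-level or single-cell PAs remain in the analysis,
then every column — habitat count included — is z-scored over the analysed
set.  The scaling is retained alongside the matrix for back-transformation.

## 3. The spatial count model

The response is the integer number of species for which a PA provides
refugia; in situ and ex situ counts are modelled separately.

    y_i ~ Poisson(mu_i),    log mu_i = x_i' beta + w(s_i)

`w` is a zero-mean Gaussian random field with squared-exponential covariance
`k(d) = gp_sigma² exp(-d²/(2 gp_rho²))`, realised as a low-rank predictive
process over `m` knots (default 15, placed by k-means on the PA centroids):
`w(s) = k(s, knots) K⁻¹ w*`, `w* ~ N(0, K)`, with 1e-8 diagonal jitter.
The projected field is **centred over the observations** in both the sampler
and the forward simulator; without this constraint the intercept and the
field mean are unidentified and the intercept's split-Rhat exceeded 10 in
development runs.  Priors: `beta ~ N(0, 5²)`, half-normal on `gp_sigma`
(scale 1) and on `gp_rho` (scale = half the coordinate-extent diagonal
unless set).

A Gaussian field was chosen over a heavier-tailed alternative: nothing in
the reported quantities this package reproduces distinguishes them, and the
Gaussian predictive process keeps the sampler simple and self-contained.

**Inference** is adaptive random-walk Metropolis-within-Gibbs, implemented
in numpy with no external inference engine: each regression coefficient and
each knot effect is updated singly; `(log gp_sigma, log gp_rho)` jointly.
Proposal scales adapt by Robbins–Monro toward a target acceptance rate
(default 0.3) during warmup only, preserving detailed balance afterwards.
Defaults: 2 chains × 2500 iterations with 1000 warmup, dispersed seeded
initial states.  Summaries report posterior mean, SD, central 95% credible
interval, split-Rhat, and a significance flag (positive when the interval
lies above zero, negative below, none otherwise).  Any split-Rhat above
1.05 flags the whole result as non-converged; the result is returned, never
silently accepted.  In practice the linear coordinate covariates (northing,
easting) mix worst — a linear trend is partially exchangeable with a
long-range spatial field — and they are the usual cause of a convergence
flag; the elevation, range and area coefficients mix well (Rhat ≈ 1.00–1.04).

Known behaviour under the suppressed-field check (`prior_sigma_scale =
1e-6`): posterior coefficient means agree with a maximum-likelihood Poisson
regression to ≈ 0.005, well inside the 0.05 band the recovery tests assert.
In the 20-replicate credible-interval coverage experiment the per-coefficient
coverage is nominally 95%; with only 20 replicates the observed minimum
across 7 coefficients fluctuates by binomial noise (17–20 of 20 is typical).

## 4. The synthetic study system

The generator replaces the proprietary British datasets with a planar world
whose statistical structure matches what the screening assumes.  "Latitude"
and "longitude" are northing and easting in metres on a 600 km × 600 km
domain of 10 km cells (default), with elevation and land cover on a 10-fold
finer lattice.

* **Elevation** = northward ramp (1 m per km) + a broad Gaussian random
  field (18 km bandwidth, 350 m amplitude; hill massifs) + fine-scale
  relief (4 km bandwidth, 350 m amplitude) whose local amplitude is
  modulated by an independent broad "ruggedness" field, so some districts
  are rugged and others flat at any base elevation; clipped at sea level.
  Gaussian random fields are seeded white noise smoothed with a Gaussian
  kernel (bandwidths in metres, invariant to the fine subdivision).
* **Land cover**: nearest-nucleus tessellation; 20 classes, patches ≈ 5 km
  across.  Each species prefers one class, drawn at random.
* **Suitability** for a species is the inverse logit of a quadratic penalty
  on (a) planar distance to the species' climatic optimum (scale 150 km)
  and (b) the distance from its preferred elevation to the *span* of fine
  elevations inside the cell.  Using the span rather than the mean gives
  topographic diversity a causal, microclimate-buffering effect: rugged
  cells remain suitable for a wider band of species.  The future surface
  displaces the optimum 100 km poleward and 350 m upslope — the upper range
  of documented plant range shifts scaled to a 2080 horizon.
* **Occupancy**: each cell whose refined current suitability exceeds 0.5 is
  recorded occupied independently with probability 0.35 (hectad recording
  of rare plants is incomplete).
* **Protected areas**: 4000 axis-aligned rectangles (the British estate has
  several thousand SSSIs/NNRs), centres uniform, aspect ratio in [0.5, 2],
  clipped to the domain.  Log-areas are marginally Normal(log 10⁶ m², 1.8²)
  — median 1 km², strongly right-skewed, most PAs far below one hectad.
  The log-area z-score is correlated (0.5) with a *locally centred* site
  quality score: each cell's habitat-refined current-plus-future
  suitability summed over species, minus its 50 km Gaussian smooth.  This
  encodes designation bias — reserves exist because of their biological
  interest, and within any district the larger reserves were drawn over
  the locally best ground.  Local centring matters: a district-scale
  coupling is absorbed by the count model's spatial field, whereas the
  within-district component is genuine signal for the area covariate.
  With the coupling at 0, sizes are independent of location and the
  marginal distribution is unchanged.

What the generator does **not** emulate: observer-effort bias, dispersal,
climate-ensemble spread, realistic PA boundary shapes (classification and
zonal code use true geometric intersection, so real polygons drop in
unchanged), and land-cover change over time.  Passing tests on this world
therefore validate the *mechanics and statistics* of the pipeline — the
thresholding, overlay, bookkeeping, covariates and inference — not the
ecological fidelity of any particular British projection.

### Why these defaults give the documented covariate pattern

The end-to-end check asserts that both fitted count models find positive
effects of log mean elevation, log elevational range and log area.  Each
has a distinct causal route in the generator: elevation through the upslope
displacement of preferred elevations; range through microclimate buffering
(the span term); area through the zonal maximum over multiple cells *and*
the designation-bias coupling.  Development experiments showed the third
route is necessary: with PA size strictly independent of location, the
partial effect of area conditional on the other covariates is reliably
negative (larger-but-equally-ranged PAs are flatter on average, and larger
PAs are more often occupied and hence excluded from the ex situ pool) —
an instructive artefact of uniform random reserve placement that real
reserve networks do not exhibit.

## 5. Numerical and procedural choices

* Percentile convention: linear interpolation between closest ranks; stated
  and configurable because the original analysis does not record one.
* `tau` is computed after habitat refinement by default (configurable
  ordering is a one-line change in the pipeline; the refined and unrefined
  scores differ only on zeroed cells, which occupied cells rarely are).
* Half-open cell footprints make cell membership unambiguous on boundaries;
  zero-area contact never counts anywhere in the pipeline.
* All randomness flows from one root seed through `numpy` `SeedSequence`
  spawn keys, one stream per generator stage and per chain; identical
  (seed, config) reproduce byte-identical pipeline outputs.
* Degenerate inputs fail loudly: empty occupancy sets, PAs outside the
  modelled domain, zero-variance design columns, and fewer distinct
  coordinates than knots all raise with the offending identifier.
* Problem sizes in the test-suite and acceptance script (16–60 cell grids,
  60–4000 PAs, 20 recovery replicates at n = 400) were chosen as the
  smallest sizes at which the checked statistics are stable.

## 6. Known limitations

* The sampler is a random-walk scheme; for much larger PA sets (≫ 10⁴) or
  many knots a gradient-based sampler would mix better per unit time.
* The predictive process with 15 knots cannot represent fine-scale spatial
  noise; residual overdispersion in the classification-derived counts is
  partially absorbed by `gp_sigma`, which should not be interpreted as a
  pure spatial-range estimate.
* Northing/easting coefficients are weakly identified in the presence of
  the field (see above); their flags should be read with the convergence
  diagnostic in hand.
* Integer species counts are the modelled response.  An alternative
  continuous response (summed occupancy probabilities) appears in some
  related workflows; it is incompatible with a Poisson likelihood and is
  not implemented.
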