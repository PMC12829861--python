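# refugia

Screening protected areas as **climate refugia** for threatened plants, and
modelling which site characteristics predict them.

Climate change displaces species' suitable climates poleward and upslope.
A protected area (PA) can act as an *in situ* refugium (the species is there
now and the climate stays suitable), as an *ex situ* refugium (suitable now
and in the future but currently unoccupied — a candidate receptor site for
assisted colonisation), or it can be *at risk* (occupied now, unsuitable
later).  `refugia` turns species-distribution-model suitability surfaces,
baseline occupancy records on a 10 km recording grid and PA polygons into
this three-way classification, per species and PA, and then asks which PA
characteristics predict how many species find refugia in each site.

The package is aimed at spatial conservation analysts: it reimplements a
published screening of the British PA estate (NNRs and SSSIs, 12 threatened
vascular plants, 2080 climate projections) as a reusable, fully testable
pipeline, with a self-contained synthetic landscape generator standing in
for the proprietary national datasets.

## The method in brief

For species *s* with occupied baseline cells *O_s* and refined suitability
surfaces *S_s^now*, *S_s^2080* (scores in [0, 1], zeroed outside preferred
habitat):

* threshold: `tau_s = Q_10 { S_s^now(c) : c in O_s }` — the 10th percentile
  of suitability at occupied cells;
* per PA *j*: zonal maxima `M_j^now, M_j^2080` over all grid cells the
  polygon overlaps;
* classification: occupied PAs split on `M_j^2080 >= tau_s` (in situ vs at
  risk); unoccupied PAs with both maxima `>= tau_s` are ex situ refugia.

Species-per-PA refugia counts `y_j` are then related to six standardized
predictors (log mean elevation, log elevational range, log area, northing,
easting, habitat count) with a spatially explicit Bayesian Poisson
regression,

    y_j ~ Poisson(exp(x_j' beta + w(s_j))),

where `w` is a low-rank (predictive-process) Gaussian random field with
squared-exponential covariance, sampled by an adaptive
Metropolis-within-Gibbs scheme written in plain numpy.  A predictor is
reported as a significant positive/negative effect when its central 95%
credible interval excludes zero.  See `docs/methods.md` for assumptions,
priors and numerical choices.

## Worked example

Run a small synthetic scenario end to end (as a library; `refugia run
--outdir ...` does the same from the shell):

```python
from refugia import RunConfig, ScenarioConfig, GridSpec, run_pipeline
from refugia.glmm import SpatialGLMMConfig

cfg = RunConfig(
    outdir="demo_run",
    scenario=ScenarioConfig(seed=42, n_species=4, n_pas=300,
                            n_landcover_classes=8, landcover_nuclei_per_class=40),
    grid=GridSpec(n_cols=30, n_rows=30, fine_factor=5),
    glmm=SpatialGLMMConfig(seed=42, n_iter=1500, n_warmup=700),
)
run_pipeline(cfg)
print(open("demo_run/report.txt").read())
```

which prints (abridged):

```
Species                    Occupied  At risk  % risk  In situ  Ex situ
----------------------------------------------------------------------
sp00                             19       12    63.2        7       17
sp01                             18       11    61.1        7        8
sp02                             19       14    73.7        5        3
sp03                             19        7    36.8       12       16
Average                        18.8     11.0    58.7      7.8     11.0

Ex situ share of refugia: 59%
Retention of occupied PAs: mean 41.3% (pooled 41%)

Count model: species with in situ refugia per PA
------------------------------------------------
Parameter                 Mean      SD   Lower   Upper   Rhat  Effect
intercept               -3.292   0.325  -4.067  -2.736  1.007
log_mean_elevation       0.845   0.328   0.151   1.479  1.017  +
log_elev_range           0.002   0.279  -0.565   0.545  1.015  0
log_area                 0.837   0.224   0.376   1.225  1.005  +
...
```

Reading this: each row counts the PAs where that species is currently
present (`Occupied`), split into those losing climatic suitability by the
future period (`At risk`, also as a percentage) and those keeping it
(`In situ`); `Ex situ` counts currently unoccupied PAs suitable in both
periods.  Below, each count model row gives the posterior mean, SD and 95%
credible bounds of a standardized regression coefficient; `+` marks a
significantly positive effect (interval above zero).  Here 63.2% of
sp00's occupied PAs are at risk, and PAs at higher elevation and of larger
area host significantly more species with in situ refugia.  Small demo
scenarios are noisy; the full-size default scenario (60×60 cells, 12
species, 4000 PAs, poleward/upslope shift) recovers positive elevation,
elevational-range and area effects in both count models, the qualitative
pattern reported for the British estate.

The run directory also contains every intermediate as plain text: refined
suitability grids (`*.asc`), PA polygons (`pas.geojson`), occupancy and
covariate tables, posterior summaries (`glmm_*.csv`) and a `manifest.json`
with the configuration hash and per-stage timings.  Re-running the same
configuration reproduces every file byte for byte.

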