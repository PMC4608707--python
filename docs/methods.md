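# Methods

`fawnscape` implements a landscape-scale analysis of neonatal ungulate
(white-tailed deer fawn) survival over the post-partum season (14 May–31
August): how maternal resource selection, multi-predator encounter risk,
maternal nutrition (birth mass), preceding winter severity, and spring hiding
cover jointly shape daily and season-long mortality hazard, and how that
hazard distributes over a landscape grid.  This note documents the models,
the numerical choices behind them, and what the synthetic study system does
and does not emulate.

## The analysis grid and resource covariates

The study area is tessellated into contiguous square cells of 2115 m² (side
≈ 45.99 m), the mean telemetry error ellipse of the field design — each cell
is the finest spatial unit at which a radiolocation is trustworthy.
Vegetation comes from a 30 m categorical raster with eight classes (lowland
forest, deciduous, coniferous, mixed forest, grass/shrub, pasture, cropland,
wetland).  Per cell we compute:

- area-weighted proportions of each class (exact rectilinear overlay of
  pixels on cells; class areas are conserved to rounding);
- the area (km²) of the vegetation patch containing the cell centroid.
  Patches are 4-connected (rook) components; rook is the conservative choice
  that never merges diagonally touching patches;
- the mean distance (km) from the point to the *edges* of the nearest three
  other patches of the same class (multiple nearby patches can serve
  foraging and refuge roles simultaneously).  Distance to a patch is the
  minimum distance to its boundary-pixel centres; with fewer than three
  other patches the mean is over those available (points on very rare
  classes are kept rather than discarded), and with none the value is
  missing and logged;
- distances (m) to the nearest road and permanent-water polyline (exact
  point-to-segment geometry via shapely).

All covariates are translation-invariant and live in planar metres; no
reprojection is attempted.  Covariates are z-scored over the pooled
used + available sample with sample (ddof = 1) standard deviations, and the
fitted means/SDs are frozen so grid cells can be scored on exactly the
fitted scale.  Collinearity is screened with variance inflation factors
(VIF_j = 1/(1−R²_j), flag threshold 7).

## Resource selection (use–availability GLMM)

Second-order selection is estimated by contrasting radiolocations (1)
against an equal number of random points (0) drawn uniformly from the 100%
minimum convex polygon of all radiolocations, in a binomial mixed model with
random intercepts for fawn and year.  The fit is maximum likelihood with a
Laplace approximation to the marginal likelihood: for fixed variances the
joint penalized log-likelihood in (β, b) is maximized by damped Newton
iterations (the Hessian is assembled from per-group aggregations, so cost is
linear in rows), and variances are then maximized by a Nelder–Mead search on
the log scale.  Wald standard errors come from the joint observed
information at the mode.  Adaptive quadrature is unnecessary at these group
counts; the variance-→0 limit reproduces plain IRLS logistic regression to
machine-level accuracy (tested).

Model selection mirrors the field protocol: a null model and each covariate
alone are fitted first; individually significant covariates (Wald p < 0.05)
enter a global additive model; models are ranked by ROC AUC (computed by the
Mann–Whitney rank statistic, ties half-credited, on the population-level
fitted linear predictor — random-intercept modes are excluded, since they
would let even a covariate-free model memorize per-group class balance),
with AUC ties broken toward fewer parameters.  The top
model's standardized coefficients score every cell through the exponential
selection function w(x) = exp(β₀ + Σβₖxₖ), and a linear stretch
ŵ = (w − w_min)/(w_max − w_min) maps scores to [0, 1]; a constant surface
has no range and is mapped to 0.5 everywhere with a warning.

## Predation risk, winter severity, hiding cover

Integrated predation risk is the cellwise sum of four per-species selection
surfaces (bobcat, black bear, coyote, wolf), each in [0, 1] on the fawn
grid, so integrated risk lies in [0, 4].  Estimating those surfaces from
predator collar data is out of scope; they are inputs (and are synthesized
by the generator).

The daily winter severity index is (snow depth cm + wind speed kph +
rainfall cm) − minimum temperature °C, so severity rises with snow, wind,
rain, and cold.  The sign convention is deliberate: severity must increase
with positive values, which forces subtracting temperature from the
precipitation/wind sum rather than the reverse.  The annual index is the
sum of daily values over 1 Jan–31 Mar, then centered by subtracting the
across-year mean of the annual sums; raw sums are always reported alongside
because centering depends on the year set supplied.  Days with missing
components are excluded and counted.

Hiding cover is summarized as the mean and SD of greenness (NDVI-like)
pixel values over the study area for the composite period nearest peak
parturition (1 June); acquiring satellite composites is out of scope, so
the value is an input column.

## Survival models

Time is calendar day-of-year with delayed entry: each fawn enters the risk
set at its birth date and leaves at death or censoring on 31 Aug.  Daily
intervals are the inter-relocation gaps (t_k, t_{k+1}] carrying the
covariates of the opening relocation; seasonal records collapse each fawn
to one interval with relocation-averaged covariates (arithmetic mean by
default; median available).  Relocations dated after the fate are rejected
and counted.

Baseline annual survival uses the product-limit (Kaplan–Meier) estimator
with staggered entry and Greenwood variance; with all entries at zero it
reduces exactly to the classical estimator (tested against lifelines).
Years are compared with the k-sample log-rank test over shared risk sets
with delayed entry (hypergeometric variance, df = k − 1).

The core model is Cox proportional hazards with Gaussian random intercepts
(frailty) for fawn and year on the log hazard.  For fixed variances θ the
penalized partial likelihood is maximized jointly over (β, b) by Newton
iterations with step-halving (the penalized likelihood is non-decreasing
across iterations); ties use the Efron approximation.  Risk-set sums at the
event times are built from bucketed reverse cumulative sums over entry- and
exit-sorted rows, so an iteration costs O(n·m²) for m model columns.  The
model is scored by the Laplace-approximated integrated partial likelihood

    ipl(θ) = pl(mode) − pen(mode) − ½ Σ_f q_f log θ_f − ½ log |H_bb|,

and θ is profiled with bounded Brent searches, one variance at a time (a
coarse first sweep over (0, 2], then a refining sweep bracketed around the
current optimum; an optimum near the first-sweep ceiling triggers one
extension toward the hard ceiling of 10).  Wald SEs come from the full
observed information at the mode.  With variances pinned at zero the fit
coincides with a plain Cox model to ≤1e-6 (tested against an independent
Newton-on-partial-likelihood oracle and lifelines).

Seventeen candidate hazard models form the suite at each temporal scale
(daily, seasonal): null; each covariate alone; maternal effects
(mass + severity + mass×severity); non-ideal use (use + risk); ecological
trap (adds use×risk); weather-mediated variants (adds risk×severity); and
hiding-cover variants.  Interactions are products of the standardized main
effects.  Models are ranked by deviance explained — the integrated
log-likelihood minus the log-likelihood of the *fixed* null (no covariates,
no frailty), so the frailty-only null model itself explains deviance — with
χ² = 2 × the difference and df = parameters added.

A known property of this ranking: because fits are (near-)exact maximum
likelihood, a model nested inside another can essentially never outrank its
superset — the superset gains ≥ 0 log-likelihood from each extra parameter
(≈ χ²₁/2 under the null).  Raw deviance-explained ranking therefore favours
the largest nested family member; simulation studies of "which hypothesis
generated the data" should expect the generating model to sit just below
its supersets, separated by less than one log-likelihood unit.

## Spatial mortality prediction

Per year j, the Breslow baseline cumulative hazard at standardized
covariate 0 is accumulated over that year's risk sets (annual cohorts never
share risk sets) using the fitted linear predictor including frailty modes;
S₀ⱼ = exp(−H₀ⱼ) at season end.  Cell survival is S = S₀ⱼ^exp(xβ), with only
the spatially varying covariates (resource-use score, integrated risk)
entering x; cell-constant covariates (birth mass, winter severity, hiding
cover) sit at their sample means, i.e. 0 on the standardized scale.  The
map shows 1 − S linear-stretched to [0, 1] jointly over mapped cells and
years (the stretched quantity is mortality, per the map's interpretation;
the pre-stretch S is emitted for audit).  Within a year the stretched
mortality is strictly rank-monotone in xβ.

## The synthetic study system

The generator produces a full study system with known truth so every stage
is testable offline:

- **Landscape**: seeded multi-class region growth (Eden-type randomized
  accretion from seed pixels with multiplicity proportional to the class
  weights) on a 30 m grid, default 100×100 pixels (3×3 km).  Region growth
  (rather than Gaussian-field thresholding) gives controllable patch counts,
  which the nearest-3-patch covariate needs.  Two roads and two permanent
  water polylines cross the extent as bounded random walks.
- **Predator surfaces**: Gaussian-smoothed white noise through a logistic
  squash, one field per species — smooth, bounded stand-ins for externally
  estimated predator selection maps.  No predator movement is simulated.
- **Weather**: 90-day daily series per winter with a seasonal cosine shape;
  severity levels (mild/moderate/severe) differ in snow depth and minimum
  temperature so annual WSI is ordered severe > moderate > mild, with
  centered values spanning a few hundred index units (severe ≈ +450).
- **Cohorts**: default 42/35/47 fawns across three years; birth dates
  ~N(1 June, 10 d); birth mass ~N(4.1 kg − 0.0025 kg per WSI unit, 0.9 kg)
  truncated above 0.5 kg, so a severe winter depresses cohort mass to
  ≈ 2.9 kg.
- **Telemetry**: per fawn, cells drawn with probability ∝ exp(xβ + b_fawn)
  on the grid's standardized covariates, jittered uniformly within the cell
  (the positional-error model the 2115 m² cell encodes); default 8–40
  relocations per fawn (the field range was 2–89 with median 23; the
  distribution is exposed as a parameter because the field schedule is not
  otherwise specified).  No movement autocorrelation is simulated.
- **Fates**: day-by-day Bernoulli deaths with probability
  h₀·exp(xβ + b_fawn + b_year), a discrete-hazard approximation to the
  continuous model (h ≤ 0.05/day keeps discretization bias under ~3%).
  Default h₀ = 0.029/day with log-hazard coefficients −2.0 (resource-use
  score in [0,1]), +0.45 (integrated risk in [0,4]), −0.35/kg (mass),
  +0.0005 (WSI unit), −0.0003 (centered-mass × WSI), chosen to yield
  ≈ 45–50% seasonal mortality with maternal effects dominant and
  year-ordered survival (severe winter lowest) — the regime the analysis is
  designed for.  The generative interaction uses mass centered at the
  intercept so that the raw-scale product does not penalize heavy cohorts
  in mild winters; the analysis standardizes covariates, which centers mass
  anyway.

What passing tests on this system do *not* show: robustness to telemetry
autocorrelation, irregular relocation schedules, habitat-biased missingness,
cause-specific (competing-risk) mortality, raster misclassification, or
predator surfaces correlated with fawn selection in the adversarial ways
real landscapes produce.  The generator is a correctness harness, not an
ecological simulation.

## Problem sizes and numerical settings

Default synthetic runs use a 3×3 km landscape (≈ 4,200 grid cells), 124
fawns, ~2,900 relocations and ~60–90 deaths; the full pipeline completes in
about two minutes on one core.  Inner Newton solves converge at relative
tolerance 1e-10 (1e-7 while profiling variances); Brent tolerance on each
variance is 0.01 (0.05 on the coarse sweep); variances are reported as 0
below 2e-6.  Linear predictors are max-shifted before exponentiation;
degenerate risk sums return −∞ and are rejected by step-halving.  The
parameter-recovery studies use 5,000 used points (resource selection),
~500 events (Cox coefficient), 50 replicates (Wald coverage) and 25
replicate cohorts of ~72 fawns (suite ranking).

## Data formats

Rasters are read/written as ESRI ASCII grid text, vector lines as WKT (one
geometry per line), and tables as UTF-8 CSV with a header row — plain-text
formats that standard GIS and data tools read directly.  Survival CSVs are
validated row-wise (start < stop, event ∈ {0,1}); rejected rows are reported
with line numbers, and header mappings are configurable for externally
deposited datasets.
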