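# Methods

## Scope and data model

The package analyses two observational designs on free-ranging dogs.

**Census design.** One row per survey polygon: a manually delineated
settlement boundary (1.29–161 ha is treated as the typical range; areas
outside it warn), a settlement stratum (urban = municipality/corporation
town, rural = gram-panchayat village), the dogs observed in a single
standardized walk (sex M/F/U, age class pup/juvenile/adult), and the mapped
food-resource points.  Each resource point carries exactly one of eight
categories with fixed quality/quantity scores: meat/fish shop 8,
eatery/restaurant/hostel 7, direct feeding by humans or NGOs 6, open garbage
dump or occasional carcass 5, tea shop or temple 4, direct feeding through
begging 3, grocery/sweet shop/bakery 2, uncovered household/eatery dustbin 1.
Mixed-use sources must be entered as the single best-fitting category.
*Resource density* = Σ scores / area (score ha⁻¹); *dog density* = dog count
/ area (dogs ha⁻¹), with sex-restricted variants for the sex contrast.  Pups
count in census dog totals.

**Territory design.** One row per group × season (pre-mating: April–early
July; mating: mid-July–mid-October; post-mating pup emergence: late
October–March).  A territory polygon is the convex hull of recorded
marking/defence points — a deterministic, vertex-order-free construction
chosen because only the area feeds the models; ordered boundary walks could
give smaller (non-convex) areas, which is an acknowledged uncertainty.
Adults must be fully sexed (n_adults = n_male + n_female).

## Geometry

All distances and areas are computed on a local planarization of WGS84
coordinates: northings scale latitude offsets by the meridional radius of
curvature M(φ₀) and eastings scale longitude offsets by the prime-vertical
radius N(φ₀) times cos(latitude).  Over the ≤50 km extents of a study site
this keeps pairwise distances within 0.1% of geodesic values (checked
against a Vincenty oracle) and round-trips at sub-millimetre error.  Areas
are planar shoelace areas divided by 10,000 (hectares).  Serialized data are
always WGS84 lon/lat GeoJSON; planar coordinates are in-memory only.

## Territory resource metrics

* **Patch richness** — resource-point count (duplicate coordinates count
  separately).
* **Heterogeneity** — number of distinct categories present, 0–8.
* **Dispersion** — for each point, the mean distance to the other points;
  averaged over points.  With the default N−1 divisor this equals the mean
  pairwise inter-point distance exactly, and two points 10 m apart score
  10 m.  The divisor is configurable (`divisor="n"` shrinks every per-point
  average by (N−1)/N) because either convention appears in field protocols.
  Units are metres.  Undefined below two points: the value is NaN and model
  fitters drop incomplete rows listwise with a logged count.
* **Male:female ratio** — n_male/n_female; NaN (and listwise-dropped) for
  all-male groups, zero for all-female groups.

## Census models

The interaction GLM is a Gamma log-link fit of dog density on resource
density, an urban indicator (rural reference) and their product.  Gamma
variance is φμ²; φ is estimated by Pearson χ²/df and the Wald statistics are
t ratios under the dispersion-adjusted covariance (the `summary.glm`
convention).  Rate ratios are exp(β) with 95% Wald intervals taken on the
log scale and exponentiated.  Zero-dog polygons violate Gamma support and
are dropped with a logged count; adding a small constant instead is
config-exposed (`zero_offset`) but off by default.  The urban slope is
β₁ + β₃ with SE (var₁ + var₃ + 2cov₁₃)^½.

Rank tests use the exact Mann–Whitney null when min(n₁,n₂) ≤ 8 without
ties, otherwise the normal approximation with tie-corrected variance and a
0.5 continuity correction.  Both the U statistic and the first-sample rank
sum are reported.

**Sensitivity analysis.** Power of the two-sided two-sample t test in the
noncentral-t formulation (df = n₁+n₂−2, ncp = d/√(1/n₁+1/n₂)); the inverse
problem (d for a target power) is solved by root bracketing to |Δpower| <
1e-8.  Rank-test equivalents use AUC = Φ(d/√2) and δ = 2·AUC − 1.  For the
realized design (52 vs 41, α = 0.05) the package computes power ≈ 0.81 at
d = 0.6 and AUC ≈ 0.662 at 80% power.

## Territory models

Territory size (ha) and adult count are Gamma log-link GLMs on
{group size, heterogeneity, patch richness, male:female ratio, dispersion}
and {heterogeneity, patch richness, male:female ratio, dispersion, territory
size} respectively.  Predictors without variation are dropped (the fit
degrades gracefully to fewer terms); designs with condition number > 1e8
raise.  LR tests against intercept-only nulls report the raw deviance drop —
the quantity conventionally printed — while the p-value uses the
Pearson-dispersion-scaled drop against χ² (the `anova.glm` convention;
simulation shows the raw drop is grossly miscalibrated for Gamma responses).

**Gamma GLMM.**  Seasonal models use a Gamma log-link mixed model with a
group random intercept, estimated by Laplace-approximate marginal ML
(`glmm.py`).  The conditional mode per group is found by a vectorized Newton
iteration on a strictly concave 1-D objective; the outer optimization (BFGS
then a simplex polish) runs over fixed effects, log group-SD and the
log-dispersion coefficients.  The season factor uses mating as the reference
level, so reported contrasts are post-vs-mating and pre-vs-mating.
Standard errors come from the numerically differentiated observed
information.  The Laplace marginal likelihood was validated against
adaptive and plain Gauss–Hermite quadrature (agreement to <0.05 loglik units
on panel-sized problems, with no detectable difference in test calibration).

A fit whose group SD collapses below 1e-4 is flagged **singular** and
automatically refitted as the fixed-effects-only Gamma model (the same
fallback logic applied to the inter-patch-distance metric, which is
modelled as an OLS on the log response with season as the only predictor,
reporting F(2, n−3) and R²).

**Dispersion submodel.**  For heterogeneity, a constant-dispersion GLMM is
compared against one whose log Gamma dispersion is a season factor
(log φ = γ₀ + γ₁·pre + γ₂·post, i.e. two extra parameters), sharing the mean
structure; the comparison is a 2-df LRT plus AIC/BIC.  Dispersion-submodel
starting values regress log squared relative residuals on the dispersion
design, which lands near the optimum even under strong contrasts.

Information criteria count every estimated parameter: GLMs count
coefficients plus the Gamma shape; GLMMs count fixed effects, the group SD
and the dispersion coefficients.

## Synthetic data generator

The generator exists to make every analysis stage testable end to end; its
defaults encode the study conditions the models assume.

* **Polygons** — star-convex rings with perturbed radii, rescaled to the
  requested area exactly; census areas are drawn uniformly over 1.29–161 ha.
* **Resource layouts** — Poisson, Matérn parent–offspring (clustered) or
  hard-core (regular) point processes inside a polygon; at equal intensity
  the clustered process lowers and the hard-core process raises mean
  inter-point distance, spanning the dispersion gradient.  Categories are
  multinomial draws from per-settlement weight vectors (uniform by default).
* **Census truth** — dog density is drawn from a Gamma with mean
  exp(−0.346 + 0.110·resource − 0.106·resource·urban + 1.169·urban) — the
  fitted interaction-model point estimates as generating truth — and
  dispersion φ = 0.35 (residual CV ≈ 0.6, consistent with the field
  density spreads).  The continuous density is discretized to a whole-dog
  count and the analysis-facing density recomputed as count/area, so the
  stored pair is self-consistent; resource intensities (0.92/2.28 points
  ha⁻¹ rural/urban with lognormal site effects, σ = 0.8) put mean resource
  densities near the observed 4.1/10.3 score ha⁻¹.  Sexes are 50:50 (the
  census found no sex difference); age classes 70/15/15%
  adult/juvenile/pup.
* **Territory truth** — per group: a random intercept (SD 0.423), a layout
  spatial scale (radius 40–130 m) and mean point count (5–25) creating
  between-group spread in dispersion and richness, and a category subset of
  size 2–8 decorrelating heterogeneity from richness (all pairwise metric
  correlations stay below 0.8).  Per season: a fresh layout; an adult count
  from the intercept-only truth exp(1.776) with Gamma dispersion 0.20
  (redrawn each season — independent rows keep the null-effect truth
  testable without pseudoreplication); a sex split from a size-independent
  lognormal target ratio (a binomial split would make extreme ratios a
  small-group artefact and leak group size into the ratio covariate);
  territory area from a Gamma with mean following the published
  territory-size coefficients (−2.788, −0.0006, 0.102, 0.041, 0.391,
  0.0206) plus the group intercept and season effects (pre −0.02, post
  −0.08 on the log scale) and residual dispersion 0.012 (≈11% CV, the
  precision implied by the printed seasonal contrast's z value).  A convex
  territory polygon of that area is placed at the layout centroid (shifted
  onto a resource point if it would contain none).  108 group × season rows
  are thinned at random to the analysed panel size of 84.
* **Direct metric panels** (`gen_metric_panel`) bypass the spatial layer and
  draw a metric straight from the Gamma-GLMM truth with season-specific
  dispersion — the instrument for type-I-error and power studies of the
  dispersion submodel.

What the generator does **not** emulate: spatial autocorrelation between
census sites, territory overlap between neighbouring groups, within-season
resource turnover, observer detectability differences, and the real
between-group covariance of the metrics (defaults were chosen once to
satisfy the documented design checks).  Passing tests therefore demonstrate
the statistical machinery recovers known truths under the assumed
structure, not that the field data meet those assumptions.

## Numerical choices and problem sizes

Simulation-based checks use sizes chosen to balance Monte-Carlo precision
against runtime on a single CPU: census-truth recovery at 2,000 sites (one
fit), territory sign recovery over 200 panel replicates at the analysed
n = 84, dispersion-LRT calibration over 1,000 null replicates and 200
contrast replicates, and quadrature cross-checks on small panels.  The
dispersion-LRT reference is the asymptotic χ²₂; at 36 groups the realized
null rejection rate of the Laplace (or any ML) LRT runs slightly above the
nominal 5% (≈6% in large replications), a finite-sample property of the
likelihood-ratio asymptotics rather than of the implementation.  Power to
detect a ten-fold seasonal dispersion contrast at this design is ≈89–92%:
with one observation per group per season, a near-noiseless observation is
partially absorbed by the group random intercept, which intrinsically
limits identification of season-specific dispersion.

## Known limitations

* The Gamma GLMM uses a Laplace approximation; with very few observations
  per group and extreme dispersion contrasts the marginal ML estimates of
  (group SD, season dispersions) trade off against each other.
* Heterogeneity is an integer count (0–8) modelled as a continuous Gamma
  response, mirroring the published analysis; for territories with zero or
  saturated heterogeneity the Gamma assumption is strained.
* The convex-hull territory construction upper-bounds non-convex
  "boundary-walk" areas.
* GAM-based nonlinearity screening and pseudo-R² variants beyond the basic
  fit statistics are out of scope, as are territory-overlap statistics and
  behavioural movement simulation.
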