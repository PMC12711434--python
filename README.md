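# rdhscape

Resource-dispersion analysis of free-ranging dog populations: a tested,
reusable pipeline for the census- and territory-scale statistics used to
evaluate the **Resource Dispersion Hypothesis (RDH)** in urbanizing
landscapes, driven by a synthetic landscape generator so every stage is
verifiable without field data.

## Who this is for

Behavioural ecologists and urban-wildlife researchers analysing how
anthropogenic food resources shape the space use and social structure of
free-ranging dogs (or comparable facultatively social carnivores).  The RDH
predicts that *territory size* is set by the spatial dispersion of resource
patches while *group size* is set by patch richness, so the two can be
decoupled.  The package implements both halves of a two-scale test:

* **Census scale** — survey polygons stratified urban/rural; food sources
  scored 1–8 by type (open-air meat/fish shop = 8 … uncovered household
  dustbin = 1); *resource density* is the area-standardized score sum
  (score ha⁻¹) and *dog density* is dogs ha⁻¹.  The central model is a
  Gamma GLM with log link,

  ```
  dogs ha⁻¹ ~ resource ha⁻¹ × settlement type
  ```

  with rural as the reference, reported as estimates, Wald *t*, and rate
  ratios exp(β) with 95% CIs; the urban ("combined") slope β₁ + β₃ carries a
  delta-method SE.  Urban–rural contrasts use two-sided Mann–Whitney tests,
  and a sensitivity analysis maps the detectable standardized difference *d*
  (noncentral-*t* power) onto rank-test effect sizes via the normal-shift
  equivalence AUC = Φ(d/√2), Cliff's δ = 2·AUC − 1.

* **Territory scale** — per group × season (pre-mating, mating, post-mating):
  *patch richness* (resource-point count), *heterogeneity* (distinct
  food-source categories, 0–8), and *resource dispersion* (mean inter-point
  distance, metres).  Territory size and adult count are modelled with Gamma
  log-link GLMs (LR-tested against intercept-only nulls), seasonal effects
  with Gamma GLMMs carrying a group random intercept (Laplace ML, implemented
  here), including a season-specific **dispersion submodel**
  (log φ ~ season, 2-df LRT) for heterogeneity and a log-distance OLS
  fallback for the dispersion metric.

## Worked example

```bash
python examples/sensitivity_analysis.py
```

```
design: n1=52, n2=41, alpha=0.05, two-sided
power at d = 0.6:          0.811
d for 80% power:           0.591
Mann-Whitney AUC at that d: 0.662
Cliff's delta:             0.324
```

The census design had ~81% power for a medium standardized urban–rural
difference (d = 0.6); the smallest effect detectable with 80% power
corresponds to AUC ≈ 0.662 — a 66% chance that a random urban site
out-ranks a random rural one.

```bash
python examples/census_analysis.py
```

```
93 sites: 52 rural, 41 urban
dog density (ha^-1): urban mean 2.04 vs rural 1.27; Mann-Whitney U = 1617, p = 2e-05
...
                  term  estimate    se  t_value   p  rate_ratio
      resource_density     0.125 0.021    6.013 0.0       1.133
                 urban     1.243 0.184    6.746 0.0       3.466
resource_density:urban    -0.132 0.023   -5.659 0.0       0.876
urban combined slope = -0.0076 (SE 0.0108)
```

On a synthetic census generated under the published interaction structure,
the fitted rural slope is strongly positive (each unit of resource score per
hectare multiplies mean dog density by ~1.13) while the interaction cancels
it in urban sites — the urban combined slope is statistically flat, the
resource-decoupling signature.

`python examples/territory_analysis.py` runs the full territory model set on
a simulated 36-group × 3-season panel (84 analysed rows) and prints the
territory-size GLM (positive heterogeneity, richness, sex-ratio and
dispersion effects), the null result for adult counts, the seasonal GLMM,
and the heterogeneity dispersion-submodel LRT.

A thin CLI mirrors the library: `rdhscape simulate|score|metrics|census-fit|
territory-fit|power|run` (see `rdhscape --help`); `rdhscape run --seed 1
--out results/` executes the whole pipeline and writes CSV/GeoJSON inputs,
JSON fit tables, a Markdown report and a run manifest with per-stage row
accounting.

## Layout

```
src/rdhscape/
  geometry.py          planarization, polygon area, convex hulls (shapely)
  scoring.py           food-source categories/scores, census densities
  metrics.py           territory records and the three resource metrics
  census_models.py     rank tests, interaction GLM, power panel
  glmm.py              Gamma log-link random-intercept GLMM (Laplace ML)
  territory_models.py  territory/group GLMs, LR tests, seasonal GLMMs,
                       dispersion submodel, log-distance LM
  synthetic.py         landscape, census and panel generators
  io.py                GeoJSON/CSV interchange
  pipeline.py, cli.py  orchestration, report, thin CLI
```

See `docs/methods.md` for the statistical methodology, generator design and
known limitations.
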