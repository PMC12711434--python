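"""Territory-scale analysis on a synthetic group x season panel.

Simulates 36 dog groups over three reproductive seasons (84 analysed rows
after missingness), computes the resource metrics for each territory, and
runs the full model set: territory-size and group-size Gamma GLMs with LR
tests against their intercept-only nulls, the seasonal Gamma GLMM with a
group random intercept, the heterogeneity dispersion-submodel comparison,
and the log inter-patch-distance linear model.
"""

from rdhscape import (
    SimConfig,
    fit_dispersion_model,
    fit_group_glm,
    fit_logdistance_lm,
    fit_null_glm,
    fit_seasonal_glmm,
    fit_territory_glm,
    gen_territory_panel,
    lr_test,
    metrics_frame,
)

cfg = SimConfig(seed=42)
panel = metrics_frame(gen_territory_panel(cfg))
print(f"panel: {len(panel)} group x season rows, {panel.group_id.nunique()} groups")
print(panel[["patch_richness", "heterogeneity", "dispersion", "territory_area"]]
      .describe().loc[["mean", "std", "min", "max"]].round(2).to_string())

ts = fit_territory_glm(panel)
ts_lrt = lr_test(ts, fit_null_glm(panel.dropna(), "territory_area"))
print("\nTerritory size ~ group size + heterogeneity + richness + M:F ratio + dispersion")
print(ts.table().round(4).to_string(index=False))
print(f"LR vs null: delta deviance = {ts_lrt.statistic:.2f} on {ts_lrt.df} df, "
      f"p = {ts_lrt.pvalue:.2g}")

gs = fit_group_glm(panel)
gs_lrt = lr_test(gs, fit_null_glm(panel.dropna(), "n_adults"))
print("\nAdult count model: LR vs null: delta deviance = "
      f"{gs_lrt.statistic:.3f} on {gs_lrt.df} df, p = {gs_lrt.pvalue:.2g}")

season = fit_seasonal_glmm(panel, "territory_area")
print("\nSeasonal GLMM on territory size (reference = mating):")
print(season.table().round(3).to_string(index=False))
print(f"group random-intercept SD = {season.sd_group:.3f}"
      + (" [singular -> fixed-only fallback]" if season.fallback_fixed_only else ""))

const, seasonal, lrt = fit_dispersion_model(panel, "heterogeneity")
print("\nHeterogeneity dispersion submodel (dispersion ~ season):")
print(f"LRT chi2 = {lrt.statistic:.2f} on {lrt.df} df, p = {lrt.pvalue:.2g}; "
      f"AIC {lrt.aic_full:.1f} (seasonal) vs {lrt.aic_null:.1f} (constant)")

ld = fit_logdistance_lm(panel)
print("\nlog inter-patch distance ~ season (LM): "
      f"F({ld.extra['f_df'][0]}, {ld.extra['f_df'][1]}) = {ld.extra['f_statistic']:.2f}, "
      f"p = {ld.extra['f_pvalue']:.2g}, R^2 = {ld.extra['r_squared']:.3f}")
print()
print("Reading: territory size tracks the spatial configuration of resources")
print("(dispersion, richness, heterogeneity) and group sex ratio, while the")
print("adult count tracks none of them - the decoupling the resource")
print("dispersion hypothesis predicts.")
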