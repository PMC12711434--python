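"""Census-scale analysis on a synthetic landscape.

Simulates 93 survey polygons (52 rural, 41 urban) with scored food-resource
points and dog observations, compares densities between settlement types by
rank tests, and fits the interaction Gamma GLM

    dog density ~ resource density x settlement type  (log link)

printing the coefficient table with rate ratios and the urban combined slope.
"""

from rdhscape import SimConfig, fit_census_glm, gen_census, rank_sum_test
from rdhscape.census_models import census_frame, combined_slope

cfg = SimConfig(seed=42)
sites = gen_census(cfg)
df = census_frame(sites)

rural = df[df.settlement == "rural"]
urban = df[df.settlement == "urban"]
print(f"{len(sites)} sites: {len(rural)} rural, {len(urban)} urban")
for col, label in [("dog_density", "dog density (ha^-1)"),
                   ("resource_density", "resource density (score ha^-1)")]:
    r = rank_sum_test(urban[col], rural[col])
    print(f"{label}: urban mean {urban[col].mean():.2f} vs rural {rural[col].mean():.2f}; "
          f"Mann-Whitney U = {r.u:.0f}, p = {r.pvalue:.2g}")

fit = fit_census_glm(sites)
print(f"\nGamma GLM (log link), {fit.n_used} sites used, {fit.n_dropped} dropped:")
print(fit.table().round(3).to_string(index=False))
slope, se = combined_slope(fit, "urban")
print(f"\nurban combined slope = {slope:.4f} (SE {se:.4f})")
print()
print("Reading: the rural resource slope is positive (each extra unit of")
print("resource score per hectare multiplies mean dog density by its rate")
print("ratio), while the interaction cancels it in urban sites - the urban")
print("combined slope is near zero, the resource-decoupling pattern.")
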