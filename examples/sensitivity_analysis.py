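"""Sensitivity analysis for a two-group census design.

With 52 rural and 41 urban survey sites, how large a standardized
urban-rural difference could the study have detected?  Prints the power of
the two-sided two-sample comparison at Cohen's d = 0.6, the d giving 80%
power, and its rank-test equivalents (Mann-Whitney AUC, Cliff's delta)
under the normal-shift equivalence AUC = Phi(d / sqrt(2)).
"""

from rdhscape import PowerSpec, auc_to_cliffs, d_for_power, d_to_auc, two_sample_power

n1, n2, alpha = 52, 41, 0.05

power = two_sample_power(PowerSpec(n1, n2, alpha, d=0.6))
d80 = d_for_power(0.80, n1, n2, alpha)
auc = d_to_auc(d80)

print(f"design: n1={n1}, n2={n2}, alpha={alpha}, two-sided")
print(f"power at d = 0.6:          {power:.3f}")
print(f"d for 80% power:           {d80:.3f}")
print(f"Mann-Whitney AUC at that d: {auc:.3f}")
print(f"Cliff's delta:             {auc_to_cliffs(round(auc, 3)):.3f}")
print()
print("Reading: the design had ~81% power for a medium standardized")
print("difference; an AUC of ~0.66 means the detectable effect corresponds")
print("to a ~66% chance that a random urban site exceeds a random rural one.")
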