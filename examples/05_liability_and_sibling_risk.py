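"""Prevalence sensitivity of the liability conversion, and sibling risk.

The observed-to-liability factor depends on the assumed population
prevalence K; this shows the conversion across a grid of reported
prevalences and expresses a liability heritability as the recurrence-risk
ratio for a first-degree relative.
"""

import numpy as np

from greml import prevalence_sensitivity, sibling_recurrence_risk

# an observed-scale case-control estimate at sample case fraction P
h2_obs, se_obs, P = 0.50, 0.08, 617 / 4733

table = prevalence_sensitivity(h2_obs, se_obs, P,
                               K_grid=[0.003, 0.005, 0.008, 0.012, 0.02, 0.03])
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nThe factor (and hence h2_liab) grows monotonically with K over the")
print("rare-disease range: a rarer disease implies a more extreme threshold.")

for h2, K in [(0.58, 0.008), (0.37, 0.025), (0.43, 0.025)]:
    lam = sibling_recurrence_risk(h2, K, relative_coefficient=0.5)
    print(f"h2_liab={h2:.2f}, K={K:.3f}: sibling recurrence risk lambda = {lam:.1f}")
print("\nlambda = P(sibling affected | proband affected) / K under the")
print("liability-threshold model with additive sharing a = 0.5.")
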