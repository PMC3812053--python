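"""Estimate liability-scale SNP heritability from a simulated case-control study.

Simulates an ascertained sample under the Tourette-like architecture preset
(true liability h2 = 0.58, prevalence K = 0.8%), estimates heritability with
a single-GRM AI-REML fit, and converts the observed-scale estimate to the
liability scale.
"""

from greml import run_univariate, simulate_genotypes, simulate_liability_phenotype
from greml.presets import PRESETS, config_for_preset

preset = PRESETS["TS_GLOBAL"]
cfg = config_for_preset("TS_GLOBAL", n_total=1200, n_snps=3000, seed=1)
panel = simulate_genotypes(cfg)
G, pheno = simulate_liability_phenotype(panel, preset, seed=2)

report = run_univariate(G, pheno.status, K=preset.prevalence_K, n_pcs=0)

print(f"simulated {report.n_cases} cases / {report.n_controls} controls; "
      f"realized population prevalence {pheno.realized_prevalence:.4f}")
print(f"h2 (observed 0/1 scale) = {report.h2_observed:.3f} "
      f"(se {report.se_observed:.3f})")
print(f"liability transform factor at K={report.K}, P={report.P:.3f}: "
      f"{report.factor:.3f}")
print(f"h2 (liability scale)    = {report.h2_liab:.3f} (se {report.se_liab:.3f})")
print(f"LRT vs no-genetics model = {report.lrt:.2f}, "
      f"p = {report.p_mixture:.2e} (boundary mixture)")
print("\nThe liability estimate is the share of disease-liability variance the")
print("SNP panel explains; it should sit near the preset's 0.58 up to Monte-")
print("Carlo error and the REML ascertainment bias discussed in the docs.")
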