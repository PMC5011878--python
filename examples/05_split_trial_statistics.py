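"""Analyse a simulated split-nitrogen genotype trial.

Simulates crown-root elongation (ER_Cr) for 24 genotypes x 4 replicates at
the published study's conditions (26 % mean reduction under low N, genotypic
variance only on the high-N side), fits the genotype x nitrogen mixed model
with a random slide term and per-N residual variances, and reports the Wald
tests, per-stratum heritability and a Tukey HSD for the treatment means.
"""

from rhizoslides import (
    ModelSpec,
    TrialConfig,
    estimate_heritability,
    fit_mixed,
    mse_from_avsed,
    simulate_trial_tables,
    tukey_hsd,
)

table, truths = simulate_trial_tables(TrialConfig(traits=("ER_Cr",)), seed=4)
df = table.subset("ER_Cr")
mean_high = df.loc[df.n_level == "high", "value"].mean()
mean_low = df.loc[df.n_level == "low", "value"].mean()
print(f"mean ER_Cr: high N {mean_high:.3f} cm/d, low N {mean_low:.3f} cm/d "
      f"({(1 - mean_low / mean_high) * 100:.1f} % reduction)")

fit = fit_mixed(table, ModelSpec(response="ER_Cr"))
print("\nWald F tests (sqrt scale):")
print(fit.anova.to_string(index=False,
                          float_format=lambda v: f"{v:.4g}"))
print("\nvariance components:", {k: round(v, 5) for k, v in fit.varcomp.items()})

for lvl in ("high", "low"):
    h = estimate_heritability(table, "ER_Cr", lvl)
    print(f"h2({lvl:4s}) = {h.h2:.3f}   (sigma2_g {h.vc.sigma2_g:.5f}, "
          f"sigma2_e {h.vc.sigma2_e:.5f}, r {h.vc.r})")

q = 2.80  # studentised-range critical value chosen by the analyst
hsd = tukey_hsd(q, mse_from_avsed(fit.avsed, n=2), n=2)
print(f"\nTukey HSD for the two N means (q = {q}): {hsd:.4f} (sqrt scale)")
print("Heritable elongation under high N but not low N means selection for")
print("N foraging must score roots in the nutrient-rich compartment.")
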