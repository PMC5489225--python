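"""Power of the variance test as a G-by-E screen.

Along a grid of interaction effect sizes delta (z-units per allele in the
exposed stratum), measures how often interaction SNPs reach P_v < 0.05 and
P_int < 0.05, and the odds ratio of P_int < 0.05 given P_v < 0.05 — the
quantity that says "variance-prioritized SNPs are enriched for detectable
interactions"."""

import vqscreen as vq

base = vq.ArchitectureSpec(m_snps=150, maf_range=(0.25, 0.5),
                           prop_effect=0.0, prop_interaction=0.05,
                           delta_scale=0.1, error_family="normal")
res = vq.run_power_study(base, n=2000, delta_grid=[0.0, 0.3, 0.6, 0.9],
                         replicates=6, seed=8)
cols = ["delta", "power_pv", "power_pint", "power_both",
        "or_pint_given_pv", "or_ci_low", "or_ci_high"]
print(res[cols].round(3).to_string(index=False))
print("\ndelta = 0 rows stay near the 0.05 false-positive rate; with real "
      "interactions both tests gain power and the OR rises above 1, i.e. "
      "screening on P_v enriches for SNPs whose interaction test will fire.")
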