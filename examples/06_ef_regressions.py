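"""Hierarchical regressions of broadband symptoms on executive functioning.

Step 1: sex + previous-wave internalizing/externalizing aggregates.
Step 2: + all eight wave-1 EF measures (|z|>=4 outliers removed).
"""

from panelnet import (CohortSpec, broadband_aggregates, filter_ef_table,
                      hierarchical_compare, simulate_cohort)

spec = CohortSpec(n_persons=2000, seed=6)
truth, panel, ef = simulate_cohort(spec)
ef = filter_ef_table(ef, threshold=4.0)
symptoms = broadband_aggregates(panel)

for target in ("internalizing", "externalizing"):
    comp = hierarchical_compare(symptoms, ef, target=target, wave=2)
    fl = comp.step2.coefficients.set_index("term").loc["fluct_tempo"]
    print(f"{target:13s} wave 2:  R2 {comp.step1.r2:.3f} -> "
          f"{comp.step2.r2:.3f} (delta {comp.delta_r2:.4f});  "
          f"fluct_tempo beta={fl['std_estimate']:.3f} (p={fl['p']:.3f})")

print("\nEF measures add almost no variance beyond previous-wave symptoms")
print("(small delta R2) and the sustained-attention coefficient sits in the")
print("weak-effect band — the regime the synthetic cohort is built to")
print("emulate. Estimation is FIML, so attrited persons still contribute.")
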