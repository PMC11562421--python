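"""Panel graphical VAR: within/between decomposition with model search.

Detrends and standardizes the panel, fits the saturated panel GVAR by FIML,
prunes and step-up searches the network parameters at alpha=.05, and prints
the resulting fit indices and temporal hub.
"""

import numpy as np

from panelnet import (CohortSpec, detrend_and_standardize, fit_indices,
                      fit_saturated_gvar, prune_stepup, simulate_cohort,
                      strength_in_out)

spec = CohortSpec(n_persons=1500, seed=4)
truth, panel, _ = simulate_cohort(spec)
det = detrend_and_standardize(panel)

sat = fit_saturated_gvar(det, n_starts=2, seed=0)
pruned, trace = prune_stepup(sat, alpha=0.05)
fit = fit_indices(pruned.loglik, pruned.n_params, pruned.stats)

n_pruned = sum(1 for t in trace if t["step"] == "prune")
n_added = sum(1 for t in trace if t["step"] == "step-up")
print(f"saturated logL {sat.loglik:.1f} -> pruned logL {pruned.loglik:.1f}")
print(f"model search: {n_pruned} parameters pruned, {n_added} re-added")
print(f"fit: chi2={fit.chi2:.1f} (df={fit.df}), RMSEA={fit.rmsea:.3f}, "
      f"CFI={fit.cfi:.3f}, TLI={fit.tli:.3f}")

cent = strength_in_out(pruned.params.B.T, node_names=det.variable_names)
top = cent.table.sort_values("out_strength", ascending=False).iloc[0]
print(f"temporal hub: {top.node} (out-strength {top.out_strength:.2f})")

print("\nRMSEA near 0 and CFI/TLI near 1 say the pruned sparse structure")
print("reproduces the stacked-wave covariance; the temporal network is the")
print("within-person lag-1 matrix, cleaned of trait-level confounding by")
print("the random-intercept (between-person) component.")
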