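"""Cross-lagged panel network between consecutive waves.

Node-wise LASSO with 10-fold cross-validated penalties; out-strength ranks
which symptoms predict the rest of the network one wave later.
"""

from panelnet import CohortSpec, estimate_clpn, simulate_cohort, strength_in_out

spec = CohortSpec(n_persons=1500, seed=3)
truth, panel, _ = simulate_cohort(spec)

net = estimate_clpn(panel, 1, 2, k=10, seed=30)
print(f"wave 1 -> 2 network on n={net.n_used} complete cases, "
      f"{int((net.weights != 0).sum())} nonzero coefficients")

cent = strength_in_out(net.weights, node_names=net.node_names)
top = cent.table.sort_values("out_strength", ascending=False).head(3)
print("top out-strength (influence on the next wave):")
for r in top.itertuples():
    print(f"  {r.node:9s} out={r.out_strength:.2f} in={r.in_strength:.2f}")

print("\nEdges are standardized lag-1 regression coefficients controlling")
print("for all other nodes; the planted hub (depressive problems) shows the")
print("highest out-strength, the 'catalyst symptom' pattern.")
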