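"""Case-dropping bootstrap stability of CLPN centrality.

Re-estimates the wave 1->2 network on person subsamples and reports how far
cases can be dropped before centrality stops correlating with the
full-sample result.
"""

import numpy as np

from panelnet import (CohortSpec, case_drop_bootstrap, estimate_clpn,
                      simulate_cohort, strength_in_out)

spec = CohortSpec(n_persons=800, p=6, seed=5)
truth, panel, _ = simulate_cohort(spec)


def estimator(data):
    return estimate_clpn(data, 1, 2, seed=50)


def metric(net):
    tab = strength_in_out(net.weights)
    return np.concatenate([tab["in_strength"], tab["out_strength"]])


res = case_drop_bootstrap(panel, estimator, metric,
                          proportions=(0.1, 0.25, 0.4), n_boot=30, seed=5)
for q in res.drop_proportions:
    r = res.correlations[float(q)]
    print(f"drop {q:.2f}: mean correlation with full sample {np.mean(r):.2f}")
print(f"CS coefficient: {res.cs_coefficient}")

print("\nThe CS coefficient is the largest drop proportion at which >=95%")
print("of bootstraps still correlate >=0.7 with the full-sample centrality;")
print("values >=0.25 are conventionally read as adequate stability.")
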