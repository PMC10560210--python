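"""Co-extinction simulation: how fast does a layer collapse under targeting?

Removes chaperones one at a time under four ordering scenarios; a client
goes extinct with its last chaperone. T is the area under the curve of
surviving clients vs removed chaperones: low T = fast collapse.
"""

import numpy as np

from ccinet import generate_nested_multilayer, robustness_suite
from ccinet.robustness import removal_order, robustness_T, simulate_extinctions

net = generate_nested_multilayer(n_chaperones=15, n_clients=300, n_layers=4, seed=0)
layer = net.incidence[:, :, 0]

order = removal_order(layer, net.chaperone_ids, "degree")
curve = simulate_extinctions(layer, net.chaperone_ids, order, "degree")
print("degree-targeted removal of layer env0:")
print("  removed fraction:", np.round(curve.x[::5], 2).tolist())
print("  surviving clients:", np.round(curve.y[::5], 3).tolist())
print(f"  T = {robustness_T(curve):.4f}")

labels = np.array([0] * 8 + [1] * 7)  # two modules for the modular scenarios
table = robustness_suite(net, labels, n_random_reps=50, seed=1)
print("\nmean T per scenario over all layers:")
print(table.groupby("scenario")["T"].mean().round(4).to_string())
print("\nRemoving hubs first (degree order, or the hub-heavy module first) "
      "collapses the network faster than random removal (lower T); starting "
      "with the low-degree module delays the collapse instead.")
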