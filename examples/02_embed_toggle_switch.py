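"""Embedding a toggle switch in a random network erodes its switch behavior.

Generates one random 5-node, E:2N background with an embedded toggle switch,
simulates the randomized-parameter ensemble, and compares the motif metrics
with a random pair of background nodes (the control showing the signature is
specific to the motif).  The motif's in-degree profile is printed because the
total number of incoming edges on the motif — not network size — is what
drives the loss of canonical dynamics.
"""

import numpy as np

import motifres as mr
from motifres.analysis import random_node_control

topo = mr.generate_embedded_network("TS", order_n=5, connectivity_x=2, seed=8)
prof = mr.in_degree_profile(topo)
print(f"network: {topo.n_nodes} nodes, {topo.n_edges} edges; "
      f"in_A={prof['in_A']}, in_B={prof['in_B']}, in_TS={prof['in_motif']}")

table = mr.simulate_ensemble(topo, n_models=1000, n_init=20, seed=9, t_max=300)
rec = mr.compute_metrics(table)
print(f"motif nodes   : CC(A,B) {rec['CC_AB']:+.3f}  F1 {rec['F1']:.3f}  "
      f"BiC_A {rec['BiC_A']:.3f}")

ctrl = random_node_control(table, np.random.default_rng(10))
print(f"control nodes ({ctrl['nodes']}): CC {ctrl['CC_AB']:+.3f}  "
      f"F1 {ctrl['F1']:.3f}")
print("The motif pair stays strongly anti-correlated while an arbitrary "
      "background pair does not; raising the motif's in-degree erases this "
      "distinction (see examples/04).")
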