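"""Causal density and global efficiency on hand-built directed networks."""

import numpy as np

from spikegc import causal_density, global_efficiency
from spikegc.granger import GCNetwork


def net(F):
    F = np.asarray(F, dtype=float)
    return GCNetwork(node_ids=list(range(F.shape[0])), F=F, pvalues=None,
                     sig_mask=F > 0, window_center=0.0, space_tag="original")


full = net(np.ones((4, 4)) - np.eye(4))
print(f"complete 4-node graph: Cd = {causal_density(full)} (all 12 ordered pairs connected)")

w = 2.0
complete = net(w * (np.ones((5, 5)) - np.eye(5)))
print(f"complete graph, all weights {w}: E = {global_efficiency(complete)} "
      "(direct edge 1/w always beats any 2-hop path)")

chain = np.zeros((3, 3))
chain[1, 0] = 2.0   # a -> b, strength 2 (edge length 1/2)
chain[2, 1] = 2.0   # b -> c
print(f"3-node chain a->b->c: E = {global_efficiency(net(chain)):.4f} "
      "(= (2 + 2 + 1)/6 = 5/6; a reaches c through b with path length 1)")

sparse = net(np.diag([0.0, 0.0, 0.0]))
print(f"empty network: E = {global_efficiency(sparse)} (no pair is reachable)")
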