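"""Generate a random regulatory network topology and inspect it.

Builds a 40-gene Erdős–Rényi network at density 0.05 with regulatory
strengths drawn from U(-3, 3), then prints its structural summary.  The
edge count equals round(0.05 * 40 * 39) = 78; the skeleton is connected and
the diagonal is zero (no autoregulation).
"""

import numpy as np

from noisenet import generate_topology, node_strengths

graph = generate_topology("ER", n_genes=40, density=0.05, seed=7)
strengths = node_strengths(graph)

print(f"model: {graph.topology_model}, genes: {graph.n_genes}, "
      f"directed edges: {graph.n_edges}")
print(f"connected skeleton: {graph.skeleton_connected()}")
nz = graph.weights[graph.weights != 0]
print(f"weight range: [{nz.min():.2f}, {nz.max():.2f}]  "
      f"(activators: {(nz > 0).sum()}, repressors: {(nz < 0).sum()})")
top = strengths.sort_values("outstrength", ascending=False).head(3)
print("\nstrongest regulators (outstrength = sum of outgoing |w|):")
print(top.to_string(index=False))
# A gene's instrength measures how strongly it is regulated; outstrength
# how strongly it regulates others.  Both drive where selection on
# expression noise falls later in the pipeline.
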