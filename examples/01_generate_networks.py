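"""Build the arenas: synthetic networks and edge-list round trips.

Generates a Barabasi-Albert and an Erdos-Renyi graph with the same target
mean degree, prints their summary statistics, and shows the plain-text
edge-list IO with low-degree pruning (the preprocessing applied to
empirical communication networks before benchmarking).
"""

import tempfile
from pathlib import Path

from epiloc import generate_ba, generate_er, graph_stats, prune_low_degree, \
    read_edge_list, write_edge_list

ba = generate_ba(1000, 8, seed=0)
er = generate_er(1000, 8, seed=0)
for name, g in [("Barabasi-Albert", ba), ("Erdos-Renyi", er)]:
    s = graph_stats(g)
    print(f"{name}: N={s.n_nodes} E={s.n_edges} <k>={s.mean_degree:.2f} "
          f"connected={s.connected}")
# BA is scale-free: its hubs have far larger degree than the ER maximum
print("max degree  BA:", max(d for _, d in ba.g.degree()),
      " ER:", max(d for _, d in er.g.degree()))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "ba.edges"
    write_edge_list(ba, path)
    back = read_edge_list(path)
    print("round trip: N", back.node_count, "E", back.edge_count)

# iterative pruning removes degree-<2 nodes until none remain (cascading)
pruned = prune_low_degree(er, min_degree=2)
print(f"after pruning k<2: N={pruned.node_count} "
      f"(removed {er.node_count - pruned.node_count} nodes)")
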