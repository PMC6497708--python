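"""Equilibrium selection under the reinforcement-learning dynamics.

Two classic topologies: a star whose hub prefers action A (the hub should
dictate the equilibrium) and two 5-cliques joined by a single bridge with
opposite within-clique preference majorities (communities should settle on
different actions).
"""

import numpy as np

from netcoord import EXPERIMENT, PreferenceAssignment, batch_simulate, within_cluster_homogeneity
from netcoord.networks import Network
import networkx as nx


def build(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return Network(g)


# --- star: hub (node 0) prefers A, 3 A-types vs 3 B-types overall
star = build(6, [(0, i) for i in range(1, 6)])
star_prefs = PreferenceAssignment({0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "B"})
traces = batch_simulate(star, star_prefs, EXPERIMENT, rounds=20, replicates=200, seed=11)
all_a = sum((t.actions[:, -1] == "A").all() for t in traces)
all_b = sum((t.actions[:, -1] == "B").all() for t in traces)
print(f"star, hub prefers A: {all_a} replicates end all-A vs {all_b} all-B (of 200)")
print("  -> the high-degree hub dictates which equilibrium is selected\n")

# --- two bridged 5-cliques with opposite preference majorities
edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
edges += [(4, 5)]
cliques = build(10, edges)
clique_prefs = PreferenceAssignment(
    {0: "A", 1: "A", 2: "A", 3: "A", 4: "B", 5: "B", 6: "B", 7: "B", 8: "B", 9: "A"}
)
partition = [list(range(5)), list(range(5, 10))]
traces = batch_simulate(cliques, clique_prefs, EXPERIMENT, rounds=20, replicates=200, seed=13)
within, between = zip(*(within_cluster_homogeneity(t, partition) for t in traces))
print(
    f"bridged cliques: mean last-5-rounds agreement within communities "
    f"{np.mean(within):.2f}, between communities {np.mean(between):.2f}"
)
print("  -> behavior is homogeneous inside each community, heterogeneous across")
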