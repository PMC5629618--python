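"""Assemble a signaling subnetwork by shortest-path linking on a toy interactome.

Sources (disease genes or drug targets) are linked to each activated TF by a
shortest path over the unweighted PPI graph; up-regulated TF targets hang off
their TF as regulatory edges. Linker genes are interactome genes recruited
only because they lie on a retained path.
"""

import networkx as nx

import moarank as mr
from moarank.io import Interactome

g = nx.Graph()
g.add_edges_from([
    ("EGFR", "GRB2"), ("GRB2", "SOS1"), ("SOS1", "HRAS"), ("HRAS", "RAF1"),
    ("RAF1", "MAP2K1"), ("MAP2K1", "MAPK1"), ("MAPK1", "JUN"),
    ("EGFR", "SHC1"), ("SHC1", "GRB2"),  # a parallel, equally short route
    ("JUN", "CCND1"),
])
interactome = Interactome(graph=g)

net = mr.build_signaling_network(
    interactome,
    sources={"EGFR"},
    tfs={"JUN"},
    reg_targets={"CCND1"},
    tfmap={"JUN": {"CCND1"}},
    tie_break="lexicographic",
)

print(f"network: {net.n_nodes} nodes, {net.n_edges} edges")
for n in sorted(net.nodes):
    print(f"  {n:8s} roles={sorted(net.roles(n))}")
print("regulatory edges:", [tuple(sorted(e)) for e in net.edges_of_kind("regulatory")])
# EGFR reaches JUN through one deterministic shortest path (GRB2 beats SHC1
# lexicographically where both routes are equally short); CCND1 joins as a
# regulated target of JUN.
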