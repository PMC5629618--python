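"""Shared test utilities: independent brute-force oracles and tiny builders."""

from __future__ import annotations

import hashlib
from pathlib import Path

import networkx as nx
import numpy as np

from moarank.netbuild import SignalingNetwork
from moarank.scoring import RankedList


def all_shortest_paths_bruteforce(g: nx.Graph, src: str, dst: str) -> list[list[str]]:
    """Every shortest path by exhaustive simple-path enumeration (DFS).

    Independent of the package's BFS-based search; only for tiny graphs.
    """
    if src == dst:
        return [[src]]
    best: list[list[str]] = []
    best_len = [len(g) + 1]

    def walk(node: str, path: list[str]) -> None:
        if len(path) - 1 > best_len[0]:
            return
        for nb in g[node]:
            if nb in path:
                continue
            if nb == dst:
                plen = len(path)  # edge count of path + [nb]
                if plen < best_len[0]:
                    best_len[0] = plen
                    best.clear()
                if plen == best_len[0]:
                    best.append(path + [nb])
            else:
                walk(nb, path + [nb])

    walk(src, [src])
    return best


def random_connected_graph(rng: np.random.Generator, n_nodes: int) -> nx.Graph:
    """Small connected Erdos-Renyi-style graph with gene-symbol-like labels."""
    labels = [f"G{i:02d}" for i in range(n_nodes)]
    while True:
        g = nx.Graph()
        g.add_nodes_from(labels)
        p = min(1.0, 2.5 / max(n_nodes - 1, 1))
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < p:
                    g.add_edge(labels[i], labels[j])
        if nx.is_connected(g):
            return g


def make_network(
    node_roles: dict[str, set[str]],
    edges: list[tuple[str, str, str]] = (),
    provenance: dict | None = None,
) -> SignalingNetwork:
    g = nx.Graph()
    for n, roles in node_roles.items():
        g.add_node(n, roles=set(roles))
    for a, b, kind in edges:
        g.add_edge(a, b, kind=kind)
    return SignalingNetwork(graph=g, provenance=provenance or {})


def hash_tree(path: Path) -> dict[str, str]:
    out = {}
    for f in sorted(Path(path).rglob("*")):
        if f.is_file():
            out[str(f.relative_to(path))] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out


# Printed worked example: the ten screening-active drugs among the top-30
# ranked drugs of a prostate-cancer cell-line study — (rank, drug,
# sensitivity score, growth-inhibition rate on the screened line).
TOP30_ACTIVES = [
    (1, "Staurosporine", 0.468, -16.375),
    (4, "Docetaxel", 0.265, 18.695),
    (6, "Paclitaxel", 0.257, 1.426),
    (7, "Auranofin", 0.255, -63.994),
    (12, "Bortezomib", 0.245, -74.068),
    (13, "Cladribine", 0.244, 2.411),
    (15, "Dactinomycin", 0.236, -15.905),
    (19, "Homoharringtonine", 0.226, -42.758),
    (21, "Digoxin", 0.205, -71.924),
    (30, "Etoposide", 0.188, 43.669),
]

ACTIVE_CUTOFF = 54.57  # growth rate <= mean - 1.5 sd over the full screen
N_RANKED = 402  # screened drugs with both target info and expression profiles
N_ACTIVE_IN_RANKING = 26


def reconstruct_ranking(
    n_total: int = N_RANKED, n_active: int = N_ACTIVE_IN_RANKING
) -> tuple[RankedList, dict[str, float]]:
    """Rebuild a full ranking + screening rates consistent with the printed
    worked example: the ten named actives at their printed ranks and scores,
    the remaining actives placed far down the list, filler drugs with
    interpolated scores and clearly inactive growth rates."""
    known = {r: (name, score) for r, name, score, _ in TOP30_ACTIVES}
    xs = [r for r, *_ in TOP30_ACTIVES] + [n_total]
    ys = [s for _, _, s, _ in TOP30_ACTIVES] + [0.0]
    extra_active_ranks = set(range(301, 301 + (n_active - len(TOP30_ACTIVES))))
    entries = []
    rates: dict[str, float] = {}
    for r in range(1, n_total + 1):
        if r in known:
            name, score = known[r]
            rates[name] = dict((n, g) for _, n, _, g in TOP30_ACTIVES)[name]
        else:
            score = float(np.interp(r, xs, ys))
            if r in extra_active_ranks:
                name = f"ExtraActive{r}"
                rates[name] = 40.0  # below the active cutoff
            else:
                name = f"Inactive{r}"
                rates[name] = 80.0
        entries.append((r, name, score))
    return RankedList(entries=entries), rates
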