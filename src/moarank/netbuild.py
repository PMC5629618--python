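"""Signaling-subnetwork construction by shortest-path linking.

A signaling network (patient Pnet or per-drug-instance MoAnet) is assembled by
mapping three gene sets onto the protein-protein interactome — *sources*
(disease-associated genes or drug targets), *activated TFs*, and the TFs'
*up-regulated target genes* — then linking every (source, TF) pair by a
shortest path over the unweighted interactome and attaching each up-regulated
target to its regulating TF with a regulatory edge. Interactome edges carry
unit cost, so Dijkstra's algorithm reduces to breadth-first search.

Node roles (``source``, ``linker``, ``tf``, ``target``) are non-exclusive and
accumulate; edges are flagged ``ppi`` (on a retained shortest path) or
``regulatory`` (TF -> up-regulated target, inserted even when the pair is not
an interactome edge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import networkx as nx

from .io import DrugCatalog, ExpressionMatrix, Interactome, InstanceProfileSet, TFTargetMap
from .tfactivity import (
    DEFAULT_THRESHOLD,
    FoldChangeProfile,
    compute_fold_change,
    identify_activated_tfs,
    upregulated_targets,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SignalingNetwork",
    "map_to_interactome",
    "shortest_path",
    "build_signaling_network",
    "build_pnet",
    "build_moanet",
]

TieBreak = Literal["lexicographic", "all"]


@dataclass
class SignalingNetwork:
    """A Pnet or MoAnet: role-annotated node set plus flagged edge set.

    ``graph`` nodes carry a ``roles`` set attribute; edges carry a ``kind``
    attribute (``ppi`` | ``regulatory``). ``provenance`` records the network
    label (``pnet`` | ``moanet``) and, for a MoAnet, the drug id, instance id
    and cell line it came from.
    """

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def roles(self, gene: str) -> set[str]:
        return set(self.graph.nodes[gene].get("roles", set()))

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if role in d.get("roles", set())}

    def edges_of_kind(self, kind: str) -> set[frozenset[str]]:
        return {
            frozenset((a, b))
            for a, b, d in self.graph.edges(data=True)
            if d.get("kind") == kind
        }


def map_to_interactome(
    genes: Iterable[str], net: Interactome
) -> tuple[set[str], set[str]]:
    """Intersect a gene set with the interactome's node set.

    Returns ``(mapped, dropped)``; an empty mapped set is only a warning —
    the caller decides whether that is fatal.
    """
    genes = set(genes)
    mapped = genes & net.nodes
    dropped = genes - mapped
    if dropped:
        logger.info("dropped %d genes absent from the interactome", len(dropped))
    if genes and not mapped:
        logger.warning("none of the %d genes map onto the interactome", len(genes))
    return mapped, dropped


def _lex_shortest_path(
    g: nx.Graph, src: str, dist_to_dst: Mapping[str, int]
) -> list[str]:
    """Lexicographically smallest shortest path from ``src`` toward the node
    the distance map was built from, by greedy minimal-neighbor descent."""
    path = [src]
    cur = src
    while dist_to_dst[cur] > 0:
        cur = min(n for n in g[cur] if dist_to_dst.get(n, -1) == dist_to_dst[cur] - 1)
        path.append(cur)
    return path


def shortest_path(
    net: Interactome,
    src: str,
    dst: str,
    tie_break: TieBreak = "lexicographic",
) -> list[list[str]]:
    """Shortest path(s) between two interactome genes (unit edge cost).

    ``lexicographic`` returns a single deterministic path — the
    lexicographically smallest node sequence among all shortest paths;
    ``all`` returns every shortest path. An unreachable pair yields ``[]``.
    ``src == dst`` yields the single-node path.
    """
    g = net.graph
    for n in (src, dst):
        if n not in g:
            raise KeyError(f"gene {n!r} not in interactome")
    if src == dst:
        return [[src]]
    if tie_break == "all":
        if not nx.has_path(g, src, dst):
            return []
        return [list(p) for p in nx.all_shortest_paths(g, src, dst)]
    dist = nx.single_source_shortest_path_length(g, dst)
    if src not in dist:
        return []
    return [_lex_shortest_path(g, src, dist)]


def _add_path(g: nx.Graph, path: list[str], src: str, dst: str) -> None:
    for n in path:
        if n not in g:
            g.add_node(n, roles=set())
    g.nodes[src]["roles"].add("source")
    g.nodes[dst]["roles"].add("tf")
    for n in path[1:-1]:
        g.nodes[n]["roles"].add("linker")
    for a, b in zip(path, path[1:]):
        g.add_edge(a, b, kind="ppi")


def build_signaling_network(
    net: Interactome,
    sources: Iterable[str],
    tfs: Iterable[str],
    reg_targets: Iterable[str],
    tfmap: TFTargetMap | Mapping[str, set[str]] | None = None,
    tie_break: TieBreak = "lexicographic",
    max_path_len: int | None = None,
) -> SignalingNetwork:
    """Assemble a signaling subnetwork from sources, TFs and regulated targets.

    All three sets are first mapped onto the interactome (unmapped genes are
    excluded, with a log entry). Every connected (source, TF) pair contributes
    its shortest path(s); intermediate nodes get the ``linker`` role and path
    edges the ``ppi`` flag. Each (TF, regulated target) pair from ``tfmap``
    becomes a ``regulatory`` edge, inserted whether or not the interactome
    contains it. A source that is itself a TF carries both roles with no
    self-path. Raises if no (source, TF) pair is connected.

    ``max_path_len`` optionally drops paths longer than the cap (edge count).
    """
    g_in = net.graph
    sources_m, s_drop = map_to_interactome(sources, net)
    tfs_m, t_drop = map_to_interactome(tfs, net)
    targets_m, r_drop = map_to_interactome(reg_targets, net)
    if not sources_m or not tfs_m:
        raise ValueError(
            "no sources or no TFs map onto the interactome "
            f"(dropped sources: {sorted(s_drop)}, dropped TFs: {sorted(t_drop)})"
        )

    out = nx.Graph()
    n_unreachable = 0
    connected = False
    for tf in sorted(tfs_m):
        dist = nx.single_source_shortest_path_length(g_in, tf)
        for src in sorted(sources_m):
            if src == tf:
                # same gene in both roles: include it, no self-path
                if src not in out:
                    out.add_node(src, roles=set())
                out.nodes[src]["roles"].update(("source", "tf"))
                connected = True
                continue
            if src not in dist:
                n_unreachable += 1
                continue
            if max_path_len is not None and dist[src] > max_path_len:
                n_unreachable += 1
                continue
            if tie_break == "all":
                paths = [list(p) for p in nx.all_shortest_paths(g_in, src, tf)]
            else:
                paths = [_lex_shortest_path(g_in, src, dist)]
            for path in paths:
                _add_path(out, path, src=path[0], dst=path[-1])
            connected = True
    if n_unreachable:
        logger.info("%d (source, TF) pairs unreachable or over the path cap", n_unreachable)
    if not connected:
        raise ValueError("no (source, TF) pair is connected: empty core network")

    # regulatory layer: TF -> up-regulated target, for TFs present in the core
    if targets_m and tfmap is not None:
        reg_map = tfmap.targets if isinstance(tfmap, TFTargetMap) else tfmap
        for tf in sorted(set(out.nodes) & tfs_m):
            for tgt in sorted(set(reg_map.get(tf, ())) & targets_m):
                if tgt == tf:
                    continue
                if tgt not in out:
                    out.add_node(tgt, roles=set())
                out.nodes[tgt]["roles"].add("target")
                if not out.has_edge(tf, tgt):
                    out.add_edge(tf, tgt, kind="regulatory")
    elif targets_m and tfmap is None:
        logger.warning(
            "regulated targets given without a TF-target map; no regulatory edges added"
        )

    return SignalingNetwork(graph=out, provenance={"label": "signaling"})


def build_pnet(
    expr: ExpressionMatrix,
    interactome: Interactome,
    tfmap: TFTargetMap,
    disease_genes: Iterable[str],
    tf_threshold: float = DEFAULT_THRESHOLD,
    fc_threshold: float = DEFAULT_THRESHOLD,
    tie_break: TieBreak = "lexicographic",
    max_path_len: int | None = None,
) -> SignalingNetwork:
    """Patient disease signaling network: disease genes as sources, TFs
    activated in the case/control fold-change profile, and their up-regulated
    (fold change >= ``fc_threshold``) target genes."""
    profile = compute_fold_change(expr)
    activations = identify_activated_tfs(profile, tfmap, threshold=tf_threshold)
    active = [a for a in activations if a.activated]
    if not active:
        raise ValueError("no transcription factor is activated; cannot build Pnet")
    up = upregulated_targets(active, profile, tfmap, fc_threshold=fc_threshold)
    net = build_signaling_network(
        interactome,
        sources=disease_genes,
        tfs=[a.tf for a in active],
        reg_targets=up,
        tfmap=tfmap,
        tie_break=tie_break,
        max_path_len=max_path_len,
    )
    net.provenance = {"label": "pnet"}
    return net


def build_moanet(
    instances: InstanceProfileSet,
    instance_id: str,
    interactome: Interactome,
    tfmap: TFTargetMap,
    catalog: DrugCatalog,
    tf_threshold: float = DEFAULT_THRESHOLD,
    z_threshold: float = DEFAULT_THRESHOLD,
    tie_break: TieBreak = "lexicographic",
    max_path_len: int | None = None,
) -> SignalingNetwork | None:
    """Mechanism-of-action network of one drug instance.

    Sources are the drug's catalog targets; TF activation and target
    up-regulation are computed from the instance's z-score profile (z-scores
    standing in for fold changes). Returns ``None`` — with a log entry — when
    the instance cannot yield a network (drug absent from the catalog, drug
    without targets, no activated TF, or nothing connects).
    """
    meta = instances.metadata.loc[instance_id]
    drug_id = meta["drug_id"]
    if drug_id not in catalog:
        logger.info("instance %s skipped: drug %s not in catalog", instance_id, drug_id)
        return None
    record = catalog[drug_id]
    if not record.targets:
        logger.info("instance %s skipped: drug %s has no targets", instance_id, drug_id)
        return None

    profile = FoldChangeProfile(values=instances.profile(instance_id), mode="zscore")
    activations = identify_activated_tfs(profile, tfmap, threshold=tf_threshold)
    active = [a for a in activations if a.activated]
    if not active:
        logger.info("instance %s skipped: no activated TF", instance_id)
        return None
    up = upregulated_targets(active, profile, tfmap, fc_threshold=z_threshold)
    try:
        net = build_signaling_network(
            interactome,
            sources=record.targets,
            tfs=[a.tf for a in active],
            reg_targets=up,
            tfmap=tfmap,
            tie_break=tie_break,
            max_path_len=max_path_len,
        )
    except ValueError as exc:
        logger.info("instance %s skipped: %s", instance_id, exc)
        return None
    net.provenance = {
        "label": "moanet",
        "drug_id": drug_id,
        "instance_id": instance_id,
        "cell_line": meta["cell_line"],
    }
    return net
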