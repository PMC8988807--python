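"""Spectra Similarity Molecular Network (SSMN) construction and filters.

Nodes are protonated-representative consensus spectra; edges connect pairs
whose (modified-)cosine similarity reaches a minimum score with enough
matched peaks. Topology filters then tame hub nodes (degree cap), split
oversized connected components (component-size cap), and prune
media-background (BED) nodes and singletons. Default parameters: minimum
edge cosine 0.6, maximum degree 15, maximum component size 200.

All filters are deterministic: edge removals iterate offending nodes in
node-id order and break score ties lexicographically, so identical input
and configuration yield byte-identical edge lists.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import networkx as nx

from .node_builder import Node
from .similarity import DEFAULT_FRAG_TOL, cosine_similarity

__all__ = [
    "build_ssmn",
    "degree_cap_filter",
    "component_size_filter",
    "mutual_top_k_filter",
    "prune_bed_and_singletons",
    "write_edge_list",
    "write_components",
]

DEFAULT_MIN_COSINE = 0.6
DEFAULT_MAX_DEGREE = 15
DEFAULT_MAX_COMPONENT_SIZE = 200
DEFAULT_MIN_MATCHED = 4  # peaks; guards against spurious single-peak edges


def build_ssmn(
    nodes: Sequence[Node],
    min_cosine: float = DEFAULT_MIN_COSINE,
    frag_tol: float = DEFAULT_FRAG_TOL,
    allow_shift: bool = True,
    min_matched: int = DEFAULT_MIN_MATCHED,
) -> nx.Graph:
    """Score all node pairs and keep edges with cosine >= ``min_cosine`` and
    at least ``min_matched`` matched peak pairs."""
    if not 0.0 <= min_cosine <= 1.0:
        raise ValueError(f"min_cosine must be in [0, 1], got {min_cosine}")
    graph = nx.Graph()
    ordered = sorted(nodes, key=lambda n: n.node_id)
    for node in ordered:
        graph.add_node(node.node_id, mz=node.precursor_mz, rt=node.rt)
    for i, u in enumerate(ordered):
        if len(u.consensus) == 0:
            continue
        for v in ordered[i + 1 :]:
            if len(v.consensus) == 0:
                continue
            result = cosine_similarity(
                u.consensus, v.consensus, frag_tol=frag_tol, allow_shift=allow_shift
            )
            if result.score >= min_cosine and result.n_matched >= min_matched:
                graph.add_edge(u.node_id, v.node_id, cosine=result.score)
    return graph


def _sorted_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def degree_cap_filter(graph: nx.Graph, max_degree: int = DEFAULT_MAX_DEGREE) -> nx.Graph:
    """Enforce a hard degree cap.

    While any node exceeds ``max_degree``, visit offending nodes in node-id
    order and remove that node's lowest-scoring incident edge (score ties
    broken by lexicographic neighbor id). Returns a filtered copy.
    """
    if max_degree < 1:
        raise ValueError(f"max_degree must be >= 1, got {max_degree}")
    g = graph.copy()
    while True:
        offenders = sorted(n for n in g.nodes if g.degree(n) > max_degree)
        if not offenders:
            return g
        node = offenders[0]
        victim = min(
            g.edges(node, data=True),
            key=lambda e: (e[2]["cosine"], e[1]),
        )
        g.remove_edge(victim[0], victim[1])


def component_size_filter(
    graph: nx.Graph, max_size: int = DEFAULT_MAX_COMPONENT_SIZE
) -> nx.Graph:
    """Split oversized connected components.

    While any component exceeds ``max_size``, remove the lowest-scoring edge
    inside the offending component (ties broken by lexicographic edge id;
    components processed in order of their smallest node id). Returns a
    filtered copy.
    """
    if max_size < 1:
        raise ValueError(f"max_size must be >= 1, got {max_size}")
    g = graph.copy()
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_size]
        if not oversized:
            return g
        component = min(oversized, key=min)
        victim = min(
            (
                (data["cosine"], *_sorted_edge(u, v))
                for u, v, data in g.edges(component, data=True)
            ),
        )
        g.remove_edge(victim[1], victim[2])


def mutual_top_k_filter(graph: nx.Graph, k: int = DEFAULT_MAX_DEGREE) -> nx.Graph:
    """Alternative neighbor limit: keep an edge only when each endpoint ranks
    it among its own ``k`` highest-scoring edges (mutual top-K)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    keep: dict[str, set[tuple[str, str]]] = {}
    for node in graph.nodes:
        ranked = sorted(
            graph.edges(node, data=True),
            key=lambda e: (-e[2]["cosine"], e[1]),
        )[:k]
        keep[node] = {_sorted_edge(u, v) for u, v, _ in ranked}
    g = graph.copy()
    for u, v in list(g.edges):
        edge = _sorted_edge(u, v)
        if edge not in keep[u] or edge not in keep[v]:
            g.remove_edge(u, v)
    return g


def prune_bed_and_singletons(graph: nx.Graph, nodes: Sequence[Node]) -> nx.Graph:
    """Remove BED-detected (culture-media) nodes with their incident edges,
    then remove nodes left without any connection. Applied once, in that
    order."""
    flags = {n.node_id: n.bed_detected for n in nodes}
    g = graph.copy()
    bed = [n for n in g.nodes if flags.get(n, False)]
    g.remove_nodes_from(bed)
    singletons = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(singletons)
    return g


def write_edge_list(graph: nx.Graph, path: str | Path, score_key: str = "cosine") -> Path:
    """Deterministic edge-list CSV (source,target,<score_key>)."""
    path = Path(path)
    rows = sorted(
        (_sorted_edge(u, v) + (data.get(score_key, ""),))
        for u, v, data in graph.edges(data=True)
    )
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", score_key])
        for u, v, score in rows:
            writer.writerow(
                [u, v, f"{score:.6f}" if isinstance(score, float) else score]
            )
    return path


def write_components(graph: nx.Graph, path: str | Path) -> Path:
    """Component-membership CSV (node_id,component)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "component"])
        components = sorted(nx.connected_components(graph), key=min)
        for idx, comp in enumerate(components):
            for node in sorted(comp):
                writer.writerow([node, idx])
    return path
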