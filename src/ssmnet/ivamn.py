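"""Ionization Variant Annotation Molecular Network (IVAMN).

Links nodes that are alternative ionization forms of one compound —
adducts ([M+Na]+, [M+NH4]+), the M+1 isotopologue and the [2M+H]+ dimer —
based on co-elution plus exact adduct mass arithmetic. The connected
components ("variant groups") are then used to (a) pick one protonated
representative per compound and (b) remove blank-derived contaminants
together with their first immediate network neighbors.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import networkx as nx

from .mass_calc import PROTONATED, AdductRule, DEFAULT_ADDUCT_RULES
from .node_builder import Node

__all__ = [
    "build_ivamn",
    "variant_groups",
    "select_protonated_representatives",
    "remove_blank_contaminants",
]

DEFAULT_IVAMN_PREC_TOL = 0.01  # Da; adduct arithmetic is exact, keep tight
DEFAULT_IVAMN_RT_TOL = 0.1  # minutes; true ionization variants co-elute


def _rule_pair_residual(
    mz_u: float, mz_v: float, rule_u: AdductRule, rule_v: AdductRule
) -> float:
    """Residual of explaining (mz_u, mz_v) as (rule_u, rule_v) of one neutral
    mass: infer M exactly from u under rule_u and measure v's deviation."""
    m = rule_u.neutral_mass(mz_u)
    return abs(mz_v - rule_v.mz(m))


def build_ivamn(
    nodes: Sequence[Node],
    rules: Sequence[AdductRule] = DEFAULT_ADDUCT_RULES,
    prec_tol: float = DEFAULT_IVAMN_PREC_TOL,
    rt_tol: float = DEFAULT_IVAMN_RT_TOL,
) -> nx.Graph:
    """Build the ionization-variant network over ``nodes``.

    An undirected edge (u, v) is added when the nodes co-elute
    (|Δrt| <= rt_tol) and some ordered pair of distinct rules explains both
    m/z values as ionizations of a single neutral mass within ``prec_tol``.
    When several rule pairs fit, the one with the smallest residual wins.
    Edges carry ``rule`` ("<rule_u>~<rule_v>" oriented from the stored
    ``source``), ``rule_u``, ``rule_v`` and ``residual`` attributes.
    """
    if not rules:
        raise ValueError("rule set must be non-empty")
    if prec_tol < 0 or rt_tol < 0:
        raise ValueError("tolerances must be >= 0")
    graph = nx.Graph()
    for node in nodes:
        graph.add_node(node.node_id, mz=node.precursor_mz, rt=node.rt)
    ordered = sorted(nodes, key=lambda n: n.node_id)
    for u, v in itertools.combinations(ordered, 2):
        if abs(u.rt - v.rt) > rt_tol:
            continue
        best: tuple[float, AdductRule, AdductRule] | None = None
        for rule_u, rule_v in itertools.permutations(rules, 2):
            residual = min(
                _rule_pair_residual(u.precursor_mz, v.precursor_mz, rule_u, rule_v),
                _rule_pair_residual(v.precursor_mz, u.precursor_mz, rule_v, rule_u),
            )
            if residual <= prec_tol and (best is None or residual < best[0]):
                best = (residual, rule_u, rule_v)
        if best is not None:
            residual, rule_u, rule_v = best
            graph.add_edge(
                u.node_id,
                v.node_id,
                rule=f"{rule_u.name}~{rule_v.name}",
                rule_u=rule_u.name,
                rule_v=rule_v.name,
                source=u.node_id,
                target=v.node_id,
                residual=residual,
            )
    return graph


def variant_groups(graph: nx.Graph) -> list[set[str]]:
    """Connected components of the IVAMN, sorted by smallest member id."""
    return sorted(nx.connected_components(graph), key=min)


def select_protonated_representatives(
    graph: nx.Graph,
    nodes: Sequence[Node],
    rules: Sequence[AdductRule] = DEFAULT_ADDUCT_RULES,
    prec_tol: float = DEFAULT_IVAMN_PREC_TOL,
) -> list[Node]:
    """Flag exactly one protonated representative per variant group, in place.

    For every node in a group, hypothesise it is the [M+H]+ ion and count
    how many other group members are explained as some other rule applied to
    the implied neutral mass. The node explaining the most members wins
    (ties: larger total MS1 area, then node id). Singleton groups flag
    themselves; groups with no resolvable [M+H]+ fall back to the
    highest-total-area node.
    """
    by_id = {n.node_id: n for n in nodes}
    missing = set(graph.nodes) - set(by_id)
    if missing:
        raise ValueError(f"graph contains node ids not in the node list: {sorted(missing)}")
    for node in nodes:
        node.protonated_representative = False
    others = [r for r in rules if r.name != PROTONATED.name]
    flagged: list[Node] = []
    for group in variant_groups(graph):
        members = [by_id[i] for i in sorted(group)]
        if len(members) == 1:
            members[0].protonated_representative = True
            flagged.append(members[0])
            continue
        scored = []
        for cand in members:
            m = PROTONATED.neutral_mass(cand.precursor_mz)
            explained = sum(
                1
                for other in members
                if other is not cand
                and any(
                    abs(other.precursor_mz - rule.mz(m)) <= prec_tol for rule in others
                )
            )
            scored.append((-explained, -cand.total_area, cand.node_id, cand))
        scored.sort(key=lambda t: t[:3])
        best = scored[0]
        if -best[0] == 0:
            # No member is consistent with [M+H]+: fall back to abundance.
            best = min(scored, key=lambda t: (t[1], t[2]))
        best[3].protonated_representative = True
        flagged.append(best[3])
    return flagged


def remove_blank_contaminants(
    graph: nx.Graph, nodes: Sequence[Node]
) -> list[Node]:
    """Drop blank-detected nodes and their first IVAMN neighbors.

    Returns the surviving nodes; requires ``blank_detected`` flags to be set
    (see :func:`ssmnet.node_builder.set_detection_flags`).
    """
    by_id = {n.node_id: n for n in nodes}
    missing = set(graph.nodes) - set(by_id)
    if missing:
        raise ValueError(f"graph contains node ids not in the node list: {sorted(missing)}")
    blank = {n.node_id for n in nodes if n.blank_detected}
    neighbors = {m for b in blank if b in graph for m in graph.neighbors(b)}
    removed = blank | neighbors
    return [n for n in nodes if n.node_id not in removed]
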