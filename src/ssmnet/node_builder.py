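"""Cluster raw MS/MS spectra into consensus nodes and build count tables.

Spectra that co-elute (|Δrt| <= rt_tol), share a precursor
(|Δm/z| <= prec_tol) and look alike (cosine >= min_cosine) are grouped by
single linkage into one node per compound-ionization form. Each node
carries a consensus spectrum plus per-sample MS1-area and spectrum-count
vectors, and flags recording whether the node was detected in any BLANK or
BED sample — the basis for downstream contaminant and media-background
removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import DEFAULT_FRAG_TOL, cosine_similarity
from .spectra_io import Group, Peak, SampleRecord, Spectrum

__all__ = [
    "Node",
    "cluster_spectra",
    "consensus_spectrum",
    "build_count_table",
    "set_detection_flags",
]


@dataclass
class Node:
    """A consensus MS/MS feature with per-sample quantification."""

    node_id: str
    consensus: Spectrum
    member_ids: tuple[str, ...]
    area_by_sample: dict[str, float] = field(default_factory=dict)
    count_by_sample: dict[str, int] = field(default_factory=dict)
    blank_detected: bool = False
    bed_detected: bool = False
    protonated_representative: bool = False

    @property
    def precursor_mz(self) -> float:
        return self.consensus.precursor_mz

    @property
    def rt(self) -> float:
        return self.consensus.rt

    @property
    def total_area(self) -> float:
        return float(sum(self.area_by_sample.values()))


def consensus_spectrum(
    members: Sequence[Spectrum], frag_tol: float = DEFAULT_FRAG_TOL
) -> Spectrum:
    """Merge member spectra into one consensus.

    Fragment peaks within ``frag_tol`` of each other (chained along ascending
    m/z) are merged to an intensity-weighted mean m/z with summed intensity;
    the consensus precursor is the intensity-weighted mean of member
    precursors and the retention time is the plain mean.
    """
    if not members:
        raise ValueError("cannot build a consensus of zero spectra")
    if len(members) == 1:
        return members[0]
    all_peaks = sorted(
        (p for s in members for p in s.peaks), key=lambda p: p.mz
    )
    merged: list[Peak] = []
    group_mz: list[float] = []
    group_int: list[float] = []

    def flush() -> None:
        total = sum(group_int)
        if total > 0:
            mz = float(np.average(group_mz, weights=group_int))
        else:
            mz = float(np.mean(group_mz))
        merged.append(Peak(mz, total))

    for p in all_peaks:
        if group_mz and p.mz - group_mz[-1] > frag_tol:
            flush()
            group_mz, group_int = [], []
        group_mz.append(p.mz)
        group_int.append(p.intensity)
    if group_mz:
        flush()

    tic = np.array([sum(p.intensity for p in s.peaks) for s in members])
    weights = tic if tic.sum() > 0 else np.ones(len(members))
    precursor = float(
        np.average([s.precursor_mz for s in members], weights=weights)
    )
    rt = float(np.mean([s.rt for s in members]))
    return Spectrum(
        spectrum_id="consensus",
        precursor_mz=precursor,
        peaks=tuple(merged),
        rt=rt,
        charge=members[0].charge,
    )


def cluster_spectra(
    spectra: Sequence[Spectrum],
    prec_tol: float = 0.05,
    rt_tol: float = 0.2,
    min_cosine: float = 0.6,
    frag_tol: float = DEFAULT_FRAG_TOL,
) -> list[Node]:
    """Single-linkage clustering of spectra into nodes.

    Two spectra are linked when |Δprecursor| <= prec_tol, |Δrt| <= rt_tol
    and their (direct) cosine similarity >= min_cosine. Every spectrum ends
    up in exactly one node. The result is invariant to input order: spectra
    are processed sorted by (precursor m/z, rt, spectrum_id) and node ids
    are assigned in that order.
    """
    if prec_tol < 0 or rt_tol < 0:
        raise ValueError("tolerances must be >= 0")
    order = sorted(spectra, key=lambda s: (s.precursor_mz, s.rt, s.spectrum_id))
    n = len(order)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    # Sliding window over the precursor-sorted list keeps this near-linear
    # for well-separated features.
    for i in range(n):
        j = i + 1
        while j < n and order[j].precursor_mz - order[i].precursor_mz <= prec_tol:
            if abs(order[j].rt - order[i].rt) <= rt_tol and find(i) != find(j):
                if (
                    len(order[i]) > 0
                    and len(order[j]) > 0
                    and cosine_similarity(
                        order[i], order[j], frag_tol=frag_tol
                    ).score
                    >= min_cosine
                ):
                    union(i, j)
            j += 1

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    nodes: list[Node] = []
    for idx, root in enumerate(sorted(groups)):
        members = [order[i] for i in groups[root]]
        members.sort(key=lambda s: s.spectrum_id)
        cons = consensus_spectrum(members, frag_tol=frag_tol)
        area: dict[str, float] = {}
        count: dict[str, int] = {}
        for s in members:
            area[s.sample_id] = area.get(s.sample_id, 0.0) + s.ms1_area
            count[s.sample_id] = count.get(s.sample_id, 0) + 1
        nodes.append(
            Node(
                node_id=f"N{idx:05d}",
                consensus=cons,
                member_ids=tuple(s.spectrum_id for s in members),
                area_by_sample=area,
                count_by_sample=count,
            )
        )
    return nodes


def set_detection_flags(
    nodes: Iterable[Node],
    manifest: Sequence[SampleRecord],
    min_blank_relative_area: float = 0.0,
) -> None:
    """Set ``blank_detected`` / ``bed_detected`` flags in place.

    A node is blank-detected when it has any spectrum count in a BLANK
    sample (and, if ``min_blank_relative_area`` > 0, its summed BLANK area is
    at least that fraction of its total area); analogously for BED samples.
    Raises ``ValueError`` when a node references a sample id absent from the
    manifest.
    """
    by_group: dict[Group, set[str]] = {g: set() for g in Group}
    known: set[str] = set()
    for rec in manifest:
        by_group[rec.group].add(rec.sample_id)
        known.add(rec.sample_id)
    for node in nodes:
        unknown = set(node.count_by_sample) - known
        if unknown:
            raise ValueError(
                f"node {node.node_id} references unknown sample ids {sorted(unknown)}"
            )
        for group, attr in ((Group.BLANK, "blank_detected"), (Group.BED, "bed_detected")):
            sample_ids = by_group[group]
            detected = any(
                node.count_by_sample.get(s, 0) > 0 for s in sample_ids
            )
            if detected and min_blank_relative_area > 0 and node.total_area > 0:
                group_area = sum(node.area_by_sample.get(s, 0.0) for s in sample_ids)
                detected = group_area >= min_blank_relative_area * node.total_area
            setattr(node, attr, detected)


def build_count_table(
    nodes: Sequence[Node], manifest: Sequence[SampleRecord]
) -> pd.DataFrame:
    """One row per node: id, precursor m/z, rt, flags, then per-sample area
    and count columns (``area_<sample>``, ``count_<sample>``)."""
    set_detection_flags(nodes, manifest)
    sample_ids = [r.sample_id for r in manifest]
    rows = []
    for node in nodes:
        row: dict[str, object] = {
            "node_id": node.node_id,
            "mz": node.precursor_mz,
            "rt_min": node.rt,
            "protonated_representative": int(node.protonated_representative),
            "blank_detected": node.blank_detected,
            "bed_detected": node.bed_detected,
        }
        for sid in sample_ids:
            row[f"area_{sid}"] = node.area_by_sample.get(sid, 0.0)
            row[f"count_{sid}"] = node.count_by_sample.get(sid, 0)
        rows.append(row)
    return pd.DataFrame(rows)
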