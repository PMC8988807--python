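"""Condition comparison of node abundances.

Per-node MS1 areas are normalised row-wise by each node's maximum area, the
detection profiles are compared by cosine similarity (the heat-map matrix,
with an average-linkage leaf order for rendering), and per-condition means
are turned into pseudo-counted fold changes with up/down/unchanged flags.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .node_builder import Node
from .spectra_io import Group, SampleRecord

__all__ = [
    "abundance_matrix",
    "normalize_by_row_max",
    "profile_similarity_matrix",
    "condition_fold_change",
    "per_sample_detection",
]


def abundance_matrix(
    nodes: Sequence[Node], manifest: Sequence[SampleRecord], groups: tuple[Group, ...] = (Group.SAMPLE,)
) -> pd.DataFrame:
    """Node x sample matrix of MS1 areas, restricted to the given groups."""
    sample_ids = [r.sample_id for r in manifest if r.group in groups]
    data = {
        node.node_id: [node.area_by_sample.get(s, 0.0) for s in sample_ids]
        for node in nodes
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=sample_ids)


def normalize_by_row_max(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its maximum; all-zero rows are left unchanged.

    After normalization every detected node has maximum exactly 1.0 across
    samples, so profiles compare detection patterns rather than raw yields.
    """
    if (matrix.values < 0).any():
        raise ValueError("abundance values must be non-negative")
    row_max = matrix.max(axis=1)
    divisor = row_max.replace(0.0, 1.0)
    return matrix.div(divisor, axis=0)


def profile_similarity_matrix(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Node x node cosine similarity of (normalised) row profiles.

    Zero rows get similarity 0 against every other node and 1 with
    themselves. Also returns the average-linkage hierarchical-clustering
    leaf order on 1 - cosine distance, for heat-map rendering.
    """
    values = matrix.to_numpy(dtype=float)
    norms = np.linalg.norm(values, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = values / safe[:, None]
    sim = unit @ unit.T
    sim = np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    sim[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(sim, 1.0)
    sim_df = pd.DataFrame(sim, index=matrix.index, columns=matrix.index)

    if len(matrix) > 1:
        dist = np.clip(1.0 - sim, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        linkage = average(squareform(dist, checks=False))
        order = [matrix.index[i] for i in leaves_list(linkage)]
    else:
        order = list(matrix.index)
    return sim_df, order


def condition_fold_change(
    matrix: pd.DataFrame,
    condition_map: Mapping[str, str],
    reference: str,
    pseudo: float | None = None,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-node fold change of mean area in each condition vs ``reference``.

    ``fold_change = (mean_cond + pseudo) / (mean_ref + pseudo)``; the pseudo
    count (default 5% of the smallest nonzero area in the matrix) keeps
    absences finite. Flags: ``up`` when fold change >= threshold, ``down``
    when <= 1/threshold, else ``unchanged``.
    """
    conditions = sorted(set(condition_map.values()))
    if reference not in conditions:
        raise ValueError(
            f"unknown reference condition {reference!r}; available: {conditions}"
        )
    if pseudo is None:
        nonzero = matrix.values[matrix.values > 0]
        pseudo = 0.05 * float(nonzero.min()) if nonzero.size else 1.0
    samples_by_condition = {
        cond: [s for s in matrix.columns if condition_map.get(s) == cond]
        for cond in conditions
    }
    means = pd.DataFrame(
        {
            cond: matrix[cols].mean(axis=1) if cols else 0.0
            for cond, cols in samples_by_condition.items()
        }
    )
    rows = []
    for node_id, node_means in means.iterrows():
        ref_mean = node_means[reference]
        for cond in conditions:
            if cond == reference:
                continue
            fc = (node_means[cond] + pseudo) / (ref_mean + pseudo)
            if fc >= threshold:
                flag = "up"
            elif fc <= 1.0 / threshold:
                flag = "down"
            else:
                flag = "unchanged"
            rows.append(
                {
                    "node_id": node_id,
                    "condition": cond,
                    "mean_area": node_means[cond],
                    "reference_mean_area": ref_mean,
                    "fold_change": fc,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def per_sample_detection(
    nodes: Sequence[Node], manifest: Sequence[SampleRecord]
) -> pd.DataFrame:
    """Per node and sample: detection flag and area, plus the sample's group
    and condition — the numeric data behind per-sample ring/pie charts."""
    rows = []
    for node in nodes:
        for rec in manifest:
            count = node.count_by_sample.get(rec.sample_id, 0)
            rows.append(
                {
                    "node_id": node.node_id,
                    "sample_id": rec.sample_id,
                    "group": rec.group.value,
                    "condition": rec.condition,
                    "detected": count > 0,
                    "count": count,
                    "area": node.area_by_sample.get(rec.sample_id, 0.0),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "node_id",
            "sample_id",
            "group",
            "condition",
            "detected",
            "count",
            "area",
        ],
    )
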