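"""End-to-end orchestration of the molecular-networking analysis.

Stage order: read manifest and MGFs → restrict fragments to the acquisition
m/z range → cluster spectra into nodes → count tables → ionization-variant
network (IVAMN) → blank-contaminant removal with first-neighbor propagation
→ protonated-representative selection → spectra-similarity network (SSMN)
→ degree cap → component-size split → BED/singleton pruning → differential
tables → extracted-ion chromatograms for the configured target m/z list.

Every intermediate is written to the output directory and a JSON run log
records the parameters and per-stage node counts, which telescope:
clustered >= post-blank-removal >= representatives >= SSMN nodes >=
post-prune nodes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd
import yaml

from . import differential, ivamn as ivamn_mod, node_builder, ssmn as ssmn_mod
from .mass_calc import DEFAULT_ADDUCT_RULES, extract_eic, read_ms1_csv, write_eic_csv
from .node_builder import Node
from .spectra_io import Group, SampleRecord, read_manifest, read_mgf, filter_scan_range

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters with the published defaults where one exists
    (minimum edge cosine 0.6, maximum degree 15, maximum component size 200,
    EIC window ±0.01 Da, acquisition range 30–2,000 Da)."""

    manifest: str = "manifest.csv"
    output_dir: str = "ssmn_output"
    ms1_csv: str | None = None  # optional MS1 peak table for EICs

    min_mz: float = 30.0
    max_mz: float = 2000.0

    cluster_prec_tol: float = 0.05
    cluster_rt_tol: float = 0.2
    cluster_min_cosine: float = 0.6
    frag_tol: float = 0.025

    ivamn_prec_tol: float = 0.01
    ivamn_rt_tol: float = 0.1
    min_blank_relative_area: float = 0.0

    ssmn_min_cosine: float = 0.6
    ssmn_min_matched: int = 4
    ssmn_allow_shift: bool = True
    max_degree: int = 15
    max_component_size: int = 200
    degree_filter: str = "cap"  # "cap" (hard degree cap) or "mutual_top_k"
    prune_bed: bool = True

    fold_reference: str | None = None  # default: first condition in manifest
    fold_threshold: float = 2.0
    fold_pseudo: float | None = None

    eic_targets: tuple[float, ...] = (401.26, 399.25, 345.20, 343.19)
    eic_tol: float = 0.01

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["eic_targets"] = list(self.eic_targets)
        with path.open("w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "eic_targets" in d:
            d["eic_targets"] = tuple(d["eic_targets"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Handles to every stage product of one run."""

    config: PipelineConfig
    manifest: list[SampleRecord]
    nodes: list[Node]  # all clustered nodes, flags set
    ivamn: nx.Graph  # over all nodes
    survivors: list[Node]  # after blank removal
    representatives: list[Node]  # flagged protonated representatives
    ssmn_raw: nx.Graph  # before topology filters
    ssmn: nx.Graph  # after degree cap, component split, pruning
    count_table: pd.DataFrame
    abundance: pd.DataFrame
    normalized: pd.DataFrame
    profile_similarity: pd.DataFrame
    fold_table: pd.DataFrame
    detection_table: pd.DataFrame
    fold_reference: str
    eics: dict[float, dict[str, list[tuple[float, float]]]]
    counts: dict[str, int]
    output_dir: Path


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # ---- read ----
    manifest_path = Path(config.manifest)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    spectra = []
    for rec in manifest:
        mgf_path = base / rec.file_path
        if not mgf_path.exists():
            raise PipelineError("read", f"manifest file not found: {mgf_path}")
        for s in read_mgf(mgf_path):
            s.sample_id = s.sample_id or rec.sample_id
            spectra.append(s)
    counts["spectra_read"] = len(spectra)

    # ---- scan-range filter ----
    spectra = filter_scan_range(spectra, config.min_mz, config.max_mz)
    counts["spectra_in_range"] = len(spectra)

    # ---- cluster ----
    nodes = node_builder.cluster_spectra(
        spectra,
        prec_tol=config.cluster_prec_tol,
        rt_tol=config.cluster_rt_tol,
        min_cosine=config.cluster_min_cosine,
        frag_tol=config.frag_tol,
    )
    counts["nodes_clustered"] = len(nodes)

    # ---- count tables & flags ----
    node_builder.set_detection_flags(
        nodes, manifest, min_blank_relative_area=config.min_blank_relative_area
    )

    # ---- IVAMN ----
    ivamn_graph = ivamn_mod.build_ivamn(
        nodes,
        rules=DEFAULT_ADDUCT_RULES,
        prec_tol=config.ivamn_prec_tol,
        rt_tol=config.ivamn_rt_tol,
    )
    counts["ivamn_edges"] = ivamn_graph.number_of_edges()

    # ---- blank removal ----
    survivors = ivamn_mod.remove_blank_contaminants(ivamn_graph, nodes)
    counts["nodes_post_blank_removal"] = len(survivors)

    # ---- representative selection ----
    surviving_graph = ivamn_graph.subgraph([n.node_id for n in survivors])
    representatives = ivamn_mod.select_protonated_representatives(
        surviving_graph, survivors, prec_tol=config.ivamn_prec_tol
    )
    counts["protonated_representatives"] = len(representatives)

    # ---- SSMN ----
    ssmn_raw = ssmn_mod.build_ssmn(
        representatives,
        min_cosine=config.ssmn_min_cosine,
        frag_tol=config.frag_tol,
        allow_shift=config.ssmn_allow_shift,
        min_matched=config.ssmn_min_matched,
    )
    counts["ssmn_nodes_raw"] = ssmn_raw.number_of_nodes()
    counts["ssmn_edges_raw"] = ssmn_raw.number_of_edges()

    if config.degree_filter == "mutual_top_k":
        filtered = ssmn_mod.mutual_top_k_filter(ssmn_raw, config.max_degree)
    else:
        filtered = ssmn_mod.degree_cap_filter(ssmn_raw, config.max_degree)
    filtered = ssmn_mod.component_size_filter(filtered, config.max_component_size)
    if config.prune_bed:
        filtered = ssmn_mod.prune_bed_and_singletons(filtered, representatives)
    counts["ssmn_nodes_final"] = filtered.number_of_nodes()
    counts["ssmn_edges_final"] = filtered.number_of_edges()

    # ---- differential ----
    conditions = [r.condition for r in manifest if r.group is Group.SAMPLE]
    if not conditions:
        raise PipelineError("differential", "manifest contains no SAMPLE rows")
    fold_reference = config.fold_reference or conditions[0]
    condition_map = {
        r.sample_id: r.condition for r in manifest if r.group is Group.SAMPLE
    }
    abundance = differential.abundance_matrix(representatives, manifest)
    normalized = differential.normalize_by_row_max(abundance)
    if len(normalized):
        profile_sim, leaf_order = differential.profile_similarity_matrix(normalized)
    else:
        profile_sim, leaf_order = normalized.copy(), []
    fold_table = differential.condition_fold_change(
        abundance,
        condition_map,
        reference=fold_reference,
        pseudo=config.fold_pseudo,
        threshold=config.fold_threshold,
    )
    detection = differential.per_sample_detection(representatives, manifest)

    # ---- EICs ----
    eics: dict[float, dict[str, list[tuple[float, float]]]] = {}
    ms1_csv = config.ms1_csv
    if ms1_csv is None:
        candidate = base / "ms1.csv"
        ms1_csv = str(candidate) if candidate.exists() else None
    if ms1_csv is not None:
        scans_by_sample = read_ms1_csv(ms1_csv)
        for target in config.eic_targets:
            eics[target] = {
                sid: extract_eic(scans, target, config.eic_tol)
                for sid, scans in scans_by_sample.items()
            }

    # ---- write outputs ----
    count_table = node_builder.build_count_table(nodes, manifest)
    rep_flags = {n.node_id for n in representatives if n.protonated_representative}
    count_table["protonated_representative"] = (
        count_table["node_id"].isin(rep_flags).astype(int)
    )
    count_table.to_csv(out / "node_count_table.csv", index=False)
    ssmn_mod.write_edge_list(ivamn_graph, out / "ivamn_edges.csv", score_key="rule")
    nx.write_graphml(ivamn_graph, out / "ivamn.graphml")
    pd.Series(sorted(n.node_id for n in survivors)).to_csv(
        out / "survivors.csv", index=False, header=["node_id"]
    )
    ssmn_mod.write_edge_list(ssmn_raw, out / "ssmn_raw_edges.csv")
    ssmn_mod.write_edge_list(filtered, out / "ssmn_edges.csv")
    nx.write_graphml(filtered, out / "ssmn.graphml")
    ssmn_mod.write_components(filtered, out / "ssmn_components.csv")
    abundance.to_csv(out / "abundance.csv", index_label="node_id")
    normalized.to_csv(out / "abundance_normalized.csv", index_label="node_id")
    profile_sim.to_csv(out / "profile_similarity.csv", index_label="node_id")
    (out / "profile_leaf_order.csv").write_text(
        "node_id\n" + "".join(f"{n}\n" for n in leaf_order), encoding="utf-8"
    )
    fold_table.to_csv(out / "fold_change.csv", index=False)
    detection.to_csv(out / "per_sample_detection.csv", index=False)
    for target, traces in eics.items():
        write_eic_csv(traces, out / f"eic_{target:.2f}.csv")

    run_log = {
        "parameters": {**asdict(config), "eic_targets": list(config.eic_targets)},
        "fold_reference": fold_reference,
        "counts": counts,
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    return PipelineResult(
        config=config,
        manifest=manifest,
        nodes=nodes,
        ivamn=ivamn_graph,
        survivors=survivors,
        representatives=representatives,
        ssmn_raw=ssmn_raw,
        ssmn=filtered,
        count_table=count_table,
        abundance=abundance,
        normalized=normalized,
        profile_similarity=profile_sim,
        fold_table=fold_table,
        detection_table=detection,
        fold_reference=fold_reference,
        eics=eics,
        counts=counts,
        output_dir=out,
    )
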