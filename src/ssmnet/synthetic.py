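"""Synthetic OSMAC-style LC-MS/MS experiment with full ground truth.

Generates the complete input bundle the pipeline consumes — per-sample MGF
files, MS1 peak tables, a sample manifest — together with a ground-truth
table mapping every emitted MS/MS spectrum to its compound, family,
ionization variant and planted condition effect.

The default configuration emulates a "one strain, many compounds" media
experiment: a family of four epoxyketone-peptide congeners (related by 2H
and C4H8 mass offsets, plus a pair of stereoisomers of the dihydro
compound at different retention times) whose production is up-regulated in
one culture medium, alongside decoy compound families (lipopeptide-,
macrolactam-, macrolide-, diketopiperazine- and carotenoid-like) with
opposing media preferences, blank-derived contaminants and culture-media
background ions.

All randomness derives from one integer seed through hierarchical
``numpy.random`` streams, so identical configurations generate
byte-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import mass_calc
from .mass_calc import (
    DEFAULT_ADDUCT_RULES,
    MS1Scan,
    PROTONATED,
    monoisotopic_mass,
    write_ms1_csv,
)
from .similarity import cosine_similarity
from .spectra_io import Group, Peak, SampleRecord, Spectrum, write_manifest, write_mgf

__all__ = [
    "CompoundSpec",
    "VariantModel",
    "ExperimentConfig",
    "GroundTruth",
    "GeneratedExperiment",
    "make_epoxyketone_default_config",
    "generate_experiment",
    "score_recovery",
]

_RULES_BY_NAME = {r.name: r for r in DEFAULT_ADDUCT_RULES}


@dataclass
class CompoundSpec:
    """One planted compound: formula, fragment fingerprint, elution and yield."""

    compound_id: str
    formula: str
    family_id: str
    fragment_mzs: tuple[float, ...]
    fragment_intensities: tuple[float, ...]
    rt: float
    base_intensity: float
    category: str = "compound"  # compound | contaminant | media
    condition_effects: dict[str, float] = field(default_factory=dict)

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def mz_protonated(self) -> float:
        return PROTONATED.mz(self.neutral_mass)


@dataclass
class VariantModel:
    """Emission probability and intensity (relative to [M+H]+) per variant."""

    probability: dict[str, float] = field(
        default_factory=lambda: {
            "[M+Na]+": 0.6,
            "[M+NH4]+": 0.4,
            "M+1": 0.9,
            "[2M+H]+": 0.25,
        }
    )
    intensity_factor: dict[str, float] = field(
        default_factory=lambda: {
            "[M+Na]+": 0.3,
            "[M+NH4]+": 0.2,
            "M+1": 0.25,
            "[2M+H]+": 0.1,
        }
    )


@dataclass
class ExperimentConfig:
    """Fully specifies one synthetic experiment."""

    compounds: list[CompoundSpec]
    conditions: dict[str, int]  # condition label -> number of culture samples
    n_blanks: int = 2
    n_beds: int = 2
    variants: VariantModel = field(default_factory=VariantModel)
    intensity_cv: float = 0.2  # biological/injection noise on compound yield
    fragment_cv: float = 0.05  # per-peak wobble of fragment intensities
    mz_jitter_sd: float = 0.002  # Da, on fragment and precursor m/z
    rt_jitter_sd: float = 0.01  # minutes, scan-to-scan apex wobble
    n_noise_peaks: int = 3  # extra low-level peaks per MS/MS spectrum
    detection_floor_fraction: float = 0.01  # of the compound's base intensity
    rt_range: tuple[float, float] = (0.5, 11.5)
    ms1_scan_interval: float = 0.02  # minutes
    ms1_peak_sigma: float = 0.04  # minutes, chromatographic peak width
    seed: int = 42

    def validate(self) -> None:
        if not self.compounds:
            raise ValueError("config must contain at least one compound")
        for p in self.variants.probability.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("variant probabilities must be in [0, 1]")
        if self.rt_range[0] >= self.rt_range[1]:
            raise ValueError("rt_range must be increasing")
        for c in self.compounds:
            if any(f >= c.mz_protonated for f in c.fragment_mzs):
                raise ValueError(
                    f"compound {c.compound_id}: fragments must be below [M+H]+"
                )
            if len(c.fragment_mzs) != len(c.fragment_intensities):
                raise ValueError(
                    f"compound {c.compound_id}: fragment m/z and intensity "
                    "lists must have equal length"
                )
        seen = set()
        for c in self.compounds:
            if c.compound_id in seen:
                raise ValueError(f"duplicate compound_id {c.compound_id!r}")
            seen.add(c.compound_id)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            yaml.safe_dump(_config_to_dict(self), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with Path(path).open(encoding="utf-8") as fh:
            return _config_from_dict(yaml.safe_load(fh))


def _config_to_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["rt_range"] = list(config.rt_range)
    for c in d["compounds"]:
        c["fragment_mzs"] = [float(x) for x in c["fragment_mzs"]]
        c["fragment_intensities"] = [float(x) for x in c["fragment_intensities"]]
    return d


def _config_from_dict(d: Mapping) -> ExperimentConfig:
    compounds = [
        CompoundSpec(
            compound_id=c["compound_id"],
            formula=c["formula"],
            family_id=c["family_id"],
            fragment_mzs=tuple(c["fragment_mzs"]),
            fragment_intensities=tuple(c["fragment_intensities"]),
            rt=c["rt"],
            base_intensity=c["base_intensity"],
            category=c.get("category", "compound"),
            condition_effects=dict(c.get("condition_effects", {})),
        )
        for c in d["compounds"]
    ]
    variants = VariantModel(
        probability=dict(d["variants"]["probability"]),
        intensity_factor=dict(d["variants"]["intensity_factor"]),
    )
    return ExperimentConfig(
        compounds=compounds,
        conditions=dict(d["conditions"]),
        n_blanks=d["n_blanks"],
        n_beds=d["n_beds"],
        variants=variants,
        intensity_cv=d["intensity_cv"],
        fragment_cv=d["fragment_cv"],
        mz_jitter_sd=d["mz_jitter_sd"],
        rt_jitter_sd=d["rt_jitter_sd"],
        n_noise_peaks=d["n_noise_peaks"],
        detection_floor_fraction=d["detection_floor_fraction"],
        rt_range=tuple(d["rt_range"]),
        ms1_scan_interval=d["ms1_scan_interval"],
        ms1_peak_sigma=d["ms1_peak_sigma"],
        seed=d["seed"],
    )


# --------------------------------------------------------------------------
# Default configuration: the epoxyketone-style media experiment
# --------------------------------------------------------------------------

# Structure (fragment fingerprints) is part of the experimental design, not
# of the per-run noise, so it is drawn from a fixed internal stream.
_STRUCTURE_SEED = 715517


def _family_fragments(
    rng: np.random.Generator,
    masses: Sequence[float],
    n_fragments: int = 12,
    n_shifted: int = 4,
    n_dropped: int = 2,
    member_variation_sd: float = 0.6,
) -> list[tuple[tuple[float, ...], tuple[float, ...]]]:
    """Fragment fingerprints for one compound family.

    A shared backbone ladder of ``n_fragments`` fragments is sampled below
    the lightest member; each member keeps the ladder but (a) shifts
    ``n_shifted`` fragments by its mass offset from the first member — so
    congeners share >= 60% of fragment m/z directly and the rest modulo the
    family offset — (b) drops ``n_dropped`` fragments, and (c) rescales
    intensities log-normally so members are similar but not identical.
    """
    min_mass = min(masses)
    ladder = np.sort(rng.uniform(80.0, 0.8 * min_mass, size=n_fragments))
    base_int = rng.uniform(10.0, 100.0, size=n_fragments)
    shifted_idx = rng.choice(n_fragments, size=n_shifted, replace=False)
    out = []
    for mass in masses:
        delta = mass - masses[0]
        mzs = ladder.copy()
        mzs[shifted_idx] += delta
        intensities = base_int * rng.lognormal(0.0, member_variation_sd, n_fragments)
        drop = rng.choice(n_fragments, size=n_dropped, replace=False)
        keep = np.setdiff1d(np.arange(n_fragments), drop)
        order = np.argsort(mzs[keep])
        kept = keep[order]
        out.append((tuple(float(x) for x in mzs[kept]), tuple(float(x) for x in intensities[kept])))
    return out


def make_epoxyketone_default_config(seed: int = 42) -> ExperimentConfig:
    """The default in-silico media experiment.

    One four-congener epoxyketone family (2H and C4H8 mass relations, with
    the dihydro C20 compound present as two stereoisomers at 6.6 and
    7.4 min) up-regulated in medium A1, five decoy families with opposing
    media preferences, three blank contaminants and three culture-media
    background ions, across four media x two replicates plus two blanks and
    two media controls (12 samples, 25 planted compounds).
    """
    rng = np.random.default_rng(_STRUCTURE_SEED)
    compounds: list[CompoundSpec] = []

    def add_family(
        family_id: str,
        entries: Sequence[tuple[str, str, float, float]],
        effects: Mapping[str, float],
        category: str = "compound",
    ) -> None:
        masses = [monoisotopic_mass(f) for _, f, _, _ in entries]
        fingerprints = _family_fragments(rng, masses)
        for (cid, formula, rt, base), (mzs, ints) in zip(entries, fingerprints):
            compounds.append(
                CompoundSpec(
                    compound_id=cid,
                    formula=formula,
                    family_id=family_id,
                    fragment_mzs=mzs,
                    fragment_intensities=ints,
                    rt=rt,
                    base_intensity=base,
                    category=category,
                    condition_effects=dict(effects),
                )
            )

    # Epoxyketone-peptide-like family: dihydro/final congeners related by
    # 2H (saturation) and C4H8 (acyl chain length); the C20 dihydro compound
    # appears as two stereoisomers at different retention times.
    epoxy_effects = {"A1": 1.0, "TSB": 0.2, "TSBY": 0.1, "ISP2": 0.1}
    add_family(
        "epoxyketone",
        [
            ("EPX_dh20_iso1", "C20H36N2O6", 6.6, 1.0e6),
            ("EPX_dh20_iso2", "C20H36N2O6", 7.4, 6.0e5),
            ("EPX_20", "C20H34N2O6", 7.0, 8.0e5),
            ("EPX_dh16", "C16H28N2O6", 5.2, 7.0e5),
            ("EPX_16", "C16H26N2O6", 5.6, 4.0e5),
        ],
        epoxy_effects,
    )
    add_family(
        "lipopeptide",
        [
            ("LIP_1", "C48H82N10O12", 8.6, 9.0e5),
            ("LIP_2", "C52H90N10O12", 9.1, 7.0e5),
            ("LIP_3", "C56H98N10O12", 9.6, 5.0e5),
            ("LIP_4", "C60H106N10O12", 10.1, 4.0e5),
        ],
        {"A1": 0.1, "TSB": 0.5, "TSBY": 1.0, "ISP2": 1.0},
    )
    add_family(
        "macrolactam",
        [
            ("MLA_1", "C24H36N2O4", 4.2, 8.0e5),
            ("MLA_2", "C24H34N2O4", 4.6, 6.0e5),
            ("MLA_3", "C28H44N2O4", 5.0, 5.0e5),
            ("MLA_4", "C28H42N2O4", 5.4, 4.0e5),
        ],
        {"A1": 0.05, "TSB": 0.2, "TSBY": 1.0, "ISP2": 1.0},
    )
    add_family(
        "macrolide",
        [
            ("MCL_1", "C36H62O12", 7.8, 7.0e5),
            ("MCL_2", "C37H64O12", 8.2, 6.0e5),
            ("MCL_3", "C36H60O12", 8.6, 5.0e5),
            ("MCL_4", "C38H66O12", 9.0, 4.0e5),
        ],
        {"A1": 1.0, "TSB": 0.8, "TSBY": 0.25, "ISP2": 0.7},
    )
    add_family(
        "diketopiperazine",
        [
            ("DKP_1", "C14H16N2O2", 2.4, 6.0e5),
            ("DKP_2", "C15H18N2O2", 2.8, 5.0e5),
            ("DKP_3", "C16H20N2O2", 3.2, 4.0e5),
            ("DKP_4", "C17H22N2O2", 3.6, 3.0e5),
        ],
        {"A1": 0.2, "TSB": 0.2, "TSBY": 0.3, "ISP2": 1.0},
    )
    add_family(
        "carotenoid",
        [
            ("CAR_1", "C40H56", 10.4, 5.0e5),
            ("CAR_2", "C40H54", 10.7, 4.0e5),
            ("CAR_3", "C40H58", 11.0, 3.5e5),
            ("CAR_4", "C40H56O", 11.3, 3.0e5),
        ],
        {"A1": 1.0, "TSB": 1.0, "TSBY": 1.0, "ISP2": 1.0},
    )
    # Blank-derived contaminants (plasticizer-like singleton families),
    # present in blank injections and carried into every culture sample.
    for cid, formula, rt, base in [
        ("CONT_1", "C24H38O4", 9.4, 4.0e5),
        ("CONT_2", "C16H22O4", 6.1, 3.0e5),
        ("CONT_3", "C12H24O6", 3.9, 2.5e5),
    ]:
        add_family(cid, [(cid, formula, rt, base)], {}, category="contaminant")
    # Culture-media background ions, present in media controls (BED) and in
    # every culture sample.
    for cid, formula, rt, base in [
        ("MED_1", "C12H22O11", 1.0, 6.0e5),
        ("MED_2", "C6H14N4O2", 1.4, 4.0e5),
        ("MED_3", "C5H9NO4", 1.8, 3.0e5),
    ]:
        add_family(cid, [(cid, formula, rt, base)], {}, category="media")

    return ExperimentConfig(
        compounds=compounds,
        conditions={"A1": 2, "TSB": 2, "TSBY": 2, "ISP2": 2},
        seed=seed,
    )


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-spectrum provenance plus compound-level design of the experiment."""

    spectra: pd.DataFrame
    compounds: pd.DataFrame
    config: ExperimentConfig

    def theoretical_spectrum(self, compound_id: str) -> Spectrum:
        """Noise-free [M+H]+ MS/MS spectrum of a planted compound."""
        spec = next(
            c for c in self.config.compounds if c.compound_id == compound_id
        )
        return Spectrum(
            spectrum_id=f"theory|{compound_id}",
            precursor_mz=spec.mz_protonated,
            peaks=tuple(
                Peak(m, i)
                for m, i in zip(spec.fragment_mzs, spec.fragment_intensities)
            ),
            rt=spec.rt,
        )

    def expected_variant_groups(self) -> dict[str, set[str]]:
        """compound_id -> set of variant rule names emitted anywhere."""
        non_noise = self.spectra
        return {
            cid: set(sub["variant"])
            for cid, sub in non_noise.groupby("compound_id")
        }

    def same_family_pairs(
        self, frag_tol: float = 0.025, allow_shift: bool = True
    ) -> pd.DataFrame:
        """All within-family compound pairs with their true (noise-free)
        modified-cosine similarity, for 'compound'-category families."""
        rows = []
        specs = [c for c in self.config.compounds if c.category == "compound"]
        for i, a in enumerate(specs):
            for b in specs[i + 1 :]:
                if a.family_id != b.family_id:
                    continue
                score = cosine_similarity(
                    self.theoretical_spectrum(a.compound_id),
                    self.theoretical_spectrum(b.compound_id),
                    frag_tol=frag_tol,
                    allow_shift=allow_shift,
                ).score
                rows.append(
                    {
                        "compound_a": a.compound_id,
                        "compound_b": b.compound_id,
                        "family_id": a.family_id,
                        "true_cosine": score,
                    }
                )
        return pd.DataFrame(rows)

    def true_fold_changes(self, reference: str) -> pd.DataFrame:
        """Planted fold change of each 'compound' compound per condition."""
        rows = []
        for c in self.config.compounds:
            if c.category != "compound":
                continue
            ref = c.condition_effects.get(reference, 0.0)
            for cond, effect in c.condition_effects.items():
                if cond == reference:
                    continue
                rows.append(
                    {
                        "compound_id": c.compound_id,
                        "condition": cond,
                        "true_fold_change": effect / ref if ref > 0 else math.inf,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class GeneratedExperiment:
    """In-memory handles plus file paths of one generated bundle."""

    output_dir: Path
    manifest: list[SampleRecord]
    spectra_by_sample: dict[str, list[Spectrum]]
    scans_by_sample: dict[str, list[MS1Scan]]
    ground_truth: GroundTruth
    manifest_path: Path
    ms1_path: Path
    ground_truth_path: Path
    config_path: Path


def _sample_plan(config: ExperimentConfig) -> list[SampleRecord]:
    records = []
    for cond in config.conditions:
        for i in range(config.conditions[cond]):
            sid = f"{cond}_r{i + 1}"
            records.append(SampleRecord(sid, f"{sid}.mgf", Group.SAMPLE, cond))
    for i in range(config.n_blanks):
        sid = f"BLANK_{i + 1}"
        records.append(SampleRecord(sid, f"{sid}.mgf", Group.BLANK, ""))
    for i in range(config.n_beds):
        sid = f"BED_{i + 1}"
        records.append(SampleRecord(sid, f"{sid}.mgf", Group.BED, ""))
    return records


def _compound_effect(compound: CompoundSpec, record: SampleRecord) -> float | None:
    """Mean intensity multiplier of ``compound`` in ``record``; None = absent."""
    if compound.category == "compound":
        if record.group is Group.SAMPLE:
            return compound.condition_effects.get(record.condition, 0.0)
        return None
    if compound.category == "contaminant":
        return 1.0 if record.group in (Group.SAMPLE, Group.BLANK) else None
    if compound.category == "media":
        return 1.0 if record.group in (Group.SAMPLE, Group.BED) else None
    raise ValueError(f"unknown compound category {compound.category!r}")


# A constant background ion present in every MS1 scan of every sample: it
# anchors the full scan grid (and mimics the lock-mass signal of a
# calibrated run). No MS/MS spectrum is emitted for it.
_BACKGROUND_MZ = 922.0098
_BACKGROUND_INTENSITY = 1.0e3


def generate_experiment(
    config: ExperimentConfig, output_dir: str | Path
) -> GeneratedExperiment:
    """Generate the full bundle into ``output_dir`` (created if needed).

    Deterministic given ``config`` (including its seed): per-sample MGF
    files, a combined MS1 CSV, a manifest CSV, the ground-truth CSV and the
    config as YAML.
    """
    config.validate()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(config.seed)
    variant_rng, yield_rng, msms_rng, ms1_rng = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    # Which ionization variants each compound produces (a property of the
    # compound and source conditions, fixed across samples).
    variant_names = sorted(config.variants.probability)
    variants_of: dict[str, list[str]] = {}
    for compound in config.compounds:
        chosen = [PROTONATED.name]
        for name in variant_names:
            if variant_rng.random() < config.variants.probability[name]:
                chosen.append(name)
        variants_of[compound.compound_id] = chosen

    manifest = _sample_plan(config)
    sigma_log = math.sqrt(math.log(1.0 + config.intensity_cv**2))
    area_factor = config.ms1_peak_sigma * math.sqrt(2.0 * math.pi)

    grid = np.arange(
        config.rt_range[0], config.rt_range[1] + 1e-9, config.ms1_scan_interval
    )

    spectra_by_sample: dict[str, list[Spectrum]] = {}
    scans_by_sample: dict[str, list[MS1Scan]] = {}
    gt_rows: list[dict] = []

    for record in manifest:
        spectra: list[Spectrum] = []
        ms1_peaks: dict[int, list[tuple[float, float]]] = {
            i: [(_BACKGROUND_MZ, _BACKGROUND_INTENSITY)] for i in range(len(grid))
        }
        for compound in config.compounds:
            effect = _compound_effect(compound, record)
            if effect is None:
                continue
            mean_intensity = compound.base_intensity * effect
            realized = mean_intensity * yield_rng.lognormal(
                -0.5 * sigma_log**2, sigma_log
            )
            floor = config.detection_floor_fraction * compound.base_intensity
            apex_rt = compound.rt + msms_rng.normal(0.0, config.rt_jitter_sd)
            for variant in variants_of[compound.compound_id]:
                rule = _RULES_BY_NAME[variant]
                factor = (
                    1.0
                    if variant == PROTONATED.name
                    else config.variants.intensity_factor[variant]
                )
                variant_intensity = realized * factor
                if variant_intensity < floor:
                    continue
                precursor = rule.mz(compound.neutral_mass) + msms_rng.normal(
                    0.0, config.mz_jitter_sd
                )
                frag_mz = np.array(compound.fragment_mzs) + msms_rng.normal(
                    0.0, config.mz_jitter_sd, len(compound.fragment_mzs)
                )
                rel = np.array(compound.fragment_intensities)
                rel = rel / rel.max()
                frag_int = (
                    rel
                    * variant_intensity
                    * msms_rng.lognormal(0.0, config.fragment_cv, rel.size)
                )
                peaks = [
                    Peak(float(m), float(i)) for m, i in zip(frag_mz, frag_int)
                ]
                if config.n_noise_peaks:
                    noise_mz = msms_rng.uniform(
                        60.0, max(90.0, precursor - 20.0), config.n_noise_peaks
                    )
                    noise_int = msms_rng.uniform(
                        0.005, 0.02, config.n_noise_peaks
                    ) * variant_intensity
                    peaks.extend(
                        Peak(float(m), float(i))
                        for m, i in zip(noise_mz, noise_int)
                    )
                area = variant_intensity * area_factor
                spectrum_id = f"{record.sample_id}|{compound.compound_id}|{variant}"
                spectra.append(
                    Spectrum(
                        spectrum_id=spectrum_id,
                        precursor_mz=precursor,
                        peaks=tuple(peaks),
                        rt=max(0.0, apex_rt),
                        sample_id=record.sample_id,
                        ms1_area=area,
                    )
                )
                gt_rows.append(
                    {
                        "spectrum_id": spectrum_id,
                        "sample_id": record.sample_id,
                        "group": record.group.value,
                        "condition": record.condition,
                        "compound_id": compound.compound_id,
                        "family_id": compound.family_id,
                        "category": compound.category,
                        "variant": variant,
                        "true_mean_intensity": mean_intensity,
                        "realized_intensity": variant_intensity,
                        "true_area": area,
                    }
                )
                # MS1 trace: Gaussian elution profile around the apex.
                lo = np.searchsorted(grid, apex_rt - 4 * config.ms1_peak_sigma)
                hi = np.searchsorted(grid, apex_rt + 4 * config.ms1_peak_sigma)
                for gi in range(lo, hi):
                    z = (grid[gi] - apex_rt) / config.ms1_peak_sigma
                    inten = variant_intensity * math.exp(-0.5 * z * z)
                    if inten >= 0.002 * variant_intensity:
                        ms1_peaks[gi].append((precursor, inten))
        spectra.sort(key=lambda s: s.spectrum_id)
        spectra_by_sample[record.sample_id] = spectra
        scans_by_sample[record.sample_id] = [
            MS1Scan(
                float(grid[i]),
                np.array([p[0] for p in sorted(ms1_peaks[i])]),
                np.array([p[1] for p in sorted(ms1_peaks[i])]),
            )
            for i in range(len(grid))
        ]

    # ---- write the bundle ----
    for record in manifest:
        write_mgf(spectra_by_sample[record.sample_id], output_dir / record.file_path)
    manifest_path = write_manifest(manifest, output_dir / "manifest.csv")
    ms1_path = write_ms1_csv(scans_by_sample, output_dir / "ms1.csv")
    config_path = config.to_yaml(output_dir / "config.yaml")

    gt_spectra = pd.DataFrame(gt_rows)
    compounds_df = pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "family_id": c.family_id,
                "formula": c.formula,
                "neutral_mass": c.neutral_mass,
                "mz_protonated": c.mz_protonated,
                "rt": c.rt,
                "base_intensity": c.base_intensity,
                "category": c.category,
                "variants": ";".join(variants_of[c.compound_id]),
                **{f"effect_{k}": v for k, v in sorted(c.condition_effects.items())},
            }
            for c in config.compounds
        ]
    )
    ground_truth = GroundTruth(spectra=gt_spectra, compounds=compounds_df, config=config)
    ground_truth_path = output_dir / "ground_truth.csv"
    gt_spectra.to_csv(ground_truth_path, index=False)
    compounds_df.to_csv(output_dir / "ground_truth_compounds.csv", index=False)

    return GeneratedExperiment(
        output_dir=output_dir,
        manifest=manifest,
        spectra_by_sample=spectra_by_sample,
        scans_by_sample=scans_by_sample,
        ground_truth=ground_truth,
        manifest_path=manifest_path,
        ms1_path=ms1_path,
        ground_truth_path=ground_truth_path,
        config_path=config_path,
    )


# --------------------------------------------------------------------------
# Recovery scoring
# --------------------------------------------------------------------------


def _node_compound_map(ground_truth: GroundTruth, nodes) -> dict[str, tuple[str, str, str]]:
    """node_id -> (compound_id, category, variant) by member majority vote."""
    lookup = ground_truth.spectra.set_index("spectrum_id")[
        ["compound_id", "category", "variant"]
    ]
    out = {}
    for node in nodes:
        members = [m for m in node.member_ids if m in lookup.index]
        if not members:
            continue
        sub = lookup.loc[members]
        top = sub.groupby(["compound_id", "category", "variant"]).size().idxmax()
        out[node.node_id] = top
    return out


def score_recovery(
    ground_truth: GroundTruth,
    result,
    min_cosine: float = 0.6,
    fold_threshold: float = 2.0,
) -> dict[str, float]:
    """Score how well a pipeline run recovered the planted experiment.

    ``result`` is a :class:`ssmnet.pipeline.PipelineResult` (or any object
    with ``nodes``, ``survivors``, ``ivamn``, ``ssmn``, ``fold_table`` and
    ``fold_reference`` attributes).

    Returns fractions in [0, 1]: blank-contaminant node removal,
    protonated-representative correctness per variant group, same-family
    pair co-clustering (over pairs with true cosine >= ``min_cosine``), and
    sensitivity/specificity of the fold-change flags for planted >= 4-fold
    (respectively < 2-fold) condition effects.
    """
    import networkx as nx

    all_map = _node_compound_map(ground_truth, result.nodes)
    id_missing = [n.node_id for n in result.nodes if n.node_id not in all_map]
    if id_missing:
        raise ValueError(
            f"nodes with members unknown to the ground truth: {id_missing[:5]}"
        )

    # (a) contaminant removal
    contaminant_nodes = [
        n.node_id for n in result.nodes if all_map[n.node_id][1] == "contaminant"
    ]
    surviving_ids = {n.node_id for n in result.survivors}
    removed = [n for n in contaminant_nodes if n not in surviving_ids]
    blank_removal = len(removed) / len(contaminant_nodes) if contaminant_nodes else 1.0

    # (b) protonated-representative correctness per surviving variant group
    surviving_graph = result.ivamn.subgraph(surviving_ids)
    flagged = {n.node_id for n in result.survivors if n.protonated_representative}
    groups = list(nx.connected_components(surviving_graph))
    correct = 0
    for group in groups:
        rep = [n for n in group if n in flagged]
        if len(rep) == 1 and all_map[rep[0]][2] == PROTONATED.name:
            correct += 1
    representative_accuracy = correct / len(groups) if groups else 1.0

    # (c) same-family co-clustering in the SSMN
    pairs = ground_truth.same_family_pairs()
    pairs = pairs[pairs["true_cosine"] >= min_cosine]
    mh_node_of = {
        all_map[nid][0]: nid
        for nid in result.ssmn.nodes
        if nid in all_map and all_map[nid][2] == PROTONATED.name
    }
    component_of = {}
    for idx, comp in enumerate(nx.connected_components(result.ssmn)):
        for nid in comp:
            component_of[nid] = idx
    hits = 0
    for _, row in pairs.iterrows():
        na, nb = mh_node_of.get(row["compound_a"]), mh_node_of.get(row["compound_b"])
        if (
            na is not None
            and nb is not None
            and component_of.get(na) == component_of.get(nb)
        ):
            hits += 1
    family_coclustering = hits / len(pairs) if len(pairs) else 1.0

    # (d) fold-change flag sensitivity / specificity
    truth = ground_truth.true_fold_changes(result.fold_reference)
    node_of_compound = {
        all_map[nid][0]: nid
        for nid in surviving_ids
        if all_map[nid][2] == PROTONATED.name and all_map[nid][1] == "compound"
    }
    fold = result.fold_table.set_index(["node_id", "condition"])
    tp = fn = tn = fp = 0
    for _, row in truth.iterrows():
        tfc = row["true_fold_change"]
        planted = tfc >= 4.0 or tfc <= 0.25
        unaffected = 0.5 < tfc < 2.0
        if not planted and not unaffected:
            continue  # intermediate effects are not scored
        expected = "up" if tfc >= 4.0 else ("down" if tfc <= 0.25 else "unchanged")
        nid = node_of_compound.get(row["compound_id"])
        flag = None
        if nid is not None and (nid, row["condition"]) in fold.index:
            flag = fold.loc[(nid, row["condition"]), "flag"]
        if planted:
            if flag == expected:
                tp += 1
            else:
                fn += 1
        else:
            if flag == "unchanged":
                tn += 1
            else:
                fp += 1
    sensitivity = tp / (tp + fn) if (tp + fn) else 1.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0

    return {
        "blank_removal_fraction": blank_removal,
        "representative_accuracy": representative_accuracy,
        "family_coclustering_fraction": family_coclustering,
        "fold_change_sensitivity": sensitivity,
        "fold_change_specificity": specificity,
        "n_variant_groups": float(len(groups)),
        "n_family_pairs": float(len(pairs)),
    }
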