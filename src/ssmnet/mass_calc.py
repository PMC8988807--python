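"""Monoisotopic masses, adduct m/z arithmetic, tolerance matching and EICs.

The element mass table is embedded as constants so that results are
deterministic and computable offline. Adduct arithmetic follows
``m/z = (multiplier * M + mass_shift) / charge`` for a neutral monoisotopic
mass ``M``. Extracted-ion-chromatogram (EIC) windows are absolute Da
(default ±0.01), matching how narrow-window chromatograms are reported for
Q-TOF data.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ISOTOPE_SPACING",
    "AdductRule",
    "PROTONATED",
    "DEFAULT_ADDUCT_RULES",
    "MS1Scan",
    "parse_formula",
    "formula_union",
    "monoisotopic_mass",
    "adduct_mz",
    "within_tolerance",
    "extract_eic",
    "eic_apex_regions",
    "eic_area",
    "read_ms1_csv",
    "write_ms1_csv",
    "write_eic_csv",
]

# IUPAC monoisotopic masses of the most abundant isotope, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "S": 31.97207069,
    "P": 30.97376151,
    "K": 38.9637064864,
    "Cl": 34.968852682,
}

PROTON_MASS = 1.007276  # mass of H+ (H minus electron), Da
ISOTOPE_SPACING = 1.003355  # 13C - 12C spacing, Da
_NA_MINUS_H = 21.981944  # sodium replacing a proton, Da
_NH3_MASS = 17.026549  # neutral ammonia, Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse a Hill-notation formula string (e.g. ``C20H36N2O6``, ``2H2O``).

    An optional leading integer multiplies the whole formula. Unknown element
    symbols raise ``ValueError`` naming the symbol.
    """
    if isinstance(formula, Mapping):
        counts = dict(formula)
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")
        return counts
    text = formula.strip()
    multiplier = 1
    lead = re.match(r"^(\d+)", text)
    if lead:
        multiplier = int(lead.group(1))
        text = text[lead.end():]
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {text[pos:]!r}")
        if not m.group(0):
            break
        pos = m.end()
        el = m.group(1)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {el!r} in formula {formula!r}")
        n = int(m.group(2)) if m.group(2) else 1
        counts[el] = counts.get(el, 0) + n * multiplier
    if pos != len(text):
        raise ValueError(f"cannot parse formula {formula!r} at {text[pos:]!r}")
    return counts


def formula_union(a: str | Mapping[str, int], b: str | Mapping[str, int]) -> dict[str, int]:
    """Element-wise sum of two formulas."""
    out = parse_formula(a)
    for el, n in parse_formula(b).items():
        out[el] = out.get(el, 0) + n
    return out


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of a neutral formula; empty formula is 0.0."""
    counts = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class AdductRule:
    """Ionization-variant rule: ``m/z = (multiplier * M + mass_shift) / charge``.

    Covers adducts ([M+Na]+, [M+NH4]+), the M+1 isotopologue (13C spacing on
    top of protonation) and the proton-bound dimer [2M+H]+.
    """

    name: str
    mass_shift: float
    multiplier: int = 1
    charge: int = 1

    def mz(self, neutral_mass: float) -> float:
        if self.charge == 0:
            raise ValueError(f"adduct rule {self.name} has charge 0")
        return (self.multiplier * neutral_mass + self.mass_shift) / self.charge

    def neutral_mass(self, mz: float) -> float:
        """Invert :meth:`mz` for a singly-determined neutral mass."""
        return (mz * self.charge - self.mass_shift) / self.multiplier


PROTONATED = AdductRule("[M+H]+", PROTON_MASS)

DEFAULT_ADDUCT_RULES: tuple[AdductRule, ...] = (
    PROTONATED,
    AdductRule("[M+Na]+", PROTON_MASS + _NA_MINUS_H),
    AdductRule("[M+NH4]+", PROTON_MASS + _NH3_MASS),
    AdductRule("M+1", PROTON_MASS + ISOTOPE_SPACING),
    AdductRule("[2M+H]+", PROTON_MASS, multiplier=2),
)


def adduct_mz(neutral_mass: float, rule: AdductRule) -> float:
    """m/z of ``neutral_mass`` ionized under ``rule``."""
    return rule.mz(neutral_mass)


def within_tolerance(mz_a: float, mz_b: float, tol: float) -> bool:
    """``|mz_a - mz_b| <= tol`` with ``tol >= 0``."""
    if tol < 0:
        raise ValueError(f"tolerance must be >= 0, got {tol}")
    return abs(mz_a - mz_b) <= tol


@dataclass
class MS1Scan:
    """A survey (MS1) scan: retention time in minutes plus (m/z, intensity) peaks."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"scan rt must be >= 0, got {self.rt}")
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")


def extract_eic(
    scans: Sequence[MS1Scan], target_mz: float, tol: float = 0.01
) -> list[tuple[float, float]]:
    """Extracted ion chromatogram: per scan, the summed intensity of all
    peaks with ``|mz - target_mz| <= tol`` (0.0 when none).

    Scans must be ordered ascending by retention time.
    """
    if tol < 0:
        raise ValueError(f"tolerance must be >= 0, got {tol}")
    rts = [s.rt for s in scans]
    if any(b < a for a, b in zip(rts, rts[1:])):
        raise ValueError("MS1 scans must be ordered ascending by rt")
    trace = []
    for s in scans:
        mask = np.abs(s.mz - target_mz) <= tol
        trace.append((s.rt, float(s.intensity[mask].sum())))
    return trace


def eic_apex_regions(
    eic: Sequence[tuple[float, float]], min_fraction: float = 0.1
) -> list[tuple[float, float]]:
    """Contiguous retention-time regions where the EIC exceeds
    ``min_fraction`` of its maximum; one region per chromatographic apex for
    well-separated peaks. Returns ``[(rt_start, rt_end), ...]``.
    """
    if not eic:
        return []
    intensities = np.array([i for _, i in eic])
    peak = intensities.max()
    if peak <= 0:
        return []
    above = intensities >= min_fraction * peak
    regions: list[tuple[float, float]] = []
    start = None
    for (rt, _), flag in zip(eic, above):
        if flag and start is None:
            start = rt
        elif not flag and start is not None:
            regions.append((start, prev_rt))
            start = None
        prev_rt = rt
    if start is not None:
        regions.append((start, eic[-1][0]))
    return regions


def eic_area(eic: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an EIC (intensity x minutes)."""
    if len(eic) < 2:
        return 0.0
    rt = np.array([r for r, _ in eic])
    inten = np.array([i for _, i in eic])
    return float(np.trapezoid(inten, rt))


def read_ms1_csv(path: str | Path) -> dict[str, list[MS1Scan]]:
    """Read MS1 peaks from CSV (columns ``rt_min,mz,intensity,sample_id``)
    into rt-ordered scans grouped by sample."""
    path = Path(path)
    rows: dict[str, dict[float, list[tuple[float, float]]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            sid = row.get("sample_id", "") or ""
            rt = float(row["rt_min"])
            rows.setdefault(sid, {}).setdefault(rt, []).append(
                (float(row["mz"]), float(row["intensity"]))
            )
    out: dict[str, list[MS1Scan]] = {}
    for sid, by_rt in rows.items():
        scans = []
        for rt in sorted(by_rt):
            peaks = sorted(by_rt[rt])
            scans.append(
                MS1Scan(
                    rt,
                    np.array([p[0] for p in peaks]),
                    np.array([p[1] for p in peaks]),
                )
            )
        out[sid] = scans
    return out


def write_ms1_csv(
    scans_by_sample: Mapping[str, Sequence[MS1Scan]], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rt_min", "mz", "intensity", "sample_id"])
        for sid in sorted(scans_by_sample):
            for scan in scans_by_sample[sid]:
                for m, i in zip(scan.mz, scan.intensity):
                    writer.writerow([f"{scan.rt:.6f}", f"{m:.5f}", f"{i:.6g}", sid])
    return path


def write_eic_csv(
    eic_by_sample: Mapping[str, Sequence[tuple[float, float]]], path: str | Path
) -> Path:
    """Write EIC traces as CSV (``rt_min,intensity,sample_id``)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rt_min", "intensity", "sample_id"])
        for sid in sorted(eic_by_sample):
            for rt, inten in eic_by_sample[sid]:
                writer.writerow([f"{rt:.6f}", f"{inten:.6g}", sid])
    return path
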