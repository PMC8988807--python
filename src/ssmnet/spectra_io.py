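"""Read and write MS/MS spectra (MGF) and sample manifests.

The MGF dialect is the common proteomics/metabolomics one: ``TITLE`` carries
the spectrum id, the first ``PEPMASS`` token is the precursor m/z,
``RTINSECONDS`` is converted to minutes, and ``CHARGE`` accepts the ``1+``
style (default 1 when absent). m/z values are written with 5 decimals so
that 0.01-Da extracted-ion windows remain meaningful after a round trip.

Sample manifests are comma-delimited UTF-8 files with header
``sample_id,file,group,condition`` where ``group`` is one of SAMPLE, BLANK
(chromatographic blank injection) or BED (uninoculated culture-medium
extract), case-insensitive on input.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "Peak",
    "Spectrum",
    "Group",
    "SampleRecord",
    "MGFParseError",
    "ManifestError",
    "read_mgf",
    "write_mgf",
    "read_manifest",
    "write_manifest",
    "filter_scan_range",
]


class MGFParseError(ValueError):
    """Raised when an MGF record cannot be parsed; names the record index."""


class ManifestError(ValueError):
    """Raised for invalid sample manifests."""


@dataclass(frozen=True)
class Peak:
    """A single fragment peak: m/z in Da (> 0), intensity in counts (>= 0)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mz) and self.mz > 0):
            raise ValueError(f"peak m/z must be finite and positive, got {self.mz}")
        if not (math.isfinite(self.intensity) and self.intensity >= 0):
            raise ValueError(
                f"peak intensity must be finite and non-negative, got {self.intensity}"
            )


@dataclass
class Spectrum:
    """One MS/MS scan.

    Parameters
    ----------
    spectrum_id : unique identifier within a collection.
    precursor_mz : precursor m/z in Da (> 0).
    peaks : fragment peaks; stored sorted ascending by m/z.
    rt : retention time in minutes (>= 0).
    charge : precursor charge, default 1.
    sample_id : id of the sample the scan came from.
    ms1_area : integrated MS1 feature area of the precursor, if known.
    """

    spectrum_id: str
    precursor_mz: float
    peaks: tuple[Peak, ...] = ()
    rt: float = 0.0
    charge: int = 1
    sample_id: str = ""
    ms1_area: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.precursor_mz) and self.precursor_mz > 0):
            raise ValueError(
                f"precursor m/z must be positive, got {self.precursor_mz} "
                f"(spectrum {self.spectrum_id!r})"
            )
        if self.rt < 0:
            raise ValueError(f"retention time must be >= 0, got {self.rt}")
        if self.ms1_area < 0:
            raise ValueError(f"ms1_area must be >= 0, got {self.ms1_area}")
        self.peaks = tuple(sorted(self.peaks, key=lambda p: p.mz))

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


class Group(str, Enum):
    """Role of a sample in the experiment."""

    SAMPLE = "SAMPLE"
    BLANK = "BLANK"
    BED = "BED"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    file_path: str
    group: Group
    condition: str = ""


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Peaks are returned sorted ascending by m/z; ``RTINSECONDS`` is converted
    to minutes. Raises :class:`MGFParseError` naming the 0-based record index
    on a malformed record (missing PEPMASS, non-numeric peak line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    seen: set[str] = set()
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        index = 0
        while True:
            try:
                entry = next(reader)
            except StopIteration:
                break
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise MGFParseError(f"malformed MGF record {index} in {path}: {exc}") from exc
            params = entry.get("params", {})
            if "pepmass" not in params or params["pepmass"] is None:
                raise MGFParseError(f"MGF record {index} in {path} is missing PEPMASS")
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            title = str(params.get("title", f"scan_{index}"))
            rt_s = params.get("rtinseconds", 0.0)
            charge_param = params.get("charge")
            if charge_param:
                charge = int(charge_param[0])
            else:
                charge = 1
            mz_arr = np.asarray(entry["m/z array"], dtype=float)
            int_arr = np.asarray(entry["intensity array"], dtype=float)
            peaks = tuple(Peak(m, i) for m, i in zip(mz_arr, int_arr))
            sample_id = str(params.get("sample_id", ""))
            ms1_area = float(params.get("ms1_area", 0.0))
            if title in seen:
                raise MGFParseError(f"duplicate spectrum_id {title!r} in {path}")
            seen.add(title)
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=precursor,
                    peaks=peaks,
                    rt=float(rt_s) / 60.0,
                    charge=charge,
                    sample_id=sample_id,
                    ms1_area=ms1_area,
                )
            )
            index += 1
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> Path:
    """Write spectra to ``path`` in MGF, lossless under :func:`read_mgf`."""
    path = Path(path)
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "rtinseconds": s.rt * 60.0,
            "charge": s.charge,
        }
        if s.sample_id:
            params["sample_id"] = s.sample_id
        if s.ms1_area:
            params["ms1_area"] = repr(float(s.ms1_area))
        entries.append(
            {
                "params": params,
                "m/z array": s.mz,
                "intensity array": s.intensity,
            }
        )
    with path.open("w") as fh:
        _mgf.write(
            entries,
            output=fh,
            fragment_format="%.5f %.8g",
            use_numpy=True,
            param_formatters={
                **_mgf._default_value_formatters,
                "pepmass": lambda k, v: f"PEPMASS={float(v):.5f}",
                "rtinseconds": lambda k, v: f"RTINSECONDS={float(v):.6f}",
            },
            write_charges=False,
        )
    return path


_MANIFEST_COLUMNS = ("sample_id", "file", "group", "condition")


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read and validate a sample manifest CSV.

    Group labels are case-insensitive and normalised to uppercase; duplicate
    sample ids and unknown group labels raise :class:`ManifestError`.
    """
    path = Path(path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _MANIFEST_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ManifestError(f"manifest {path} missing columns: {missing}")
        for row_no, row in enumerate(reader, start=2):
            sample_id = row["sample_id"].strip()
            group_raw = row["group"].strip().upper()
            try:
                group = Group(group_raw)
            except ValueError:
                raise ManifestError(
                    f"unknown group {row['group']!r} at manifest row {row_no} "
                    f"(sample_id={sample_id!r}); expected SAMPLE, BLANK or BED"
                ) from None
            if sample_id in seen:
                raise ManifestError(f"duplicate sample_id {sample_id!r} at row {row_no}")
            seen.add(sample_id)
            records.append(
                SampleRecord(
                    sample_id=sample_id,
                    file_path=row["file"].strip(),
                    group=group,
                    condition=(row.get("condition") or "").strip(),
                )
            )
    return records


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for r in records:
            writer.writerow([r.sample_id, r.file_path, r.group.value, r.condition])
    return path


def filter_scan_range(
    spectra: Iterable[Spectrum], min_mz: float = 30.0, max_mz: float = 2000.0
) -> list[Spectrum]:
    """Drop fragment peaks outside ``[min_mz, max_mz]``.

    The default window is the positive-mode instrument acquisition range of
    30–2,000 Da. Spectra left without peaks are dropped entirely.
    """
    if min_mz >= max_mz:
        raise ValueError(f"min_mz ({min_mz}) must be < max_mz ({max_mz})")
    out: list[Spectrum] = []
    for s in spectra:
        kept = tuple(p for p in s.peaks if min_mz <= p.mz <= max_mz)
        if kept:
            out.append(replace(s, peaks=kept))
    return out
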