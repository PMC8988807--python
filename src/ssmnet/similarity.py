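"""Cosine and modified-cosine MS/MS spectral similarity.

Peaks are weighted by the square root of their intensity and scaled to unit
Euclidean norm, the standard molecular-networking transform that keeps a few
dominant fragments from swamping the score. Candidate peak pairs match
either directly (|Δm/z| <= frag_tol) or, in shift-tolerant ("modified")
mode, offset by the precursor mass difference; a greedy one-to-one
alignment accepts pairs in order of descending weight product. An exhaustive
oracle (:func:`oracle_similarity`) computes the true maximum-score
alignment on small instances and is used to validate the greedy heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .spectra_io import Spectrum

__all__ = [
    "MatchKind",
    "PeakMatch",
    "SimilarityResult",
    "weight_and_normalize",
    "cosine_similarity",
    "oracle_similarity",
    "library_match",
]

DEFAULT_FRAG_TOL = 0.025  # Da; suited to Q-TOF fragment accuracy


class MatchKind(str, Enum):
    DIRECT = "direct"
    SHIFTED = "shifted"


@dataclass(frozen=True)
class PeakMatch:
    index_a: int
    index_b: int
    kind: MatchKind
    product: float


@dataclass(frozen=True)
class SimilarityResult:
    """Alignment score in [0, 1], number of matched peak pairs, and the pairs."""

    score: float
    n_matched: int
    matches: tuple[PeakMatch, ...] = ()


def weight_and_normalize(intensities: Sequence[float] | np.ndarray) -> np.ndarray:
    """Square-root intensity weights scaled to unit Euclidean norm."""
    arr = np.asarray(intensities, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot weight an empty peak list")
    if np.any(arr < 0):
        raise ValueError("intensities must be non-negative")
    w = np.sqrt(arr)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("all-zero intensities cannot be normalized")
    return w / norm


def _candidate_pairs(
    a: Spectrum, b: Spectrum, frag_tol: float, allow_shift: bool
) -> list[tuple[float, float, float, int, int, int, MatchKind]]:
    """All (product-sorted) candidate peak pairs between ``a`` and ``b``.

    Sort key is (-product, min_mz, max_mz, kind): descending weight product
    with a tie-break that is symmetric under swapping the two spectra, so
    that greedy scores are reproducible and symmetric.
    """
    wa = weight_and_normalize(a.intensity)
    wb = weight_and_normalize(b.intensity)
    shift = a.precursor_mz - b.precursor_mz
    pairs = []
    for i, pa in enumerate(a.peaks):
        for j, pb in enumerate(b.peaks):
            delta = pa.mz - pb.mz
            kinds = []
            if abs(delta) <= frag_tol:
                kinds.append(MatchKind.DIRECT)
            if allow_shift and abs(delta - shift) <= frag_tol and shift != 0.0:
                kinds.append(MatchKind.SHIFTED)
            for kind in kinds:
                product = float(wa[i] * wb[j])
                lo, hi = min(pa.mz, pb.mz), max(pa.mz, pb.mz)
                pairs.append(
                    (-product, lo, hi, 0 if kind is MatchKind.DIRECT else 1, i, j, kind)
                )
    pairs.sort(key=lambda t: t[:4])
    return pairs


def cosine_similarity(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
    allow_shift: bool = False,
) -> SimilarityResult:
    """Greedy (modified-)cosine similarity between two spectra.

    Candidate pairs are accepted in order of descending weight product; each
    peak participates in at most one accepted pair. With ``allow_shift``,
    fragment pairs offset by the precursor mass difference also match
    (modified cosine).
    """
    if frag_tol < 0:
        raise ValueError(f"frag_tol must be >= 0, got {frag_tol}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("spectra must be non-empty")
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[PeakMatch] = []
    score = 0.0
    for negp, _, _, _, i, j, kind in _candidate_pairs(a, b, frag_tol, allow_shift):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(PeakMatch(i, j, kind, -negp))
        score += -negp
    score = min(score, 1.0)
    if not matches:
        score = 0.0
    return SimilarityResult(score=score, n_matched=len(matches), matches=tuple(matches))


_ORACLE_MAX_PEAKS = 16


def oracle_similarity(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
    allow_shift: bool = False,
) -> SimilarityResult:
    """Exact maximum-score one-to-one alignment by exhaustive enumeration.

    Branch-and-bound over candidate-pair subsets; restricted to instances
    with at most 16 total peaks so the search stays tractable. Serves as the
    independent reference for :func:`cosine_similarity`.
    """
    if frag_tol < 0:
        raise ValueError(f"frag_tol must be >= 0, got {frag_tol}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("spectra must be non-empty")
    if len(a) + len(b) > _ORACLE_MAX_PEAKS:
        raise ValueError(
            f"oracle limited to {_ORACLE_MAX_PEAKS} total peaks, got {len(a) + len(b)}"
        )
    cand = _candidate_pairs(a, b, frag_tol, allow_shift)
    products = [-t[0] for t in cand]
    suffix = np.cumsum([0.0] + products[::-1])[::-1]  # suffix[k] = sum products[k:]

    best_score = 0.0
    best_matches: tuple[PeakMatch, ...] = ()

    def recurse(k: int, used_a: int, used_b: int, score: float, picked: list[int]) -> None:
        nonlocal best_score, best_matches
        if score > best_score:
            best_score = score
            best_matches = tuple(
                PeakMatch(cand[p][4], cand[p][5], cand[p][6], -cand[p][0]) for p in picked
            )
        if k == len(cand) or score + suffix[k] <= best_score:
            return
        _, _, _, _, i, j, _ = cand[k]
        if not (used_a >> i) & 1 and not (used_b >> j) & 1:
            picked.append(k)
            recurse(k + 1, used_a | (1 << i), used_b | (1 << j), score + products[k], picked)
            picked.pop()
        recurse(k + 1, used_a, used_b, score, picked)

    recurse(0, 0, 0, 0.0, [])
    score = min(best_score, 1.0)
    return SimilarityResult(score=score, n_matched=len(best_matches), matches=best_matches)


def library_match(
    query: Spectrum,
    library: Sequence[Spectrum],
    min_score: float = 0.7,
    frag_tol: float = DEFAULT_FRAG_TOL,
    allow_shift: bool = False,
) -> list[tuple[Spectrum, SimilarityResult]]:
    """Rank library spectra against ``query`` by cosine similarity.

    Returns hits scoring at least ``min_score`` sorted descending, ties
    broken by library order.
    """
    if not library:
        raise ValueError("library must be non-empty")
    scored = []
    for pos, entry in enumerate(library):
        result = cosine_similarity(query, entry, frag_tol=frag_tol, allow_shift=allow_shift)
        if result.score >= min_score:
            scored.append((-result.score, pos, entry, result))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [(entry, result) for _, _, entry, result in scored]
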