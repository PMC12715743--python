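"""Spectral matching, identification-confidence rules, and QA/QC estimators.

The spectral match score is a transparent cosine similarity on
square-root-weighted intensities scaled to 0-100, with 70 as the customary
acceptance threshold.  It is a stand-in for proprietary library-search
scores (mzCloud/mzVault best-match, FISh), not a re-implementation of them.

Confidence levels follow the Schymanski scale as operationalized for this
workflow: level 1 = structure confirmed by a reference standard (RT match
plus MS2 evidence); level 2 = probable structure, delta RT between the QSRR
prediction and the measurement <= 1.0 min (a stricter 0.5 min variant is
exposed via the threshold argument); level 3 = tentative otherwise.

QA/QC estimators: IDL (lowest calibration level with precursor S/N
strictly above 3), an MDL upper bound (lowest spike level with >= 3x blank
signal and a clear triggered MS2), recovery and matrix effect by the
standard post-extraction-spike scheme, and RSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import ppm_error

__all__ = [
    "LibraryEntry",
    "SpectralLibrary",
    "MatchResult",
    "match_spectrum",
    "AnnotationEvidence",
    "Annotation",
    "assign_confidence",
    "estimate_idl",
    "estimate_mdl",
    "RecoveryResult",
    "recovery_and_matrix_effect",
    "rsd",
]


# ---------------------------------------------------------------------------
# spectral library + cosine matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryEntry:
    compound: str
    collision_energy: float
    mz: tuple[float, ...]
    intensity: tuple[float, ...]
    precursor_mz: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("peak list lengths differ")
        if any(b < a for a, b in zip(self.mz, self.mz[1:])):
            order = sorted(range(len(self.mz)), key=lambda i: self.mz[i])
            object.__setattr__(self, "mz", tuple(self.mz[i] for i in order))
            object.__setattr__(
                self, "intensity", tuple(self.intensity[i] for i in order)
            )


@dataclass
class SpectralLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)

    def add(self, entry: LibraryEntry) -> None:
        self.entries.append(entry)

    # MSP-format text serialization --------------------------------------
    def to_msp(self, path: str | Path) -> None:
        lines = []
        for e in self.entries:
            lines.append(f"NAME: {e.compound}")
            if e.precursor_mz is not None:
                lines.append(f"PRECURSORMZ: {e.precursor_mz:.4f}")
            lines.append(f"COLLISIONENERGY: {e.collision_energy:g}")
            lines.append(f"Num Peaks: {len(e.mz)}")
            for m, i in zip(e.mz, e.intensity):
                lines.append(f"{m:.4f} {i:.1f}")
            lines.append("")
        Path(path).write_text("\n".join(lines))

    @classmethod
    def from_msp(cls, path: str | Path) -> "SpectralLibrary":
        lib = cls()
        name, ce, prec = None, 0.0, None
        peaks: list[tuple[float, float]] = []

        def flush():
            nonlocal name, ce, prec, peaks
            if name is not None:
                lib.add(
                    LibraryEntry(
                        compound=name,
                        collision_energy=ce,
                        mz=tuple(m for m, _ in peaks),
                        intensity=tuple(i for _, i in peaks),
                        precursor_mz=prec,
                    )
                )
            name, ce, prec, peaks = None, 0.0, None, []

        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                flush()
                continue
            upper = line.upper()
            if upper.startswith("NAME:"):
                name = line.split(":", 1)[1].strip()
            elif upper.startswith("PRECURSORMZ:"):
                prec = float(line.split(":", 1)[1])
            elif upper.startswith("COLLISIONENERGY:"):
                ce = float(line.split(":", 1)[1])
            elif upper.startswith("NUM PEAKS:"):
                continue
            else:
                m, i = line.split()[:2]
                peaks.append((float(m), float(i)))
        flush()
        return lib


@dataclass(frozen=True)
class MatchResult:
    compound: Optional[str]
    score: float  # 0-100
    collision_energy: Optional[float] = None
    n_matched_peaks: int = 0


def _cosine_score(
    qmz: np.ndarray,
    qint: np.ndarray,
    lmz: np.ndarray,
    lint: np.ndarray,
    tol_ppm: float,
) -> tuple[float, int]:
    """Cosine of sqrt-intensity vectors after greedy ppm peak pairing."""
    qw = np.sqrt(qint)
    lw = np.sqrt(lint)
    used = np.zeros(lmz.size, dtype=bool)
    dot = 0.0
    n_matched = 0
    for i in range(qmz.size):
        half = qmz[i] * tol_ppm * 1e-6
        j0, j1 = np.searchsorted(lmz, (qmz[i] - half, qmz[i] + half))
        best_j, best_d = -1, math.inf
        for j in range(j0, j1):
            if used[j]:
                continue
            d = abs(lmz[j] - qmz[i])
            if d < best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            used[best_j] = True
            dot += qw[i] * lw[best_j]
            n_matched += 1
    nq = float(np.linalg.norm(qw))
    nl = float(np.linalg.norm(lw))
    if nq == 0 or nl == 0 or dot == 0:
        return 0.0, n_matched
    score = 100.0 * dot / (nq * nl)
    return min(100.0, round(score, 10)), n_matched


def match_spectrum(
    query_mz: Sequence[float],
    query_intensity: Sequence[float],
    library: SpectralLibrary,
    tol_ppm: float = 10.0,
) -> MatchResult:
    """Best library match of an MS2 peak list across compounds and CEs."""
    qmz = np.asarray(query_mz, dtype=float)
    qint = np.asarray(query_intensity, dtype=float)
    if qmz.size == 0:
        raise ValueError("empty query spectrum")
    order = np.argsort(qmz, kind="stable")
    qmz, qint = qmz[order], qint[order]
    if not library.entries:
        return MatchResult(compound=None, score=0.0)
    best = MatchResult(compound=None, score=-1.0)
    for e in library.entries:
        score, n = _cosine_score(
            qmz, qint, np.asarray(e.mz), np.asarray(e.intensity), tol_ppm
        )
        if score > best.score:
            best = MatchResult(
                compound=e.compound,
                score=score,
                collision_energy=e.collision_energy,
                n_matched_peaks=n,
            )
    return best


# ---------------------------------------------------------------------------
# confidence assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationEvidence:
    standard_rt_match: bool = False
    ms2_match_score: Optional[float] = None  # 0-100
    delta_rt: Optional[float] = None  # minutes, |observed - predicted|


@dataclass(frozen=True)
class Annotation:
    compound: str
    formula: str
    evidence: AnnotationEvidence
    confidence_level: int


def assign_confidence(
    evidence: AnnotationEvidence,
    ms2_score_threshold: float = 70.0,
    delta_rt_threshold: float = 1.0,
) -> int:
    """Schymanski confidence level (1-3) from the available evidence.

    Level 1 needs both a reference-standard RT match and MS2 evidence at or
    above the score threshold; otherwise level 2 when delta RT is within the
    threshold, level 3 when it exceeds it.  Monotone: decreasing delta RT
    never increases the level.
    """
    has_ms2 = (
        evidence.ms2_match_score is not None
        and evidence.ms2_match_score >= ms2_score_threshold
    )
    if evidence.standard_rt_match and has_ms2:
        return 1
    if evidence.delta_rt is not None:
        return 2 if evidence.delta_rt <= delta_rt_threshold else 3
    raise ValueError(
        "insufficient evidence: need a standard RT+MS2 match or a delta RT"
    )


# ---------------------------------------------------------------------------
# detection limits, recovery, matrix effect, RSD
# ---------------------------------------------------------------------------

def estimate_idl(
    calibration: Sequence[tuple[float, float]],
) -> Optional[float]:
    """Instrument detection limit: lowest calibration concentration whose
    precursor S/N strictly exceeds 3; None when every level fails."""
    if not calibration:
        raise ValueError("empty calibration series")
    concs = [c for c, _ in calibration]
    if concs != sorted(concs):
        raise ValueError("calibration concentrations must be ascending")
    for conc, sn in calibration:
        if sn > 3.0:
            return conc
    return None


def estimate_mdl(
    spike_levels: Sequence[tuple[float, float, float, bool]],
) -> Optional[float]:
    """Method detection limit (upper bound): lowest spike level with sample
    signal >= 3x the process blank AND a clear triggered MS2 spectrum.

    ``spike_levels`` rows are (conc, sample peak height, blank peak height,
    ms2_triggered), sorted ascending by concentration.
    """
    concs = [row[0] for row in spike_levels]
    if concs != sorted(concs):
        raise ValueError("spike levels must be ascending")
    for conc, sample_h, blank_h, triggered in spike_levels:
        if triggered and sample_h >= 3.0 * blank_h:
            return conc
    return None


@dataclass(frozen=True)
class RecoveryResult:
    recovery_pct: float
    matrix_effect_pct: float  # negative = suppression
    undefined: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


def recovery_and_matrix_effect(
    spiked: float,
    unspiked: float,
    post_extraction_spiked: float,
    solvent_standard: float,
) -> RecoveryResult:
    """Recovery and matrix effect from the post-extraction-spike scheme.

    recovery% = 100 x (pre-extraction spiked - unspiked)
                    / (post-extraction spiked - unspiked)
    ME%       = 100 x (post-extraction spiked / solvent standard - 1)

    Zero denominators yield NaN with an ``undefined`` marker; a negative
    recovery (unspiked exceeding spiked) is flagged.
    """
    if min(spiked, unspiked, post_extraction_spiked, solvent_standard) < 0:
        raise ValueError("peak areas must be non-negative")
    undefined: list[str] = []
    flags: list[str] = []
    denom = post_extraction_spiked - unspiked
    if denom <= 0:
        recovery = math.nan
        undefined.append("recovery")
    else:
        recovery = 100.0 * (spiked - unspiked) / denom
        if recovery < 0:
            flags.append("negative_recovery")
    if solvent_standard <= 0:
        me = math.nan
        undefined.append("matrix_effect")
    else:
        me = 100.0 * (post_extraction_spiked / solvent_standard - 1.0)
    return RecoveryResult(
        recovery_pct=recovery,
        matrix_effect_pct=me,
        undefined=tuple(undefined),
        flags=tuple(flags),
    )


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, percent (sample SD / mean x 100).

    Returns NaN (undefined) for a zero mean; requires n >= 2.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = float(np.mean(arr))
    if mean == 0:
        return math.nan
    return 100.0 * float(np.std(arr, ddof=1)) / mean
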