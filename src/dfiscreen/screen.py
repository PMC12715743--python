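"""Precursor prioritization by diagnostic fragment ions (DDA and DIA).

DDA rule: a ddMS2 precursor becomes a candidate when (1) its MS1 peak is at
least ``blank_ratio`` times higher than the corresponding process-blank
signal and (2) at least ``min_diagnostic_ions`` distinct diagnostic fragment
ions match (within ``fragment_tol`` ppm) in the MS2 scans merged across the
collision-energy scheme.  Surviving precursors are additionally constrained
to have at least one elemental-formula candidate under the configured
element/RDBE/ppm bounds.

DIA rule: candidate precursors are full-scan ions (intensity >=
``dia_min_intensity`` at CE 0) located at the retention times where
diagnostic fragment ions peak in the all-ion-fragmentation traces, retained
only when their intensity decreases consistently across the ordered CE
scheme (strictly decreasing by default; a relative slack is configurable
because the qualitative rule does not quantify "consistently").  Blank-ratio
and formula constraints then apply as in DDA, and accepted candidates can be
exported as an inclusion list for targeted ddMS2 reacquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import (
    ElementBounds,
    FormulaCandidate,
    DEFAULT_BOUNDS,
    decompose_mass,
    ppm_error,
)
from .fragments import (
    PARABEN,
    PROTOCATECHUATE,
    DiagnosticRegistry,
    FragmentIon,
    diagnostic_set,
)
from .msio import (
    ACQ_AIF,
    ACQ_DDMS2,
    ACQ_FULL,
    EIC,
    Spectrum,
    SpectrumRun,
    detect_peaks,
    extract_eic,
)

__all__ = [
    "ScreenParams",
    "MatchedIon",
    "PrecursorCandidate",
    "screen_dda",
    "screen_dia",
    "export_inclusion_list",
]


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds of the prioritization rules (defaults as used for
    screening follicular-fluid-type matrices)."""

    min_diagnostic_ions: int = 4
    fragment_tol: float = 10.0  # ppm, MS2 diagnostic-ion matching
    precursor_tol: float = 5.0  # ppm, MS1/precursor matching
    blank_ratio: float = 3.0  # fold over process blank
    coelution_window: float = 0.1  # minutes
    element_bounds: ElementBounds = DEFAULT_BOUNDS
    dia_min_intensity: float = 1e5  # CE-0 full-scan floor
    dia_decrease_slack: float = 0.0  # relative slack on the CE decrease rule
    ce_scheme: tuple[float, ...] = (10.0, 20.0, 40.0)

    def __post_init__(self) -> None:
        if self.min_diagnostic_ions < 1:
            raise ValueError("min_diagnostic_ions must be >= 1")
        for name in ("fragment_tol", "precursor_tol", "blank_ratio",
                     "coelution_window", "dia_min_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MatchedIon:
    label: str
    observed_mz: float
    ppm: float
    collision_energy: float


@dataclass
class PrecursorCandidate:
    """A prioritized precursor with its screening evidence."""

    mz: float
    rt: float
    matched_ions: list[MatchedIon]
    n_matched: int
    blank_ratio_observed: float
    formula_candidates: list[FormulaCandidate]
    class_call: str  # paraben | protocatechuate | ambiguous
    source: str  # DDA | DIA
    height: float = 0.0

    def to_row(self) -> dict:
        return {
            "mz": round(self.mz, 4),
            "rt": round(self.rt, 3),
            "n_matched": self.n_matched,
            "matched_ions": ";".join(
                f"{m.label}@{m.observed_mz:.4f}({m.ppm:+.1f}ppm,CE{m.collision_energy:g})"
                for m in self.matched_ions
            ),
            "blank_ratio": (
                math.inf
                if math.isinf(self.blank_ratio_observed)
                else round(self.blank_ratio_observed, 2)
            ),
            "formulas": ";".join(c.formula.hill() for c in self.formula_candidates),
            "class": self.class_call,
            "source": self.source,
            "height": self.height,
        }


def candidates_to_frame(candidates: Sequence[PrecursorCandidate]) -> pd.DataFrame:
    cols = ["mz", "rt", "n_matched", "matched_ions", "blank_ratio",
            "formulas", "class", "source", "height"]
    return pd.DataFrame([c.to_row() for c in candidates], columns=cols)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _class_sets(registry: DiagnosticRegistry) -> dict[str, set[FragmentIon]]:
    return {
        PARABEN: diagnostic_set(registry, PARABEN),
        PROTOCATECHUATE: diagnostic_set(registry, PROTOCATECHUATE),
    }


def _match_diagnostics(
    spectra: Sequence[Spectrum],
    ions: set[FragmentIon],
    tol_ppm: float,
) -> list[MatchedIon]:
    """Best match per distinct ion label across the given MS2 scans."""
    best: dict[str, MatchedIon] = {}
    for ion in sorted(ions, key=lambda i: i.label):
        theo = ion.mz
        half = theo * tol_ppm * 1e-6
        for s in spectra:
            if not s.mz.size:
                continue
            i0, i1 = np.searchsorted(s.mz, (theo - half, theo + half))
            if i1 <= i0:
                continue
            seg = slice(i0, i1)
            j = i0 + int(np.argmax(s.intensity[seg]))
            obs = float(s.mz[j])
            err = ppm_error(obs, theo)
            prev = best.get(ion.label)
            if prev is None or abs(err) < abs(prev.ppm):
                best[ion.label] = MatchedIon(
                    label=ion.label,
                    observed_mz=obs,
                    ppm=err,
                    collision_energy=s.collision_energy,
                )
    return [best[k] for k in sorted(best)]


def _classify(
    spectra: Sequence[Spectrum],
    registry: DiagnosticRegistry,
    params: ScreenParams,
) -> tuple[list[MatchedIon], int, str]:
    """Count matched diagnostic labels per class and call the class."""
    sets = _class_sets(registry)
    per_class = {
        cls: _match_diagnostics(spectra, ions, params.fragment_tol)
        for cls, ions in sets.items()
    }
    counts = {cls: len(m) for cls, m in per_class.items()}
    passing = [c for c, n in counts.items() if n >= params.min_diagnostic_ions]
    if len(passing) == 1:
        cls = passing[0]
    elif len(passing) > 1:
        cls = "ambiguous"
    else:
        cls = max(counts, key=lambda c: counts[c])
    merged: dict[str, MatchedIon] = {}
    for m in per_class[PARABEN] + per_class[PROTOCATECHUATE]:
        if m.label not in merged or abs(m.ppm) < abs(merged[m.label].ppm):
            merged[m.label] = m
    n_matched = max(counts.values()) if counts else 0
    return [merged[k] for k in sorted(merged)], n_matched, cls


def _ms1_height(
    run: SpectrumRun,
    mz: float,
    rt: float,
    params: ScreenParams,
    window: float = 0.3,
) -> float:
    """Apex MS1 intensity at ``mz`` near ``rt`` (max within the rt window)."""
    eic = extract_eic(run, mz, params.precursor_tol, ms_level=1)
    if eic.rt.size == 0:
        return 0.0
    sel = (eic.rt >= rt - window) & (eic.rt <= rt + window)
    if not np.any(sel):
        return 0.0
    return float(eic.intensity[sel].max())


def _blank_ratio(
    sample_height: float,
    blanks: Sequence[SpectrumRun],
    mz: float,
    rt: float,
    params: ScreenParams,
    window: float = 0.3,
) -> float:
    blank_max = 0.0
    for blank in blanks:
        blank_max = max(blank_max, _ms1_height(blank, mz, rt, params, window))
    if blank_max <= 0:
        return math.inf
    return sample_height / blank_max


# ---------------------------------------------------------------------------
# DDA screening
# ---------------------------------------------------------------------------

def _cluster_dda_scans(
    run: SpectrumRun, params: ScreenParams
) -> list[tuple[float, float, list[Spectrum]]]:
    """Group ddMS2 scans by precursor m/z (within tol) and elution window.

    Returns (mean precursor m/z, median rt, scans) per cluster; scans of one
    precursor separated by more than 0.3 min are treated as distinct elution
    events.
    """
    scans = run.scans(ms_level=2, acquisition=ACQ_DDMS2)
    scans = sorted(scans, key=lambda s: (s.precursor_mz, s.rt))
    clusters: list[list[Spectrum]] = []
    for s in scans:
        placed = False
        for cluster in clusters:
            ref = cluster[-1]
            if (
                abs(ppm_error(s.precursor_mz, ref.precursor_mz))
                <= params.precursor_tol
                and s.rt - cluster[-1].rt <= 0.3
            ):
                cluster.append(s)
                placed = True
                break
        if not placed:
            clusters.append([s])
    out = []
    for cluster in clusters:
        mzs = [s.precursor_mz for s in cluster]
        rts = sorted(s.rt for s in cluster)
        out.append(
            (float(np.mean(mzs)), float(rts[len(rts) // 2]), cluster)
        )
    return sorted(out, key=lambda c: (c[0], c[1]))


def screen_dda(
    sample: SpectrumRun,
    blanks: Sequence[SpectrumRun],
    registry: DiagnosticRegistry,
    params: ScreenParams = ScreenParams(),
) -> list[PrecursorCandidate]:
    """Prioritize ddMS2 precursors by the diagnostic-ion and blank rules."""
    if sample.mode != "DDA":
        raise ValueError(f"screen_dda requires a DDA run, got {sample.mode!r}")
    if not blanks:
        raise ValueError("at least one process blank run is required")
    candidates: list[PrecursorCandidate] = []
    for prec_mz, rt, scans in _cluster_dda_scans(sample, params):
        matched, n_matched, cls = _classify(scans, registry, params)
        if n_matched < params.min_diagnostic_ions:
            continue
        height = _ms1_height(sample, prec_mz, rt, params)
        ratio = _blank_ratio(height, blanks, prec_mz, rt, params)
        if ratio < params.blank_ratio:
            continue
        formulas = decompose_mass(prec_mz, params.element_bounds)
        if not formulas:
            continue
        candidates.append(
            PrecursorCandidate(
                mz=prec_mz,
                rt=rt,
                matched_ions=matched,
                n_matched=n_matched,
                blank_ratio_observed=ratio,
                formula_candidates=formulas,
                class_call=cls,
                source="DDA",
                height=height,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# DIA screening
# ---------------------------------------------------------------------------

def _nearest_scan(scans: Sequence[Spectrum], rt: float) -> Optional[Spectrum]:
    if not scans:
        return None
    return min(scans, key=lambda s: abs(s.rt - rt))


def _intensity_at(spectrum: Spectrum, mz: float, tol_ppm: float) -> float:
    if spectrum is None or not spectrum.mz.size:
        return 0.0
    half = mz * tol_ppm * 1e-6
    i0, i1 = np.searchsorted(spectrum.mz, (mz - half, mz + half))
    return float(spectrum.intensity[i0:i1].sum())


def screen_dia(
    sample: SpectrumRun,
    blanks: Sequence[SpectrumRun],
    registry: DiagnosticRegistry,
    params: ScreenParams = ScreenParams(),
) -> list[PrecursorCandidate]:
    """Select DIA precursors by the CE-decrease rule at diagnostic-ion RTs."""
    if sample.mode != "DIA":
        raise ValueError(f"screen_dia requires a DIA run, got {sample.mode!r}")
    if not blanks:
        raise ValueError("at least one process blank run is required")

    full_scans = sample.scans(ms_level=1, acquisition=ACQ_FULL)
    aif_by_ce = {
        ce: sample.scans(ms_level=2, acquisition=ACQ_AIF, ce=ce)
        for ce in params.ce_scheme
    }
    all_aif = sample.scans(ms_level=2, acquisition=ACQ_AIF)

    # (a) retention times where any diagnostic ion peaks in the AIF traces
    event_rts: list[float] = []
    union_ions = _class_sets(registry)[PARABEN] | _class_sets(registry)[PROTOCATECHUATE]
    for ion in sorted(union_ions, key=lambda i: i.label):
        for ce in params.ce_scheme:
            eic = extract_eic(
                sample, ion.mz, params.fragment_tol,
                ms_level=2, acquisition=ACQ_AIF, ce=ce,
            )
            if eic.rt.size == 0 or not np.any(eic.intensity > 0):
                continue
            for peak in detect_peaks(eic, min_snr=3.0):
                event_rts.append(peak.rt)
    # merge events within the coelution window
    event_rts.sort()
    merged_rts: list[float] = []
    for rt in event_rts:
        if not merged_rts or rt - merged_rts[-1] > params.coelution_window:
            merged_rts.append(rt)

    candidates: dict[tuple[float, float], PrecursorCandidate] = {}
    for rt in merged_rts:
        full = _nearest_scan(full_scans, rt)
        if full is None or abs(full.rt - rt) > params.coelution_window:
            continue
        # (b) full-scan ions above the intensity floor at this rt
        strong = full.mz[full.intensity >= params.dia_min_intensity]
        for prec_mz in map(float, strong):
            # (c) intensity must decrease consistently across the CE scheme
            seq = [_intensity_at(full, prec_mz, params.fragment_tol)]
            for ce in params.ce_scheme:
                scan = _nearest_scan(aif_by_ce[ce], rt)
                seq.append(_intensity_at(scan, prec_mz, params.fragment_tol))
            # the AIF residual precursor is matched at fragment_tol: the
            # full-scan and AIF m/z values are both observed (jittered)
            # quantities, so their difference spreads wider than a one-sided
            # precursor tolerance
            ok = all(
                nxt < prev * (1.0 + params.dia_decrease_slack)
                for prev, nxt in zip(seq, seq[1:])
            )
            if not ok:
                continue
            # diagnostic-ion evidence from AIF scans near this rt
            nearby = [s for s in all_aif if abs(s.rt - rt) <= params.coelution_window]
            matched, n_matched, cls = _classify(nearby, registry, params)
            if n_matched < params.min_diagnostic_ions:
                continue
            # (d) blank-ratio and formula constraints as in DDA
            height = _ms1_height(sample, prec_mz, rt, params)
            ratio = _blank_ratio(height, blanks, prec_mz, rt, params)
            if ratio < params.blank_ratio:
                continue
            formulas = decompose_mass(prec_mz, params.element_bounds)
            if not formulas:
                continue
            key = (round(prec_mz, 3), round(rt, 1))
            if key in candidates:
                continue
            candidates[key] = PrecursorCandidate(
                mz=prec_mz,
                rt=rt,
                matched_ions=matched,
                n_matched=n_matched,
                blank_ratio_observed=ratio,
                formula_candidates=formulas,
                class_call=cls,
                source="DIA",
                height=height,
            )
    return sorted(candidates.values(), key=lambda c: (c.mz, c.rt))


# ---------------------------------------------------------------------------
# inclusion-list export
# ---------------------------------------------------------------------------

def export_inclusion_list(
    candidates: Sequence[PrecursorCandidate],
    rt_window: float = 0.4,
) -> pd.DataFrame:
    """Inclusion-list rows (m/z, rt start/end) for targeted reacquisition.

    The retention-time window (default 0.4 min) is centered on the candidate
    apex; candidates sharing m/z at distinct retention times stay separate.
    """
    rows = [
        {
            "mz": round(c.mz, 4),
            "rt_start": round(c.rt - rt_window / 2, 3),
            "rt_end": round(c.rt + rt_window / 2, 3),
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=["mz", "rt_start", "rt_end"])
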