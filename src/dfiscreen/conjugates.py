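"""Phase II conjugate screening and hydrolyzed-vs-unhydrolyzed comparison.

Sulfate, glucuronide and glycine conjugates of parabens and their phase I
metabolites ionize as [M-H]- at the free-form mass plus the conjugation
delta.  Their MS2 spectra lose the conjugate moiety to regenerate the
deprotonated free form, which then fragments along its diagnostic pathways;
sulfates additionally show the SO3 radical anion (m/z 79.9568) and sometimes
hydrogensulfate (m/z 96.9596).  A conjugate hit therefore requires the
free-form fragment plus at least one additional evidence ion.

Because conjugates are cleaved by enzymatic hydrolysis, comparing free-form
signals between hydrolyzed and unhydrolyzed aliquots of the same sample
reveals speciation: a strong gain on hydrolysis (or a free form detectable
only after hydrolysis, with a conjugate hit in the unhydrolyzed run) marks a
predominantly conjugated compound.  The fold-change thresholds (5x for
predominantly conjugated, 1.5x for predominantly free) are this module's
own quantitative rendering of a qualitative comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import ppm_error
from .compounds import Standard
from .fragments import (
    CONJUGATE_DELTAS,
    HYDROGEN_SULFATE_MZ,
    PHENOLIC_ACID,
    SULFITE_RADICAL_MZ,
    DiagnosticRegistry,
    conjugate_mass,
    diagnostic_set,
)
from .screen import ScreenParams, _cluster_dda_scans, _match_diagnostics
from .msio import SpectrumRun, detect_peaks, extract_eic

__all__ = [
    "ConjugateHit",
    "screen_conjugates",
    "compare_hydrolysis",
    "VERDICT_CONJUGATED",
    "VERDICT_PARTIAL",
    "VERDICT_FREE",
    "VERDICT_ABSENT",
]

VERDICT_CONJUGATED = "predominantly_conjugated"
VERDICT_PARTIAL = "partially_conjugated"
VERDICT_FREE = "predominantly_free"
VERDICT_ABSENT = "not_detected"

#: Speciation rule table (documented, applied by compare_hydrolysis):
#: fold >= FOLD_CONJUGATED, or free form undetected before hydrolysis while a
#: conjugate hit exists          -> predominantly_conjugated
#: fold <= FOLD_FREE and no hit  -> predominantly_free
#: detected, anything else       -> partially_conjugated
#: detected in neither run       -> not_detected
FOLD_CONJUGATED = 5.0
FOLD_FREE = 1.5


@dataclass(frozen=True)
class ConjugateHit:
    conjugation: str  # sulfate | glucuronide | glycine
    precursor_mz: float
    rt: float
    target: str  # free-form compound name
    free_form_mz: float
    evidence: tuple[str, ...]  # labels of matched evidence ions
    n_evidence: int

    def to_row(self) -> dict:
        return {
            "conjugation": self.conjugation,
            "precursor_mz": round(self.precursor_mz, 4),
            "rt": round(self.rt, 3),
            "target": self.target,
            "free_form_mz": round(self.free_form_mz, 4),
            "evidence": ";".join(self.evidence),
            "n_evidence": self.n_evidence,
        }


def hits_to_frame(hits: Sequence[ConjugateHit]) -> pd.DataFrame:
    cols = ["conjugation", "precursor_mz", "rt", "target", "free_form_mz",
            "evidence", "n_evidence"]
    return pd.DataFrame([h.to_row() for h in hits], columns=cols)


def _target_diag_ions(registry: DiagnosticRegistry, target: Standard):
    """Diagnostic ions applicable to a target's free form."""
    if target.compound_class == PHENOLIC_ACID:
        # acids fragment through the shared pathway ions attributed to them
        return {
            i for i in registry.ions
            if i.screening and PHENOLIC_ACID in i.classes
        }
    return diagnostic_set(registry, target.compound_class, target.name)


def _spectrum_has(spectra, mz: float, tol_ppm: float) -> bool:
    half = mz * tol_ppm * 1e-6
    for s in spectra:
        if not s.mz.size:
            continue
        i0, i1 = np.searchsorted(s.mz, (mz - half, mz + half))
        if i1 > i0:
            return True
    return False


def screen_conjugates(
    run: SpectrumRun,
    registry: DiagnosticRegistry,
    targets: Sequence[Standard],
    params: ScreenParams = ScreenParams(),
    conjugations: Sequence[str] = ("sulfate", "glucuronide", "glycine"),
) -> list[ConjugateHit]:
    """Screen a DDA run for phase II conjugates of the target compounds.

    For each target x conjugation the ddMS2 precursors at the expected
    conjugate [M-H]- (within ``precursor_tol``) are inspected; a hit needs
    the free-form fragment (neutral loss of the conjugate moiety) plus at
    least one further evidence ion (sulfate marker ions or a diagnostic ion
    of the free form).
    """
    if run.mode != "DDA":
        raise ValueError(f"screen_conjugates requires a DDA run, got {run.mode!r}")
    for c in conjugations:
        if c not in CONJUGATE_DELTAS:
            raise ValueError(f"unknown conjugation type: {c!r}")

    clusters = _cluster_dda_scans(run, params)
    hits: list[ConjugateHit] = []
    for target in targets:
        free_mz = target.mz
        diag = _target_diag_ions(registry, target)
        for conj in conjugations:
            expected = conjugate_mass(target.neutral, conj)
            for prec_mz, rt, scans in clusters:
                if abs(ppm_error(prec_mz, expected)) > params.precursor_tol:
                    continue
                evidence: list[str] = []
                if not _spectrum_has(scans, free_mz, params.fragment_tol):
                    continue
                evidence.append(f"[M-H]- {target.name}")
                if conj == "sulfate":
                    if _spectrum_has(scans, SULFITE_RADICAL_MZ, params.fragment_tol):
                        evidence.append("SO3-.")
                    if _spectrum_has(scans, HYDROGEN_SULFATE_MZ, params.fragment_tol):
                        evidence.append("HSO4-")
                matched = _match_diagnostics(scans, diag, params.fragment_tol)
                evidence.extend(m.label for m in matched)
                if len(evidence) < 2:
                    continue
                hits.append(
                    ConjugateHit(
                        conjugation=conj,
                        precursor_mz=prec_mz,
                        rt=rt,
                        target=target.name,
                        free_form_mz=free_mz,
                        evidence=tuple(evidence),
                        n_evidence=len(evidence),
                    )
                )
    return sorted(hits, key=lambda h: (h.precursor_mz, h.rt))


def _free_form_height(
    run: SpectrumRun,
    target: Standard,
    params: ScreenParams,
    min_snr: float,
    detection_floor: float,
) -> float:
    """Apex height of the free form's MS1 peak, 0.0 if undetected."""
    eic = extract_eic(run, target.mz, params.precursor_tol, ms_level=1)
    if eic.rt.size == 0:
        return 0.0
    peaks = detect_peaks(eic, min_snr=min_snr)
    peaks = [p for p in peaks if p.height >= detection_floor]
    if not peaks:
        return 0.0
    near = [p for p in peaks if abs(p.rt - target.rt) <= 0.3]
    pool = near if near else peaks
    return max(p.height for p in pool)


def compare_hydrolysis(
    hydrolyzed: SpectrumRun,
    unhydrolyzed: SpectrumRun,
    targets: Sequence[Standard],
    conjugate_hits: Sequence[ConjugateHit],
    params: ScreenParams = ScreenParams(),
    min_snr: float = 3.0,
    detection_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-target speciation report from paired hydrolyzed/unhydrolyzed runs.

    Both runs must have been acquired and extracted with identical EIC
    parameters.  Returns a frame with apex heights, fold change
    (hydrolyzed / unhydrolyzed, inf when the free form appears only after
    hydrolysis) and the rule-table verdict.
    """
    hit_targets = {h.target for h in conjugate_hits}
    rows = []
    for target in targets:
        h = _free_form_height(hydrolyzed, target, params, min_snr, detection_floor)
        u = _free_form_height(unhydrolyzed, target, params, min_snr, detection_floor)
        has_hit = target.name in hit_targets
        if h <= 0 and u <= 0:
            verdict = VERDICT_ABSENT
            fold = math.nan
        else:
            fold = h / u if u > 0 else math.inf
            if fold >= FOLD_CONJUGATED or (u <= 0 and has_hit):
                verdict = VERDICT_CONJUGATED
            elif fold <= FOLD_FREE and not has_hit:
                verdict = VERDICT_FREE
            else:
                verdict = VERDICT_PARTIAL
        rows.append(
            {
                "target": target.name,
                "hydrolyzed_height": h,
                "unhydrolyzed_height": u,
                "fold_change": fold,
                "conjugate_hit": has_hit,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["target", "hydrolyzed_height", "unhydrolyzed_height",
                 "fold_change", "conjugate_hit", "verdict"],
    )
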