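"""Seeded simulator of DDA/DIA runs of a spiked biofluid-like matrix.

The generator emulates the acquisition structure used for screening
follicular-fluid extracts: negative-mode full scans (80-1000 m/z) every
cycle; in DDA, top-5 data-dependent MS2 with a 1.5 Th isolation window,
an intensity trigger threshold and a 7 s dynamic-exclusion analog, each
selected precursor fragmented at 10, 20 and 40 eV; in DIA, three all-ion
fragmentation scans per cycle at the same collision energies.

Analytes elute as Gaussian chromatographic peaks (default 0.15 min FWHM)
with apex intensity = concentration x response factor x matrix suppression.
Fragment m/z values come from the diagnostic-ion registry with seeded ppm
jitter (sigma 2 ppm, truncated at 3 sigma so ground-truth ions stay inside a
10 ppm screening window), and peak intensities carry Poisson counting noise.
The matrix model contributes baseline noise peaks and benzophenone-like
interference channels that fragment to m/z 91.0184 only — reproducing the
main false-positive channel that the >= 4-ion rule must reject.

Collision-energy-dependent fragment profiles default to the qualitative
HCD pattern for each class (ester-cleavage ions dominant at 10-20 eV, the
phenolate/decarboxylation families growing at 40 eV); they are plain dicts
and fully config-driven.  Compounds simulated below the trigger threshold
never acquire MS2, reproducing the missed-trigger failure mode of
low-concentration spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import ElementalFormula, mz_deprotonated
from .compounds import STANDARDS, Standard
from .fragments import (
    HYDROGEN_SULFATE_MZ,
    NO_HETEROLYTIC_LOSS,
    PARABEN,
    PHENOLIC_ACID,
    PROTOCATECHUATE,
    SULFITE_RADICAL_MZ,
    DiagnosticRegistry,
    build_registry,
    conjugate_mass,
    diagnostic_set,
)
from .msio import (
    ACQ_AIF,
    ACQ_DDMS2,
    ACQ_FULL,
    DEFAULT_CE_SCHEME,
    Spectrum,
    SpectrumRun,
)

__all__ = [
    "CompoundSpec",
    "MatrixModel",
    "GroundTruth",
    "GroundTruthEntry",
    "SimConfig",
    "generate_run",
    "generate_spike_series",
    "default_matrix",
    "specs_from_standards",
]

#: Default detector response: area-units of apex intensity per ng/mL, chosen
#: so a 25 ng/mL spike sits near 1e6 (an order of magnitude above the DDA
#: trigger analog) and 1 ng/mL sits below the trigger.
DEFAULT_RESPONSE_FACTOR = 4.0e4

#: Residual (unfragmented) precursor fraction per collision energy, strictly
#: decreasing with CE as observed for these soft precursors.
DEFAULT_SURVIVAL = {10.0: 0.55, 20.0: 0.25, 40.0: 0.08}

#: Qualitative CE-resolved fragment profiles (relative to the precursor MS1
#: intensity).  Ester-cleavage ions (A/F) dominate at low CE; phenolate,
#: decarboxylation and CO-loss families grow at 40 eV.
PARABEN_PROFILE: dict[float, dict[str, float]] = {
    10.0: {"A1": 0.30, "A2": 0.15, "B1": 0.05, "B2": 0.02},
    20.0: {"A1": 0.60, "A2": 0.35, "B1": 0.25, "B2": 0.06, "C": 0.12,
           "D2": 0.05, "B3": 0.08, "E": 0.10},
    40.0: {"A1": 0.25, "A2": 0.15, "B1": 0.55, "B2": 0.10, "B3": 0.45,
           "C": 0.40, "D2": 0.12, "E": 0.50},
}

PROTOCATECHUATE_PROFILE: dict[float, dict[str, float]] = {
    10.0: {"F1": 0.30, "F2": 0.15, "G1": 0.06},
    20.0: {"F1": 0.60, "F2": 0.35, "G1": 0.25, "C": 0.12, "D1": 0.08,
           "H": 0.05, "B3": 0.06, "E": 0.08, "J": 0.06},
    40.0: {"F1": 0.20, "F2": 0.12, "G1": 0.50, "G3": 0.15, "C": 0.40,
           "D1": 0.18, "D2": 0.08, "H": 0.12, "J": 0.35, "K": 0.15,
           "B3": 0.40, "E": 0.45},
}

#: The hydrolysis acids fragment sparsely: 4-HB gives only the phenolate B1;
#: 3,4-DHB decarboxylates to G1 with further H/H2O losses at high CE.
PHENOLIC_ACID_PROFILES: dict[str, dict[float, dict[str, float]]] = {
    "4-HB": {
        10.0: {"B1": 0.20},
        20.0: {"B1": 0.50},
        40.0: {"B1": 0.80},
    },
    "3,4-DHB": {
        10.0: {"G1": 0.30},
        20.0: {"G1": 0.50, "C": 0.10},
        40.0: {"G1": 0.40, "C": 0.30, "B3": 0.35},
    },
}

_CLASS_PROFILES = {
    PARABEN: PARABEN_PROFILE,
    PROTOCATECHUATE: PROTOCATECHUATE_PROFILE,
}

#: Conjugate MS2 behaviour: the moiety is lost first (free-form ion), the
#: sulfate markers appear at mid/high CE, and the regenerated free form
#: fragments along its own pathways at 40 eV (scaled down).
CONJUGATE_FREE_ION = {10.0: 0.35, 20.0: 0.60, 40.0: 0.30}
CONJUGATE_SO3 = {10.0: 0.0, 20.0: 0.25, 40.0: 0.30}
CONJUGATE_HSO4 = {10.0: 0.0, 20.0: 0.08, 40.0: 0.05}
CONJUGATE_DIAG_SCALE = 0.25  # free-form diagnostic ions at 40 eV


@dataclass
class CompoundSpec:
    """Ground-truth description of one simulated analyte (or conjugate)."""

    name: str
    formula: str  # neutral formula of the FREE form, Hill notation
    rt: float  # minutes
    compound_class: str  # paraben | protocatechuate | phenolic_acid
    concentration: float  # ng/mL
    response_factor: float = DEFAULT_RESPONSE_FACTOR
    fragment_profile: Optional[dict[float, dict[str, float]]] = None
    conjugate: Optional[str] = None  # sulfate | glucuronide | glycine
    survival: Optional[dict[float, float]] = None  # per-CE precursor residual
    #: free-form compound name for profile lookup and structural exclusions
    #: when ``name`` is a derived label (e.g. "MeP-sulfate" -> "MeP")
    base_name: Optional[str] = None

    @property
    def profile_name(self) -> str:
        return self.base_name or self.name

    @property
    def neutral(self) -> ElementalFormula:
        return ElementalFormula.parse(self.formula)

    @property
    def mz(self) -> float:
        """[M-H]- of the species as simulated (conjugated if applicable)."""
        if self.conjugate:
            return conjugate_mass(self.neutral, self.conjugate)
        return mz_deprotonated(self.neutral)

    @property
    def free_mz(self) -> float:
        return mz_deprotonated(self.neutral)


@dataclass
class MatrixModel:
    """Baseline noise, interference channels and ionization suppression."""

    noise_level: float = 300.0  # exponential scale of baseline peaks
    n_noise_peaks: int = 40  # per full scan
    n_noise_peaks_ms2: int = 8
    #: benzophenone-like channels: (m/z, rt, apex intensity); they fragment
    #: to m/z 91.0184 only.
    interference: tuple[tuple[float, float, float], ...] = ()
    suppression: float = 0.85  # multiplicative on analyte response, (0, 1]

    def __post_init__(self) -> None:
        if self.noise_level <= 0:
            raise ValueError("noise level must be positive")
        if not (0 < self.suppression <= 1):
            raise ValueError("suppression must be in (0, 1]")


def default_matrix(with_interference: bool = True) -> MatrixModel:
    """Biofluid-like matrix with benzophenone-type interference channels."""
    interference = ()
    if with_interference:
        interference = (
            # (deprotonated m/z, rt, apex intensity): hydroxybenzophenones
            (float(mz_deprotonated("C13H10O5")), 7.40, 8.0e5),
            (float(mz_deprotonated("C13H10O2")), 9.55, 6.0e5),
            (float(mz_deprotonated("C13H10O3")), 8.60, 7.0e5),
        )
    return MatrixModel(interference=interference)


@dataclass(frozen=True)
class GroundTruthEntry:
    name: str
    mz: float
    rt: float
    concentration: float
    compound_class: str
    conjugate: Optional[str]
    apex_intensity: float
    n_applicable_ions: int
    expected_candidate: bool


@dataclass
class GroundTruth:
    mode: str
    seed: int
    entries: list[GroundTruthEntry]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": e.name,
                    "mz": round(e.mz, 4),
                    "rt": e.rt,
                    "concentration": e.concentration,
                    "class": e.compound_class,
                    "conjugate": e.conjugate or "",
                    "apex_intensity": round(e.apex_intensity, 1),
                    "n_applicable_ions": e.n_applicable_ions,
                    "expected_candidate": e.expected_candidate,
                }
                for e in self.entries
            ]
        )

    def expected_names(self) -> set[str]:
        return {e.name for e in self.entries if e.expected_candidate}


@dataclass(frozen=True)
class SimConfig:
    """Acquisition-geometry knobs of the simulator."""

    cycle_time: float = 0.02  # minutes between full scans
    peak_fwhm: float = 0.15  # minutes
    ce_scheme: tuple[float, ...] = DEFAULT_CE_SCHEME
    trigger_threshold: float = 1.0e5  # DDA intensity trigger analog
    top_n: int = 5  # DDA loop count
    dynamic_exclusion: float = 7.0 / 60.0  # minutes
    isolation_width: float = 1.5  # Th
    mz_jitter_ppm: float = 2.0  # sigma; truncated at 3 sigma
    scan_range: tuple[float, float] = (80.0, 1000.0)
    ms2_scan_range: tuple[float, float] = (75.0, 1000.0)


# ---------------------------------------------------------------------------
# fragment tables
# ---------------------------------------------------------------------------

def _applicable_labels(spec: CompoundSpec, registry: DiagnosticRegistry) -> set[str]:
    """Screening-set labels the compound can actually produce."""
    if spec.compound_class == PHENOLIC_ACID:
        profile = spec.fragment_profile or PHENOLIC_ACID_PROFILES.get(
            spec.profile_name, {}
        )
        return {lbl for per_ce in profile.values() for lbl in per_ce}
    return {
        i.label
        for i in diagnostic_set(registry, spec.compound_class, spec.profile_name)
    }


def _free_profile(spec: CompoundSpec, registry: DiagnosticRegistry) -> dict[float, dict[str, float]]:
    if spec.fragment_profile is not None:
        profile = spec.fragment_profile
    elif spec.compound_class == PHENOLIC_ACID:
        profile = PHENOLIC_ACID_PROFILES.get(spec.profile_name)
        if profile is None:
            raise ValueError(
                f"no default fragment profile for phenolic acid {spec.name!r}; "
                "pass fragment_profile explicitly"
            )
    else:
        profile = _CLASS_PROFILES[spec.compound_class]
    if spec.compound_class != PHENOLIC_ACID:
        allowed = _applicable_labels(spec, registry) | {"D2", "G3", "H", "K"}
        if spec.profile_name in NO_HETEROLYTIC_LOSS:
            allowed -= {"A1", "B1"}
        profile = {
            ce: {lbl: v for lbl, v in per_ce.items() if lbl in allowed}
            for ce, per_ce in profile.items()
        }
    return profile


def _fragment_table(
    spec: CompoundSpec, registry: DiagnosticRegistry
) -> dict[float, list[tuple[float, float]]]:
    """Per-CE list of (theoretical fragment m/z, relative intensity)."""
    table: dict[float, list[tuple[float, float]]] = {}
    survival = spec.survival or DEFAULT_SURVIVAL
    if spec.conjugate is None:
        profile = _free_profile(spec, registry)
        for ce, per_ce in profile.items():
            rows = [(registry[lbl].mz, rel) for lbl, rel in sorted(per_ce.items())]
            rows.append((spec.mz, survival.get(ce, 0.1)))
            table[ce] = sorted(rows)
    else:
        diag40 = _free_profile(
            replace(spec, conjugate=None, fragment_profile=spec.fragment_profile),
            registry,
        ).get(40.0, {})
        for ce in (10.0, 20.0, 40.0):
            rows = [(spec.free_mz, CONJUGATE_FREE_ION[ce])]
            if spec.conjugate == "sulfate":
                if CONJUGATE_SO3[ce] > 0:
                    rows.append((SULFITE_RADICAL_MZ, CONJUGATE_SO3[ce]))
                if CONJUGATE_HSO4[ce] > 0:
                    rows.append((HYDROGEN_SULFATE_MZ, CONJUGATE_HSO4[ce]))
            if ce == 40.0:
                rows.extend(
                    (registry[lbl].mz, rel * CONJUGATE_DIAG_SCALE)
                    for lbl, rel in sorted(diag40.items())
                )
            rows.append((spec.mz, survival.get(ce, 0.1)))
            table[ce] = sorted(rows)
    return table


# ---------------------------------------------------------------------------
# run generation
# ---------------------------------------------------------------------------

def _gauss(t: float, rt: float, sigma: float) -> float:
    return math.exp(-0.5 * ((t - rt) / sigma) ** 2)


class _PeakBuilder:
    """Accumulates jittered, Poisson-noised centroid peaks for one scan."""

    def __init__(self, rng: np.random.Generator, jitter_ppm: float,
                 mz_range: tuple[float, float]):
        self.rng = rng
        self.jitter = jitter_ppm
        self.lo, self.hi = mz_range
        self.mz: list[float] = []
        self.intensity: list[float] = []

    def add(self, mz: float, intensity: float) -> None:
        if intensity < 5.0 or not (self.lo <= mz <= self.hi):
            return
        eps = float(self.rng.normal(0.0, self.jitter))
        eps = max(-3.0 * self.jitter, min(3.0 * self.jitter, eps))
        noisy = float(self.rng.poisson(intensity))
        if noisy <= 0:
            return
        self.mz.append(mz * (1.0 + eps * 1e-6))
        self.intensity.append(noisy)

    def add_noise(self, n: int, scale: float) -> None:
        mzs = self.rng.uniform(self.lo, self.hi, n)
        intens = self.rng.exponential(scale, n)
        for m, i in zip(mzs, intens):
            if i >= 5.0:
                self.mz.append(float(m))
                self.intensity.append(float(np.floor(i)))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.mz), np.asarray(self.intensity)


def generate_run(
    compounds: Sequence[CompoundSpec],
    matrix: MatrixModel | None = None,
    mode: str = "DDA",
    seed: int = 0,
    registry: DiagnosticRegistry | None = None,
    config: SimConfig = SimConfig(),
    rt_window: Optional[tuple[float, float]] = None,
) -> tuple[SpectrumRun, GroundTruth]:
    """Simulate one acquisition and return it with its ground truth.

    ``rt_window`` defaults to the compound retention range padded by 0.75
    min; pass it explicitly for blank runs so they cover the sample window.
    Identical seeds reproduce identical runs byte-for-byte after mzML
    serialization.
    """
    if mode not in ("DDA", "DIA"):
        raise ValueError("mode must be 'DDA' or 'DIA'")
    matrix = matrix if matrix is not None else default_matrix()
    registry = registry or build_registry()
    names = [c.name for c in compounds]
    if len(set(names)) != len(names):
        raise ValueError("compound names must be distinct")

    if rt_window is None:
        if compounds:
            rts = [c.rt for c in compounds]
            rt_window = (min(rts) - 0.75, max(rts) + 0.75)
        else:
            rt_window = (0.0, 2.0)
    t0, t1 = rt_window
    for c in compounds:
        if not (t0 <= c.rt <= t1):
            raise ValueError(
                f"{c.name}: rt {c.rt} outside the run window {rt_window}"
            )

    rng = np.random.default_rng(seed)
    sigma = config.peak_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    tables = {c.name: _fragment_table(c, registry) for c in compounds}
    apex = {
        c.name: c.concentration * c.response_factor * matrix.suppression
        for c in compounds
    }

    spectra: list[Spectrum] = []
    exclusion: dict[float, float] = {}  # precursor m/z -> excluded-until time
    index = 0
    n_cycles = int(round((t1 - t0) / config.cycle_time))
    for k in range(n_cycles):
        t = t0 + k * config.cycle_time
        # ---- full scan -------------------------------------------------
        builder = _PeakBuilder(rng, config.mz_jitter_ppm, config.scan_range)
        ms1_species: list[tuple[float, float, str]] = []  # (mz, inten, name)
        for c in compounds:
            inten = apex[c.name] * _gauss(t, c.rt, sigma)
            builder.add(c.mz, inten)
            ms1_species.append((c.mz, inten, c.name))
        for i_mz, i_rt, i_apex in matrix.interference:
            inten = i_apex * _gauss(t, i_rt, sigma)
            builder.add(i_mz, inten)
            ms1_species.append((i_mz, inten, f"__interference@{i_mz:.4f}"))
        builder.add_noise(matrix.n_noise_peaks, matrix.noise_level)
        mz_arr, int_arr = builder.arrays()
        spectra.append(
            Spectrum(index, 1, t, mz_arr, int_arr, 0.0, ACQ_FULL)
        )
        index += 1

        if mode == "DDA":
            # ---- top-N trigger with dynamic exclusion ------------------
            triggerable = [
                (inten, mz, name)
                for mz, inten, name in ms1_species
                if inten >= config.trigger_threshold
                and exclusion.get(round(mz, 3), -1.0) < t
            ]
            triggerable.sort(key=lambda x: (-x[0], x[1]))
            for rank, (inten, prec_mz, name) in enumerate(
                triggerable[: config.top_n]
            ):
                exclusion[round(prec_mz, 3)] = t + config.dynamic_exclusion
                for j, ce in enumerate(config.ce_scheme):
                    b = _PeakBuilder(
                        rng, config.mz_jitter_ppm, config.ms2_scan_range
                    )
                    for mz, sp_int, sp_name in ms1_species:
                        if abs(mz - prec_mz) > config.isolation_width / 2:
                            continue
                        if sp_name.startswith("__interference"):
                            b.add(91.0184, sp_int * 0.5)
                            b.add(mz, sp_int * DEFAULT_SURVIVAL.get(ce, 0.1))
                        else:
                            for f_mz, rel in tables[sp_name].get(ce, []):
                                b.add(f_mz, sp_int * rel)
                    b.add_noise(matrix.n_noise_peaks_ms2, matrix.noise_level)
                    m2, i2 = b.arrays()
                    spectra.append(
                        Spectrum(
                            index, 2,
                            t + (rank * len(config.ce_scheme) + j + 1) * 1e-3,
                            m2, i2, ce, ACQ_DDMS2,
                            precursor_mz=prec_mz,
                            isolation_width=config.isolation_width,
                        )
                    )
                    index += 1
        else:  # DIA / AIF
            lo, hi = config.ms2_scan_range
            center, width = (lo + hi) / 2, hi - lo
            for j, ce in enumerate(config.ce_scheme):
                b = _PeakBuilder(rng, config.mz_jitter_ppm, config.ms2_scan_range)
                for mz, sp_int, sp_name in ms1_species:
                    if sp_name.startswith("__interference"):
                        b.add(91.0184, sp_int * 0.5)
                        b.add(mz, sp_int * DEFAULT_SURVIVAL.get(ce, 0.1))
                    else:
                        # fragment tables already carry the residual
                        # precursor at the per-CE survival fraction
                        for f_mz, rel in tables[sp_name].get(ce, []):
                            b.add(f_mz, sp_int * rel)
                b.add_noise(matrix.n_noise_peaks_ms2 * 2, matrix.noise_level)
                m2, i2 = b.arrays()
                spectra.append(
                    Spectrum(
                        index, 2, t + (j + 1) * 2e-3, m2, i2, ce, ACQ_AIF,
                        precursor_mz=center, isolation_width=width,
                    )
                )
                index += 1

    entries = []
    for c in compounds:
        n_applicable = len(_applicable_labels(c, registry))
        expected = (
            c.conjugate is None
            and apex[c.name] >= config.trigger_threshold
            and n_applicable >= 4
        )
        entries.append(
            GroundTruthEntry(
                name=c.name,
                mz=c.mz,
                rt=c.rt,
                concentration=c.concentration,
                compound_class=c.compound_class,
                conjugate=c.conjugate,
                apex_intensity=apex[c.name],
                n_applicable_ions=n_applicable,
                expected_candidate=expected,
            )
        )
    run = SpectrumRun(
        spectra=spectra,
        mode=mode,
        ce_scheme=tuple(config.ce_scheme),
        metadata={
            "scan_range": config.scan_range,
            "ms2_scan_range": config.ms2_scan_range,
            "isolation_width": config.isolation_width,
            "rt_window": rt_window,
        },
    )
    return run, GroundTruth(mode=mode, seed=seed, entries=entries)


def specs_from_standards(
    names: Sequence[str],
    concentration: float,
    standards: Sequence[Standard] = STANDARDS,
) -> list[CompoundSpec]:
    """CompoundSpecs for named standards at one spike concentration."""
    by_name = {s.name: s for s in standards}
    specs = []
    for name in names:
        s = by_name[name]
        specs.append(
            CompoundSpec(
                name=s.name,
                formula=s.formula,
                rt=s.rt,
                compound_class=s.compound_class,
                concentration=concentration,
            )
        )
    return specs


@dataclass
class SpikeSeries:
    runs: list[tuple[float, int, SpectrumRun, GroundTruth]]  # (level, rep, ...)
    blanks: list[SpectrumRun]
    manifest: pd.DataFrame


def generate_spike_series(
    compound_names: Sequence[str] = ("MeP", "EtP", "PrP", "BuP", "BzP"),
    levels: Sequence[float] = (1.0, 5.0, 25.0),
    replicates: int = 3,
    matrix: MatrixModel | None = None,
    mode: str = "DDA",
    seed: int = 0,
) -> SpikeSeries:
    """Spiked-sample series: ``levels x replicates`` runs plus 3 blanks.

    Replicates at a level share compound retention times but have
    independent noise; blanks share the matrix (and its interference
    channels) only.  Deterministic for a given seed.
    """
    if list(levels) != sorted(levels):
        raise ValueError("spike levels must be ascending")
    matrix = matrix if matrix is not None else default_matrix()
    registry = build_registry()
    master = np.random.default_rng(seed)

    base_specs = specs_from_standards(compound_names, 1.0)
    rts = [s.rt for s in base_specs]
    window = (min(rts) - 0.75, max(rts) + 0.75)

    runs = []
    rows = []
    for level in levels:
        for rep in range(replicates):
            child_seed = int(master.integers(0, 2**31 - 1))
            specs = [replace(s, concentration=level) for s in base_specs]
            run, truth = generate_run(
                specs, matrix, mode=mode, seed=child_seed,
                registry=registry, rt_window=window,
            )
            runs.append((level, rep, run, truth))
            m = truth.manifest()
            m.insert(0, "replicate", rep)
            m.insert(0, "level_ng_mL", level)
            rows.append(m)
    blanks = []
    for rep in range(3):
        child_seed = int(master.integers(0, 2**31 - 1))
        blank, _ = generate_run(
            [], matrix, mode=mode, seed=child_seed,
            registry=registry, rt_window=window,
        )
        blanks.append(blank)
    manifest = pd.concat(rows, ignore_index=True)
    return SpikeSeries(runs=runs, blanks=blanks, manifest=manifest)
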