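"""Centroid mzML input/output, scan modelling and ion chromatograms.

A run is an ordered list of centroid spectra carrying MS level, retention
time (minutes throughout — the chromatographic gradient is specified in
minutes), collision energy, acquisition type (full scan, ddMS2, or all-ion
fragmentation) and, for ddMS2, the precursor isolation window.

Reading and writing use a self-contained mzML 1.1.0 layer built on lxml
(64-bit float binary arrays, zlib or no compression on read, uncompressed on
write) that round-trips exactly.  Only centroided data are supported:
spectra flagged as profile mode are rejected loudly, mirroring a workflow
that operates on centroided Orbitrap data.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from scipy import signal as _signal

__all__ = [
    "Spectrum",
    "SpectrumRun",
    "EIC",
    "ChromPeak",
    "UnsupportedDataError",
    "read_run",
    "write_run",
    "extract_eic",
    "detect_peaks",
]

ACQ_FULL = "full"
ACQ_DDMS2 = "ddMS2"
ACQ_AIF = "AIF"

#: Default acquisition metadata: full-scan range 80-1000 m/z, AIF range
#: 75-1000, 1.5 Th ddMS2 isolation window, 10/20/40 eV collision energies.
DEFAULT_METADATA = {
    "scan_range": (80.0, 1000.0),
    "ms2_scan_range": (75.0, 1000.0),
    "isolation_width": 1.5,
}
DEFAULT_CE_SCHEME = (10.0, 20.0, 40.0)


class UnsupportedDataError(ValueError):
    """Raised for inputs outside the supported centroid/negative-mode model."""


@dataclass
class Spectrum:
    """One centroid scan."""

    index: int
    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    collision_energy: float = 0.0  # eV; 0 for full scans
    acquisition: str = ACQ_FULL
    precursor_mz: Optional[float] = None  # isolation center (ddMS2/AIF)
    isolation_width: Optional[float] = None  # Th

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if self.ms_level == 2 and self.acquisition == ACQ_FULL:
            raise ValueError("MS2 spectrum requires ddMS2 or AIF acquisition tag")
        if self.acquisition == ACQ_DDMS2 and self.precursor_mz is None:
            raise ValueError("ddMS2 spectrum requires precursor isolation info")


@dataclass
class SpectrumRun:
    """An ordered LC-MS(/MS) acquisition."""

    spectra: list[Spectrum]
    mode: str = "full_only"  # DDA | DIA | full_only
    ce_scheme: tuple[float, ...] = DEFAULT_CE_SCHEME
    metadata: dict = field(default_factory=lambda: dict(DEFAULT_METADATA))

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.rt)
        if self.mode in ("DDA", "DIA") and not self.ce_scheme:
            raise ValueError("DDA/DIA runs need a non-empty CE scheme")

    def __len__(self) -> int:
        return len(self.spectra)

    def scans(
        self,
        ms_level: Optional[int] = None,
        acquisition: Optional[str] = None,
        ce: Optional[float] = None,
    ) -> list[Spectrum]:
        out = []
        for s in self.spectra:
            if ms_level is not None and s.ms_level != ms_level:
                continue
            if acquisition is not None and s.acquisition != acquisition:
                continue
            if ce is not None and abs(s.collision_energy - ce) > 0.25:
                continue
            out.append(s)
        return out


@dataclass
class EIC:
    """Extracted ion chromatogram in a ppm window around a target m/z."""

    target_mz: float
    tolerance_ppm: float
    rt: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    collision_energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)


@dataclass(frozen=True)
class ChromPeak:
    rt: float  # apex, minutes
    height: float
    area: float
    rt_start: float
    rt_end: float
    snr: float


# ---------------------------------------------------------------------------
# mzML writing
# ---------------------------------------------------------------------------

def _b64(array: np.ndarray) -> str:
    return base64.b64encode(
        np.asarray(array, dtype="<f8").tobytes()
    ).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: str | None = None) -> str:
    unit_attr = ""
    if unit == "minute":
        unit_attr = ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"'
    elif unit == "ev":
        unit_attr = ' unitCvRef="UO" unitAccession="UO:0000266" unitName="electronvolt"'
    elif unit == "mz":
        unit_attr = ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'
    elif unit == "counts":
        unit_attr = ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"'
    return (
        f'<cvParam cvRef="MS" accession="{accession}" name="{name}" '
        f'value="{value}"{unit_attr}/>'
    )


def _spectrum_xml(s: Spectrum, index: int) -> str:
    parts = [
        f'<spectrum index="{index}" id="scan={index + 1}" '
        f'defaultArrayLength="{s.mz.size}">',
        _cv("MS:1000511", "ms level", str(s.ms_level)),
        _cv("MS:1000127", "centroid spectrum"),
        _cv("MS:1000129", "negative scan"),
        _cv("MS:1000579", "MS1 spectrum") if s.ms_level == 1
        else _cv("MS:1000580", "MSn spectrum"),
        f'<userParam name="acquisition" value="{s.acquisition}"/>',
        '<scanList count="1">',
        _cv("MS:1000795", "no combination"),
        "<scan>",
        _cv("MS:1000016", "scan start time", f"{s.rt:.6f}", unit="minute"),
        "</scan>",
        "</scanList>",
    ]
    if s.ms_level == 2:
        center = s.precursor_mz if s.precursor_mz is not None else 0.0
        width = s.isolation_width if s.isolation_width is not None else 0.0
        parts += [
            '<precursorList count="1">',
            "<precursor>",
            "<isolationWindow>",
            _cv("MS:1000827", "isolation window target m/z", f"{center:.6f}", unit="mz"),
            _cv("MS:1000828", "isolation window lower offset", f"{width / 2:.6f}", unit="mz"),
            _cv("MS:1000829", "isolation window upper offset", f"{width / 2:.6f}", unit="mz"),
            "</isolationWindow>",
        ]
        if s.acquisition == ACQ_DDMS2:
            parts += [
                '<selectedIonList count="1">',
                "<selectedIon>",
                _cv("MS:1000744", "selected ion m/z", f"{center:.6f}", unit="mz"),
                "</selectedIon>",
                "</selectedIonList>",
            ]
        parts += [
            "<activation>",
            _cv("MS:1000422", "beam-type collision-induced dissociation"),
            _cv("MS:1000045", "collision energy", f"{s.collision_energy:.2f}", unit="ev"),
            "</activation>",
            "</precursor>",
            "</precursorList>",
        ]
    mz_b64 = _b64(s.mz)
    int_b64 = _b64(s.intensity)
    parts += [
        '<binaryDataArrayList count="2">',
        f'<binaryDataArray encodedLength="{len(mz_b64)}">',
        _cv("MS:1000523", "64-bit float"),
        _cv("MS:1000576", "no compression"),
        _cv("MS:1000514", "m/z array", unit="mz"),
        f"<binary>{mz_b64}</binary>",
        "</binaryDataArray>",
        f'<binaryDataArray encodedLength="{len(int_b64)}">',
        _cv("MS:1000523", "64-bit float"),
        _cv("MS:1000576", "no compression"),
        _cv("MS:1000515", "intensity array", unit="counts"),
        f"<binary>{int_b64}</binary>",
        "</binaryDataArray>",
        "</binaryDataArrayList>",
        "</spectrum>",
    ]
    return "".join(parts)


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<cvList count="2">
<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
</cvList>
<fileDescription><fileContent>
<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
</fileContent></fileDescription>
<softwareList count="1"><software id="dfiscreen" version="0.1.0"><cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="dfiscreen"/></software></softwareList>
<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"><cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/></instrumentConfiguration></instrumentConfigurationList>
<dataProcessingList count="1"><dataProcessing id="dp1"><processingMethod order="0" softwareRef="dfiscreen"><cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/></processingMethod></dataProcessing></dataProcessingList>
"""


def write_run(run: SpectrumRun, path: str | Path) -> None:
    """Serialize a run to centroid mzML 1.1.0 (uncompressed 64-bit floats)."""
    path = Path(path)
    chunks = [_MZML_HEADER]
    chunks.append(
        '<run id="run" defaultInstrumentConfigurationRef="IC1">'
        f'<spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="dp1">'
    )
    for i, s in enumerate(run.spectra):
        chunks.append(_spectrum_xml(s, i))
    chunks.append("</spectrumList></run></mzML>\n")
    path.write_text("".join(chunks), encoding="utf-8")


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, str]:
    """name -> value for the cvParams/userParams directly under ``elem``."""
    out = {}
    for child in elem:
        if _local(child.tag) in ("cvParam", "userParam"):
            out[child.get("name")] = child.get("value", "")
    return out


def _find_child(elem, name):
    for child in elem:
        if _local(child.tag) == name:
            return child
    return None


def _iter_children(elem, name):
    return [c for c in elem if _local(c.tag) == name]


def _decode_binary_arrays(spectrum_elem) -> tuple[np.ndarray, np.ndarray]:
    mz = intensity = None
    bdal = _find_child(spectrum_elem, "binaryDataArrayList")
    if bdal is None:
        return np.empty(0), np.empty(0)
    for bda in _iter_children(bdal, "binaryDataArray"):
        params = _cv_params(bda)
        binary = _find_child(bda, "binary")
        raw = base64.b64decode(binary.text or "")
        if "zlib compression" in params:
            raw = zlib.decompress(raw)
        if "64-bit float" in params:
            data = np.frombuffer(raw, dtype="<f8")
        elif "32-bit float" in params:
            data = np.frombuffer(raw, dtype="<f4").astype(np.float64)
        else:
            raise UnsupportedDataError("unsupported binary array encoding")
        if "m/z array" in params:
            mz = data
        elif "intensity array" in params:
            intensity = data
    if mz is None or intensity is None:
        return np.empty(0), np.empty(0)
    return mz.copy(), intensity.copy()


def _parse_spectrum(elem, index: int, path_name: str) -> Spectrum:
    params = _cv_params(elem)
    if "profile spectrum" in params:
        raise UnsupportedDataError(
            f"{path_name}: profile-mode spectra are not supported; "
            "centroid the data first"
        )
    ms_level = int(params.get("ms level", 1))
    acquisition = params.get(
        "acquisition", ACQ_FULL if ms_level == 1 else ACQ_DDMS2
    )
    rt = 0.0
    scan_list = _find_child(elem, "scanList")
    if scan_list is not None:
        scan = _find_child(scan_list, "scan")
        if scan is not None:
            for child in scan:
                if (
                    _local(child.tag) == "cvParam"
                    and child.get("name") == "scan start time"
                ):
                    rt = float(child.get("value"))
                    if "second" in (child.get("unitName") or ""):
                        rt /= 60.0
    ce = 0.0
    precursor_mz = None
    isolation_width = None
    plist = _find_child(elem, "precursorList")
    if plist is not None:
        prec = _find_child(plist, "precursor")
        iso = _find_child(prec, "isolationWindow")
        if iso is not None:
            iso_params = _cv_params(iso)
            if "isolation window target m/z" in iso_params:
                precursor_mz = float(iso_params["isolation window target m/z"])
                lo = float(iso_params.get("isolation window lower offset", 0.0))
                hi = float(iso_params.get("isolation window upper offset", 0.0))
                isolation_width = lo + hi
        act = _find_child(prec, "activation")
        if act is not None:
            act_params = _cv_params(act)
            if "collision energy" in act_params:
                ce = float(act_params["collision energy"])
    mz, intensity = _decode_binary_arrays(elem)
    return Spectrum(
        index=index,
        ms_level=ms_level,
        rt=rt,
        mz=mz,
        intensity=intensity,
        collision_energy=ce,
        acquisition=acquisition,
        precursor_mz=precursor_mz,
        isolation_width=isolation_width,
    )


def read_run(path: str | Path) -> SpectrumRun:
    """Read a centroid mzML file into a :class:`SpectrumRun`.

    Collision energy and acquisition type are taken from per-scan metadata;
    the run mode is inferred from the scan types present (any ddMS2 scan ->
    DDA, any AIF scan -> DIA, otherwise full_only).  Profile-mode spectra
    raise :class:`UnsupportedDataError`; malformed XML raises an lxml parse
    error.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    index = 0
    for _, elem in etree.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        spectra.append(_parse_spectrum(elem, index, path.name))
        index += 1
        elem.clear(keep_tail=True)
    acqs = {s.acquisition for s in spectra}
    if ACQ_DDMS2 in acqs:
        mode = "DDA"
    elif ACQ_AIF in acqs:
        mode = "DIA"
    else:
        mode = "full_only"
    ces = tuple(sorted({s.collision_energy for s in spectra if s.ms_level == 2}))
    return SpectrumRun(
        spectra=spectra,
        mode=mode,
        ce_scheme=ces if ces else DEFAULT_CE_SCHEME,
    )


# ---------------------------------------------------------------------------
# chromatogram extraction and peak detection
# ---------------------------------------------------------------------------

def extract_eic(
    run: SpectrumRun,
    target_mz: float,
    tolerance_ppm: float,
    ms_level: int = 1,
    ce: Optional[float] = None,
    acquisition: Optional[str] = None,
) -> EIC:
    """Sum peak intensities within +-tolerance_ppm of ``target_mz`` per scan.

    Scans are filtered by MS level and, optionally, collision energy and
    acquisition type; scans without a matching peak contribute zero.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    half = target_mz * tolerance_ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    rts, intens = [], []
    for s in run.scans(ms_level=ms_level, acquisition=acquisition, ce=ce):
        rts.append(s.rt)
        if s.mz.size:
            i0, i1 = np.searchsorted(s.mz, (lo, hi))
            intens.append(float(s.intensity[i0:i1].sum()))
        else:
            intens.append(0.0)
    return EIC(
        target_mz=target_mz,
        tolerance_ppm=tolerance_ppm,
        rt=np.array(rts),
        intensity=np.array(intens),
        ms_level=ms_level,
        collision_energy=ce,
    )


def _mad_noise(y: np.ndarray) -> float:
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    return 1.4826 * float(mad)


def detect_peaks(eic: EIC, min_snr: float = 3.0) -> list[ChromPeak]:
    """Local-maximum chromatographic peaks with MAD-based signal-to-noise.

    Noise is 1.4826 x the median absolute deviation of the trace computed
    outside detected peak regions (floored at one count so that S/N stays
    finite on zero-baseline traces).  Peaks with S/N below ``min_snr`` are
    dropped.  Deterministic for a given trace.
    """
    y = eic.intensity
    if y.size == 0:
        raise ValueError("empty EIC trace")
    if not np.any(y > 0):
        return []
    idx, props = _signal.find_peaks(y, height=0.0, prominence=np.max(y) * 0.02)
    if idx.size == 0:
        return []
    widths, _, left_ips, right_ips = _signal.peak_widths(y, idx, rel_height=0.97)
    # noise from the peak-free portion of the trace
    mask = np.ones(y.size, dtype=bool)
    for li, ri in zip(left_ips, right_ips):
        mask[int(np.floor(li)) : int(np.ceil(ri)) + 1] = False
    baseline = y[mask]
    noise = _mad_noise(baseline) if baseline.size else 0.0
    noise = max(noise, 1.0)
    peaks = []
    for j, (i, li, ri) in enumerate(zip(idx, left_ips, right_ips)):
        i0, i1 = int(np.floor(li)), int(np.ceil(ri))
        height = float(y[i])
        snr = height / noise
        if snr < min_snr:
            continue
        area = float(np.trapezoid(y[i0 : i1 + 1], eic.rt[i0 : i1 + 1]))
        peaks.append(
            ChromPeak(
                rt=float(eic.rt[i]),
                height=height,
                area=area,
                rt_start=float(eic.rt[i0]),
                rt_end=float(eic.rt[i1]),
                snr=snr,
            )
        )
    return peaks


def peaks_to_frame(peaks: Sequence[ChromPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rt": p.rt,
                "height": p.height,
                "area": p.area,
                "rt_start": p.rt_start,
                "rt_end": p.rt_end,
                "snr": p.snr,
            }
            for p in peaks
        ],
        columns=["rt", "height", "area", "rt_start", "rt_end", "snr"],
    )
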