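"""Elemental mass arithmetic for negative-mode small-molecule screening.

Everything downstream (the diagnostic-ion registry, precursor formula
assignment, conjugate mass prediction) is built on the primitives here:
monoisotopic masses over a small CHONS(+D) alphabet, the deprotonation
convention for [M-H]- ions, signed ppm errors, ring-and-double-bond
equivalents (RDBE), and bounded enumeration of candidate elemental formulas.

Mass convention
---------------
[M-H]- m/z is computed as the neutral monoisotopic mass minus the mass of a
hydrogen *atom* (1.007825 Da), neglecting the electron.  This is the
convention used throughout the Orbitrap screening literature for printed
fragment m/z values (e.g. 4-hydroxybenzoate at 137.0239, not 137.0244) and it
carries a systematic ~0.00055 Da offset versus proton-mass subtraction.  At
the 5-10 ppm tolerances used for screening the offset is immaterial, but it
matters when matching published 4-decimal m/z tables.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "MONOISOTOPIC",
    "HYDROGEN_MASS",
    "ELECTRON_OFFSET_NOTE",
    "ElementalFormula",
    "FormulaCandidate",
    "ElementBounds",
    "DEFAULT_BOUNDS",
    "monoisotopic_mass",
    "mz_deprotonated",
    "ppm_error",
    "rdbe",
    "decompose_mass",
]

#: Monoisotopic atomic masses (Da).  D is deuterium: counted as hydrogen for
#: RDBE purposes but carrying its own mass.
MONOISOTOPIC: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825032,
    "D": 2.014101778,
    "N": 14.003074005,
    "O": 15.994914620,
    "S": 31.972071174,
}

HYDROGEN_MASS = MONOISOTOPIC["H"]

ELECTRON_OFFSET_NOTE = (
    "m/z = M - 1.007825 (hydrogen-atom subtraction, electron mass neglected); "
    "systematic offset vs proton subtraction ~0.00055 Da"
)

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping[str, int]):
    """Immutable element->count mapping over the C/H/D/N/O/S alphabet.

    Parsed from and rendered to Hill notation (carbon, hydrogen, then the
    remaining elements alphabetically, with deuterium written as ``D`` right
    after ``H``).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = dict(counts)
        clean: dict[str, int] = {}
        for elem, n in items.items():
            if elem not in MONOISOTOPIC:
                raise ValueError(f"unknown element symbol: {elem!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {elem}: {n}")
            if n:
                clean[elem] = n
        if not clean:
            raise ValueError("formula must contain at least one atom")
        self._counts = clean

    # -- construction -----------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-notation formula string such as ``"C7H6O3"``."""
        if not text or not text.strip():
            raise ValueError("empty formula string")
        pos = 0
        counts: dict[str, int] = {}
        for match in _TOKEN.finditer(text.strip()):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            if not match.group(0):
                break
            elem, num = match.group(1), match.group(2)
            counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
            pos = match.end()
        if pos != len(text.strip()):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    # -- Mapping protocol --------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        return self._counts.get(elem, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, elem: object) -> bool:
        return elem in self._counts

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self._counts)
        for elem, n in other.items():
            merged[elem] = merged.get(elem, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self._counts)
        for elem, n in other.items():
            merged[elem] = merged.get(elem, 0) - n
            if merged[elem] < 0:
                raise ValueError(
                    f"cannot subtract {other} from {self}: negative {elem}"
                )
        return ElementalFormula(merged)

    def replace_h_with_d(self, n: int) -> "ElementalFormula":
        """Substitute ``n`` protium atoms with deuterium."""
        if n < 0:
            raise ValueError("substitution count must be >= 0")
        if n == 0:
            return self
        if n > self["H"]:
            raise ValueError(
                f"{self} has only {self['H']} H; cannot substitute {n}"
            )
        counts = dict(self._counts)
        counts["H"] = counts.get("H", 0) - n
        counts["D"] = counts.get("D", 0) + n
        return ElementalFormula(counts)

    # -- rendering ---------------------------------------------------------
    def hill(self) -> str:
        order = []
        if "C" in self._counts:
            order.append("C")
            if "H" in self._counts:
                order.append("H")
            order.extend(sorted(e for e in self._counts if e not in ("C", "H")))
        else:
            order = sorted(self._counts)
        out = []
        for elem in order:
            n = self._counts[elem]
            out.append(elem if n == 1 else f"{elem}{n}")
        return "".join(out)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def _as_formula(formula: ElementalFormula | str) -> ElementalFormula:
    if isinstance(formula, str):
        return ElementalFormula.parse(formula)
    return formula


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass (Da) of a neutral molecule or a bare ion composition."""
    f = _as_formula(formula)
    return sum(MONOISOTOPIC[elem] * n for elem, n in sorted(f.items()))


def mz_deprotonated(neutral: ElementalFormula | str) -> float:
    """[M-H]- m/z of a neutral molecule (hydrogen-atom subtraction)."""
    f = _as_formula(neutral)
    if f["H"] + f["D"] < 1:
        raise ValueError(f"{f} has no abstractable hydrogen for [M-H]-")
    return monoisotopic_mass(f) - HYDROGEN_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def rdbe(formula: ElementalFormula | str) -> float:
    """Ring-and-double-bond equivalents on the neutral-formula basis.

    For the CHOS alphabet this is C - (H + D)/2 + 1; nitrogen (used only for
    amino-acid conjugates) adds the usual +N/2 term.  Radical fragment ions
    are not RDBE-screened; the constraint applies to neutral precursor
    compositions only.
    """
    f = _as_formula(formula)
    return f["C"] - (f["H"] + f["D"]) / 2 + f["N"] / 2 + 1


@dataclass(frozen=True)
class FormulaCandidate:
    """A neutral formula consistent with an observed [M-H]- m/z."""

    formula: ElementalFormula
    mass_error: float  # signed ppm vs the queried m/z
    rdbe: float

    def __str__(self) -> str:
        return f"{self.formula.hill()} ({self.mass_error:+.2f} ppm, RDBE {self.rdbe:.1f})"


@dataclass(frozen=True)
class ElementBounds:
    """Element-count, RDBE and mass-tolerance constraints for decomposition."""

    elements: Mapping[str, tuple[int, int]]
    rdbe_range: tuple[float, float]
    tolerance_ppm: float

    def __post_init__(self) -> None:
        for elem, (lo, hi) in self.elements.items():
            if elem not in MONOISOTOPIC:
                raise ValueError(f"unknown element symbol: {elem!r}")
            if lo > hi or lo < 0:
                raise ValueError(f"invalid bounds for {elem}: ({lo}, {hi})")
        if self.rdbe_range[0] > self.rdbe_range[1]:
            raise ValueError("invalid RDBE range")
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance must be positive")


#: Composition restrictions used for precursor formula assignment:
#: 7-30 C, 6-60 H, 3-10 O, 0-1 S, RDBE 5-10, 5 ppm.
DEFAULT_BOUNDS = ElementBounds(
    elements={"C": (7, 30), "H": (6, 60), "O": (3, 10), "S": (0, 1)},
    rdbe_range=(5.0, 10.0),
    tolerance_ppm=5.0,
)


def _senior_even_electron(counts: Mapping[str, int]) -> bool:
    # Degree-sum parity for a neutral CHNOS molecule: 4C + H + 3N + 2O + 2S
    # must be even for a valid even-electron structure.
    return (counts.get("H", 0) + counts.get("N", 0)) % 2 == 0


def decompose_mass(
    mz: float, bounds: ElementBounds = DEFAULT_BOUNDS
) -> list[FormulaCandidate]:
    """Enumerate neutral formulas whose [M-H]- m/z matches ``mz``.

    Exhaustive over the in-bound element grid: every combination of non-H
    element counts is visited and the hydrogen count solved from the mass
    window, which is equivalent to (but much faster than) brute-force nested
    enumeration over all elements.  The ppm tolerance is applied on the ion
    mass axis.  Results are sorted by |ppm error|, then even-electron (Senior
    rule) validity, then Hill string.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if "H" not in bounds.elements:
        raise ValueError("bounds must include a hydrogen range")

    h_lo, h_hi = bounds.elements["H"]
    others = sorted(e for e in bounds.elements if e != "H")
    ranges = [range(bounds.elements[e][0], bounds.elements[e][1] + 1) for e in others]

    target = mz + HYDROGEN_MASS  # neutral monoisotopic mass at 0 ppm
    tol_da = bounds.tolerance_ppm * 1e-6 * mz
    out: list[FormulaCandidate] = []
    for combo in itertools.product(*ranges):
        base = sum(MONOISOTOPIC[e] * n for e, n in zip(others, combo))
        rem_lo = target - tol_da - base
        rem_hi = target + tol_da - base
        if rem_hi < HYDROGEN_MASS:
            continue
        h_min = max(h_lo, 1, math.ceil(rem_lo / HYDROGEN_MASS - 1e-9))
        h_max = min(h_hi, math.floor(rem_hi / HYDROGEN_MASS + 1e-9))
        for h in range(h_min, h_max + 1):
            counts = {e: n for e, n in zip(others, combo)}
            counts["H"] = h
            neutral_mass = base + h * HYDROGEN_MASS
            err = ppm_error(mz, neutral_mass - HYDROGEN_MASS)
            if abs(err) > bounds.tolerance_ppm:
                continue
            r = counts.get("C", 0) - h / 2 + counts.get("N", 0) / 2 + 1
            if not (bounds.rdbe_range[0] <= r <= bounds.rdbe_range[1]):
                continue
            out.append(
                FormulaCandidate(
                    formula=ElementalFormula(counts), mass_error=err, rdbe=r
                )
            )
    out.sort(
        key=lambda c: (
            abs(c.mass_error),
            not _senior_even_electron(c.formula),
            c.formula.hill(),
        )
    )
    return out
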