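"""Diagnostic product-ion registry for parabens and their phase I metabolites.

Under negative-mode HCD, parabens (alkyl/benzyl 4-hydroxybenzoates) fragment
through a characteristic cascade: cleavage of the ester R group (heterolytic
olefin loss -> A1, homolytic radical loss -> A2), decarboxylation to the
phenolate series (B1/B2/B3), CO elimination from the rearranged acyl species
(C), and a CH-loss branch (D2 -> E).  Ring-hydroxylated metabolites (alkyl
protocatechuates, i.e. 3,4-dihydroxybenzoates) follow the same mechanisms
shifted by one oxygen (F/G/H/J/K series), and several ions (B3, E, C/G2, D2)
are shared between the two classes.  The registry below encodes each ion's
elemental composition, radical character, formation edge (parent ion plus
neutral or radical loss) and class membership, so that m/z values, deuterated
analogs and conjugate masses are always *computed* from formulas rather than
hard-coded.

Screening sets
--------------
Three ions (m/z 91.0184, 95.0133, 108.0211) are common diagnostics for both
classes.  The paraben set adds 92.0262, 93.0340, 136.0160 and 137.0239
(7 ions total); the protocatechuate set adds 109.0290, 111.0082, 124.0160,
152.0110 and 153.0188 (8 ions total).  Methyl and benzyl parabens cannot
undergo the heterolytic R-olefin loss (methyl has no beta-hydrogen; benzyl
would need to lose a benzene ring as an olefin), so A1 — and its CO2-loss
daughter B1 — are excluded from their applicable sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .chem import (
    ElementalFormula,
    HYDROGEN_MASS,
    MONOISOTOPIC,
    monoisotopic_mass,
    mz_deprotonated,
)

__all__ = [
    "FragmentIon",
    "DiagnosticRegistry",
    "build_registry",
    "diagnostic_set",
    "deuterated_analog",
    "conjugate_mass",
    "CONJUGATE_DELTAS",
    "SULFITE_RADICAL_MZ",
    "HYDROGEN_SULFATE_MZ",
]

PARABEN = "paraben"
PROTOCATECHUATE = "protocatechuate"
PHENOLIC_ACID = "phenolic_acid"

#: Compounds for which the heterolytic [R-olefin] loss is structurally
#: impossible, removing A1 and its daughter B1 from the applicable set.
NO_HETEROLYTIC_LOSS = frozenset({"MeP", "BzP"})

#: Marker ions seen in sulfate-conjugate MS2 spectra (module convention for
#: the nominal m/z 80 and 97 ions): the SO3 radical anion and hydrogensulfate.
SULFITE_RADICAL_MZ = monoisotopic_mass("SO3")  # 79.9568
HYDROGEN_SULFATE_MZ = monoisotopic_mass("HSO4")  # 96.9596

#: Neutral mass additions for phase II conjugation of a free phenolic acid or
#: ester.  Sulfation adds SO3; glucuronidation adds C6H8O6; glycine
#: (hippurate-type) conjugation replaces the carboxyl -OH with -NHCH2COOH,
#: a net +C2H3NO on the neutral.
CONJUGATE_DELTAS: dict[str, ElementalFormula] = {
    "sulfate": ElementalFormula.parse("SO3"),
    "glucuronide": ElementalFormula.parse("C6H8O6"),
    "glycine": ElementalFormula.parse("C2H3NO"),
}


@dataclass(frozen=True)
class FragmentIon:
    """A product ion in the fragmentation-pathway graph.

    ``formula`` is the *ion* composition (charge -1, electron mass
    neglected), so its monoisotopic mass is directly the theoretical m/z.
    ``parent`` is the label of the precursor node ("precursor" for ions formed
    directly from [M-H]-) and ``loss`` the neutral/radical loss on that edge.
    ``screening`` is False for mechanistic intermediates drawn in the pathway
    (resonance/rearranged forms) that are not observed as distinct m/z.
    """

    label: str
    formula: ElementalFormula
    radical: bool
    parent: str
    loss: str
    classes: frozenset[str]
    screening: bool = True

    @property
    def mz(self) -> float:
        return monoisotopic_mass(self.formula)

    def __str__(self) -> str:
        return f"{self.label} {self.formula.hill()}{'·' if self.radical else ''}- m/z {self.mz:.4f}"


# label: (ion formula, radical?, parent, loss, classes, screening)
_ION_TABLE: list[tuple[str, str, bool, str, str, frozenset[str], bool]] = [
    # paraben (4-hydroxybenzoate) series
    ("A1", "C7H5O3", False, "precursor", "R-olefin", frozenset({PARABEN}), True),
    ("A2", "C7H4O3", True, "precursor", "R•", frozenset({PARABEN}), True),
    ("A3", "C7H4O3", True, "A2", "rearrangement", frozenset({PARABEN}), False),
    ("B1", "C6H5O", False, "A1", "CO2", frozenset({PARABEN, PHENOLIC_ACID}), True),
    ("B2", "C6H4O", True, "A2", "CO2", frozenset({PARABEN}), True),
    ("B3", "C6H3O", False, "B2", "H•", frozenset({PARABEN, PROTOCATECHUATE, PHENOLIC_ACID}), True),
    ("C", "C6H4O2", True, "A3", "CO", frozenset({PARABEN, PROTOCATECHUATE, PHENOLIC_ACID}), True),
    ("D2", "C6H3O3", False, "A2", "CH", frozenset({PARABEN, PROTOCATECHUATE}), True),
    ("E", "C5H3O2", False, "D2", "CO", frozenset({PARABEN, PROTOCATECHUATE}), True),
    # protocatechuate (3,4-dihydroxybenzoate) series
    ("F1", "C7H5O4", False, "precursor", "R-olefin", frozenset({PROTOCATECHUATE}), True),
    ("F2", "C7H4O4", True, "precursor", "R•", frozenset({PROTOCATECHUATE}), True),
    ("F3", "C7H4O4", True, "F2", "rearrangement", frozenset({PROTOCATECHUATE}), False),
    ("G1", "C6H5O2", False, "F1", "CO2", frozenset({PROTOCATECHUATE, PHENOLIC_ACID}), True),
    ("G3", "C6H3O2", False, "C", "H•", frozenset({PROTOCATECHUATE}), True),
    ("H", "C6H3O4", False, "F2", "CH", frozenset({PROTOCATECHUATE}), True),
    ("J", "C5H3O3", False, "H", "CO", frozenset({PROTOCATECHUATE}), True),
    ("K", "C4H3O2", False, "J", "CO", frozenset({PROTOCATECHUATE}), True),
    ("D1", "C6H4O3", True, "F3", "CO", frozenset({PROTOCATECHUATE}), True),
]

#: Additional pathway edges beyond each ion's primary formation route:
#: (parent label, child label, loss).  G2 is the same ion as C reached from
#: the protocatechuate side.
_EXTRA_EDGES: list[tuple[str, str, str]] = [
    ("F2", "C", "CO2"),   # the "G2" formation route
    ("D1", "D2", "H•"),
    ("G1", "B3", "H2O"),
]

#: Composition of the named losses used for edge mass-balance checks.
_LOSS_FORMULAS: dict[str, str] = {
    "CO2": "CO2",
    "CO": "CO",
    "H•": "H",
    "H2O": "H2O",
    "CH": "CH",
}

#: Alternate label for the shared decarboxylation ion at m/z 108.0211.
G2_ALIAS = "C"


@dataclass(frozen=True)
class DiagnosticRegistry:
    """All pathway ions plus the class screening and characteristic sets."""

    ions: tuple[FragmentIon, ...]
    edges: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        self._check_mass_balance()

    # -- lookup ------------------------------------------------------------
    def __getitem__(self, label: str) -> FragmentIon:
        if label == "G2":
            label = G2_ALIAS
        for ion in self.ions:
            if ion.label == label:
                return ion
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [i.label for i in self.ions]

    @property
    def common_set(self) -> frozenset[str]:
        """Diagnostic ions shared by both screening classes (91/95/108)."""
        return frozenset({"B3", "E", "C"})

    @property
    def paraben_extra(self) -> frozenset[str]:
        return frozenset({"B2", "B1", "A2", "A1"})

    @property
    def protocatechuate_extra(self) -> frozenset[str]:
        return frozenset({"G1", "J", "D1", "F2", "F1"})

    def characteristic_set(self, compound_class: str) -> set[FragmentIon]:
        """All observed (screening-flagged) ions attributed to a class."""
        return {
            i for i in self.ions if i.screening and compound_class in i.classes
        }

    def screening_mzs(self, compound_class: str, compound: str | None = None) -> list[float]:
        return sorted(i.mz for i in diagnostic_set(self, compound_class, compound))

    # -- integrity ---------------------------------------------------------
    def _check_mass_balance(self) -> None:
        by_label = {}
        for ion in self.ions:
            by_label.setdefault(ion.label, ion)
        all_edges = [(i.parent, i.label, i.loss) for i in self.ions] + list(self.edges)
        for parent, child, loss in all_edges:
            if parent == "precursor" or loss == "rearrangement":
                continue
            loss_formula = _LOSS_FORMULAS.get(loss)
            if loss_formula is None:
                raise ValueError(f"unbalanced edge {parent}->{child}: loss {loss!r}")
            expected = by_label[parent].mz - monoisotopic_mass(loss_formula)
            if abs(expected - by_label[child].mz) > 1e-3:
                raise ValueError(
                    f"mass balance violated on {parent} -{loss}-> {child}: "
                    f"{expected:.4f} vs {by_label[child].mz:.4f}"
                )

    # -- export ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": i.label,
                "formula": i.formula.hill(),
                "mz": round(i.mz, 4),
                "radical": i.radical,
                "parent": i.parent,
                "loss": i.loss,
                "classes": "|".join(sorted(i.classes)),
                "screening": i.screening,
            }
            for i in self.ions
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_registry() -> DiagnosticRegistry:
    """Construct the diagnostic-ion registry, verifying edge mass balance."""
    ions = tuple(
        FragmentIon(
            label=label,
            formula=ElementalFormula.parse(formula),
            radical=radical,
            parent=parent,
            loss=loss,
            classes=classes,
            screening=screening,
        )
        for label, formula, radical, parent, loss, classes, screening in _ION_TABLE
    )
    return DiagnosticRegistry(ions=ions, edges=tuple(_EXTRA_EDGES))


def diagnostic_set(
    registry: DiagnosticRegistry,
    compound_class: str,
    compound: Optional[str] = None,
) -> set[FragmentIon]:
    """Class screening set, minus per-compound structural exclusions.

    MeP and BzP cannot form A1 (no heterolytic R-olefin loss) and therefore
    cannot form its CO2-loss daughter B1 either; both are dropped from their
    applicable sets.
    """
    if compound_class == PARABEN:
        labels = set(registry.common_set) | set(registry.paraben_extra)
    elif compound_class == PROTOCATECHUATE:
        labels = set(registry.common_set) | set(registry.protocatechuate_extra)
    else:
        raise ValueError(f"unknown screening class: {compound_class!r}")
    if compound is not None and compound in NO_HETEROLYTIC_LOSS:
        labels -= {"A1", "B1"}
    return {registry[label] for label in labels}


def deuterated_analog(ion: FragmentIon, ring_deuteriums: int) -> FragmentIon:
    """Ring-deuterated analog of a fragment ion (e.g. for PrP-d4 standards).

    Substitutes ``ring_deuteriums`` hydrogens with deuterium and recomputes
    the m/z; the caller accounts for deuterium consumed by ring-hydrogen
    losses on the pathway (a CD loss leaves one fewer D on the daughter).
    """
    if ring_deuteriums == 0:
        return ion
    new_formula = ion.formula.replace_h_with_d(ring_deuteriums)
    return FragmentIon(
        label=f"{ion.label}-d{ring_deuteriums}",
        formula=new_formula,
        radical=ion.radical,
        parent=ion.parent,
        loss=ion.loss,
        classes=ion.classes,
        screening=ion.screening,
    )


def conjugate_mass(
    free_form: ElementalFormula | str, conjugation: str
) -> float:
    """Expected [M-H]- m/z of a phase II conjugate of ``free_form``.

    Sulfation adds SO3 (+79.9568), glucuronidation adds C6H8O6 (+176.0321)
    and glycine conjugation adds C2H3NO (+57.0215) to the neutral mass.
    """
    if conjugation not in CONJUGATE_DELTAS:
        raise ValueError(f"unknown conjugation type: {conjugation!r}")
    if isinstance(free_form, str):
        free_form = ElementalFormula.parse(free_form)
    return mz_deprotonated(free_form + CONJUGATE_DELTAS[conjugation])
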