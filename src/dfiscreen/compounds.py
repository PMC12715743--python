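"""Reference-standard table: parabens, alkyl protocatechuates, phenolic acids.

Fourteen standards spanning the paraben chemical space (linear, branched and
benzyl 4-hydroxybenzoate esters), their ring-hydroxylated phase I metabolites
(3,4-dihydroxybenzoate esters) and the two hydrolysis acids.  Retention
times are the defaults used by the synthetic-run generator: they are
synthetic values on a 30 min reversed-phase (biphenyl) gradient, ordered by
lipophilicity, and include the MeP/OH-EtP and BzP/iPeP coelution pairs seen
on such columns.  Real analyses should override them from a measured
standards table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chem import ElementalFormula, mz_deprotonated
from .fragments import PARABEN, PHENOLIC_ACID, PROTOCATECHUATE

__all__ = ["Standard", "STANDARDS", "standards_frame", "get_standard"]


@dataclass(frozen=True)
class Standard:
    name: str
    full_name: str
    formula: str  # neutral, Hill notation
    smiles: str
    compound_class: str
    rt: float  # minutes (synthetic gradient default)

    @property
    def neutral(self) -> ElementalFormula:
        return ElementalFormula.parse(self.formula)

    @property
    def mz(self) -> float:
        """[M-H]- m/z."""
        return mz_deprotonated(self.neutral)


STANDARDS: tuple[Standard, ...] = (
    Standard("3,4-DHB", "3,4-dihydroxybenzoic acid", "C7H6O4",
             "O=C(O)c1ccc(O)c(O)c1", PHENOLIC_ACID, 2.90),
    Standard("4-HB", "4-hydroxybenzoic acid", "C7H6O3",
             "O=C(O)c1ccc(O)cc1", PHENOLIC_ACID, 3.80),
    Standard("OH-MeP", "methyl 3,4-dihydroxybenzoate", "C8H8O4",
             "COC(=O)c1ccc(O)c(O)c1", PROTOCATECHUATE, 4.70),
    Standard("OH-EtP", "ethyl 3,4-dihydroxybenzoate", "C9H10O4",
             "CCOC(=O)c1ccc(O)c(O)c1", PROTOCATECHUATE, 5.85),
    Standard("MeP", "methyl paraben", "C8H8O3",
             "COC(=O)c1ccc(O)cc1", PARABEN, 5.90),
    Standard("EtP", "ethyl paraben", "C9H10O3",
             "CCOC(=O)c1ccc(O)cc1", PARABEN, 6.90),
    Standard("iPrP", "isopropyl paraben", "C10H12O3",
             "CC(C)OC(=O)c1ccc(O)cc1", PARABEN, 7.60),
    Standard("PrP", "propyl paraben", "C10H12O3",
             "CCCOC(=O)c1ccc(O)cc1", PARABEN, 8.00),
    Standard("iBuP", "isobutyl paraben", "C11H14O3",
             "CC(C)COC(=O)c1ccc(O)cc1", PARABEN, 8.80),
    Standard("BuP", "butyl paraben", "C11H14O3",
             "CCCCOC(=O)c1ccc(O)cc1", PARABEN, 9.20),
    Standard("BzP", "benzyl paraben", "C14H12O3",
             "O=C(OCc1ccccc1)c1ccc(O)cc1", PARABEN, 10.10),
    Standard("iPeP", "isopentyl paraben", "C12H16O3",
             "CC(C)CCOC(=O)c1ccc(O)cc1", PARABEN, 10.18),
    Standard("2-EtHeP", "2-ethylhexyl paraben", "C15H22O3",
             "CCCCC(CC)COC(=O)c1ccc(O)cc1", PARABEN, 12.30),
    Standard("OcP", "octyl paraben", "C15H22O3",
             "CCCCCCCCOC(=O)c1ccc(O)cc1", PARABEN, 12.80),
)

_BY_NAME = {s.name: s for s in STANDARDS}


def get_standard(name: str) -> Standard:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown standard {name!r}; known: {sorted(_BY_NAME)}"
        ) from None


def standards_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": s.name,
                "full_name": s.full_name,
                "formula": s.formula,
                "smiles": s.smiles,
                "class": s.compound_class,
                "rt": s.rt,
                "mz": round(s.mz, 4),
            }
            for s in STANDARDS
        ]
    )
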