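"""Linear QSRR retention-time model.

A quantitative structure-retention relationship maps 2D physicochemical
descriptors of a structure to its retention time on the gradient used for
acquisition.  The descriptor pool is a fixed, documented set of ten standard
RDKit descriptors; model building runs forward stepwise selection that
minimizes leave-one-out RMSE, followed by ordinary least squares on the
selected subset.  The selection step makes the model robust to the exact
composition of the pool.  Predictions feed the identification-confidence
rules through the gap between modeled and experimental retention times
(delta RT).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

__all__ = [
    "DESCRIPTOR_NAMES",
    "compute_descriptors",
    "RTModel",
    "fit_qsrr",
    "delta_rt",
]

#: Fixed descriptor pool, in canonical order.  All are cheap 2D descriptors
#: with a direct reversed-phase interpretation: lipophilicity (clogp), size
#: (mw, heavy_atoms), polarity (tpsa, hbd, hba), flexibility (rotatable
#: bonds, fraction_csp3) and aromaticity (aromatic_rings, ring_count).
_DESCRIPTOR_FUNCS = {
    "aromatic_rings": lambda m: float(rdMolDescriptors.CalcNumAromaticRings(m)),
    "clogp": lambda m: float(Crippen.MolLogP(m)),
    "fraction_csp3": lambda m: float(rdMolDescriptors.CalcFractionCSP3(m)),
    "hba": lambda m: float(Lipinski.NumHAcceptors(m)),
    "hbd": lambda m: float(Lipinski.NumHDonors(m)),
    "heavy_atoms": lambda m: float(m.GetNumHeavyAtoms()),
    "mw": lambda m: float(Descriptors.MolWt(m)),
    "ring_count": lambda m: float(rdMolDescriptors.CalcNumRings(m)),
    "rotatable_bonds": lambda m: float(Lipinski.NumRotatableBonds(m)),
    "tpsa": lambda m: float(rdMolDescriptors.CalcTPSA(m)),
}
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(sorted(_DESCRIPTOR_FUNCS))


def compute_descriptors(smiles: str) -> dict[str, float]:
    """Descriptor vector (fixed order) for a SMILES structure string."""
    if not smiles or not smiles.strip():
        raise ValueError("empty structure string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    return {name: _DESCRIPTOR_FUNCS[name](mol) for name in DESCRIPTOR_NAMES}


def descriptor_table(smiles_list: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame([compute_descriptors(s) for s in smiles_list])


@dataclass
class RTModel:
    """Affine retention model over a selected descriptor subset."""

    descriptor_names: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]  # minutes per descriptor unit
    r_squared: float
    rmse: float  # training RMSE, minutes
    n_training: int

    def predict(self, descriptors: Mapping[str, float] | str) -> float:
        """Predict retention time (minutes) from a descriptor mapping or a
        SMILES string."""
        if isinstance(descriptors, str):
            descriptors = compute_descriptors(descriptors)
        return self.intercept + sum(
            c * descriptors[name]
            for name, c in zip(self.descriptor_names, self.coefficients)
        )

    # plain-text serialization -------------------------------------------
    def to_text(self, path: str | Path) -> None:
        lines = [
            f"# linear QSRR model; n={self.n_training} "
            f"R2={self.r_squared:.6f} RMSE={self.rmse:.4f} min",
            f"intercept\t{self.intercept!r}",
        ]
        for name, c in zip(self.descriptor_names, self.coefficients):
            lines.append(f"{name}\t{c!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "RTModel":
        names, coefs = [], []
        intercept = 0.0
        header = {}
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                for tok in line.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = float(v)
                continue
            key, value = line.split("\t")
            if key == "intercept":
                intercept = float(value)
            else:
                names.append(key)
                coefs.append(float(value))
        return cls(
            descriptor_names=tuple(names),
            intercept=intercept,
            coefficients=tuple(coefs),
            r_squared=header.get("R2", float("nan")),
            rmse=header.get("RMSE", float("nan")),
            n_training=int(header.get("n", 0)),
        )


def _design(X: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    return np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in cols])


def _loo_rmse(A: np.ndarray, y: np.ndarray) -> float:
    """Closed-form leave-one-out RMSE for OLS via the hat matrix."""
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    # hat diagonal through the pseudo-inverse (stable for thin matrices)
    pinv = np.linalg.pinv(A)
    h = np.einsum("ij,ji->i", A, pinv)
    denom = 1.0 - h
    denom[np.abs(denom) < 1e-12] = np.nan
    loo = resid / denom
    if np.any(np.isnan(loo)):
        return float("inf")
    return float(np.sqrt(np.mean(loo**2)))


def fit_qsrr(
    training: pd.DataFrame | Sequence[tuple[Mapping[str, float], float]],
    rt: Sequence[float] | None = None,
    max_descriptors: int = 4,
) -> RTModel:
    """Fit the QSRR model by forward stepwise LOO selection + OLS.

    ``training`` is either a descriptor DataFrame with ``rt`` given
    separately, or a sequence of (descriptor mapping, rt) pairs.  Selection
    adds the descriptor that most reduces leave-one-out RMSE (ties broken
    lexicographically by descriptor name, making the fit independent of row
    or column order) and stops when no descriptor improves it or
    ``max_descriptors`` is reached.  Collinear additions (rank-deficient or
    ill-conditioned designs) are skipped.
    """
    if rt is None:
        pairs = list(training)
        X = pd.DataFrame([dict(d) for d, _ in pairs])
        y = np.array([float(v) for _, v in pairs])
    else:
        X = pd.DataFrame(training).copy()
        y = np.asarray(rt, dtype=float)
    n = len(y)
    if n != len(X):
        raise ValueError("descriptor rows and rt values differ in length")
    if n < max_descriptors + 2:
        raise ValueError(
            f"need at least max_descriptors + 2 = {max_descriptors + 2} "
            f"training rows, got {n}"
        )
    if not np.all(np.isfinite(X.to_numpy(float))):
        raise ValueError("non-finite descriptor values")

    pool = sorted(X.columns)
    selected: list[str] = []
    best_rmse = _loo_rmse(_design(X, []), y)  # intercept-only baseline
    improved = True
    while improved and len(selected) < max_descriptors:
        improved = False
        scores: list[tuple[float, str]] = []
        for name in pool:
            if name in selected:
                continue
            A = _design(X, selected + [name])
            if np.linalg.matrix_rank(A) < A.shape[1] or np.linalg.cond(A) > 1e10:
                continue  # collinear with the current subset
            scores.append((_loo_rmse(A, y), name))
        if not scores:
            break
        scores.sort(key=lambda t: (t[0], t[1]))
        rmse, name = scores[0]
        if rmse < best_rmse - 1e-12:
            selected.append(name)
            best_rmse = rmse
            improved = True
    selected = sorted(selected)

    A = _design(X, selected)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RTModel(
        descriptor_names=tuple(selected),
        intercept=float(beta[0]),
        coefficients=tuple(float(b) for b in beta[1:]),
        r_squared=r2,
        rmse=float(np.sqrt(ss_res / n)),
        n_training=n,
    )


def delta_rt(
    model: RTModel,
    structure: str | Mapping[str, float],
    observed_rt: float,
) -> tuple[float, float]:
    """(predicted rt, |observed - predicted|) in minutes."""
    predicted = model.predict(structure)
    return predicted, abs(observed_rt - predicted)
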