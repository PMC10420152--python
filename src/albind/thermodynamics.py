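"""Van't Hoff thermodynamics of binding and force classification.

The temperature dependence of the association constant gives the standard
enthalpy and entropy changes through the Van't Hoff relation

    ln K = −ΔH⁰/(R·T) + ΔS⁰/R,

an ordinary least-squares line in 1/T, and the free energy change follows
from ΔG⁰ = ΔH⁰ − T·ΔS⁰.  The signs of ΔH⁰ and ΔS⁰ classify the dominant
binding forces (Ross–Subramanian convention): both negative → hydrogen
bonding / van der Waals; both positive → hydrophobic; ΔH⁰ < 0 with
ΔS⁰ > 0 → electrostatic.  The fourth quadrant is reported unclassified.
"""

from __future__ import annotations

import dataclasses
import warnings
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, InsufficientDataError

__all__ = [
    "GAS_CONSTANT",
    "ForceClass",
    "ThermoResult",
    "VantHoffRegression",
    "vant_hoff_fit",
    "gibbs",
    "classify_forces",
]

#: Molar gas constant, J·mol⁻¹·K⁻¹.
GAS_CONSTANT = 8.314


class ForceClass(str, Enum):
    hbond_vdw = "hbond_vdw"
    hydrophobic = "hydrophobic"
    electrostatic = "electrostatic"
    unclassified = "unclassified"


def classify_forces(dH_kJ_per_mol: float, dS_J_per_mol_K: float) -> ForceClass:
    """Dominant binding force from the signs of ΔH⁰ and ΔS⁰.

    Zero values are treated as their closed side of the stated rule table
    never arises in practice; exact zeros fall through to unclassified.
    """
    if not (np.isfinite(dH_kJ_per_mol) and np.isfinite(dS_J_per_mol_K)):
        raise DomainError("ΔH⁰ and ΔS⁰ must be finite")
    if dH_kJ_per_mol < 0 and dS_J_per_mol_K < 0:
        return ForceClass.hbond_vdw
    if dH_kJ_per_mol > 0 and dS_J_per_mol_K > 0:
        return ForceClass.hydrophobic
    if dH_kJ_per_mol < 0 and dS_J_per_mol_K > 0:
        return ForceClass.electrostatic
    return ForceClass.unclassified


def gibbs(dH_kJ_per_mol: float, dS_J_per_mol_K: float, T_K: float) -> float:
    """ΔG⁰ = ΔH⁰ − T·ΔS⁰ in kJ/mol (ΔS⁰ supplied in J·mol⁻¹·K⁻¹)."""
    if T_K <= 0:
        raise DomainError(f"temperature must be > 0 K, got {T_K}")
    return dH_kJ_per_mol - T_K * dS_J_per_mol_K / 1000.0


@dataclasses.dataclass
class ThermoResult:
    """Van't Hoff fit outcome.

    ``dG_kJ_per_mol_by_T[T] = dH_kJ_per_mol − T·dS_J_per_mol_K/1000``
    holds exactly; ``spontaneous`` is True iff every ΔG⁰ is negative.
    """

    dH_kJ_per_mol: float
    dH_stderr_kJ_per_mol: float
    dS_J_per_mol_K: float
    dS_stderr_J_per_mol_K: float
    dG_kJ_per_mol_by_T: dict[float, float]
    r_squared: float
    force_class: ForceClass
    spontaneous: bool
    warnings: list[str] = dataclasses.field(default_factory=list)


class VantHoffRegression(RegressorMixin, BaseEstimator):
    """OLS of ln K on 1/T; slope → ΔH⁰, intercept → ΔS⁰.

    Attributes
    ----------
    dH_kJ_per_mol_ : float
        −slope·R, converted to kJ/mol.
    dS_J_per_mol_K_ : float
        intercept·R.
    r_squared_ : float
    """

    def __init__(self, gas_constant: float = GAS_CONSTANT):
        self.gas_constant = gas_constant

    def fit(self, X, y):
        T = np.asarray(X, dtype=float).reshape(-1)
        Ka = np.asarray(y, dtype=float).reshape(-1)
        if T.size != Ka.size:
            raise DomainError("temperatures and Ka differ in length")
        if T.size < 2:
            raise InsufficientDataError("Van't Hoff fit needs ≥ 2 temperatures")
        if np.any(T <= 0):
            raise DomainError("temperatures must be > 0 K")
        if np.any(Ka <= 0):
            raise DomainError("association constants must be > 0")
        if np.unique(T).size != T.size:
            raise DomainError("temperatures must be distinct")
        self.exact_ = T.size == 2
        if self.exact_:
            warnings.warn(
                "Van't Hoff fit with only 2 temperatures is an exact line "
                "(zero residual)",
                stacklevel=2,
            )
        res = stats.linregress(1.0 / T, np.log(Ka))
        R = self.gas_constant
        self.dH_kJ_per_mol_ = float(-res.slope * R / 1000.0)
        self.dH_stderr_kJ_per_mol_ = float((res.stderr or 0.0) * R / 1000.0)
        self.dS_J_per_mol_K_ = float(res.intercept * R)
        self.dS_stderr_J_per_mol_K_ = float((res.intercept_stderr or 0.0) * R)
        self.r_squared_ = float(res.rvalue**2)
        return self

    def predict(self, X):
        """Predicted Ka at the given temperatures."""
        T = np.asarray(X, dtype=float).reshape(-1)
        R = self.gas_constant
        lnK = -self.dH_kJ_per_mol_ * 1000.0 / (R * T) + self.dS_J_per_mol_K_ / R
        return np.exp(lnK)


def vant_hoff_fit(
    temperatures_K: Sequence[float], Ka_per_M: Sequence[float]
) -> ThermoResult:
    """Van't Hoff analysis of (T, Ka) pairs.

    Fits ln K on 1/T by ordinary least squares with R = 8.314
    J·mol⁻¹·K⁻¹, evaluates ΔG⁰ at every input temperature, classifies the
    dominant binding force from the signs of ΔH⁰/ΔS⁰ and flags
    spontaneity (all ΔG⁰ < 0).
    """
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        est = VantHoffRegression().fit(temperatures_K, Ka_per_M)
    T = np.asarray(temperatures_K, dtype=float).reshape(-1)
    dG = {float(t): gibbs(est.dH_kJ_per_mol_, est.dS_J_per_mol_K_, float(t)) for t in T}
    return ThermoResult(
        dH_kJ_per_mol=est.dH_kJ_per_mol_,
        dH_stderr_kJ_per_mol=est.dH_stderr_kJ_per_mol_,
        dS_J_per_mol_K=est.dS_J_per_mol_K_,
        dS_stderr_J_per_mol_K=est.dS_stderr_J_per_mol_K_,
        dG_kJ_per_mol_by_T=dG,
        r_squared=est.r_squared_,
        force_class=classify_forces(est.dH_kJ_per_mol_, est.dS_J_per_mol_K_),
        spontaneous=bool(all(v < 0 for v in dG.values())),
        warnings=[str(w.message) for w in caught],
    )
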