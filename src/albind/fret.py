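"""Förster resonance energy transfer: overlap integral, critical distance,
transfer efficiency and donor–acceptor distance.

The spectral overlap between donor (tryptophan) emission and acceptor
(ligand) absorption,

    J = Σ F(λ) ε(λ) λ⁴ Δλ / Σ F(λ) Δλ,

is evaluated with λ in cm and ε in L·mol⁻¹·cm⁻¹ so that J carries units
cm³·L·mol⁻¹ — the only convention under which the critical-distance
prefactor is dimensionally standard:

    R₀⁶ = 8.8×10⁻²⁵ · K² · N⁻⁴ · φ · J   (R₀ in cm).

Transfer efficiency and distance are linked by
E = 1 − F/F₀ = R₀⁶ / (R₀⁶ + r⁶); a distance below 8 nm indicates
non-radiative energy transfer between donor and acceptor.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import DomainError
from .spectra import AxisKind, Spectrum

__all__ = [
    "FretResult",
    "overlap_integral",
    "forster_radius",
    "transfer_efficiency",
    "binding_distance",
    "efficiency_from_intensities",
    "analyze_fret",
    "DEFAULT_K2",
    "DEFAULT_REFRACTIVE_INDEX",
    "DEFAULT_QUANTUM_YIELD",
    "NONRADIATIVE_DISTANCE_NM",
]

#: Orientation factor for freely rotating dipoles.
DEFAULT_K2 = 2.0 / 3.0
#: Refractive index of the aqueous buffer medium.
DEFAULT_REFRACTIVE_INDEX = 1.336
#: Fluorescence quantum yield of tryptophan in serum albumin.
DEFAULT_QUANTUM_YIELD = 0.118
#: Distances below this indicate non-radiative energy transfer.
NONRADIATIVE_DISTANCE_NM = 8.0

_NM_TO_CM = 1e-7


@dataclasses.dataclass
class FretResult:
    """Energy-transfer summary.

    ``E = R0_nm⁶/(R0_nm⁶ + r_nm⁶)`` holds exactly among the stored fields.
    When a J-derived R₀ disagrees with a user-supplied one, both are kept:
    ``R0_from_J_nm`` is reported alongside without reconciliation.
    """

    J_cm3_L_per_mol: float | None
    R0_nm: float
    E: float
    r_nm: float
    K2: float
    refractive_index: float
    quantum_yield: float
    nonradiative: bool
    R0_from_J_nm: float | None = None


def overlap_integral(
    donor_emission: Spectrum,
    acceptor_absorption: Spectrum,
    acceptor_conc_M: float,
    path_cm: float = 1.0,
) -> float:
    """Spectral overlap J in cm³·L·mol⁻¹.

    The acceptor absorbance A(λ) is converted to a molar extinction
    ε(λ) = A/(c·l) and linearly interpolated onto the donor grid (zero
    outside its support): the donor emission defines the weighting
    measure.  The result is invariant to uniform rescaling of the donor
    intensities.  Disjoint wavelength supports give 0 with a warning.
    """
    if donor_emission.axis_kind is not AxisKind.wavelength_nm:
        raise DomainError("donor emission must be on a wavelength axis")
    if acceptor_absorption.axis_kind is not AxisKind.wavelength_nm:
        raise DomainError("acceptor absorption must be on a wavelength axis")
    if acceptor_conc_M <= 0 or path_cm <= 0:
        raise DomainError("acceptor concentration and path length must be > 0")

    lam_nm = donor_emission.axis
    F = donor_emission.intensity
    if lam_nm[0] > lam_nm[-1]:  # normalise to ascending wavelength
        lam_nm, F = lam_nm[::-1], F[::-1]
    acc_lam = acceptor_absorption.axis
    acc_A = acceptor_absorption.intensity
    if acc_lam[0] > acc_lam[-1]:
        acc_lam, acc_A = acc_lam[::-1], acc_A[::-1]

    eps = np.interp(lam_nm, acc_lam, acc_A, left=0.0, right=0.0) / (
        acceptor_conc_M * path_cm
    )
    if lam_nm[-1] < acc_lam[0] or lam_nm[0] > acc_lam[-1]:
        warnings.warn(
            "donor emission and acceptor absorption have disjoint wavelength "
            "supports; J = 0",
            stacklevel=2,
        )
        return 0.0

    lam_cm = lam_nm * _NM_TO_CM
    dlam = np.gradient(lam_cm)
    denom = np.sum(F * dlam)
    if denom <= 0:
        raise DomainError("donor emission has non-positive total intensity")
    return float(np.sum(F * eps * lam_cm**4 * dlam) / denom)


def forster_radius(
    J: float,
    K2: float = DEFAULT_K2,
    N: float = DEFAULT_REFRACTIVE_INDEX,
    phi: float = DEFAULT_QUANTUM_YIELD,
) -> float:
    """Critical distance R₀ (nm) at which transfer efficiency is 50%."""
    if J < 0:
        raise DomainError("overlap integral must be ≥ 0")
    if K2 <= 0 or N <= 0 or phi <= 0:
        raise DomainError("K², N and φ must be > 0")
    r0_cm6 = 8.8e-25 * K2 * N**-4 * phi * J
    return float(r0_cm6 ** (1.0 / 6.0) / _NM_TO_CM)


def transfer_efficiency(R0_nm: float, r_nm: float) -> float:
    """E = R₀⁶/(R₀⁶ + r⁶); strictly decreasing in r, 0.5 at r = R₀."""
    if R0_nm <= 0 or r_nm <= 0:
        raise DomainError("R₀ and r must be > 0")
    x = (r_nm / R0_nm) ** 6
    return float(1.0 / (1.0 + x))


def binding_distance(E: float, R0_nm: float) -> float:
    """Solve E = R₀⁶/(R₀⁶ + r⁶) for the donor–acceptor distance r (nm)."""
    if not 0.0 < E < 1.0:
        raise DomainError(f"transfer efficiency must lie in (0, 1), got {E}")
    if R0_nm <= 0:
        raise DomainError("R₀ must be > 0")
    return float(R0_nm * (1.0 / E - 1.0) ** (1.0 / 6.0))


def efficiency_from_intensities(F: float, F0: float) -> float:
    """E = 1 − F/F₀ from donor intensities with and without acceptor."""
    if F0 <= 0 or F <= 0:
        raise DomainError("intensities must be > 0")
    if F > F0:
        raise DomainError("quenched intensity F cannot exceed F0")
    return float(1.0 - F / F0)


def analyze_fret(
    F: float,
    F0: float,
    donor_emission: Spectrum | None = None,
    acceptor_absorption: Spectrum | None = None,
    acceptor_conc_M: float | None = None,
    path_cm: float = 1.0,
    R0_nm: float | None = None,
    K2: float = DEFAULT_K2,
    N: float = DEFAULT_REFRACTIVE_INDEX,
    phi: float = DEFAULT_QUANTUM_YIELD,
) -> FretResult:
    """Full FRET chain: efficiency from intensities, R₀ from spectra (or
    supplied directly), and the donor–acceptor distance.

    If both spectra and an explicit ``R0_nm`` are given, the supplied R₀
    is used for the distance and the J-derived one is reported alongside
    (``R0_from_J_nm``) without reconciliation.
    """
    E = efficiency_from_intensities(F, F0)
    J = None
    r0_from_j = None
    if donor_emission is not None and acceptor_absorption is not None:
        if acceptor_conc_M is None:
            raise DomainError("acceptor concentration needed to convert A(λ) to ε(λ)")
        J = overlap_integral(donor_emission, acceptor_absorption, acceptor_conc_M, path_cm)
        r0_from_j = forster_radius(J, K2, N, phi)
    r0 = R0_nm if R0_nm is not None else r0_from_j
    if r0 is None:
        raise DomainError("supply either donor/acceptor spectra or R0_nm")
    r = binding_distance(E, r0)
    return FretResult(
        J_cm3_L_per_mol=J,
        R0_nm=float(r0),
        E=E,
        r_nm=r,
        K2=K2,
        refractive_index=N,
        quantum_yield=phi,
        nonradiative=bool(r < NONRADIATIVE_DISTANCE_NM),
        R0_from_J_nm=r0_from_j,
    )
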