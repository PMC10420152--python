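"""Synthetic-spectra generators with known ground truth.

Every analysis stage in this package is validated against data produced
here: fluorescence quenching titrations obeying the Stern–Volmer and
double-logarithm binding laws, Beer–Lambert ligand absorbance driving an
inner-filter effect, amide-I envelopes that are sums of Gaussian component
bands, and CD ellipticities linear in helix content through the
mean-residue-ellipticity mapping.

Forward quenching law
---------------------
Peak intensities satisfy, before noise,

    F0/F = (1 + K_D [Q]) · (1 + K_a [Q]^n)

with K_D the dynamic Stern–Volmer constant.  Fixtures for recovery tests
use pure regimes (one factor switched off) so that the linear
Stern–Volmer law or the double-log binding law holds exactly, matching how
the two fits are performed independently in practice.

Noise is multiplicative Gaussian on every intensity sample (photomultiplier
shot noise is signal-proportional at these signal levels); a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import DomainError
from .spectra import AxisKind, Spectrum, TitrationSeries

__all__ = [
    "QuenchingGroundTruth",
    "AmideIGroundTruth",
    "generate_titration",
    "generate_amide_i",
    "generate_cd",
    "generate_band_series",
    "titration_design",
    "HSA_AMIDE_I_CENTERS",
]

#: Amide-I component-band centers (cm⁻¹) reported for ligand-free HSA;
#: used as a realistic seven-band layout for synthetic envelopes.
HSA_AMIDE_I_CENTERS = (
    1610.96,
    1623.22,
    1634.95,
    1645.22,
    1655.67,
    1666.79,
    1679.42,
)


@dataclasses.dataclass
class QuenchingGroundTruth:
    """Ground-truth parameters for a synthetic quenching titration.

    ``ligand_eps_ex`` / ``ligand_eps_em`` are the ligand molar
    absorptivities (L·mol⁻¹·cm⁻¹) at the excitation and emission
    wavelengths; they drive the inner-filter attenuation
    exp[−(A_ex + A_em)/2] with A = ε·[Q]·1 cm.
    """

    Ksv_dynamic_per_M: float = 0.0
    Ka_per_M: float = 0.0
    n_sites: float = 1.0
    F0_peak: float = 1000.0
    emission_center_nm: float = 337.0
    emission_width_nm: float = 25.0
    noise_sd_rel: float = 0.0
    ligand_eps_ex: float = 0.0
    ligand_eps_em: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "Ksv_dynamic_per_M",
            "Ka_per_M",
            "F0_peak",
            "noise_sd_rel",
            "ligand_eps_ex",
            "ligand_eps_em",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.emission_width_nm <= 0:
            raise DomainError("emission_width_nm must be > 0")
        if self.n_sites <= 0:
            raise DomainError("n_sites must be > 0")


@dataclasses.dataclass
class AmideIGroundTruth:
    """Gaussian component bands (center cm⁻¹, sigma cm⁻¹, area) for an
    amide-I envelope, plus relative noise level and RNG seed."""

    bands: Sequence[tuple[float, float, float]]
    noise_sd_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for center, width, area in self.bands:
            if not (1600.0 <= center <= 1700.0):
                raise DomainError(f"band center {center} outside [1600, 1700] cm⁻¹")
            if width <= 0 or area <= 0:
                raise DomainError("band widths and areas must be > 0")
        if self.noise_sd_rel < 0:
            raise DomainError("noise_sd_rel must be non-negative")


def generate_titration(
    gt: QuenchingGroundTruth,
    concentrations_M: Sequence[float],
    temperature_K: float,
    wavelengths_nm: np.ndarray | None = None,
    protein_concentration_M: float = 5e-7,
) -> TitrationSeries:
    """Simulate an emission titration under the mixed quenching law.

    The emission band is Gaussian around ``gt.emission_center_nm``.  The
    noiseless *corrected* peak intensity follows
    ``F0/F = (1 + Ksv_dynamic[Q])(1 + Ka[Q]^n)``; observed spectra are then
    attenuated by the inner-filter factor ``exp[−(A_ex + A_em)/2]`` with
    ``A = ε·[Q]·1 cm`` so that the standard correction recovers the
    noiseless truth exactly.
    """
    conc = np.asarray(concentrations_M, dtype=float)
    if conc.size < 1 or conc[0] != 0.0 or np.any(np.diff(conc) <= 0):
        raise DomainError("concentrations must start at 0 and be strictly ascending")
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(300.0, 500.0 + 1e-9, 1.0)
    rng = np.random.default_rng(gt.seed)

    band = np.exp(
        -((wavelengths_nm - gt.emission_center_nm) ** 2)
        / (2.0 * gt.emission_width_nm**2)
    )
    spectra = []
    for q in conc:
        ratio = (1.0 + gt.Ksv_dynamic_per_M * q) * (
            1.0 + gt.Ka_per_M * q**gt.n_sites if q > 0 else 1.0
        )
        a_ex = gt.ligand_eps_ex * q * 1.0
        a_em = gt.ligand_eps_em * q * 1.0
        ife = np.exp(-(a_ex + a_em) / 2.0)
        intensity = gt.F0_peak / ratio * ife * band
        if gt.noise_sd_rel > 0:
            intensity = intensity * (
                1.0 + rng.normal(0.0, gt.noise_sd_rel, size=intensity.size)
            )
        spectra.append(
            Spectrum(
                AxisKind.wavelength_nm,
                wavelengths_nm,
                intensity,
                label=f"[Q]={q:.6g} M",
            )
        )
    return TitrationSeries(
        temperature_K=temperature_K,
        ligand_concentrations_M=conc,
        spectra=spectra,
        protein_concentration_M=protein_concentration_M,
        label=f"synthetic titration, T={temperature_K} K",
    )


def generate_amide_i(gt: AmideIGroundTruth, grid: np.ndarray) -> Spectrum:
    """Sum-of-Gaussians amide-I envelope on ``grid`` (cm⁻¹).

    The integral of the noiseless curve equals the sum of band areas up to
    quadrature error, provided the grid covers [1595, 1705] cm⁻¹.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() > 1595.0 or grid.max() < 1705.0:
        raise DomainError("grid must cover [1595, 1705] cm⁻¹")
    rng = np.random.default_rng(gt.seed)
    intensity = np.zeros_like(grid)
    for center, width, area in gt.bands:
        intensity += (
            area
            / (width * np.sqrt(2.0 * np.pi))
            * np.exp(-((grid - center) ** 2) / (2.0 * width**2))
        )
    if gt.noise_sd_rel > 0:
        scale = intensity.max() if intensity.max() > 0 else 1.0
        # relative to the envelope maximum so baseline regions stay noisy too
        intensity = intensity + rng.normal(
            0.0, gt.noise_sd_rel * scale, size=intensity.size
        )
    return Spectrum(AxisKind.wavenumber_cm1, grid, intensity, label="synthetic amide I")


def generate_cd(
    helix_fraction: float,
    Cp_M: float = 2e-6,
    n_residues: int = 585,
    path_mm: float = 1.0,
) -> float:
    """Observed CD (mdeg) at 208 nm for a given helix fraction.

    Inverts the mean-residue-ellipticity mapping: a helix fraction h maps
    to MRE₂₀₈ = −(4000 + 29000·h) deg·cm²·dmol⁻¹, and the observed signal
    is MRE·10·C_p·n·l with the path length in cm.  Feeding the result back
    through ``mre`` and ``helix_fraction`` reproduces h exactly.
    """
    if not 0.0 <= helix_fraction <= 1.0:
        raise DomainError("helix_fraction must lie in [0, 1]")
    if Cp_M <= 0 or n_residues <= 0 or path_mm <= 0:
        raise DomainError("Cp_M, n_residues and path_mm must be positive")
    mre_208 = -(4000.0 + 29000.0 * helix_fraction)
    return mre_208 * 10.0 * Cp_M * n_residues * (path_mm / 10.0)


def generate_band_series(
    centers_nm: Sequence[float],
    amplitudes: Sequence[float],
    width_nm: float,
    concentrations_M: Sequence[float],
    grid_nm: np.ndarray,
    temperature_K: float = 310.0,
    noise_sd_rel: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Gaussian-band series with per-member center and amplitude.

    Used to emulate UV-vis or synchronous-fluorescence titrations whose
    peak drifts and/or decays with ligand concentration.
    """
    centers = np.asarray(centers_nm, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    conc = np.asarray(concentrations_M, dtype=float)
    if not (centers.size == amps.size == conc.size):
        raise DomainError("centers, amplitudes and concentrations must align")
    grid_nm = np.asarray(grid_nm, dtype=float)
    rng = np.random.default_rng(seed)
    spectra = []
    for c, a in zip(centers, amps):
        y = a * np.exp(-((grid_nm - c) ** 2) / (2.0 * width_nm**2))
        if noise_sd_rel > 0:
            y = y * (1.0 + rng.normal(0.0, noise_sd_rel, size=y.size))
        spectra.append(Spectrum(AxisKind.wavelength_nm, grid_nm, y))
    return TitrationSeries(
        temperature_K=temperature_K,
        ligand_concentrations_M=conc,
        spectra=spectra,
        label="synthetic band series",
    )


def titration_design(
    Ka_per_M: float,
    n_sites: float = 1.0,
    quench_span: tuple[float, float] = (3.0, 1000.0),
    n_points: int = 8,
) -> np.ndarray:
    """Concentration design bracketing the quenching transition.

    Returns 0 followed by ``n_points`` log-spaced concentrations chosen so
    the static quenching term Ka·[Q]^n spans ``quench_span``.  Spanning the
    transition keeps the double-log fit well conditioned: log[(F0−F)/F] is
    then O(1) at every point and the extrapolation to log[Q] = 0 is as
    short as the binding constant allows.
    """
    lo, hi = quench_span
    if Ka_per_M <= 0 or lo <= 0 or hi <= lo:
        raise DomainError("need Ka > 0 and 0 < lo < hi")
    q_lo = (lo / Ka_per_M) ** (1.0 / n_sites)
    q_hi = (hi / Ka_per_M) ** (1.0 / n_sites)
    return np.concatenate([[0.0], np.geomspace(q_lo, q_hi, n_points)])
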