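"""Fluorescence quenching analysis: inner-filter correction, Stern–Volmer
fits, mechanism classification and double-logarithm binding fits.

The Stern–Volmer law relates the quenched-to-unquenched intensity ratio to
quencher concentration,

    F0/F = 1 + Ksv [Q] = 1 + Kq τ0 [Q],

and the double-logarithm binding isotherm gives the association constant
and the number of binding sites,

    log10[(F0 − F)/F] = log10 Ka + n log10 [Q].

Both are ordinary least-squares lines; they are exposed as scikit-learn
style estimators (:class:`SternVolmerRegression`, :class:`DoubleLogBinding`)
with thin functional wrappers returning result records.
"""

from __future__ import annotations

import dataclasses
import warnings
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, InsufficientDataError
from .spectra import TitrationSeries, peak_intensity

__all__ = [
    "Mechanism",
    "QuenchingResult",
    "BindingResult",
    "ife_correct",
    "SternVolmerRegression",
    "stern_volmer_fit",
    "classify_mechanism",
    "DoubleLogBinding",
    "double_log_fit",
    "series_peak_ratios",
    "analyze_titration",
    "KQ_STATIC_THRESHOLD",
    "DEFAULT_TAU0_S",
]

#: Diffusion-limited quenching rate constant (L·mol⁻¹·s⁻¹); Kq above this
#: indicates a static (complex-forming) quenching component.
KQ_STATIC_THRESHOLD = 2.0e10

#: Default unquenched tryptophan fluorescence lifetime (s).
DEFAULT_TAU0_S = 1e-8


class Mechanism(str, Enum):
    dynamic = "dynamic"
    static = "static"
    mixed = "mixed"


def ife_correct(F_obs, A_ex, A_em):
    """Inner-filter-effect correction F_cor = F_obs · exp[(A_ex + A_em)/2].

    ``A_ex`` and ``A_em`` are the system absorbances at the excitation and
    emission wavelengths.  Accepts scalars or arrays; the corrected signal
    is always ≥ the observed one.
    """
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise DomainError("absorbances must be non-negative")
    out = np.asarray(F_obs, dtype=float) * np.exp((A_ex + A_em) / 2.0)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class QuenchingResult:
    """Stern–Volmer fit at one temperature.

    ``Kq_per_M_s = Ksv_per_M / tau0_s`` holds exactly.
    """

    temperature_K: float | None
    Ksv_per_M: float
    Ksv_stderr_per_M: float
    Kq_per_M_s: float
    tau0_s: float
    r_squared: float
    intercept: float
    F0F_ratios: np.ndarray
    concentrations_M: np.ndarray
    mechanism: Mechanism | None = None
    warnings: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class BindingResult:
    """Double-logarithm binding fit at one temperature."""

    temperature_K: float | None
    Ka_per_M: float
    Ka_stderr_per_M: float
    n_sites: float
    n_stderr: float
    r_squared: float
    n_used: int
    n_excluded: int


def _average_duplicates(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average y over duplicate x values (replicate-equivalent, cleaner reporting)."""
    ux, inverse = np.unique(x, return_inverse=True)
    if ux.size == x.size:
        return x, y
    uy = np.zeros_like(ux)
    counts = np.zeros_like(ux)
    np.add.at(uy, inverse, y)
    np.add.at(counts, inverse, 1.0)
    return ux, uy / counts


class SternVolmerRegression(RegressorMixin, BaseEstimator):
    """Ordinary least-squares Stern–Volmer line with free intercept.

    Ksv is the fitted slope.  The intercept is left free rather than pinned
    at 1: an intercept deviating from 1 by more than ``intercept_warn_tol``
    signals inner-filter under-correction and raises a data-quality
    warning instead of silently forcing the model.

    Parameters
    ----------
    tau0_s : float
        Unquenched fluorophore lifetime; Kq = Ksv/τ0.
    intercept_warn_tol : float
        Relative deviation of the intercept from 1 that triggers the
        data-quality warning.

    Attributes
    ----------
    Ksv_ : float
        Fitted Stern–Volmer constant (M⁻¹).
    Ksv_stderr_ : float
        Standard error of the slope.
    Kq_ : float
        Quenching rate constant Ksv_/tau0_s (M⁻¹·s⁻¹), exact by definition.
    intercept_ : float
    r_squared_ : float
    warnings_ : list of str
    """

    def __init__(self, tau0_s: float = DEFAULT_TAU0_S, intercept_warn_tol: float = 0.05):
        self.tau0_s = tau0_s
        self.intercept_warn_tol = intercept_warn_tol

    def fit(self, X, y):
        q = np.asarray(X, dtype=float).reshape(-1)
        ratios = np.asarray(y, dtype=float).reshape(-1)
        if q.size != ratios.size:
            raise DomainError("concentrations and ratios differ in length")
        if np.any(~np.isfinite(q)) or np.any(~np.isfinite(ratios)):
            raise DomainError("non-finite values in Stern–Volmer input")
        q, ratios = _average_duplicates(q, ratios)
        if q.size < 3:
            raise InsufficientDataError(
                f"Stern–Volmer fit needs ≥ 3 distinct concentrations, got {q.size}"
            )
        res = stats.linregress(q, ratios)
        self.Ksv_ = float(res.slope)
        self.Ksv_stderr_ = float(res.stderr)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.Kq_ = self.Ksv_ / self.tau0_s
        self.warnings_ = []
        if self.Ksv_ < 0:
            self.warnings_.append("negative_Ksv")
        if abs(self.intercept_ - 1.0) > self.intercept_warn_tol:
            self.warnings_.append("intercept_far_from_1")
        for w in self.warnings_:
            warnings.warn(f"Stern–Volmer fit: {w}", stacklevel=2)
        return self

    def predict(self, X):
        q = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.Ksv_ * q


def stern_volmer_fit(
    concentrations_M: Sequence[float],
    F0F: Sequence[float],
    tau0_s: float = DEFAULT_TAU0_S,
    temperature_K: float | None = None,
) -> QuenchingResult:
    """Fit the Stern–Volmer line to F0/F ratios; see :class:`SternVolmerRegression`."""
    est = SternVolmerRegression(tau0_s=tau0_s).fit(concentrations_M, F0F)
    return QuenchingResult(
        temperature_K=temperature_K,
        Ksv_per_M=est.Ksv_,
        Ksv_stderr_per_M=est.Ksv_stderr_,
        Kq_per_M_s=est.Kq_,
        tau0_s=tau0_s,
        r_squared=est.r_squared_,
        intercept=est.intercept_,
        F0F_ratios=np.asarray(F0F, dtype=float),
        concentrations_M=np.asarray(concentrations_M, dtype=float),
        warnings=list(est.warnings_),
    )


def classify_mechanism(results_by_T: Sequence[QuenchingResult]) -> Mechanism:
    """Classify the quenching mechanism from per-temperature fits.

    Static evidence: every Kq exceeds the diffusion limit (2×10¹⁰
    L·mol⁻¹·s⁻¹).  Dynamic evidence: Ksv strictly increases with
    temperature.  Both together mean mixed quenching.  With a single
    temperature only the Kq magnitude is usable and the verdict is
    flagged low-confidence via a warning.
    """
    if len(results_by_T) == 0:
        raise InsufficientDataError("no quenching results supplied")
    ordered = sorted(results_by_T, key=lambda r: (r.temperature_K is None, r.temperature_K))
    kq = np.array([r.Kq_per_M_s for r in ordered])
    static_ev = bool(np.all(kq > KQ_STATIC_THRESHOLD))
    if len(ordered) == 1:
        warnings.warn(
            "mechanism classified from a single temperature (Kq magnitude only); "
            "low confidence",
            stacklevel=2,
        )
        return Mechanism.static if static_ev else Mechanism.dynamic
    ksv = np.array([r.Ksv_per_M for r in ordered])
    dynamic_ev = bool(np.all(np.diff(ksv) > 0))
    if static_ev and dynamic_ev:
        return Mechanism.mixed
    if static_ev:
        return Mechanism.static
    if dynamic_ev:
        return Mechanism.dynamic
    # Kq at or below the diffusion limit is itself dynamic evidence; an
    # unclear temperature trend does not overturn it, but flag it.
    warnings.warn(
        "Kq below static threshold but Ksv not strictly increasing with T; "
        "classified dynamic with ambiguous temperature trend",
        stacklevel=2,
    )
    return Mechanism.dynamic


class DoubleLogBinding(RegressorMixin, BaseEstimator):
    """Double-logarithm binding isotherm fitted by ordinary least squares.

    Fits log10[(F0−F)/F] = log10 Ka + n·log10[Q] on the nonzero
    concentrations.  The response passed to :meth:`fit` is the ratio
    F0/F, so (F0−F)/F = F0/F − 1.  Points with F ≥ F0 (ratio ≤ 1) carry no
    quenching information on the log scale; they are excluded and counted.

    Attributes
    ----------
    Ka_ : float
        Association constant, 10**intercept, with [Q] in mol/L.
    n_ : float
        Hill-type number of binding sites (the fitted slope).
    Ka_stderr_, n_stderr_, r_squared_ : float
    n_used_, n_excluded_ : int
    """

    def fit(self, X, y):
        q = np.asarray(X, dtype=float).reshape(-1)
        ratio = np.asarray(y, dtype=float).reshape(-1)
        if q.size != ratio.size:
            raise DomainError("concentrations and ratios differ in length")
        nonzero = q > 0
        usable = nonzero & np.isfinite(ratio) & (ratio > 1.0)
        self.n_excluded_ = int(np.count_nonzero(nonzero) - np.count_nonzero(usable))
        q_u, r_u = _average_duplicates(q[usable], ratio[usable])
        self.n_used_ = int(np.count_nonzero(usable))
        if q_u.size < 3:
            raise InsufficientDataError(
                f"double-log fit needs ≥ 3 usable points, got {q_u.size} "
                f"({self.n_excluded_} excluded)"
            )
        x = np.log10(q_u)
        yy = np.log10(r_u - 1.0)
        res = stats.linregress(x, yy)
        self.n_ = float(res.slope)
        self.n_stderr_ = float(res.stderr)
        self.log10_Ka_ = float(res.intercept)
        self.Ka_ = float(10.0**res.intercept)
        # delta method: SE(Ka) = ln(10) · Ka · SE(intercept)
        self.Ka_stderr_ = float(np.log(10.0) * self.Ka_ * res.intercept_stderr)
        self.r_squared_ = float(res.rvalue**2)
        return self

    def predict(self, X):
        q = np.asarray(X, dtype=float).reshape(-1)
        return 1.0 + self.Ka_ * q**self.n_


def double_log_fit(
    concentrations_M: Sequence[float],
    F0,
    F: Sequence[float],
    temperature_K: float | None = None,
) -> BindingResult:
    """Fit the double-log binding line from raw intensities.

    ``F0`` may be a scalar (one ligand-free reference intensity) or a
    per-point array.  Invariant to common rescaling of all intensities.
    """
    F = np.asarray(F, dtype=float).reshape(-1)
    F0 = np.broadcast_to(np.asarray(F0, dtype=float), F.shape)
    if np.any(F <= 0):
        raise DomainError("intensities must be positive")
    est = DoubleLogBinding().fit(concentrations_M, F0 / F)
    return BindingResult(
        temperature_K=temperature_K,
        Ka_per_M=est.Ka_,
        Ka_stderr_per_M=est.Ka_stderr_,
        n_sites=est.n_,
        n_stderr=est.n_stderr_,
        r_squared=est.r_squared_,
        n_used=est.n_used_,
        n_excluded=est.n_excluded_,
    )


def series_peak_ratios(
    series: TitrationSeries,
    eps_ex_per_M_cm: float = 0.0,
    eps_em_per_M_cm: float = 0.0,
    path_cm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-concentration corrected peak intensities and F0/F ratios.

    The emission maximum is located once on the ligand-free reference
    spectrum and the same grid point is read off every member, so genuine
    peak shifts are not conflated with quenching.  If ligand molar
    absorptivities are given, each intensity is inner-filter corrected
    with A = ε·[Q]·path before the ratio is formed.

    Returns ``(F_corrected, F0_over_F)``.
    """
    ref = series.spectra[0]
    peak_pos = float(ref.axis[int(np.argmax(ref.intensity))])
    q = series.ligand_concentrations_M
    raw = np.array([peak_intensity(s, peak_pos) for s in series.spectra])
    corrected = ife_correct(
        raw, eps_ex_per_M_cm * q * path_cm, eps_em_per_M_cm * q * path_cm
    )
    return corrected, corrected[0] / corrected


def analyze_titration(
    series: TitrationSeries,
    tau0_s: float = DEFAULT_TAU0_S,
    eps_ex_per_M_cm: float = 0.0,
    eps_em_per_M_cm: float = 0.0,
) -> tuple[QuenchingResult, BindingResult]:
    """Full single-temperature quenching analysis of a titration series.

    Extracts corrected peak ratios, fits the Stern–Volmer line and the
    double-log binding line, and returns both result records.
    """
    F_cor, ratios = series_peak_ratios(series, eps_ex_per_M_cm, eps_em_per_M_cm)
    qres = stern_volmer_fit(
        series.ligand_concentrations_M, ratios, tau0_s, series.temperature_K
    )
    bres = double_log_fit(
        series.ligand_concentrations_M, F_cor[0], F_cor, series.temperature_K
    )
    return qres, bres
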