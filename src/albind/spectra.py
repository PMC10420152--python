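"""Core data model: single spectra and concentration-indexed titration series.

A :class:`Spectrum` is one measured curve on a strictly monotone wavelength
(nm) or wavenumber (cm⁻¹) grid; a :class:`TitrationSeries` bundles one
spectrum per ligand concentration at a fixed temperature, with the
ligand-free reference always first.  All concentrations are mol/L,
temperatures K, fluorescence in arbitrary units, absorbance in AU and
circular dichroism in millidegrees.

The on-disk format is deliberately minimal: comma-separated UTF-8 text with
a "." decimal separator and a single header row.  The first column is the
axis ("nm" or "cm-1"); each remaining column is one titration member whose
header is its molar ligand concentration.
"""

from __future__ import annotations

import dataclasses
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

__all__ = [
    "AxisKind",
    "Spectrum",
    "TitrationSeries",
    "read_titration_table",
    "write_titration_table",
    "peak_intensity",
]

#: Number of significant digits written to disk; chosen so a write→read
#: round trip is bit-faithful at the reader's float64 precision.
_WRITE_DIGITS = 12


class AxisKind(str, Enum):
    """Physical meaning of a spectrum's abscissa."""

    wavelength_nm = "wavelength_nm"
    wavenumber_cm1 = "wavenumber_cm-1"

    @property
    def column_header(self) -> str:
        return "nm" if self is AxisKind.wavelength_nm else "cm-1"


_HEADER_TO_KIND = {
    "nm": AxisKind.wavelength_nm,
    "wavelength": AxisKind.wavelength_nm,
    "wavelength_nm": AxisKind.wavelength_nm,
    "cm-1": AxisKind.wavenumber_cm1,
    "cm^-1": AxisKind.wavenumber_cm1,
    "wavenumber": AxisKind.wavenumber_cm1,
    "wavenumber_cm-1": AxisKind.wavenumber_cm1,
}


@dataclasses.dataclass
class Spectrum:
    """One measured curve on a strictly monotone axis grid.

    Parameters
    ----------
    axis_kind : AxisKind
        Whether the axis is wavelength (nm) or wavenumber (cm⁻¹).
    axis : array-like
        Strictly monotone grid, length ≥ 2, finite.
    intensity : array-like
        Signal values, same length as ``axis``, finite.
    label : str
        Free-text description.
    """

    axis_kind: AxisKind
    axis: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.axis_kind = AxisKind(self.axis_kind)
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("axis and intensity must be one-dimensional")
        if self.axis.size != self.intensity.size:
            raise FormatError(
                f"axis has {self.axis.size} points but intensity has "
                f"{self.intensity.size}"
            )
        if self.axis.size < 2:
            raise FormatError("a spectrum needs at least 2 grid points")
        if not np.all(np.isfinite(self.axis)) or not np.all(
            np.isfinite(self.intensity)
        ):
            raise FormatError("non-finite values in spectrum")
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise FormatError("axis grid is not strictly monotone")

    def __len__(self) -> int:
        return int(self.axis.size)

    def isclose(self, other: "Spectrum", rtol: float = 1e-9) -> bool:
        return (
            self.axis_kind is other.axis_kind
            and self.axis.size == other.axis.size
            and np.allclose(self.axis, other.axis, rtol=rtol, atol=0)
            and np.allclose(self.intensity, other.intensity, rtol=rtol, atol=0)
        )


@dataclasses.dataclass
class TitrationSeries:
    """Spectra indexed by ligand concentration at one temperature.

    Invariants enforced at construction: concentrations non-negative,
    strictly increasing and starting at exactly 0 (the ligand-free
    reference); all member spectra share one axis grid; temperature > 0.
    """

    temperature_K: float
    ligand_concentrations_M: np.ndarray
    spectra: list[Spectrum]
    protein_concentration_M: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.ligand_concentrations_M = np.asarray(
            self.ligand_concentrations_M, dtype=float
        )
        if self.temperature_K <= 0:
            raise DomainError(f"temperature_K must be > 0, got {self.temperature_K}")
        c = self.ligand_concentrations_M
        if c.ndim != 1 or c.size != len(self.spectra):
            raise FormatError(
                f"{c.size} concentrations but {len(self.spectra)} spectra"
            )
        if c.size == 0:
            raise FormatError("empty titration series")
        if c[0] != 0.0:
            raise FormatError(
                f"first concentration must be 0 (ligand-free reference), got {c[0]}"
            )
        if np.any(c < 0):
            raise FormatError("negative ligand concentration")
        if np.any(np.diff(c) <= 0):
            raise FormatError("ligand concentrations must be strictly increasing")
        ref = self.spectra[0]
        for i, s in enumerate(self.spectra[1:], start=1):
            if s.axis_kind is not ref.axis_kind or s.axis.size != ref.axis.size or not np.allclose(
                s.axis, ref.axis, rtol=1e-12, atol=0
            ):
                raise FormatError(f"spectrum {i} is not on the shared axis grid")

    @property
    def axis(self) -> np.ndarray:
        return self.spectra[0].axis

    @property
    def axis_kind(self) -> AxisKind:
        return self.spectra[0].axis_kind

    def intensity_matrix(self) -> np.ndarray:
        """(n_concentrations, n_axis) intensity array."""
        return np.vstack([s.intensity for s in self.spectra])

    def isclose(self, other: "TitrationSeries", rtol: float = 1e-9) -> bool:
        return (
            np.isclose(self.temperature_K, other.temperature_K, rtol=rtol)
            and self.ligand_concentrations_M.size
            == other.ligand_concentrations_M.size
            and np.allclose(
                self.ligand_concentrations_M,
                other.ligand_concentrations_M,
                rtol=rtol,
                atol=0,
            )
            and all(a.isclose(b, rtol) for a, b in zip(self.spectra, other.spectra))
        )


def read_titration_table(
    path, temperature_K: float, meta: Mapping | None = None
) -> TitrationSeries:
    """Read a titration series from a comma-separated text file.

    The first column is the axis grid (header ``nm`` or ``cm-1``); every
    other column is one spectrum whose header is its ligand concentration
    in mol/L.  Columns are sorted into ascending concentration order.

    Raises
    ------
    FormatError
        On ragged rows, unparseable headers or a non-monotone axis, naming
        the offending row or column.
    """
    meta = dict(meta or {})
    try:
        df = pd.read_csv(path, sep=",", header=0, dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed delimited text ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need an axis column plus ≥ 1 spectrum column")

    axis_header = str(df.columns[0]).strip().lower()
    try:
        axis_kind = _HEADER_TO_KIND[axis_header]
    except KeyError:
        raise FormatError(
            f"{path}: first header {df.columns[0]!r} is not a recognised axis "
            f"(expected one of {sorted(set(_HEADER_TO_KIND))})"
        ) from None

    concentrations = []
    for col in df.columns[1:]:
        try:
            concentrations.append(float(str(col).strip()))
        except ValueError:
            raise FormatError(
                f"{path}: column header {col!r} is not a concentration in mol/L"
            ) from None

    def _column(name, j):
        out = np.empty(df.shape[0])
        for i, raw in enumerate(df.iloc[:, j]):
            try:
                out[i] = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {i + 2}, column {name!r}: "
                    f"unparseable value {raw!r}"
                ) from None
        return out

    axis = _column(df.columns[0], 0)
    d = np.diff(axis)
    if axis.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise FormatError(f"{path}: axis column is not strictly monotone")

    order = np.argsort(concentrations, kind="stable")
    label = str(meta.get("label", ""))
    spectra = []
    sorted_conc = []
    for rank, idx in enumerate(order):
        col = df.columns[1 + idx]
        spectra.append(
            Spectrum(axis_kind, axis, _column(col, 1 + idx), label=label)
        )
        sorted_conc.append(concentrations[idx])

    return TitrationSeries(
        temperature_K=temperature_K,
        ligand_concentrations_M=np.array(sorted_conc),
        spectra=spectra,
        protein_concentration_M=meta.get("protein_concentration_M"),
        label=label,
    )


def write_titration_table(series: TitrationSeries, path) -> None:
    """Write a titration series in the format of :func:`read_titration_table`.

    Values carry ≥ 10 significant digits so the round trip is bit-faithful
    at float64 reader precision.
    """
    fmt = f"%.{_WRITE_DIGITS}g"
    headers = [series.axis_kind.column_header] + [
        fmt % c for c in series.ligand_concentrations_M
    ]
    mat = np.column_stack([series.axis] + [s.intensity for s in series.spectra])
    lines = [",".join(headers)]
    for row in mat:
        lines.append(",".join(fmt % v for v in row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def peak_intensity(spectrum: Spectrum, at_axis_value: float) -> float:
    """Intensity at the grid point nearest ``at_axis_value``.

    Nearest-grid-point lookup, no interpolation: reproducible, and grid
    resolution in this domain (≤ 1 nm / ≤ 1 cm⁻¹) is below analysis
    sensitivity.  Ties break toward the lower index.
    """
    lo = min(spectrum.axis[0], spectrum.axis[-1])
    hi = max(spectrum.axis[0], spectrum.axis[-1])
    if not (lo <= at_axis_value <= hi):
        raise DomainError(
            f"axis value {at_axis_value} outside spectrum range [{lo}, {hi}]"
        )
    idx = int(np.argmin(np.abs(spectrum.axis - at_axis_value)))
    return float(spectrum.intensity[idx])
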