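"""Peak-position and intensity-trend tracking across a titration.

Used for UV-vis absorbance titrations (e.g. the ~214 nm peptide-backbone
band red-shifting on ligand binding) and for synchronous fluorescence
series at Δλ = 15 nm (tyrosine) or 60 nm (tryptophan).  Peak positions
are refined by parabolic interpolation through the three grid points
around the in-window argmax, so sub-grid shifts survive a coarse grid;
the intensity trend is a strict all-pairs monotonicity verdict, not an
endpoint comparison.
"""

from __future__ import annotations

import dataclasses
from enum import Enum
from itertools import combinations

import numpy as np

from .errors import DomainError
from .spectra import TitrationSeries

__all__ = ["ShiftDirection", "IntensityTrend", "ShiftReport", "track_peak"]

_DIRECTION_TOL = 1e-9


class ShiftDirection(str, Enum):
    red = "red"
    blue = "blue"
    none = "none"


class IntensityTrend(str, Enum):
    increasing = "increasing"
    decreasing = "decreasing"
    flat = "flat"


@dataclasses.dataclass
class ShiftReport:
    """Per-concentration peak positions/intensities for one band window."""

    concentrations_M: np.ndarray
    positions: np.ndarray  # NaN where flagged
    intensities: np.ndarray
    flagged: np.ndarray  # True where no interior local maximum was found
    total_shift: float
    direction: ShiftDirection
    intensity_trend: IntensityTrend
    window: tuple[float, float]


def _parabolic_peak(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points (i-1, i, i+1); falls back to
    the raw grid point when the curvature is non-concave."""
    if i == 0 or i == y.size - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    if a >= 0:
        return float(x1), float(y1)
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    xv = -b / (2 * a)
    yv = y1 - a * ((x1 - xv) ** 2)  # parabola value at vertex, anchored at x1
    return float(xv), float(yv)


def _trend(values: np.ndarray) -> IntensityTrend:
    """Strict all-pairs monotonicity verdict."""
    if values.size < 2:
        return IntensityTrend.flat
    pairs = list(combinations(range(values.size), 2))
    if all(values[j] > values[i] for i, j in pairs):
        return IntensityTrend.increasing
    if all(values[j] < values[i] for i, j in pairs):
        return IntensityTrend.decreasing
    return IntensityTrend.flat


def track_peak(series: TitrationSeries, window: tuple[float, float]) -> ShiftReport:
    """Track the band maximum inside ``window`` across a titration.

    Per spectrum the peak is the in-window argmax, refined parabolically.
    A spectrum whose in-window maximum sits on the window edge has no
    local maximum there; it is flagged and excluded from the shift and
    trend.  ``total_shift`` is last-minus-first valid position; direction
    is red (toward longer wavelength) for positive shift.
    """
    lo, hi = float(window[0]), float(window[1])
    axis = series.axis
    amin, amax = min(axis[0], axis[-1]), max(axis[0], axis[-1])
    if lo >= hi or lo < amin or hi > amax:
        raise DomainError(
            f"window [{lo}, {hi}] not inside axis range [{amin}, {amax}]"
        )
    sel = np.flatnonzero((axis >= lo) & (axis <= hi))
    if sel.size < 3:
        raise DomainError("window contains fewer than 3 grid points")

    n = len(series.spectra)
    positions = np.full(n, np.nan)
    intensities = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    for k, spec in enumerate(series.spectra):
        yw = spec.intensity[sel]
        j = int(np.argmax(yw))
        if j == 0 or j == yw.size - 1:
            flagged[k] = True
            continue
        i = sel[j]
        positions[k], intensities[k] = _parabolic_peak(spec.axis, spec.intensity, i)

    valid = ~flagged
    if np.count_nonzero(valid) >= 2:
        vpos = positions[valid]
        total_shift = float(vpos[-1] - vpos[0])
    else:
        total_shift = 0.0
    if total_shift > _DIRECTION_TOL:
        direction = ShiftDirection.red
    elif total_shift < -_DIRECTION_TOL:
        direction = ShiftDirection.blue
    else:
        direction = ShiftDirection.none

    return ShiftReport(
        concentrations_M=series.ligand_concentrations_M.copy(),
        positions=positions,
        intensities=intensities,
        flagged=flagged,
        total_shift=total_shift,
        direction=direction,
        intensity_trend=_trend(intensities[valid]),
        window=(lo, hi),
    )
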