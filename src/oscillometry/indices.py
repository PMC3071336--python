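"""Hallmark impulse-oscillometry indices of a single impedance spectrum.

The clinically reported quantities are:

* ``R5``, ``R20`` — resistance at 5 and 20 Hz;
* ``fdR = R5 − R20`` — the (negative) frequency-dependence of resistance,
  an index of peripheral airway obstruction;
* ``X5`` — reactance at 5 Hz;
* ``Fres`` — resonant frequency, where the reactance crosses zero;
* ``AX`` — the "Goldman triangle": integrated magnitude of the negative
  reactance from 5 Hz up to Fres, kPa/L.

All lookups interpolate linearly in frequency on the measurement grid;
no extrapolation beyond the grid span is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import ImpedanceSpectrum, InvalidInputError

__all__ = [
    "IOSIndices",
    "value_at",
    "compute_fdr",
    "compute_fres",
    "compute_ax",
    "compute_indices",
    "OutOfRangeError",
]


class OutOfRangeError(InvalidInputError):
    """Query frequency outside the measured grid span."""


@dataclass(frozen=True)
class IOSIndices:
    """Bundle of IOS indices derived from one spectrum.

    ``fres`` is ``None`` when the reactance never reaches zero on the grid;
    ``ax`` is then ``None`` as well (undefined, never silently zero). When
    the reactance is already non-negative at 5 Hz, ``ax`` is 0.
    """

    R5: float
    R20: float
    fdR: float
    X5: float
    fres: float | None
    ax: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "R5": self.R5,
            "R20": self.R20,
            "fdR": self.fdR,
            "X5": self.X5,
            "fres": self.fres,
            "ax": self.ax,
        }


def value_at(spectrum: ImpedanceSpectrum, f: float, channel: str = "resistance") -> float:
    """Channel value at frequency ``f``: exact on grid points, linear between.

    Raises :class:`OutOfRangeError` for queries outside the grid span.
    """
    if channel not in ("resistance", "reactance"):
        raise InvalidInputError(f"channel must be 'resistance' or 'reactance', got {channel!r}")
    grid = np.asarray(spectrum.frequencies)
    if not (grid[0] <= f <= grid[-1]):
        raise OutOfRangeError(
            f"{f} Hz outside measured span [{grid[0]}, {grid[-1]}] Hz; extrapolation refused"
        )
    vals = np.asarray(getattr(spectrum, channel))
    return float(np.interp(f, grid, vals))


def compute_fdr(spectrum: ImpedanceSpectrum) -> float:
    """Frequency-dependence of resistance, R5 − R20 (kPa·s/L)."""
    return value_at(spectrum, 5.0, "resistance") - value_at(spectrum, 20.0, "resistance")


def compute_fres(spectrum: ImpedanceSpectrum) -> float | None:
    """Resonant frequency: first zero crossing of the reactance, Hz.

    Linear interpolation between the bracketing grid points; an exact grid
    zero returns that frequency. Returns ``None`` when the reactance stays
    negative over the whole grid, or when it is already non-negative at the
    lowest frequency (resonance below the grid; AX treats that case as 0).
    """
    f = np.asarray(spectrum.frequencies)
    x = np.asarray(spectrum.reactance)
    if x[0] >= 0:
        return None
    for i in range(1, len(f)):
        if x[i] >= 0:
            if x[i] == 0.0:
                return float(f[i])
            # negative -> positive between i-1 and i
            frac = -x[i - 1] / (x[i] - x[i - 1])
            return float(f[i - 1] + frac * (f[i] - f[i - 1]))
    return None


def compute_ax(spectrum: ImpedanceSpectrum) -> float | None:
    """Reactance area AX (kPa/L): trapezoidal integral of |X| from 5 Hz to Fres.

    Endpoints at 5 Hz and at the interpolated zero crossing; interior grid
    points in between contribute trapezoids. Conventions: 0 when X(5) >= 0
    (resonance at or below 5 Hz); ``None`` (undefined, flagged upstream) when
    the reactance never reaches zero on the grid.
    """
    x5 = value_at(spectrum, 5.0, "reactance")
    if x5 >= 0:
        return 0.0
    fres = compute_fres(spectrum)
    if fres is None or fres <= 5.0:
        return None if fres is None else 0.0
    f = np.asarray(spectrum.frequencies)
    x = np.asarray(spectrum.reactance)
    inner = (f > 5.0) & (f < fres)
    fs = np.concatenate(([5.0], f[inner], [fres]))
    xs = np.concatenate(([x5], x[inner], [0.0]))
    return float(np.trapezoid(np.abs(xs), fs))


def compute_indices(spectrum: ImpedanceSpectrum) -> IOSIndices:
    """All IOS indices of one spectrum (deterministic)."""
    r5 = value_at(spectrum, 5.0, "resistance")
    r20 = value_at(spectrum, 20.0, "resistance")
    return IOSIndices(
        R5=r5,
        R20=r20,
        fdR=r5 - r20,
        X5=value_at(spectrum, 5.0, "reactance"),
        fres=compute_fres(spectrum),
        ax=compute_ax(spectrum),
    )
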