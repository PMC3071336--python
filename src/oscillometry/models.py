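"""Equivalent-circuit models of respiratory input impedance.

Two lumped-parameter topologies used to interpret forced-oscillation
(impulse oscillometry) spectra:

* **eRIC** (extended RIC): central airway resistance ``Rc`` in series with
  airway inertance ``I`` and a peripheral branch of resistance ``Rp`` in
  parallel with compliance ``Cp``::

      Z_eRIC(w) = Rc + jwI + Rp / (1 + jw Rp Cp),   w = 2*pi*f

* **aRIC** (augmented RIC): the eRIC branch with an extrathoracic shunt
  compliance ``Ce`` in parallel across the whole branch, capturing the
  upper-airway (cheeks/pharynx) shunt that raises apparent resistance at
  high frequencies::

      Z_aRIC(w) = Z_eRIC(w) / (1 + jw Ce Z_eRIC(w))

Units throughout: resistances kPa·s/L, inertance kPa·s²/L, compliances
L/kPa, frequency Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ERICParameters",
    "ARICParameters",
    "ImpedanceSpectrum",
    "eval_eric",
    "eval_aric",
    "model_fres",
    "InvalidInputError",
]

_TWO_PI = 2.0 * math.pi


class InvalidInputError(ValueError):
    """Raised when parameters or frequencies violate model preconditions."""


@dataclass(frozen=True)
class ERICParameters:
    """Constants of the extended RIC circuit.

    Attributes
    ----------
    Rc : float
        Central (large-airway) resistance, kPa·s/L. Must be > 0.
    I : float
        Large-airway inertance, kPa·s²/L. Must be > 0.
    Rp : float
        Peripheral (small-airway) resistance, kPa·s/L. Must be >= 0;
        ``Rp = 0`` is accepted as the degenerate open-branch limit for
        evaluation only (fitting bounds exclude it).
    Cp : float
        Peripheral (small-airway) compliance, L/kPa. Must be >= 0, with
        0 accepted as a degenerate limit for evaluation only.
    """

    Rc: float
    I: float
    Rp: float
    Cp: float

    def __post_init__(self) -> None:
        for name in ("Rc", "I"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("Rp", "Cp"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ARICParameters(ERICParameters):
    """eRIC constants plus the extrathoracic shunt compliance.

    ``Ce = 0`` means no shunt: the model then reproduces eRIC exactly.
    """

    Ce: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (np.isfinite(self.Ce) and self.Ce >= 0):
            raise InvalidInputError(f"Ce must be finite and >= 0, got {self.Ce!r}")

    def eric(self) -> ERICParameters:
        """Drop the shunt term."""
        return ERICParameters(self.Rc, self.I, self.Rp, self.Cp)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Respiratory impedance sampled on a frequency grid.

    ``resistance`` is Re Z and ``reactance`` is Im Z, both kPa·s/L.
    Frequencies must be strictly increasing and positive; measured
    resistance must be positive.
    """

    frequencies: tuple[float, ...]
    resistance: tuple[float, ...]
    reactance: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        r = np.asarray(self.resistance, dtype=float)
        x = np.asarray(self.reactance, dtype=float)
        if not (f.ndim == r.ndim == x.ndim == 1 and len(f) == len(r) == len(x)):
            raise InvalidInputError("frequencies, resistance, reactance must be equal-length 1-D")
        if len(f) == 0:
            raise InvalidInputError("spectrum must contain at least one frequency")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise InvalidInputError("frequencies must be finite and > 0")
        if np.any(np.diff(f) <= 0):
            raise InvalidInputError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise InvalidInputError("resistance values must be finite and > 0")
        if not np.all(np.isfinite(x)):
            raise InvalidInputError("reactance values must be finite")
        object.__setattr__(self, "frequencies", tuple(float(v) for v in f))
        object.__setattr__(self, "resistance", tuple(float(v) for v in r))
        object.__setattr__(self, "reactance", tuple(float(v) for v in x))

    @classmethod
    def from_unsorted(
        cls, frequencies, resistance, reactance
    ) -> "ImpedanceSpectrum":
        """Build a spectrum from rows in arbitrary order (canonical sort by f)."""
        order = np.argsort(np.asarray(frequencies, dtype=float), kind="stable")
        f = np.asarray(frequencies, dtype=float)[order]
        r = np.asarray(resistance, dtype=float)[order]
        x = np.asarray(reactance, dtype=float)[order]
        return cls(tuple(f), tuple(r), tuple(x))

    def restrict(self, frequencies) -> "ImpedanceSpectrum":
        """Sub-spectrum on the given frequencies (each must be a grid point)."""
        idx = []
        for f in frequencies:
            where = [i for i, g in enumerate(self.frequencies) if math.isclose(g, f)]
            if not where:
                raise InvalidInputError(f"frequency {f} Hz not on spectrum grid {self.frequencies}")
            idx.append(where[0])
        return ImpedanceSpectrum(
            tuple(self.frequencies[i] for i in idx),
            tuple(self.resistance[i] for i in idx),
            tuple(self.reactance[i] for i in idx),
        )

    def __len__(self) -> int:
        return len(self.frequencies)


def _check_frequencies(frequencies) -> np.ndarray:
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if not np.all(np.isfinite(f)) or np.any(f <= 0):
        raise InvalidInputError("all frequencies must be finite and > 0")
    return f


def eric_impedance(params: ERICParameters, frequencies) -> np.ndarray:
    """Complex eRIC input impedance Z(f) on the given frequencies."""
    f = _check_frequencies(frequencies)
    w = _TWO_PI * f
    tau = w * params.Rp * params.Cp  # dimensionless peripheral time-constant term
    denom = 1.0 + tau**2
    re = params.Rc + params.Rp / denom
    im = w * params.I - w * params.Rp**2 * params.Cp / denom
    return re + 1j * im


def aric_impedance(params: ARICParameters, frequencies) -> np.ndarray:
    """Complex aRIC input impedance: eRIC branch shunted by Ce."""
    f = _check_frequencies(frequencies)
    ze = eric_impedance(params, f)
    w = _TWO_PI * f
    return ze / (1.0 + 1j * w * params.Ce * ze)


def eval_eric(params: ERICParameters, frequencies) -> ImpedanceSpectrum:
    """Evaluate the eRIC model on a frequency grid.

    Re Z decreases strictly with frequency (from ``Rc + Rp`` at f→0 to
    ``Rc`` at f→∞); Im Z crosses zero at the resonant frequency when one
    exists (:func:`model_fres`).
    """
    z = eric_impedance(params, frequencies)
    f = _check_frequencies(frequencies)
    return ImpedanceSpectrum(tuple(f), tuple(z.real), tuple(z.imag))


def eval_aric(params: ARICParameters, frequencies) -> ImpedanceSpectrum:
    """Evaluate the aRIC model on a frequency grid (Ce=0 reproduces eRIC)."""
    z = aric_impedance(params, frequencies)
    f = _check_frequencies(frequencies)
    return ImpedanceSpectrum(tuple(f), tuple(z.real), tuple(z.imag))


def model_fres(params: ERICParameters) -> float | None:
    """Closed-form resonant frequency of the eRIC model, Hz.

    Solving Im Z = 0 gives ``w_res² = (Rp²Cp − I) / (I Rp² Cp²)``, defined
    only when ``Rp²Cp > I``; otherwise the reactance never crosses zero and
    ``None`` is returned.
    """
    num = params.Rp**2 * params.Cp - params.I
    if num <= 0:
        return None
    w2 = num / (params.I * params.Rp**2 * params.Cp**2)
    return math.sqrt(w2) / _TWO_PI
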