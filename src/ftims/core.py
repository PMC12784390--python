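"""Domain types and physical relations for dual-gate drift-tube IMS.

A drift-tube ion mobility spectrometer separates gas-phase ions by the time
``td`` they take to traverse a drift region under a uniform electric field.
The field-normalised, standard-state mobility is the *reduced mobility*

    K0 = (L / (td * E)) * (273.15 / T) * (P / 760)

with drift length ``L`` (cm), field ``E`` (V/cm), temperature ``T`` (K) and
pressure ``P`` (Torr).  When the cell geometry is unknown, the product
``C = td * K0`` is constant for a given cell and set of conditions and serves
as a one-point mobility calibration.

In the Fourier-transform (FT) mode both the entrance and exit gates are driven
by the same square wave.  The time-averaged ion transmission through the gate
pair is the *gate correlation*: the overlap of two square waves of duty
``d`` delayed by the drift time, a triangular function of the phase
``phi = frac(f * td)``.  Sweeping or stepping the gate frequency therefore
encodes each ion's drift time as a triangle-wave "interferogram" in frequency,
which an FFT converts back into a drift-time spectrum.

External drift times are in milliseconds throughout; conversion to seconds
happens exactly once, inside the functions that need SI units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "STANDARD_TEMPERATURE_K",
    "STANDARD_PRESSURE_TORR",
    "IncompleteSpeciesError",
    "InvalidCellError",
    "IonSpecies",
    "DriftCell",
    "Amplifier",
    "NoiseModel",
    "drift_time",
    "reduced_mobility",
    "resolve_drift_time",
    "matched_frequency",
    "gate_correlation",
]

#: Standard state used in the reduced-mobility correction (universal DT-IMS
#: convention).
STANDARD_TEMPERATURE_K = 273.15
STANDARD_PRESSURE_TORR = 760.0


class IncompleteSpeciesError(ValueError):
    """An :class:`IonSpecies` lacks the field required for the operation."""


class InvalidCellError(ValueError):
    """A :class:`DriftCell` has non-positive or missing parameters."""


@dataclass(frozen=True)
class IonSpecies:
    """One analyte in a simulated mixture.

    Parameters
    ----------
    name
        Label used in reports.
    K0
        Reduced mobility, cm^2 V^-1 s^-1.  Optional if ``td`` is given.
    td
        Drift time, ms.  Optional if ``K0`` is given.
    abundance
        Dimensionless relative signal contribution, >= 0.
    sigma
        Intrinsic arrival-time standard deviation, ms, >= 0 (diffusional and
        gate-depletion broadening folded into one Gaussian width).
    """

    name: str
    K0: float | None = None
    td: float | None = None
    abundance: float = 1.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.K0 is None and self.td is None:
            raise IncompleteSpeciesError(
                f"ion {self.name!r}: at least one of K0 or td must be given"
            )
        if self.K0 is not None and self.K0 <= 0:
            raise ValueError(f"ion {self.name!r}: K0 must be > 0")
        if self.td is not None and self.td <= 0:
            raise ValueError(f"ion {self.name!r}: td must be > 0")
        if self.abundance < 0:
            raise ValueError(f"ion {self.name!r}: abundance must be >= 0")
        if self.sigma < 0:
            raise ValueError(f"ion {self.name!r}: sigma must be >= 0")


@dataclass(frozen=True)
class DriftCell:
    """Drift-cell description: explicit geometry or a mobility calibration.

    ``mode="geometry"`` uses length ``L`` (cm), field ``E`` (V/cm),
    temperature ``T`` (K) and pressure ``P`` (Torr).  ``mode="calibration"``
    uses only the cell constant ``C = td * K0`` (ms cm^2 V^-1 s^-1), the
    route of choice when the geometry was never measured.
    """

    mode: str = "calibration"
    C: float | None = None
    L: float | None = None
    E: float | None = None
    T: float = 298.15
    P: float = STANDARD_PRESSURE_TORR

    def __post_init__(self) -> None:
        if self.mode == "calibration":
            if self.C is None or self.C <= 0:
                raise InvalidCellError("calibration mode requires C > 0")
        elif self.mode == "geometry":
            for field_name in ("L", "E", "T", "P"):
                value = getattr(self, field_name)
                if value is None or value <= 0:
                    raise InvalidCellError(
                        f"geometry mode requires {field_name} > 0"
                    )
        else:
            raise InvalidCellError(f"unknown cell mode {self.mode!r}")

    @classmethod
    def from_calibration(cls, C: float) -> "DriftCell":
        return cls(mode="calibration", C=C)

    @classmethod
    def from_geometry(
        cls,
        L: float,
        E: float,
        T: float = 298.15,
        P: float = STANDARD_PRESSURE_TORR,
    ) -> "DriftCell":
        return cls(mode="geometry", L=L, E=E, T=T, P=P)


@dataclass(frozen=True)
class Amplifier:
    """Transimpedance amplifier: gain (V/A) and 10-90% rise time (ms).

    Modeled as a single-pole RC low-pass.  For a first-order system the
    10-90% rise time equals ``tau * ln 9``, so ``tau = rise_time / ln 9``.
    ``rise_time = 0`` means pass-through.  A long rise time (100 ms in FT
    mode) smooths the per-frequency detector current into a steady DC level,
    which is what makes software-timed (asynchronous) data windows valid.
    """

    gain: float = 1.0e9
    rise_time: float = 100.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.rise_time < 0:
            raise ValueError("rise_time must be >= 0")

    @property
    def tau_ms(self) -> float:
        """First-order time constant in ms (0 for pass-through)."""
        return self.rise_time / math.log(9.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive white noise and baseline on the raw detector signal.

    ``white_rms`` is the standard deviation per raw sample (arbitrary signal
    units); ``baseline`` a constant offset; ``seed`` the RNG seed.  Identical
    seed and parameters produce a bit-identical noise stream.
    """

    white_rms: float = 0.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_rms < 0:
            raise ValueError("white_rms must be >= 0")


def drift_time(ion: IonSpecies, cell: DriftCell) -> float:
    """Drift time in ms of ``ion`` (which must carry ``K0``) in ``cell``.

    Geometry mode evaluates ``td = L / (K * E)`` with the mobility at cell
    conditions ``K = K0 * (T / 273.15) * (760 / P)``; calibration mode uses
    ``td = C / K0``.
    """
    if ion.K0 is None:
        raise IncompleteSpeciesError(
            f"ion {ion.name!r} has no K0; cannot derive a drift time"
        )
    if cell.mode == "calibration":
        return cell.C / ion.K0
    K = ion.K0 * (cell.T / STANDARD_TEMPERATURE_K) * (STANDARD_PRESSURE_TORR / cell.P)
    return 1.0e3 * cell.L / (K * cell.E)


def reduced_mobility(td: float, cell: DriftCell) -> float:
    """Reduced mobility K0 from a drift time in ms; exact inverse of
    :func:`drift_time`."""
    if td <= 0:
        raise ValueError("td must be > 0")
    if cell.mode == "calibration":
        return cell.C / td
    K = cell.L / (td * 1.0e-3 * cell.E)
    return K * (STANDARD_TEMPERATURE_K / cell.T) * (cell.P / STANDARD_PRESSURE_TORR)


def resolve_drift_time(ion: IonSpecies, cell: DriftCell | None = None) -> float:
    """The ion's drift time in ms: the stated ``td`` if present, otherwise
    derived from ``K0`` and ``cell``."""
    if ion.td is not None:
        return ion.td
    if cell is None:
        raise IncompleteSpeciesError(
            f"ion {ion.name!r} has no td and no cell was given"
        )
    return drift_time(ion, cell)


def matched_frequency(td: float) -> float:
    """Gate frequency (Hz) whose period equals the drift time ``td`` (ms).

    At this frequency consecutive gate openings are exactly one drift time
    apart and transmission through the gate pair is maximal.
    """
    if td <= 0:
        raise ValueError("td must be > 0")
    return 1.0e3 / td


def gate_correlation(f, td, duty: float = 0.5):
    """Time-averaged transmission of two matched square-wave gates.

    Both gates run the same square wave of frequency ``f`` (Hz) and duty
    ``duty``; the ion swarm arrives at the exit gate delayed by ``td`` (ms).
    The average open-open overlap is a triangular function of the phase
    ``phi = frac(f * td)``::

        g = max(0, duty - min(phi, 1 - phi))          (duty <= 0.5)

    which for the FT experiment's 50% duty reduces to
    ``0.5 * (1 - 2 * min(phi, 1 - phi))``: maximal (= duty) at phase 0,
    zero in anti-phase, periodic in phi with period 1.

    Accepts scalars or arrays (broadcast) for ``f`` and ``td``.
    """
    if not 0.0 < duty <= 0.5:
        raise ValueError("duty must lie in (0, 0.5]")
    f = np.asarray(f, dtype=float)
    td = np.asarray(td, dtype=float)
    if np.any(f <= 0):
        raise ValueError("f must be > 0")
    if np.any(td <= 0):
        raise ValueError("td must be > 0")
    phi = np.mod(f * td * 1.0e-3, 1.0)
    m = np.minimum(phi, 1.0 - phi)
    g = np.maximum(0.0, duty - m)
    if g.ndim == 0:
        return float(g)
    return g
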