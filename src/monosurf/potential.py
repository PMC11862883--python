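"""Surface-potential (ΔV–APL) isotherm analysis.

The apparent dipole moment of a film point is μa = ΔV·A·ε₀ with A the
molecular area (converted Å² → m²) and ε₀ the vacuum permittivity; the
monolayer's own permittivity is unknown and deliberately not modelled,
so μa is the ε₀-based apparent moment only, reported in Debye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import A2_TO_M2, DEBYE, EPSILON_0
from .errors import InputError
from .isotherm import _smooth

__all__ = [
    "PotentialIsotherm",
    "DipoleCurve",
    "MaxDipole",
    "apparent_dipole_moment",
    "detect_critical_area",
    "max_dipole",
]


@dataclass
class PotentialIsotherm:
    """Ordered (APL Å², ΔV V) samples from one compression branch."""

    apl: np.ndarray
    dv: np.ndarray
    label: str = ""
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.apl = np.asarray(self.apl, dtype=float)
        self.dv = np.asarray(self.dv, dtype=float)
        if self.apl.ndim != 1 or self.apl.shape != self.dv.shape:
            raise InputError("apl and dv must be 1-D arrays of equal length")
        if self.apl.size < 2:
            raise InputError("a potential isotherm needs at least 2 samples")
        d = np.diff(self.apl)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InputError("apl must be strictly monotone")
        if not np.all(np.isfinite(self.dv)):
            raise InputError("dv must be finite")

    def compression_order(self) -> tuple[np.ndarray, np.ndarray]:
        if self.apl[0] < self.apl[-1]:
            return self.apl[::-1], self.dv[::-1]
        return self.apl, self.dv


@dataclass
class DipoleCurve:
    """Apparent dipole moment μa (Debye) along the APL axis."""

    apl: np.ndarray
    mu_a: np.ndarray


@dataclass(frozen=True)
class MaxDipole:
    apl: float
    mu_a: float
    flat: bool = False


def apparent_dipole_moment(iso: PotentialIsotherm) -> DipoleCurve:
    """μa = ΔV·A·ε₀ per sample, in Debye."""
    mu_cm = iso.dv * (iso.apl * A2_TO_M2) * EPSILON_0  # C·m
    return DipoleCurve(apl=iso.apl.copy(), mu_a=mu_cm / DEBYE)


def dv_from_dipole(mu_a_debye: np.ndarray, apl: np.ndarray) -> np.ndarray:
    """Invert μa = ΔV·A·ε₀ back to ΔV (V); unit round-trip helper."""
    return np.asarray(mu_a_debye) * DEBYE / (np.asarray(apl) * A2_TO_M2 * EPSILON_0)


def detect_critical_area(
    iso: PotentialIsotherm,
    smoothing: int | None = 11,
    min_range: float = 1e-6,
) -> float | None:
    """APL of the sharpest ΔV rise during compression.

    Returns the APL at the maximum |d(ΔV)/d(APL)| of the (optionally
    smoothed) curve — the onset of the sharp potential rise seen when
    condensing domains reorient their dipoles. None for a flat curve
    (ΔV range below ``min_range`` volts).
    """
    apl, dv = iso.compression_order()
    if np.ptp(dv) < min_range:
        return None
    dv_s, _ = _smooth(dv, apl, smoothing)
    slope = np.gradient(dv_s, apl)
    return float(apl[int(np.argmax(np.abs(slope)))])


def max_dipole(curve: DipoleCurve) -> MaxDipole:
    """Argmax and max of μa; flags an all-flat curve."""
    if curve.mu_a.size == 0:
        raise InputError("empty dipole curve")
    if np.ptp(curve.mu_a) < 1e-15:
        return MaxDipole(apl=float(curve.apl[0]), mu_a=float(curve.mu_a[0]), flat=True)
    i = int(np.argmax(curve.mu_a))
    return MaxDipole(apl=float(curve.apl[i]), mu_a=float(curve.mu_a[i]))
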