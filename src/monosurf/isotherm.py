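"""π–APL isotherm analysis for Langmuir monolayers.

Covers the standard compression-branch measurements: surface pressure
from tension (π = γ_water − γ), the in-plane compression modulus
Cs⁻¹ = −A·(∂π/∂A), Davies–Rideal phase classification from Cs⁻¹ bands,
lift-off and collapse detection, and stability metrics from constant-π
relaxation traces (A/A₀ vs t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .constants import GAMMA_WATER
from .errors import InputError

__all__ = [
    "Isotherm",
    "ModulusCurve",
    "RelaxationTrace",
    "CollapsePoint",
    "RelaxationMetrics",
    "surface_pressure_from_tension",
    "compression_modulus",
    "classify_phase",
    "PHASE_BANDS",
    "detect_lift_off",
    "detect_collapse",
    "relaxation_metrics",
]


@dataclass
class Isotherm:
    """Ordered (APL, π) samples from one compression branch.

    APL in Å², π in mN·m⁻¹; APL must be strictly monotone (recorded
    decreasing during compression, but an increasing grid is accepted
    and handled in compression order internally).
    """

    apl: np.ndarray
    pi: np.ndarray
    temperature: float = 36.6
    compression_rate: float = 10.0
    label: str = ""
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.apl = np.asarray(self.apl, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.apl.ndim != 1 or self.apl.shape != self.pi.shape:
            raise InputError("apl and pi must be 1-D arrays of equal length")
        if self.apl.size < 2:
            raise InputError("an isotherm needs at least 2 samples")
        d = np.diff(self.apl)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InputError("apl must be strictly monotone")

    def compression_order(self) -> tuple[np.ndarray, np.ndarray]:
        """(apl, pi) with APL decreasing (compression direction)."""
        if self.apl[0] < self.apl[-1]:
            return self.apl[::-1], self.pi[::-1]
        return self.apl, self.pi


@dataclass
class ModulusCurve:
    """Cs⁻¹ along an isotherm, indexed both by π and by APL."""

    pi: np.ndarray
    cs_inv: np.ndarray
    apl: np.ndarray
    smoothing: str = "none"

    @property
    def max_modulus(self) -> float:
        return float(np.nanmax(self.cs_inv))

    @property
    def pi_at_max(self) -> float:
        return float(self.pi[int(np.nanargmax(self.cs_inv))])


@dataclass
class RelaxationTrace:
    """A/A₀ vs time at a constant surface-pressure setpoint."""

    t: np.ndarray
    rel_area: np.ndarray
    setpoint_pi: float = 30.0
    label: str = ""
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rel_area = np.asarray(self.rel_area, dtype=float)
        if self.t.shape != self.rel_area.shape or self.t.ndim != 1:
            raise InputError("t and rel_area must be 1-D arrays of equal length")
        if self.t.size < 2 or np.any(np.diff(self.t) <= 0):
            raise InputError("t must be strictly increasing")
        if abs(self.rel_area[0] - 1.0) > 0.05:
            raise InputError("rel_area must start at 1 (A = A0 at t = 0)")


@dataclass(frozen=True)
class CollapsePoint:
    pi: float
    apl: float


@dataclass(frozen=True)
class RelaxationMetrics:
    area_loss_fraction: float
    initial_rate: float  # s⁻¹, ≥ 0 for a decaying film
    exp_constant: float  # s⁻¹ from log-linear fit


def surface_pressure_from_tension(
    gamma: float | np.ndarray, gamma_water: float = GAMMA_WATER
) -> float | np.ndarray:
    """π = γ_water − γ.  Negative π is allowed (expanded film noise)."""
    result = gamma_water - np.asarray(gamma, dtype=float)
    return float(result) if result.ndim == 0 else result


def _smooth(y: np.ndarray, x: np.ndarray, window: int | None) -> tuple[np.ndarray, str]:
    """Savitzky–Golay smoothing on a (near-)uniform grid; raw otherwise."""
    if window is None or window < 3 or y.size < 4:
        return y, "none"
    window = min(window, y.size if y.size % 2 else y.size - 1)
    if window % 2 == 0:
        window -= 1
    if window < 3:
        return y, "none"
    dx = np.abs(np.diff(x))
    if dx.std() > 0.01 * dx.mean():  # savgol assumes uniform spacing
        return y, "none (non-uniform grid)"
    order = min(3, window - 1)
    return savgol_filter(y, window, order), f"savgol(window={window}, order={order})"


def compression_modulus(
    iso: Isotherm, smoothing: int | None = 11
) -> ModulusCurve:
    """Cs⁻¹(A) = −A·dπ/dA by central finite differences.

    π(A) is optionally smoothed with a local-polynomial (Savitzky–Golay)
    filter before differentiation; endpoints use one-sided differences
    (numpy.gradient). ``smoothing`` is the window length in samples, or
    None for the raw derivative.
    """
    if iso.apl.size < 4:
        raise InputError("compression modulus needs at least 4 samples")
    apl, pi = iso.compression_order()
    pi_s, desc = _smooth(pi, apl, smoothing)
    dpi_dA = np.gradient(pi_s, apl)
    cs_inv = -apl * dpi_dA
    return ModulusCurve(pi=pi_s, cs_inv=cs_inv, apl=apl, smoothing=desc)


#: Davies–Rideal Cs⁻¹ bands (mN·m⁻¹); a boundary belongs to the lower band.
PHASE_BANDS: tuple[tuple[float, str], ...] = (
    (12.5, "gaseous"),
    (50.0, "LE"),
    (100.0, "intermediate LE-LC"),
    (250.0, "LC"),
    (np.inf, "solid"),
)


def classify_phase(cs_inv: float) -> str:
    """Monolayer phase label from the compression modulus (Davies–Rideal)."""
    if cs_inv < 0:
        raise InputError(f"Cs⁻¹ must be non-negative, got {cs_inv}")
    for upper, label in PHASE_BANDS:
        if cs_inv <= upper:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def detect_lift_off(
    iso: Isotherm,
    pi_threshold: float = 0.5,
    baseline_fraction: float = 0.1,
) -> float | None:
    """APL at which π first rises above its large-area baseline.

    The baseline is the median π over the leading ``baseline_fraction``
    of samples (largest areas). The rise is located where π first
    exceeds baseline + ``pi_threshold`` during compression; the onset
    itself is then estimated by a hinge (change-point) least-squares
    fit — π = baseline above the onset area, a linear rise below it —
    over the samples up to ~6× the threshold above baseline. The hinge
    apex is the reported lift-off; unlike the raw threshold crossing it
    is unbiased on clean curves and robust to instrument-scale noise.
    Returns None when π never exceeds the threshold (no lift-off).
    """
    apl, pi = iso.compression_order()
    n_base = max(2, int(round(baseline_fraction * apl.size)))
    baseline = float(np.median(pi[:n_base]))
    above = np.nonzero(pi > baseline + pi_threshold)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    past = np.nonzero(pi[i:] > baseline + 6.0 * pi_threshold)[0]
    i1 = i + int(past[0]) if past.size else pi.size - 1
    window = slice(0, min(i1 + 1, pi.size))
    areas = apl[window]
    y = pi[window] - baseline
    if areas.size < 3:
        return float(apl[i])
    best_rss, best_a = np.inf, float(apl[i])
    for a in np.linspace(areas[-1], areas[0], 400):
        x = np.maximum(a - areas, 0.0)
        sx2 = float((x * x).sum())
        if sx2 == 0.0:
            continue
        slope = float((x * y).sum()) / sx2
        if slope < 0:
            continue
        resid = y - slope * x
        rss = float((resid * resid).sum())
        if rss < best_rss:
            best_rss, best_a = rss, float(a)
    return best_a


def detect_collapse(
    iso: Isotherm,
    smoothing: int | None = None,
    plateau_tol: float = 0.05,
) -> CollapsePoint | None:
    """First plateau/kink of the compression branch after π > π_max/2.

    During compression dπ/dA is strongly negative; collapse is flagged at
    the first sample where the derivative changes sign or its magnitude
    drops below ``plateau_tol`` × its peak magnitude. Returns None for a
    strictly rising branch with no plateau.
    """
    apl, pi = iso.compression_order()
    if apl.size < 4:
        raise InputError("collapse detection needs at least 4 samples")
    pi_s, _ = _smooth(pi, apl, smoothing)
    dpi_dA = np.gradient(pi_s, apl)
    pi_max = pi_s.max()
    if pi_max <= 0:
        return None
    slope_scale = np.max(-dpi_dA)
    if slope_scale <= 0:
        return None
    started = np.nonzero(pi_s > 0.5 * pi_max)[0]
    if started.size == 0:
        return None
    for k in range(int(started[0]), apl.size):
        if dpi_dA[k] > 0 or -dpi_dA[k] < plateau_tol * slope_scale:
            return CollapsePoint(pi=float(pi_s[k]), apl=float(apl[k]))
    return None


def relaxation_metrics(
    trace: RelaxationTrace, initial_fraction: float = 0.1
) -> RelaxationMetrics:
    """Stability metrics of a constant-π relaxation trace.

    area_loss_fraction = 1 − min(A/A₀); the initial decay rate is the
    negated least-squares slope over the first ``initial_fraction`` of
    samples; the exponential constant k comes from a log-linear fit of
    A/A₀ = exp(−k·t) over the strictly positive samples.
    """
    t, y = trace.t, trace.rel_area
    loss = float(1.0 - y.min())
    n0 = max(3, int(round(initial_fraction * t.size)))
    slope0 = np.polyfit(t[:n0], y[:n0], 1)[0]
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(y[pos]) > 0:
        k = -np.polyfit(t[pos], np.log(y[pos]), 1)[0]
    else:
        k = 0.0
    return RelaxationMetrics(
        area_loss_fraction=loss,
        initial_rate=float(-slope0),
        exp_constant=float(k),
    )
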