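"""Ground-truth generators for every analysis stage.

Each generator draws from an explicitly seeded ``numpy.random.Generator``
(no global state), attaches a machine-readable ``ground_truth`` record to
its output, and is byte-deterministic under a fixed seed. The defaults
emulate the study conditions of a cholesterol-enriched lung-surfactant
monolayer: π–APL isotherms with lift-off at 86 Å², a maximum compression
modulus inside the LE–LC coexistence band and collapse at 42 mN·m⁻¹; a
DPPC:POPC:POPG:CHOL film of 1016 molecules per leaflet; ΔV curves with a
sharp critical-area rise; constant-π relaxation decays; and pressure
series whose tension estimator has a prescribed expectation.

Scenes are geometric fixtures — jittered-lattice films with straight,
tilted bead chains — not equilibrium ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .composition import MonolayerComposition, lung_surfactant
from .constants import BAR_NM_TO_MN_PER_M
from .errors import InputError
from .isotherm import Isotherm, RelaxationTrace
from .potential import PotentialIsotherm
from .traj import FrameSet, PressureSeries

__all__ = [
    "PhaseSegment",
    "IsothermModel",
    "TiltSpec",
    "SceneSpec",
    "gen_isotherm",
    "gen_scene",
    "gen_pressure_series",
    "gen_potential_curve",
    "gen_relaxation",
]


# ---------------------------------------------------------------------------
# Isotherms


@dataclass(frozen=True)
class PhaseSegment:
    """One isotherm segment with a prescribed compression modulus."""

    apl_min: float
    apl_max: float
    cs_inv: float

    def __post_init__(self) -> None:
        if self.apl_min >= self.apl_max:
            raise InputError("segment requires apl_min < apl_max")
        if self.cs_inv < 0:
            raise InputError("prescribed Cs⁻¹ must be non-negative")


@dataclass(frozen=True)
class IsothermModel:
    """Piecewise-modulus isotherm model with lift-off and collapse.

    Segments are listed in compression order (descending APL), must be
    contiguous, and the first must start at the lift-off area. Within a
    segment dπ/dA = −Cs⁻¹/A, so π grows as Cs⁻¹·ln(A_top/A); π plateaus
    once it reaches ``collapse_pi``.
    """

    lift_off_apl: float = 86.0
    segments: tuple[PhaseSegment, ...] = (PhaseSegment(30.0, 86.0, 75.0),)
    collapse_pi: float = 42.0
    noise_sd: float = 0.0
    seed: int = 0
    apl_max: float = 110.0
    apl_step: float = 0.25

    def __post_init__(self) -> None:
        if self.collapse_pi <= 0:
            raise InputError("collapse_pi must be positive")
        if self.lift_off_apl >= self.apl_max:
            raise InputError("lift_off_apl must be below apl_max")
        if self.segments:
            if abs(self.segments[0].apl_max - self.lift_off_apl) > 1e-9:
                raise InputError("first segment must start at the lift-off area")
            for a, b in zip(self.segments[:-1], self.segments[1:]):
                if abs(a.apl_min - b.apl_max) > 1e-9:
                    raise InputError("segments must be contiguous and ordered")


def _pi_of_apl(model: IsothermModel, apl: float) -> float:
    """Noise-free π at one APL (before the collapse plateau)."""
    if apl >= model.lift_off_apl:
        return 0.0
    pi = 0.0
    for seg in model.segments:
        if apl >= seg.apl_max:
            break
        bottom = max(apl, seg.apl_min)
        pi += seg.cs_inv * math.log(seg.apl_max / bottom)
        if apl >= seg.apl_min:
            break
    return pi


def _collapse_apl(model: IsothermModel) -> float | None:
    """APL at which the noise-free curve reaches collapse_pi, if any."""
    pi = 0.0
    for seg in model.segments:
        if seg.cs_inv <= 0:
            continue
        gain = seg.cs_inv * math.log(seg.apl_max / seg.apl_min)
        if pi + gain >= model.collapse_pi:
            return seg.apl_max * math.exp(-(model.collapse_pi - pi) / seg.cs_inv)
        pi += gain
    return None


def gen_isotherm(model: IsothermModel = IsothermModel()) -> Isotherm:
    """Synthesise a compression π–APL isotherm from a piecewise model."""
    apl_min = model.segments[-1].apl_min if model.segments else model.lift_off_apl
    n = int(round((model.apl_max - apl_min) / model.apl_step)) + 1
    apl = model.apl_max - model.apl_step * np.arange(n)
    pi = np.array([_pi_of_apl(model, a) for a in apl])
    pi = np.minimum(pi, model.collapse_pi)
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        pi = pi + rng.normal(0.0, model.noise_sd, size=pi.shape)
    truth = {
        "lift_off_apl": model.lift_off_apl,
        "segments": [
            {"apl_min": s.apl_min, "apl_max": s.apl_max, "cs_inv": s.cs_inv}
            for s in model.segments
        ],
        "collapse_pi": model.collapse_pi,
        "collapse_apl": _collapse_apl(model),
        "noise_sd": model.noise_sd,
        "seed": model.seed,
    }
    return Isotherm(apl=apl, pi=pi, label="synthetic", ground_truth=truth)


# ---------------------------------------------------------------------------
# Scenes

#: head-group bead names per species (listed top → subphase)
_HEAD_BEADS = {
    "DPPC": ("GL1", "GL2", "PO4", "NC3"),
    "POPC": ("GL1", "GL2", "PO4", "NC3"),
    "POPG": ("GL1", "GL2", "PO4", "GL0"),
}
_CHOL_BEADS = ("ROH", "R1", "R2", "R3", "R4", "R5")
_DRUG_BEADS = ("SC1", "SC2", "SC3", "SC4", "SC5", "SC6")
_BOND_LENGTH = 0.47  # nm, chain bead spacing
_HEAD_SPACING = 0.30  # nm, head bead stacking below the interface


@dataclass(frozen=True)
class TiltSpec:
    """Chain-tilt distribution: 'delta' (exact angle) or 'gaussian'."""

    kind: str = "delta"
    mean_deg: float = 0.0
    sd_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("delta", "gaussian"):
            raise InputError("tilt kind must be 'delta' or 'gaussian'")
        if not 0.0 <= self.mean_deg <= 90.0:
            raise InputError("tilt mean must lie in [0, 90] degrees")

    def expected_p2(self) -> float | None:
        if self.kind == "delta":
            c = math.cos(math.radians(self.mean_deg))
            return 0.5 * (3.0 * c * c - 1.0)
        return None


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic monolayer scene."""

    composition: MonolayerComposition = field(default_factory=lung_surfactant)
    apl: float = 49.0
    tilt: TiltSpec = TiltSpec()
    drug_count: int = 0
    drug_placement: str = "dispersed"  # dispersed | aggregated | airborne
    drug_cluster_sizes: tuple[int, ...] | None = None
    pores: tuple[tuple[float, float, float], ...] = ()  # (cx, cy, r) nm
    collapse_fraction: float = 0.0
    collapse_displacement: float = 3.0
    n_frames: int = 1
    seed: int = 0
    jitter: float = 0.05  # nm, lateral lattice jitter
    box_height: float = 15.0  # nm
    interface_z: float = 5.0  # nm

    def __post_init__(self) -> None:
        if self.apl <= 0:
            raise InputError("apl must be positive")
        if math.sqrt(self.apl) / 10.0 < 0.40:
            raise InputError(
                f"over-packed scene: APL {self.apl} Å² gives a lattice "
                "spacing below 0.40 nm"
            )
        if self.drug_placement not in ("dispersed", "aggregated", "airborne"):
            raise InputError("unknown drug placement mode")
        if self.drug_placement == "aggregated":
            sizes = self.drug_cluster_sizes
            if not sizes or sum(sizes) != self.drug_count:
                raise InputError(
                    "aggregated placement needs cluster sizes summing to "
                    "drug_count"
                )
        if not 0.0 <= self.collapse_fraction <= 1.0:
            raise InputError("collapse_fraction must lie in [0, 1]")
        if self.n_frames < 1:
            raise InputError("n_frames must be at least 1")


def _species_order(spec: SceneSpec, rng: np.random.Generator) -> list[str]:
    names: list[str] = []
    for name, count in spec.composition.leaflet_counts().items():
        names.extend([name] * count)
    rng.shuffle(names)
    return names


def _build_lipid(
    species: str,
    site: np.ndarray,
    theta: float,
    phi: float,
    z0: float,
) -> tuple[list[str], np.ndarray]:
    """Bead names and coordinates for one molecule anchored at ``site``."""
    u = np.array(
        [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi),
         math.cos(theta)]
    )
    x, y = site
    if species == "CHOL":
        names = list(_CHOL_BEADS)
        base = np.array([x, y, z0])
        coords = base + np.arange(len(names))[:, None] * 0.30 * u
        return names, coords
    heads = _HEAD_BEADS[species]
    names = list(heads)
    coords = [np.array([x, y, z0 - i * _HEAD_SPACING]) for i in range(len(heads))]
    chain_a = ("C1A", "C2A", "C3A", "C4A") if species == "DPPC" else (
        "C1A", "D2A", "C3A", "C4A"
    )
    chain_b = ("C1B", "C2B", "C3B", "C4B")
    for chain, x_off in ((chain_a, 0.0), (chain_b, 0.23)):
        anchor = np.array([x + x_off, y, z0])
        for k, bead in enumerate(chain):
            names.append(bead)
            coords.append(anchor + (k + 1) * _BOND_LENGTH * u)
    return names, np.asarray(coords)


def _place_drugs(
    spec: SceneSpec, lx: float, ly: float, z_top: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Center positions of each drug molecule per placement mode."""
    n = spec.drug_count
    if n == 0:
        return []
    if spec.drug_placement == "aggregated":
        sizes = spec.drug_cluster_sizes or ()
        n_clusters = len(sizes)
        grid = math.ceil(math.sqrt(n_clusters))
        step_x, step_y = lx / grid, ly / grid
        if min(step_x, step_y) < 3.0:
            raise InputError("box too small to separate drug clusters")
        centers = []
        for k, size in enumerate(sizes):
            cx = (k % grid + 0.5) * step_x
            cy = (k // grid + 0.5) * step_y
            for m in range(size):  # stacked in z: single-linkage chain
                centers.append(np.array([cx, cy, z_top + 1.0 + 0.45 * m]))
        return centers
    # dispersed / airborne: coarse grid, guaranteed mutual separation.
    # dispersed drugs sit Gaussian around the head-group plane (where the
    # drug accumulates in the monolayer); airborne drugs float near the
    # top of the box.
    grid = math.ceil(math.sqrt(n))
    step_x, step_y = lx / grid, ly / grid
    if min(step_x, step_y) < 1.5:
        raise InputError("box too small to disperse the requested drug count")
    centers = []
    for k in range(n):
        cx = (k % grid + 0.5) * step_x
        cy = (k // grid + 0.5) * step_y
        if spec.drug_placement == "dispersed":
            z = spec.interface_z - 0.45 + rng.normal(0.0, 0.3)
        else:
            z = spec.box_height - 1.5
        centers.append(np.array([cx, cy, z]))
    return centers


def _drug_molecule(center: np.ndarray) -> tuple[list[str], np.ndarray]:
    offsets = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.20, 0.0, 0.0],
            [0.0, 0.20, 0.0],
            [0.20, 0.20, 0.0],
            [0.10, 0.10, 0.20],
            [0.10, 0.10, -0.20],
        ]
    )
    return list(_DRUG_BEADS), center + offsets


def gen_scene(spec: SceneSpec = SceneSpec()) -> FrameSet:
    """Build a monolayer FrameSet from a scene recipe.

    Lipids are placed on a jittered square lattice at the requested APL
    (one leaflet), chains as straight bead rods tilted per the tilt
    distribution (azimuths uniform). Drugs are placed per mode, pore
    disks excise lipids, and collapse displaces a molecule fraction
    downward — applied to frames after the first when the scene has
    several frames, so the first frame is a flat-film baseline.
    """
    rng = np.random.default_rng(spec.seed)
    n_lipids = spec.composition.n_per_leaflet
    lx = ly = math.sqrt(spec.apl * n_lipids) / 10.0  # Å² → nm
    species = _species_order(spec, rng)

    # vacancy-free lattice: rows share the lipids as evenly as possible,
    # each row spreading its own count across the full box width
    n_rows = math.ceil(math.sqrt(n_lipids))
    base, extra = divmod(n_lipids, n_rows)
    row_sites: list[tuple[float, float]] = []
    for j in range(n_rows):
        count = base + (1 if j < extra else 0)
        for i in range(count):
            row_sites.append(((i + 0.5) * lx / count, (j + 0.5) * ly / n_rows))

    sites = []
    kept_species = []
    for k in range(n_lipids):
        sx, sy = row_sites[k]
        inside_pore = False
        for cx, cy, r in spec.pores:
            dx = sx - cx - lx * round((sx - cx) / lx)
            dy = sy - cy - ly * round((sy - cy) / ly)
            if dx * dx + dy * dy <= r * r:
                inside_pore = True
                break
        if not inside_pore:
            sites.append((sx, sy))
            kept_species.append(species[k])
    if not sites:
        raise InputError("all lipids excised by pores")

    n_kept = len(sites)
    n_collapse = int(round(spec.collapse_fraction * n_kept))
    collapse_ids = set(rng.choice(n_kept, size=n_collapse, replace=False).tolist())
    drug_centers = _place_drugs(
        spec, lx, ly, spec.interface_z + 4 * _BOND_LENGTH, rng
    )

    frames = []
    names_out: list[str] | None = None
    resn_out: list[str] | None = None
    resid_out: list[int] | None = None
    for f in range(spec.n_frames):
        coords: list[np.ndarray] = []
        names: list[str] = []
        resn: list[str] = []
        resid: list[int] = []
        rid = 0
        for m, ((sx, sy), sp) in enumerate(zip(sites, kept_species)):
            rid += 1
            jx, jy = rng.normal(0.0, spec.jitter, size=2)
            site = np.array([sx + jx, sy + jy])
            if spec.tilt.kind == "delta":
                theta = math.radians(spec.tilt.mean_deg)
            else:
                theta = math.radians(
                    float(
                        np.clip(
                            rng.normal(spec.tilt.mean_deg, spec.tilt.sd_deg),
                            0.0,
                            90.0,
                        )
                    )
                )
            phi = rng.uniform(0.0, 2.0 * math.pi)
            b_names, b_coords = _build_lipid(sp, site, theta, phi, spec.interface_z)
            apply_collapse = (spec.n_frames == 1) or (f > 0)
            if apply_collapse and m in collapse_ids:
                b_coords = b_coords - [0.0, 0.0, spec.collapse_displacement]
            coords.append(b_coords)
            names.extend(b_names)
            resn.extend([sp] * len(b_names))
            resid.extend([rid] * len(b_names))
        for center in drug_centers:
            rid += 1
            b_names, b_coords = _drug_molecule(center)
            coords.append(b_coords)
            names.extend(b_names)
            resn.extend(["MF"] * len(b_names))
            resid.extend([rid] * len(b_names))
        frames.append(np.concatenate(coords, axis=0))
        if names_out is None:
            names_out, resn_out, resid_out = names, resn, resid

    box = np.tile([lx, ly, spec.box_height], (spec.n_frames, 1))
    truth = {
        "apl": spec.apl,
        "box": [lx, ly, spec.box_height],
        "n_lipids": n_kept,
        "composition_counts": spec.composition.leaflet_counts(),
        "tilt": {
            "kind": spec.tilt.kind,
            "mean_deg": spec.tilt.mean_deg,
            "sd_deg": spec.tilt.sd_deg,
            "expected_p2": spec.tilt.expected_p2(),
        },
        "drug": {
            "count": spec.drug_count,
            "placement": spec.drug_placement,
            "cluster_sizes": (
                sorted(spec.drug_cluster_sizes, reverse=True)
                if spec.drug_cluster_sizes
                else None
            ),
        },
        "pores": [
            {"center": [cx, cy], "radius": r, "area": math.pi * r * r}
            for cx, cy, r in spec.pores
        ],
        "collapse": {
            "fraction": spec.collapse_fraction,
            "displacement": spec.collapse_displacement,
            "n_molecules": int(n_collapse),
        },
        "seed": spec.seed,
    }
    return FrameSet(
        coords=np.stack(frames),
        box=box,
        resnames=np.array(resn_out, dtype=object),
        beadnames=np.array(names_out, dtype=object),
        resids=np.array(resid_out, dtype=int),
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# Pressure series, potential curves, relaxation traces


def gen_pressure_series(
    gamma_target: float = 23.0,
    lz: float = 20.0,
    n_interfaces: int = 2,
    noise_sd: float = 0.0,
    n: int = 1000,
    dt: float = 10.0,
    seed: int = 0,
) -> PressureSeries:
    """Pressure-tensor series whose γ estimator expectation is the target.

    The anisotropy ΔP = Pzz − (Pxx+Pyy)/2 is set to
    γ·n_interfaces/(0.1·Lz) bar; independent Gaussian noise of
    ``noise_sd`` bar is added to each tensor component.
    """
    if n < 1:
        raise InputError("n must be at least 1")
    rng = np.random.default_rng(seed)
    dp = gamma_target * n_interfaces / (BAR_NM_TO_MN_PER_M * lz)
    pzz = np.full(n, 1.0)
    pxx = np.full(n, 1.0 - dp)
    pyy = np.full(n, 1.0 - dp)
    if noise_sd > 0:
        pzz = pzz + rng.normal(0.0, noise_sd, n)
        pxx = pxx + rng.normal(0.0, noise_sd, n)
        pyy = pyy + rng.normal(0.0, noise_sd, n)
    truth = {
        "gamma_target": gamma_target,
        "lz": lz,
        "n_interfaces": n_interfaces,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return PressureSeries(
        t=dt * np.arange(n),
        pxx=pxx,
        pyy=pyy,
        pzz=pzz,
        lz=np.full(n, lz),
        ground_truth=truth,
    )


def gen_potential_curve(
    critical_apl: float = 85.0,
    dv_max: float = 0.4,
    width: float = 2.0,
    apl_max: float = 120.0,
    apl_min: float = 40.0,
    apl_step: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PotentialIsotherm:
    """Sigmoidal ΔV–APL curve with a prescribed critical (inflection) area."""
    if width <= 0:
        raise InputError("width must be positive")
    n = int(round((apl_max - apl_min) / apl_step)) + 1
    apl = apl_max - apl_step * np.arange(n)
    dv = dv_max / (1.0 + np.exp((apl - critical_apl) / width))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dv = dv + rng.normal(0.0, noise_sd, n)
    truth = {
        "critical_apl": critical_apl,
        "dv_max": dv_max,
        "width": width,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return PotentialIsotherm(apl=apl, dv=dv, label="synthetic", ground_truth=truth)


def gen_relaxation(
    rate: float = 0.01,
    mode: str = "exp",
    setpoint_pi: float = 30.0,
    t_max: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RelaxationTrace:
    """Constant-π relaxation trace: exp(−k·t) or linear 1 − b·t decay."""
    if mode not in ("exp", "linear"):
        raise InputError("mode must be 'exp' or 'linear'")
    if rate < 0:
        raise InputError("rate must be non-negative")
    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    if mode == "exp":
        y = np.exp(-rate * t)
    else:
        y = np.maximum(1.0 - rate * t, 1e-6)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, t.size)
        noise[0] = 0.0  # A/A0 starts at exactly 1
        y = y + noise
    truth = {
        "rate": rate,
        "mode": mode,
        "noise_sd": noise_sd,
        "seed": seed,
        "setpoint_pi": setpoint_pi,
    }
    return RelaxationTrace(
        t=t, rel_area=y, setpoint_pi=setpoint_pi, ground_truth=truth
    )
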