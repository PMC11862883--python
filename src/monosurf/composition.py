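"""Monolayer composition, dosing and box-geometry arithmetic.

Links mole fractions, molecular weights, drug % w/w mass concentrations,
absolute molecule counts and the area-per-lipid (APL) ↔ box-edge relation
for a lung-surfactant monolayer model (DPPC:POPC:POPG:CHOL with an
optional corticosteroid load).

The drug mass concentration of a film carrying ``n`` drug molecules is

    C (% w/w) = 100 · n·MW_d / (n·MW_d + Σ_i N_i·MW_i)

where ``N_i``, ``MW_i`` run over the lipid species; Avogadro's number
cancels, so the ratio is evaluated directly on count·MW products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .constants import (
    AVOGADRO,
    MW_CHOL,
    MW_DPPC,
    MW_MOMETASONE_FUROATE,
    MW_POPC,
    MW_POPG_NA,
)
from .errors import InputError

__all__ = [
    "LipidSpecies",
    "MonolayerComposition",
    "DrugSpec",
    "BoxGeometry",
    "MassFractions",
    "lung_surfactant",
    "lung_surfactant_nominal",
    "mass_fractions",
    "concentration_for_count",
    "drug_count_for_concentration",
    "dose_to_molecules",
    "apl_from_box",
    "box_for_apl",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species: name, molecular weight (g·mol⁻¹), mole fraction."""

    name: str
    molecular_weight: float
    mole_fraction: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise InputError(
                f"molecular weight of {self.name!r} must be positive, "
                f"got {self.molecular_weight}"
            )
        if not 0.0 <= self.mole_fraction <= 1.0:
            raise InputError(
                f"mole fraction of {self.name!r} must lie in [0, 1], "
                f"got {self.mole_fraction}"
            )


@dataclass(frozen=True)
class MonolayerComposition:
    """An ordered lipid mixture with absolute per-species molecule counts.

    ``counts`` are totals over all leaflets and must be divisible into
    ``n_leaflets`` equal films only in aggregate (``total_molecules %
    n_leaflets == 0``); per-species counts need not split evenly.
    """

    species: tuple[LipidSpecies, ...]
    counts: tuple[int, ...]
    n_leaflets: int = 2

    def __post_init__(self) -> None:
        if not self.species:
            raise InputError("composition must contain at least one species")
        if len(self.counts) != len(self.species):
            raise InputError("one count per species required")
        if any((not isinstance(c, int)) or c < 0 for c in self.counts):
            raise InputError("counts must be non-negative integers")
        if self.n_leaflets not in (1, 2):
            raise InputError("n_leaflets must be 1 or 2")
        total = sum(self.counts)
        if total == 0:
            raise InputError("composition must contain at least one molecule")
        if total % self.n_leaflets:
            raise InputError(
                f"total molecule count {total} not divisible by "
                f"{self.n_leaflets} leaflets"
            )
        frac_sum = sum(s.mole_fraction for s in self.species)
        if abs(frac_sum - 1.0) > _FRACTION_TOL:
            raise InputError(
                f"mole fractions must sum to 1 (got {frac_sum!r})"
            )

    @property
    def total_molecules(self) -> int:
        return sum(self.counts)

    @property
    def n_per_leaflet(self) -> int:
        return self.total_molecules // self.n_leaflets

    @property
    def lipid_mass(self) -> float:
        """Σ N_i·MW_i over all species (g·mol⁻¹-weighted count sum)."""
        return sum(
            c * s.molecular_weight for c, s in zip(self.counts, self.species)
        )

    def leaflet_counts(self) -> dict[str, int]:
        """Per-species counts for a single leaflet (floor division)."""
        return {
            s.name: c // self.n_leaflets
            for s, c in zip(self.species, self.counts)
        }

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        molecular_weights: Mapping[str, float],
        n_leaflets: int = 2,
    ) -> "MonolayerComposition":
        """Build from absolute counts; mole fractions are derived exactly."""
        total = sum(counts.values())
        if total == 0:
            raise InputError("composition must contain at least one molecule")
        species = tuple(
            LipidSpecies(name, molecular_weights[name], n / total)
            for name, n in counts.items()
        )
        return cls(species, tuple(int(n) for n in counts.values()), n_leaflets)

    @classmethod
    def from_fractions(
        cls,
        fractions: Mapping[str, float],
        molecular_weights: Mapping[str, float],
        total_molecules: int,
        n_leaflets: int = 2,
    ) -> "MonolayerComposition":
        """Build from mole fractions; counts by largest-remainder rounding."""
        names = list(fractions)
        raw = [fractions[n] * total_molecules for n in names]
        counts = [math.floor(r) for r in raw]
        short = total_molecules - sum(counts)
        order = sorted(
            range(len(names)), key=lambda i: raw[i] - counts[i], reverse=True
        )
        for i in order[:short]:
            counts[i] += 1
        species = tuple(
            LipidSpecies(n, molecular_weights[n], fractions[n]) for n in names
        )
        return cls(species, tuple(counts), n_leaflets)


@dataclass(frozen=True)
class DrugSpec:
    """A drug load: name, molecular weight and either count or % w/w."""

    name: str = "MF"
    molecular_weight: float = MW_MOMETASONE_FUROATE
    count: int = 0
    concentration_ww: float = 0.0

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise InputError("drug molecular weight must be positive")
        if self.count < 0:
            raise InputError("drug count must be non-negative")
        if self.concentration_ww < 0:
            raise InputError("drug concentration must be non-negative")


@dataclass(frozen=True)
class BoxGeometry:
    """Orthorhombic in-plane box: edges in Å and molecules per leaflet."""

    edge_x: float
    edge_y: float
    n_per_leaflet: int

    def __post_init__(self) -> None:
        if self.edge_x <= 0 or self.edge_y <= 0:
            raise InputError("box edges must be positive")
        if self.n_per_leaflet <= 0:
            raise InputError("n_per_leaflet must be positive")

    @property
    def apl(self) -> float:
        return apl_from_box(self)[0]


# ---------------------------------------------------------------------------
# Reference compositions

_MW_DEFAULT = {
    "DPPC": MW_DPPC,
    "POPC": MW_POPC,
    "POPG": MW_POPG_NA,
    "CHOL": MW_CHOL,
}

_REFERENCE_COUNTS = {"DPPC": 1224, "POPC": 408, "POPG": 200, "CHOL": 200}


def lung_surfactant(
    molecular_weights: Mapping[str, float] | None = None,
) -> MonolayerComposition:
    """The 2032-molecule two-leaflet reference system (1016 per leaflet)."""
    mw = dict(_MW_DEFAULT)
    if molecular_weights:
        mw.update(molecular_weights)
    return MonolayerComposition.from_counts(_REFERENCE_COUNTS, mw, n_leaflets=2)


def lung_surfactant_nominal(
    total_molecules: int = 2032,
    n_leaflets: int = 2,
) -> MonolayerComposition:
    """The nominal 60:20:10:10 mol% DPPC:POPC:POPG:CHOL mixture."""
    fractions = {"DPPC": 0.60, "POPC": 0.20, "POPG": 0.10, "CHOL": 0.10}
    return MonolayerComposition.from_fractions(
        fractions, _MW_DEFAULT, total_molecules, n_leaflets
    )


# ---------------------------------------------------------------------------
# Operations


@dataclass(frozen=True)
class MassFractions:
    """Per-species mass percentages, raw and rounded (half-to-even)."""

    raw: dict[str, float]
    rounded: dict[str, int]


def mass_fractions(composition: MonolayerComposition) -> MassFractions:
    """Convert mole fractions to mass percentages.

    The raw percentages sum to 100 exactly (up to float roundoff); the
    rounded column uses round-half-to-even per species and therefore need
    not sum to 100.
    """
    weights = {
        s.name: s.mole_fraction * s.molecular_weight for s in composition.species
    }
    total = sum(weights.values())
    if total <= 0:
        raise InputError("composition has zero total mass")
    raw = {name: 100.0 * w / total for name, w in weights.items()}
    rounded = {name: round(v) for name, v in raw.items()}
    return MassFractions(raw=raw, rounded=rounded)


def concentration_for_count(
    composition: MonolayerComposition,
    drug: DrugSpec,
    count: int | None = None,
) -> float:
    """Drug mass concentration (% w/w) for ``count`` drug molecules."""
    n = drug.count if count is None else count
    if n < 0:
        raise InputError("drug count must be non-negative")
    drug_mass = n * drug.molecular_weight
    return 100.0 * drug_mass / (drug_mass + composition.lipid_mass)


def drug_count_for_concentration(
    composition: MonolayerComposition,
    drug: DrugSpec,
    concentration_ww: float,
) -> int:
    """Integer drug count whose % w/w is closest to the requested one.

    Solves C(n) = 100·n·MW_d/(n·MW_d + M_lip) for real n, then returns
    whichever of floor/ceil minimises |C(n) − target| (ties go to the
    smaller count).
    """
    if not 0.0 <= concentration_ww < 100.0:
        raise InputError(
            f"concentration must lie in [0, 100) % w/w, got {concentration_ww}"
        )
    if concentration_ww == 0.0:
        return 0
    m_lip = composition.lipid_mass
    n_real = (
        concentration_ww * m_lip / (drug.molecular_weight * (100.0 - concentration_ww))
    )
    lo, hi = math.floor(n_real), math.ceil(n_real)
    lo = max(lo, 0)
    if lo == hi:
        return lo
    err_lo = abs(concentration_for_count(composition, drug, lo) - concentration_ww)
    err_hi = abs(concentration_for_count(composition, drug, hi) - concentration_ww)
    return lo if err_lo <= err_hi else hi


def dose_to_molecules(dose_ug: float, drug: DrugSpec | None = None) -> float:
    """Molecule count delivered by a dose in μg: dose·10⁻⁶/MW · N_A."""
    if dose_ug < 0:
        raise InputError("dose must be non-negative")
    mw = (drug or DrugSpec()).molecular_weight
    return dose_ug * 1.0e-6 / mw * AVOGADRO


def apl_from_box(geometry: BoxGeometry) -> tuple[float, int]:
    """(raw, rounded) area per lipid in Å² for a box geometry.

    Rounding is half-to-even, matching how integer APLs are quoted next
    to box edges in simulation set-up tables.
    """
    raw = geometry.edge_x * geometry.edge_y / geometry.n_per_leaflet
    return raw, round(raw)


def box_for_apl(apl: float, n_per_leaflet: int) -> float:
    """Square box edge (Å) producing the given APL for n molecules."""
    if apl <= 0 or n_per_leaflet <= 0:
        raise InputError("apl and n_per_leaflet must be positive")
    return math.sqrt(apl * n_per_leaflet)
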