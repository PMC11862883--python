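"""Analysis configuration: documented defaults, YAML loading, validation.

Every tunable of the analysis commands lives here with a default equal
to the library default, so a config file, a CLI flag and a bare library
call all agree. Unknown keys are rejected rather than ignored — a typo
in a config file must not silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InputError

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Parameters of the analysis stages with their defaults."""

    smooth: int = 11            # Savitzky–Golay window, samples (0 = raw)
    lift_off_threshold: float = 0.5   # mN/m above baseline
    r_max: float = 1.0          # RDF cutoff, nm
    bins: int = 50              # RDF bins
    rdf_mode: str = "3d"        # '3d' | '2d'
    cluster_cutoff: float = 0.6  # nm, single-linkage bead distance
    grid_cell: float = 0.25     # nm, pore occupancy grid
    min_area: float = 1.0       # nm², pore size floor
    bead_radius: float = 0.6    # nm, projected lipid footprint
    n_interfaces: int = 2       # monolayers per simulation box
    seed: int = 0
    output_dir: str = "."
    report_format: str = "json"  # 'json' | 'csv'

    def __post_init__(self) -> None:
        if self.rdf_mode not in ("3d", "2d"):
            raise InputError("rdf_mode must be '3d' or '2d'")
        if self.report_format not in ("json", "csv"):
            raise InputError("report_format must be 'json' or 'csv'")
        for name in ("r_max", "cluster_cutoff", "grid_cell", "min_area",
                     "bead_radius"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.n_interfaces < 1:
            raise InputError("n_interfaces must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config file; unknown keys raise :class:`InputError`."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such config file: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise InputError(
                f"{path}: unknown config keys {unknown}; known keys are "
                f"{sorted(known)}"
            )
        return cls(**data)

    def echo(self) -> dict:
        """The config as a plain dict, for report embedding."""
        return {f.name: getattr(self, f.name) for f in fields(self)}
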