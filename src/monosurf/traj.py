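"""Coarse-grained monolayer trajectory analysis.

Operates on :class:`FrameSet` — a lightweight container of per-frame bead
coordinates (nm) in an orthorhombic box with a residue/bead-name particle
table. Implements the monolayer observables used to characterise drug–
lung-surfactant interaction: second-Legendre (P2) chain order parameters
against the monolayer normal, surface tension from the pressure-tensor
anisotropy, radial distribution functions under the minimum-image
convention, single-linkage drug clustering, occupancy-grid pore
detection, collapse detection from head-group z-spread, axial density
profiles, and mean roughness (Ra) of height profiles.

Distances assume orthorhombic boxes throughout; triclinic input is
rejected at the IO layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, sparse, stats
from scipy.sparse.csgraph import connected_components

from .constants import BAR_NM_TO_MN_PER_M
from .errors import InputError, TopologyError

__all__ = [
    "FrameSet",
    "ChainTopology",
    "DEFAULT_TOPOLOGY",
    "PressureSeries",
    "RDFResult",
    "BondOrder",
    "OrderParameters",
    "SurfaceTension",
    "ClusterResult",
    "PoreResult",
    "CollapseResult",
    "order_parameter",
    "surface_tension",
    "rdf",
    "drug_clusters",
    "detect_pores",
    "detect_collapse_3d",
    "density_profile",
    "roughness_ra",
]

_AXES = {"x": 0, "y": 1, "z": 2}


# ---------------------------------------------------------------------------
# Containers


@dataclass
class FrameSet:
    """Bead coordinates for one or more frames plus the particle table.

    coords: (n_frames, n_particles, 3) nm; box: (n_frames, 3) nm edge
    lengths; resnames/beadnames/resids: per-particle arrays. A generator
    may attach its ground-truth record.
    """

    coords: np.ndarray
    box: np.ndarray
    resnames: np.ndarray
    beadnames: np.ndarray
    resids: np.ndarray
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must have shape (n_frames, n_particles, 3)")
        if self.box.shape != (self.coords.shape[0], 3):
            raise InputError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise InputError("box edges must be positive")
        n = self.coords.shape[1]
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.beadnames = np.asarray(self.beadnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        for arr, what in (
            (self.resnames, "resnames"),
            (self.beadnames, "beadnames"),
            (self.resids, "resids"),
        ):
            if arr.shape != (n,):
                raise InputError(f"{what} must have one entry per particle")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def select(self, expression: str) -> np.ndarray:
        """Particle indices matching a selection expression.

        Grammar: clauses joined by ``and``; each clause is
        ``resname NAME [NAME ...]`` or ``name NAME [NAME ...]`` (bead
        names). Example: ``"resname DPPC and name C1A C2A"``.
        """
        mask = np.ones(self.n_particles, dtype=bool)
        for clause in expression.split(" and "):
            tokens = clause.split()
            if len(tokens) < 2 or tokens[0] not in ("resname", "name"):
                raise InputError(f"cannot parse selection clause {clause!r}")
            values = set(tokens[1:])
            source = self.resnames if tokens[0] == "resname" else self.beadnames
            mask &= np.isin(source, list(values))
        return np.nonzero(mask)[0]


@dataclass(frozen=True)
class ChainTopology:
    """Ordered bead chains per lipid species.

    ``chains[species][chain_name]`` is the ordered bead-name list of one
    acyl chain; consecutive names define the bonds whose orientation is
    measured.
    """

    chains: Mapping[str, Mapping[str, Sequence[str]]]

    def bonds(self, species: str, chain: str) -> list[tuple[str, str]]:
        beads = self.chains[species][chain]
        return list(zip(beads[:-1], beads[1:]))


#: MARTINI-style four-bead chains; the unsaturated oleoyl chain (D2 bead)
#: is carried as sn-1 for POPC/POPG, matching how the per-chain order
#: parameters are reported for this lipid set.
DEFAULT_TOPOLOGY = ChainTopology(
    chains={
        "DPPC": {
            "sn-1": ("C1A", "C2A", "C3A", "C4A"),
            "sn-2": ("C1B", "C2B", "C3B", "C4B"),
        },
        "POPC": {
            "sn-1": ("C1A", "D2A", "C3A", "C4A"),
            "sn-2": ("C1B", "C2B", "C3B", "C4B"),
        },
        "POPG": {
            "sn-1": ("C1A", "D2A", "C3A", "C4A"),
            "sn-2": ("C1B", "C2B", "C3B", "C4B"),
        },
    }
)


@dataclass
class PressureSeries:
    """Diagonal pressure-tensor samples (bar) plus box height (nm)."""

    t: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    lz: np.ndarray
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "pxx", "pyy", "pzz", "lz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arrays[name] = arr
            setattr(self, name, arr)
        n = arrays["t"].size
        if n == 0:
            raise InputError("pressure series must be nonempty")
        for name, arr in arrays.items():
            if arr.shape != (n,):
                raise InputError("all series columns must share one length")
            if not np.all(np.isfinite(arr)):
                raise InputError(f"non-finite values in {name}")
        if np.any(arrays["lz"] <= 0):
            raise InputError("lz must be positive")


@dataclass
class RDFResult:
    """g(r) on bin centers with the raw pair counts used to build it."""

    r: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    mode: str = "3d"


# ---------------------------------------------------------------------------
# Geometry helpers


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _pair_distances(
    coords: np.ndarray,
    box: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    identical: bool,
    lateral: bool = False,
) -> np.ndarray:
    """Minimum-image distances for all A–B pairs of one frame.

    Identical groups yield each unordered pair once (i < j).
    """
    a = coords[idx_a]
    b = coords[idx_b]
    d = a[:, None, :] - b[None, :, :]
    d = _minimum_image(d, box)
    if lateral:
        d = d[..., :2]
    dist = np.sqrt((d**2).sum(axis=-1))
    if identical:
        iu = np.triu_indices(len(idx_a), k=1)
        return dist[iu]
    return dist.ravel()


# ---------------------------------------------------------------------------
# Order parameters


@dataclass(frozen=True)
class BondOrder:
    bond: str  # e.g. "C1A-D2A"
    p2: float
    sd: float  # over frames
    per_frame: tuple[float, ...]


@dataclass
class OrderParameters:
    """P2 per species → chain → bond, with frame-to-frame SD."""

    values: dict[str, dict[str, list[BondOrder]]]

    def all_p2(self) -> np.ndarray:
        return np.array(
            [
                b.p2
                for chains in self.values.values()
                for bonds in chains.values()
                for b in bonds
            ]
        )


def _bond_indices(
    frames: FrameSet, species: str, name_a: str, name_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue index pairs for a named bond of one species."""
    sel_species = frames.resnames == species
    ia = np.nonzero(sel_species & (frames.beadnames == name_a))[0]
    ib = np.nonzero(sel_species & (frames.beadnames == name_b))[0]
    missing = []
    if ia.size == 0:
        missing.append(name_a)
    if ib.size == 0:
        missing.append(name_b)
    if missing:
        raise TopologyError(
            f"species {species!r}: beads not found in particle table: "
            + ", ".join(missing)
        )
    order_a = ia[np.argsort(frames.resids[ia], kind="stable")]
    order_b = ib[np.argsort(frames.resids[ib], kind="stable")]
    if order_a.size != order_b.size or np.any(
        frames.resids[order_a] != frames.resids[order_b]
    ):
        raise TopologyError(
            f"species {species!r}: beads {name_a}/{name_b} do not pair "
            "one-to-one per residue"
        )
    return order_a, order_b


def order_parameter(
    frames: FrameSet,
    topo: ChainTopology = DEFAULT_TOPOLOGY,
    normal: str = "z",
) -> OrderParameters:
    """P2 = (3⟨cos²θ⟩ − 1)/2 per bonded bead pair of each chain.

    θ is the angle between each consecutive-bead bond vector (minimum
    image) and the monolayer normal; ⟨·⟩ averages over molecules within
    a frame, then the per-frame P2 values are averaged over frames (SD
    reported across frames). Species in the topology absent from the
    particle table are skipped; named beads missing for a present
    species raise :class:`TopologyError`.
    """
    ax = _AXES[normal]
    out: dict[str, dict[str, list[BondOrder]]] = {}
    for species, chains in topo.chains.items():
        if not np.any(frames.resnames == species):
            continue
        out[species] = {}
        for chain in chains:
            bonds = []
            for name_a, name_b in topo.bonds(species, chain):
                ia, ib = _bond_indices(frames, species, name_a, name_b)
                v = frames.coords[:, ib, :] - frames.coords[:, ia, :]
                v = _minimum_image(v, frames.box[:, None, :])
                cos2 = v[..., ax] ** 2 / (v**2).sum(axis=-1)
                p2_frames = 1.5 * cos2.mean(axis=1) - 0.5
                bonds.append(
                    BondOrder(
                        bond=f"{name_a}-{name_b}",
                        p2=float(p2_frames.mean()),
                        sd=float(p2_frames.std(ddof=0)),
                        per_frame=tuple(float(x) for x in p2_frames),
                    )
                )
            out[species][chain] = bonds
    if not out:
        raise TopologyError("no topology species present in the particle table")
    return OrderParameters(values=out)


# ---------------------------------------------------------------------------
# Surface tension


@dataclass(frozen=True)
class SurfaceTension:
    gamma: float  # mN·m⁻¹
    error: float  # block-average standard error, mN·m⁻¹
    n_blocks: int


def surface_tension(
    series: PressureSeries, n_interfaces: int = 2, n_blocks: int = 5
) -> SurfaceTension:
    """γ = (Lz/n_interfaces)·⟨Pzz − (Pxx+Pyy)/2⟩ in mN·m⁻¹.

    The per-sample integrand is block-averaged (default 5 blocks) to
    estimate the standard error of the mean in the presence of
    correlated samples.
    """
    if n_interfaces < 1:
        raise InputError("n_interfaces must be at least 1")
    anis = series.pzz - 0.5 * (series.pxx + series.pyy)  # bar
    per_sample = (series.lz / n_interfaces) * anis * BAR_NM_TO_MN_PER_M
    gamma = float(per_sample.mean())
    n_blocks = min(n_blocks, per_sample.size)
    if n_blocks >= 2:
        blocks = np.array_split(per_sample, n_blocks)
        means = np.array([b.mean() for b in blocks])
        err = float(means.std(ddof=1) / np.sqrt(n_blocks))
    else:
        err = float("nan")
    return SurfaceTension(gamma=gamma, error=err, n_blocks=n_blocks)


# ---------------------------------------------------------------------------
# Radial distribution function


def rdf(
    frames: FrameSet,
    group_a: str | np.ndarray,
    group_b: str | np.ndarray,
    r_max: float = 1.0,
    n_bins: int = 50,
    mode: str = "3d",
) -> RDFResult:
    """Distance-histogram g(r) with minimum-image periodicity.

    ``mode='3d'`` uses full 3-D distances normalised by spherical shells
    at the mean box density; ``mode='2d'`` uses lateral (x, y) distances
    normalised by rings at the mean areal density. Identical groups are
    supported (each unordered pair counted once); ``r_max`` must not
    exceed half the smallest participating box edge.
    """
    if mode not in ("3d", "2d"):
        raise InputError("mode must be '3d' or '2d'")
    idx_a = frames.select(group_a) if isinstance(group_a, str) else np.asarray(group_a)
    idx_b = frames.select(group_b) if isinstance(group_b, str) else np.asarray(group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise InputError("rdf groups must be nonempty")
    identical = idx_a.size == idx_b.size and np.array_equal(
        np.sort(idx_a), np.sort(idx_b)
    )
    if not identical and np.intersect1d(idx_a, idx_b).size:
        raise InputError("rdf groups must be disjoint or identical")
    edges_considered = frames.box[:, :2] if mode == "2d" else frames.box
    if r_max > 0.5 * edges_considered.min():
        raise InputError(
            f"r_max {r_max} exceeds half the smallest box edge "
            f"{edges_considered.min()}"
        )
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    ideal = np.zeros(n_bins)
    if identical:
        n_pairs = idx_a.size * (idx_a.size - 1) / 2.0
    else:
        n_pairs = float(idx_a.size * idx_b.size)
    for f in range(frames.n_frames):
        dist = _pair_distances(
            frames.coords[f], frames.box[f], idx_a, idx_b, identical,
            lateral=(mode == "2d"),
        )
        counts += np.histogram(dist, bins=edges)[0]
        if mode == "3d":
            volume = frames.box[f].prod()
            shell = 4.0 / 3.0 * np.pi * np.diff(edges**3)
            ideal += n_pairs * shell / volume
        else:
            area = frames.box[f, 0] * frames.box[f, 1]
            ring = np.pi * np.diff(edges**2)
            ideal += n_pairs * ring / area
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centers, g=g, counts=counts, mode=mode)


# ---------------------------------------------------------------------------
# Drug clustering


@dataclass
class ClusterResult:
    """Single-linkage molecular cluster sizes, one entry per frame."""

    sizes: list[list[int]]  # per frame, descending
    largest_fraction: list[float]

    @property
    def n_molecules(self) -> int:
        return sum(self.sizes[0]) if self.sizes else 0


def drug_clusters(
    frames: FrameSet,
    drug_selection: str | np.ndarray,
    cutoff: float = 0.6,
) -> ClusterResult:
    """Molecular clusters by single-linkage on minimum bead–bead distance.

    Two molecules are linked when any bead pair lies within ``cutoff``
    (nm, minimum image); clusters are the connected components of that
    graph, reported as size lists per frame together with the fraction
    of molecules in the largest cluster.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    idx = (
        frames.select(drug_selection)
        if isinstance(drug_selection, str)
        else np.asarray(drug_selection)
    )
    if idx.size == 0:
        raise InputError("drug selection is empty")
    mol_ids = frames.resids[idx]
    unique_mols = np.unique(mol_ids)
    n_mol = unique_mols.size
    mol_of_bead = np.searchsorted(unique_mols, mol_ids)
    sizes_per_frame: list[list[int]] = []
    largest: list[float] = []
    for f in range(frames.n_frames):
        pos = frames.coords[f, idx]
        d = pos[:, None, :] - pos[None, :, :]
        d = _minimum_image(d, frames.box[f])
        close = (d**2).sum(axis=-1) <= cutoff**2
        adj = np.zeros((n_mol, n_mol), dtype=bool)
        # molecule-level adjacency: any bead pair within cutoff
        np.logical_or.at(adj, (mol_of_bead[:, None], mol_of_bead[None, :]), close)
        np.fill_diagonal(adj, False)
        n_comp, labels = connected_components(
            sparse.csr_matrix(adj), directed=False
        )
        counts = np.bincount(labels, minlength=n_comp)
        sizes = sorted((int(c) for c in counts), reverse=True)
        sizes_per_frame.append(sizes)
        largest.append(sizes[0] / n_mol if n_mol else 0.0)
    return ClusterResult(sizes=sizes_per_frame, largest_fraction=largest)


# ---------------------------------------------------------------------------
# Pore detection


@dataclass
class PoreResult:
    count: int
    areas: list[float]  # nm², descending
    grid_cell: float


def detect_pores(
    frames: FrameSet,
    lipid_selection: str | np.ndarray = "resname DPPC POPC POPG CHOL",
    frame: int = 0,
    grid_cell: float = 0.25,
    min_area: float = 1.0,
    bead_radius: float = 0.6,
) -> PoreResult:
    """Pores as connected empty patches of the projected occupancy grid.

    Lipid beads of one frame are projected onto the x–y plane; grid
    cells whose centers fall within ``bead_radius`` of any bead
    (periodic) are occupied. Connected components of the empty cells
    (4-connectivity, periodic wrap in both directions) with area ≥
    ``min_area`` nm² are reported as pores.

    The default footprint radius (0.6 nm) closes the interstices of an
    intact film at areas per lipid up to ~61 Å², so a defect-free
    monolayer yields zero pores; shrink it (toward the single-bead vdW
    radius ~0.26 nm) for denser bead fields, e.g. finely sampled or
    atomistic projections.
    """
    if grid_cell <= 0:
        raise InputError("grid_cell must be positive")
    idx = (
        frames.select(lipid_selection)
        if isinstance(lipid_selection, str)
        else np.asarray(lipid_selection)
    )
    if idx.size == 0:
        raise InputError("lipid selection is empty")
    lx, ly = frames.box[frame, 0], frames.box[frame, 1]
    nx = max(1, int(round(lx / grid_cell)))
    ny = max(1, int(round(ly / grid_cell)))
    cx = (np.arange(nx) + 0.5) * (lx / nx)
    cy = (np.arange(ny) + 0.5) * (ly / ny)
    xy = frames.coords[frame, idx, :2] % [lx, ly]
    dx = _minimum_image(cx[:, None] - xy[None, :, 0], lx)
    dy = _minimum_image(cy[:, None] - xy[None, :, 1], ly)
    occupied = np.zeros((nx, ny), dtype=bool)
    # occupied where any bead is within bead_radius of the cell center
    r2 = bead_radius**2
    close_x = np.abs(dx) <= bead_radius
    for i in range(nx):
        beads = np.nonzero(close_x[i])[0]
        if beads.size == 0:
            continue
        d2 = dx[i, beads] ** 2 + dy[:, beads] ** 2
        occupied[i] = (d2 <= r2).any(axis=1)
    empty = ~occupied
    labels, n_lab = ndimage.label(empty, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    ))
    if n_lab:
        # merge components touching across the periodic boundaries
        parent = list(range(n_lab + 1))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for a, b in zip(labels[0, :], labels[-1, :]):
            if a and b:
                union(a, b)
        for a, b in zip(labels[:, 0], labels[:, -1]):
            if a and b:
                union(a, b)
        roots = np.array([find(l) for l in range(n_lab + 1)])
        labels = roots[labels]
    cell_area = (lx / nx) * (ly / ny)
    areas = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        area = float(np.count_nonzero(labels == lab) * cell_area)
        if area >= min_area:
            areas.append(area)
    areas.sort(reverse=True)
    return PoreResult(count=len(areas), areas=areas, grid_cell=grid_cell)


# ---------------------------------------------------------------------------
# Collapse detection


@dataclass
class CollapseResult:
    spread: np.ndarray  # interdecile head z-range per frame, nm
    collapsed: np.ndarray  # bool per frame
    bimodality: np.ndarray  # Sarle's coefficient per frame
    threshold: float


def detect_collapse_3d(
    frames: FrameSet,
    head_selection: str = "name PO4",
    spread_threshold: float | None = None,
    baseline_factor: float = 3.0,
    min_threshold: float = 0.5,
) -> CollapseResult:
    """Flag frames whose head-group z-spread indicates film collapse.

    Spread is the interdecile range (q90 − q10) of head-bead z. The
    threshold defaults to ``baseline_factor`` × the first frame's
    spread (a flat-film baseline) with a ``min_threshold`` floor (nm),
    so a near-perfectly flat baseline does not make thermal jitter look
    like collapse; a frame is collapsed when its spread exceeds the
    threshold. Sarle's bimodality coefficient of the z distribution is
    reported per frame as supporting evidence (values toward 1 indicate
    a bimodal, i.e. bilayer-folded, distribution).
    """
    idx = frames.select(head_selection)
    if idx.size == 0:
        raise InputError("head selection is empty")
    z = frames.coords[:, idx, 2]
    q10, q90 = np.quantile(z, [0.1, 0.9], axis=1)
    spread = q90 - q10
    if spread_threshold is None:
        spread_threshold = max(baseline_factor * float(spread[0]), min_threshold)
    n = idx.size
    bimod = np.full(frames.n_frames, np.nan)
    if n > 3:
        varies = z.std(axis=1) > 1e-9
        g1 = np.zeros(frames.n_frames)
        g2 = np.zeros(frames.n_frames)
        if varies.any():
            g1[varies] = stats.skew(z[varies], axis=1)
            g2[varies] = stats.kurtosis(z[varies], axis=1, fisher=True)
        corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
        bimod = np.where(varies, (g1**2 + 1.0) / (g2 + corr), np.nan)
    return CollapseResult(
        spread=spread,
        collapsed=spread > spread_threshold,
        bimodality=np.asarray(bimod, dtype=float),
        threshold=float(spread_threshold),
    )


# ---------------------------------------------------------------------------
# Density profiles and roughness


def density_profile(
    frames: FrameSet,
    selections: Mapping[str, str | np.ndarray],
    axis: str = "z",
    bin_width: float = 0.1,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Number density (nm⁻³) of each selection along one box axis.

    Returns {name: (bin centers, density)} averaged over frames; slab
    volume uses the mean box cross-section.
    """
    if bin_width <= 0:
        raise InputError("bin width must be positive")
    ax = _AXES[axis]
    length = float(frames.box[:, ax].mean())
    others = [i for i in range(3) if i != ax]
    cross = float((frames.box[:, others[0]] * frames.box[:, others[1]]).mean())
    n_bins = max(1, int(round(length / bin_width)))
    edges = np.linspace(0.0, length, n_bins + 1)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, sel in selections.items():
        idx = frames.select(sel) if isinstance(sel, str) else np.asarray(sel)
        if idx.size == 0:
            raise InputError(f"selection {name!r} is empty")
        pos = frames.coords[:, idx, ax].ravel() % length
        hist = np.histogram(pos, bins=edges)[0].astype(float)
        density = hist / (frames.n_frames * cross * (length / n_bins))
        out[name] = (0.5 * (edges[:-1] + edges[1:]), density)
    return out


def roughness_ra(heights: np.ndarray) -> float:
    """Mean roughness Ra = ⟨|z − ⟨z⟩|⟩ of an ordered height profile."""
    z = np.asarray(heights, dtype=float)
    if z.size < 2:
        raise InputError("roughness needs at least 2 samples")
    return float(np.abs(z - z.mean()).mean())
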