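"""Readers and writers for the formats the pipeline consumes and emits.

Delimited tables go through pandas (delimiter sniffed among comma, tab
and whitespace; header optional). GRO/PDB coordinate files go through
mdtraj, which keeps everything in nm internally (PDB Å are converted on
read); XYZ is parsed here with the box carried in a JSON sidecar, since
the format has no box record. Reports are JSON or CSV with a stable key
order, floats at 6 significant digits, and an embedded config echo.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ParseError
from .traj import FrameSet, PressureSeries

__all__ = [
    "read_table",
    "read_pressure_series",
    "read_frames",
    "write_frames",
    "write_report",
]


# ---------------------------------------------------------------------------
# Tables


def read_table(
    path: str | Path, columns: Sequence[str]
) -> pd.DataFrame:
    """Read a delimited numeric table into the named columns.

    The delimiter is auto-detected (comma, tab or whitespace). If the
    first row is non-numeric it is treated as a header and must contain
    the requested column names; otherwise columns are assigned
    positionally. Non-numeric cells raise :class:`ParseError` naming the
    offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: file is empty")
    first = text.lstrip().splitlines()[0]
    delim = None
    if "," in first:
        delim = ","
    elif "\t" in first:
        delim = "\t"

    def _tokens(line: str) -> list[str]:
        return [t for t in (line.split(delim) if delim else line.split())]

    has_header = not all(_is_number(t) for t in _tokens(first))
    try:
        df = pd.read_csv(
            _io.StringIO(text),
            sep=delim if delim else r"\s+",
            header=0 if has_header else None,
            dtype=str,
            skip_blank_lines=True,
        )
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    if has_header:
        df.columns = [str(c).strip() for c in df.columns]
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ParseError(
                f"{path}: missing columns {missing}; found {list(df.columns)}"
            )
        df = df[list(columns)]
    else:
        if df.shape[1] < len(columns):
            raise ParseError(
                f"{path}: expected at least {len(columns)} columns, "
                f"found {df.shape[1]}"
            )
        df = df.iloc[:, : len(columns)]
        df.columns = list(columns)
    out = {}
    for col in columns:
        converted = pd.to_numeric(df[col].str.strip(), errors="coerce")
        bad = converted.index[converted.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + (2 if has_header else 1)  # 1-based file row
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} at "
                f"row {row}, column {col!r}"
            )
        if converted.isna().any():
            row = int(converted.index[converted.isna()][0]) + (2 if has_header else 1)
            raise ParseError(f"{path}: empty cell at row {row}, column {col!r}")
        out[col] = converted.to_numpy(dtype=float)
    return pd.DataFrame(out)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_pressure_series(path: str | Path) -> PressureSeries:
    """Read a (t, Pxx, Pyy, Pzz, Lz) delimited series."""
    df = read_table(path, ["t", "Pxx", "Pyy", "Pzz", "Lz"])
    return PressureSeries(
        t=df["t"].to_numpy(),
        pxx=df["Pxx"].to_numpy(),
        pyy=df["Pyy"].to_numpy(),
        pzz=df["Pzz"].to_numpy(),
        lz=df["Lz"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Coordinate frames


def read_frames(path: str | Path, box_sidecar: str | Path | None = None) -> FrameSet:
    """Read GRO, PDB or XYZ coordinates into a FrameSet (nm internally).

    Multi-frame GRO and multi-model PDB concatenate along the frame
    axis. XYZ needs a JSON sidecar holding at least ``{"box": [lx, ly,
    lz]}`` in nm (XYZ coordinates are taken as nm). Triclinic boxes are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".gro", ".pdb"):
        return _read_mdtraj(path)
    if suffix == ".xyz":
        return _read_xyz(path, box_sidecar)
    raise FormatError(f"unsupported coordinate format: {path.name}")


def _check_gro_structure(path: Path) -> None:
    """Reject truncated GRO files (mdtraj silently drops a partial frame)."""
    lines = path.read_text().splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    i = 0
    while i < len(lines):
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: truncated GRO frame at line {i + 1}")
        try:
            n = int(lines[i + 1].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: bad atom count at line {i + 2}"
            ) from exc
        if i + 2 + n + 1 > len(lines):
            raise FormatError(f"{path}: truncated GRO frame at line {i + 1}")
        i += n + 3


def _read_mdtraj(path: Path) -> FrameSet:
    import mdtraj as md

    if path.suffix.lower() == ".gro":
        _check_gro_structure(path)
    try:
        traj = md.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot read coordinates ({exc})") from exc
    if traj.unitcell_lengths is None:
        raise FormatError(f"{path}: no box information")
    if traj.unitcell_angles is not None and not np.allclose(
        traj.unitcell_angles, 90.0, atol=1e-3
    ):
        raise FormatError(f"{path}: triclinic boxes are not supported")
    atoms = list(traj.topology.atoms)
    return FrameSet(
        coords=np.array(traj.xyz, dtype=float),
        box=np.array(traj.unitcell_lengths, dtype=float),
        resnames=np.array([a.residue.name for a in atoms], dtype=object),
        beadnames=np.array([a.name for a in atoms], dtype=object),
        resids=np.array([a.residue.resSeq for a in atoms], dtype=int),
    )


def _read_xyz(path: Path, box_sidecar: str | Path | None) -> FrameSet:
    if box_sidecar is None:
        box_sidecar = path.with_suffix(".json")
    box_sidecar = Path(box_sidecar)
    if not box_sidecar.exists():
        raise FormatError(
            f"{path}: XYZ input needs a box sidecar (looked for {box_sidecar})"
        )
    meta = json.loads(box_sidecar.read_text())
    box_row = np.asarray(meta["box"], dtype=float)
    lines = path.read_text().splitlines()
    frames = []
    names: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path}: bad atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated frame at line {i + 1}")
        frame_names = []
        coords = np.empty((n, 3))
        for k, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: short row at line {i + 3 + k}")
            frame_names.append(parts[0])
            coords[k] = [float(p) for p in parts[1:4]]
        if names is None:
            names = frame_names
        elif frame_names != names:
            raise FormatError(f"{path}: particle table changes between frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    n_frames = len(frames)
    resnames = meta.get("resnames", ["MOL"] * len(names))
    resids = meta.get("resids", list(range(1, len(names) + 1)))
    return FrameSet(
        coords=np.stack(frames),
        box=np.tile(box_row, (n_frames, 1)),
        resnames=np.array(resnames, dtype=object),
        beadnames=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
    )


def write_frames(frames: FrameSet, path: str | Path) -> None:
    """Write a FrameSet as GRO, PDB or XYZ (+ JSON box sidecar)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gro", ".pdb"):
        _write_mdtraj(frames, path)
    elif suffix == ".xyz":
        _write_xyz(frames, path)
    else:
        raise FormatError(f"unsupported coordinate format: {path.name}")


def _write_mdtraj(frames: FrameSet, path: Path) -> None:
    import mdtraj as md
    from mdtraj.core import element as _elem
    from mdtraj.core.topology import Topology

    top = Topology()
    chain = top.add_chain()
    res = None
    last = None
    for resid, resname, bead in zip(
        frames.resids, frames.resnames, frames.beadnames
    ):
        if last != (resid, resname):
            res = top.add_residue(str(resname), chain, resSeq=int(resid))
            last = (resid, resname)
        top.add_atom(str(bead), _elem.virtual, res)
    angles = np.tile([90.0, 90.0, 90.0], (frames.n_frames, 1))
    traj = md.Trajectory(
        xyz=frames.coords.astype(np.float32),
        topology=top,
        unitcell_lengths=frames.box.astype(np.float32),
        unitcell_angles=angles,
    )
    traj.save(str(path))


def _write_xyz(frames: FrameSet, path: Path) -> None:
    with path.open("w") as fh:
        for f in range(frames.n_frames):
            fh.write(f"{frames.n_particles}\n")
            fh.write(f"frame {f}\n")
            for name, (x, y, z) in zip(frames.beadnames, frames.coords[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
    sidecar = {
        "box": [float(v) for v in frames.box[0]],
        "resnames": [str(r) for r in frames.resnames],
        "resids": [int(r) for r in frames.resids],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


# ---------------------------------------------------------------------------
# Reports


def _round_floats(obj: Any) -> Any:
    """Recursively coerce floats to 6 significant digits."""
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, Mapping):
        return {str(k): _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_report(
    results: Mapping[str, Any],
    path: str | Path,
    fmt: str = "json",
    config: Mapping[str, Any] | None = None,
) -> None:
    """Write an analysis report with config echo and package version.

    JSON keeps nesting; CSV flattens keys with '.'-joined paths. Key
    order is insertion order (stable across runs), floats are rendered
    at 6 significant digits, so identical inputs give byte-identical
    reports.
    """
    from . import __version__

    path = Path(path)
    payload = {
        "version": __version__,
        "config": _round_floats(dict(config or {})),
        "results": _round_floats(dict(results)),
    }
    try:
        if fmt == "json":
            path.write_text(json.dumps(payload, indent=2) + "\n")
        elif fmt == "csv":
            rows: list[tuple[str, Any]] = []

            def _flatten(prefix: str, obj: Any) -> None:
                if isinstance(obj, Mapping):
                    for k, v in obj.items():
                        _flatten(f"{prefix}.{k}" if prefix else str(k), v)
                elif isinstance(obj, (list, tuple)):
                    rows.append((prefix, ";".join(str(v) for v in obj)))
                else:
                    rows.append((prefix, obj))

            _flatten("", payload)
            with path.open("w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["key", "value"])
                writer.writerows(rows)
        else:
            raise InputError(f"unknown report format {fmt!r}")
    except OSError as exc:
        raise FormatError(f"cannot write report to {path}: {exc}") from exc
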