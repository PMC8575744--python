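"""Trajectory data model, GRO/PDB multi-frame I/O and periodic geometry primitives.

Internal units are Angstrom and picosecond everywhere.  GRO files carry
nanometres and are converted on read/write; PDB files are already in
Angstrom.  Boxes are orthorhombic; triclinic input is rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "TrajectoryError",
    "MalformedTrajectoryError",
    "UndefinedDihedralError",
    "read_trajectory",
    "write_trajectory",
    "min_image_displacement",
    "min_image_distance",
    "dihedral",
    "center_of_mass",
    "guess_element",
    "guess_mass",
]


class TrajectoryError(ValueError):
    """Base error for trajectory I/O and validation problems."""


class MalformedTrajectoryError(TrajectoryError):
    """Frames disagree on atom count/ordering, or a record cannot be parsed."""


class UndefinedDihedralError(ValueError):
    """Raised when the central bond of a dihedral is degenerate (collinear)."""


# Standard atomic masses (amu) for the elements occurring in lipid/water/
# carotenoid systems.  Pseudo-atoms from the synthetic generator map onto
# these through their element letter.
_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}


def guess_element(name: str) -> str:
    """Guess the element from an atom name (leading letter after digits)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot guess element from atom name {name!r}")
    return stripped[0].upper()


def guess_mass(element: str) -> float:
    return _MASSES.get(element.upper(), 12.011)


@dataclass(frozen=True)
class Atom:
    """One atom of the (frame-invariant) topology.

    index is 0-based and unique; mass is in amu and strictly positive.
    """

    index: int
    name: str
    residue_name: str
    residue_id: int
    element: str = ""
    mass: float = 0.0

    def __post_init__(self):
        element = self.element or guess_element(self.name)
        mass = self.mass if self.mass > 0 else guess_mass(element)
        object.__setattr__(self, "element", element)
        object.__setattr__(self, "mass", mass)
        if self.mass <= 0:
            raise ValueError(f"atom {self.name!r}: mass must be positive")


@dataclass
class Frame:
    """Coordinates (N, 3) in Angstrom, orthorhombic box lengths, time in ps."""

    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise MalformedTrajectoryError("coords must have shape (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise MalformedTrajectoryError("box must be 3 positive lengths")


class Trajectory:
    """An ordered stack of frames sharing one topology.

    Frame times must be strictly increasing.  Coordinates can also be
    accessed as one (n_frames, n_atoms, 3) array through ``coords``.
    """

    def __init__(self, topology: Sequence[Atom], frames: Sequence[Frame]):
        self.topology = list(topology)
        self.frames = list(frames)
        if not self.frames:
            raise TrajectoryError("trajectory must contain at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise MalformedTrajectoryError(
                    f"frame {i} has {fr.coords.shape[0]} atoms, topology has {n}"
                )
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise TrajectoryError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array (built lazily, cached)."""
        cache = getattr(self, "_coords_cache", None)
        if cache is None:
            cache = np.stack([fr.coords for fr in self.frames])
            self._coords_cache = cache
        return cache

    @property
    def dt(self) -> float:
        """Uniform frame spacing in ps (validates uniformity to 1e-6 ps)."""
        t = self.times
        if len(t) < 2:
            return 1.0
        steps = np.diff(t)
        if np.ptp(steps) > 1e-6:
            raise TrajectoryError("frame spacing is not uniform")
        return float(steps[0])

    def atom_indices(self, predicate) -> np.ndarray:
        return np.array([a.index for a in self.topology if predicate(a)], dtype=int)

    def __repr__(self):
        return f"Trajectory({self.n_atoms} atoms, {self.n_frames} frames)"


# --------------------------------------------------------------------------
# GRO / PDB multi-frame I/O
# --------------------------------------------------------------------------

_NM_TO_A = 10.0
_GRO_TIME_RE = re.compile(r"t=\s*([-\d.eE+]+)")


def _read_gro(path: Path) -> Trajectory:
    lines = path.read_text().splitlines()
    topology: list[Atom] | None = None
    frames: list[Frame] = []
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise MalformedTrajectoryError(
                f"{path}: bad atom-count line at line {i + 2}"
            ) from exc
        if i + 2 + natoms > len(lines) - 1:
            raise MalformedTrajectoryError(f"{path}: truncated frame {frame_idx}")
        atom_rows = lines[i + 2 : i + 2 + natoms]
        box_line = lines[i + 2 + natoms]
        box_vals = [float(x) for x in box_line.split()]
        if len(box_vals) > 3 and any(abs(v) > 1e-12 for v in box_vals[3:]):
            raise TrajectoryError(f"{path}: triclinic boxes are not supported")
        box = np.array(box_vals[:3]) * _NM_TO_A
        coords = np.empty((natoms, 3))
        atoms: list[Atom] = []
        for j, row in enumerate(atom_rows):
            try:
                resid = int(row[0:5])
                resname = row[5:10].strip()
                name = row[10:15].strip()
                coords[j] = (float(row[20:28]), float(row[28:36]), float(row[36:44]))
            except (ValueError, IndexError) as exc:
                raise MalformedTrajectoryError(
                    f"{path}: unparseable atom record in frame {frame_idx}: {row!r}"
                ) from exc
            if topology is None:
                atoms.append(Atom(index=j, name=name, residue_name=resname, residue_id=resid))
        coords *= _NM_TO_A
        if topology is None:
            topology = atoms
        elif natoms != len(topology):
            raise MalformedTrajectoryError(
                f"{path}: frame {frame_idx} has {natoms} atoms, expected {len(topology)}"
            )
        m = _GRO_TIME_RE.search(title)
        time = float(m.group(1)) if m else float(frame_idx)
        frames.append(Frame(coords=coords, box=box, time=time))
        i += 2 + natoms + 1
        frame_idx += 1
    if topology is None:
        raise MalformedTrajectoryError(f"{path}: no frames found")
    return Trajectory(topology, frames)


def _read_pdb(path: Path) -> Trajectory:
    topology: list[Atom] | None = None
    frames: list[Frame] = []
    box = None
    cur_coords: list[tuple[float, float, float]] = []
    cur_atoms: list[Atom] = []
    in_model = False
    saw_model = False

    def close_frame():
        nonlocal topology, cur_coords, cur_atoms
        if not cur_coords:
            return
        if box is None:
            raise MalformedTrajectoryError(f"{path}: missing CRYST1 record")
        if topology is None:
            topology = list(cur_atoms)
        elif len(cur_coords) != len(topology):
            raise MalformedTrajectoryError(
                f"{path}: frame {len(frames)} has {len(cur_coords)} atoms, "
                f"expected {len(topology)}"
            )
        frames.append(
            Frame(coords=np.array(cur_coords), box=box.copy(), time=float(len(frames)))
        )
        cur_coords = []
        cur_atoms = []

    for line in path.read_text().splitlines():
        rec = line[:6]
        if rec == "CRYST1":
            a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
            alpha, beta, gamma = float(line[33:40]), float(line[40:47]), float(line[47:54])
            if any(abs(ang - 90.0) > 1e-3 for ang in (alpha, beta, gamma)):
                raise TrajectoryError(f"{path}: triclinic boxes are not supported")
            box = np.array([a, b, c])
        elif rec == "MODEL ":
            saw_model = True
            in_model = True
        elif rec == "ENDMDL":
            close_frame()
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            name = line[12:16].strip()
            resname = line[17:21].strip()
            resid = int(line[22:26])
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            if topology is None and not frames:
                cur_atoms.append(
                    Atom(index=len(cur_coords), name=name, residue_name=resname,
                         residue_id=resid)
                )
            cur_coords.append((x, y, z))
    close_frame()
    if not frames:
        raise MalformedTrajectoryError(f"{path}: no ATOM records found")
    del saw_model, in_model
    return Trajectory(topology, frames)


def read_trajectory(path, format: str | None = None) -> Trajectory:
    """Read a multi-frame GRO or PDB file into a :class:`Trajectory`.

    GRO coordinates (nm) are converted to Angstrom.  Frame times default to
    ``index * 1 ps`` when the format carries no time stamp (GRO titles with
    ``t=`` are honoured).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gro":
        return _read_gro(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unknown trajectory format {fmt!r} (expected 'gro' or 'pdb')")


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-frame GRO (nm, 0.001 precision) or PDB."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gro":
        _write_gro(traj, path)
    elif fmt == "pdb":
        _write_pdb(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r} (expected 'gro' or 'pdb')")


def _write_gro(traj: Trajectory, path: Path) -> None:
    out = []
    for fr in traj.frames:
        out.append(f"xanmem trajectory, t= {fr.time:.3f}")
        out.append(f"{traj.n_atoms:5d}")
        nm = fr.coords / _NM_TO_A
        for atom, (x, y, z) in zip(traj.topology, nm):
            out.append(
                f"{atom.residue_id % 100000:5d}{atom.residue_name:<5.5s}"
                f"{atom.name:>5.5s}{(atom.index + 1) % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        bx, by, bz = fr.box / _NM_TO_A
        out.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    path.write_text("\n".join(out) + "\n")


def _write_pdb(traj: Trajectory, path: Path) -> None:
    out = []
    bx, by, bz = traj.frames[0].box
    out.append(
        f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    )
    for imod, fr in enumerate(traj.frames, start=1):
        out.append(f"MODEL     {imod:4d}")
        for atom, (x, y, z) in zip(traj.topology, fr.coords):
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3.3s}"
            out.append(
                f"ATOM  {(atom.index + 1) % 100000:5d} {name:<4.4s} "
                f"{atom.residue_name:<4.4s}{atom.residue_id % 10000:5d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element:>2.2s}"
            )
        out.append("ENDMDL")
    out.append("END")
    path.write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# Periodic geometry primitives
# --------------------------------------------------------------------------


def min_image_displacement(a, b, box) -> np.ndarray:
    """Minimum-image displacement vector(s) a - b in an orthorhombic box.

    Broadcasts over leading dimensions of ``a`` and ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = a - b
    return d - box * np.round(d / box)


def min_image_distance(a, b, box) -> float | np.ndarray:
    """Minimum-image distance under orthorhombic periodic boundaries."""
    d = min_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, IUPAC convention: cis = 0, trans = 180.

    Range (-180, 180].  Raises :class:`UndefinedDihedralError` when either
    bonded triple is collinear (the torsion is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    scale = max(
        float(np.max(np.linalg.norm(b1, axis=-1) * b2n)),
        float(np.max(b2n * np.linalg.norm(b3, axis=-1))),
        1e-300,
    )
    if np.min(np.linalg.norm(n1, axis=-1)) < 1e-9 * scale or np.min(
        np.linalg.norm(n2, axis=-1)
    ) < 1e-9 * scale:
        raise UndefinedDihedralError("collinear atoms: dihedral undefined")
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * (b2 / b2n[..., None] if b2.ndim > 1 else b2 / b2n),
               axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> 180 so the range is (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return float(ang) if np.ndim(ang) == 0 else ang


def dihedral_series(coords: np.ndarray, idx: Sequence[int]) -> np.ndarray:
    """Dihedral of atoms ``idx`` (length 4) for every frame of a coords stack."""
    i, j, k, l = idx
    return dihedral(coords[:, i], coords[:, j], coords[:, k], coords[:, l])


def center_of_mass(
    traj_or_frame, selection: Iterable[int], masses: np.ndarray | None = None
) -> np.ndarray:
    """Mass-weighted mean coordinate of ``selection``.

    Accepts a :class:`Trajectory` (returns (n_frames, 3)) or a single
    :class:`Frame` with explicit ``masses`` for the whole topology.
    Coordinates are used as stored — molecules are assumed whole (no
    unwrapping across the box).
    """
    sel = np.asarray(list(selection), dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    if isinstance(traj_or_frame, Trajectory):
        m = np.array([traj_or_frame.topology[i].mass for i in sel])
        xyz = traj_or_frame.coords[:, sel]
        return (xyz * m[None, :, None]).sum(axis=1) / m.sum()
    frame = traj_or_frame
    if masses is None:
        raise ValueError("masses required when passing a bare Frame")
    m = np.asarray(masses, dtype=float)[sel]
    return (frame.coords[sel] * m[:, None]).sum(axis=0) / m.sum()
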