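"""Reading and writing MD trajectory frames (DL_POLY-style HISTORY dialect and XYZ).

The in-memory model is deliberately small: a :class:`Trajectory` is an ordered
sequence of :class:`Frame` objects, each carrying a periodic :class:`Cell` and a
list of :class:`AtomRecord`.  Molecule membership is not stored in either text
format; it is assigned on read as contiguous index blocks of a configured
``molecule_size`` (the layout produced by duplicating a template molecule).

Positions are in Angstrom, times in picoseconds throughout; no unit conversion
is performed.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

from .errors import GeometryError, ParseError, StructuralError

__all__ = [
    "AtomRecord",
    "Cell",
    "Frame",
    "Trajectory",
    "read_history",
    "iter_history",
    "write_history",
    "read_xyz",
    "write_xyz",
]

_PERIODIC_FLAGS = ("none", "cubic", "orthorhombic", "parallelepiped")


@dataclass(frozen=True)
class AtomRecord:
    """One atom in one frame: a verbatim label plus coordinates."""

    label: str
    global_index: int
    molecule_id: int
    position: np.ndarray
    mass: float = 0.0
    charge: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructuralError(
                f"atom {self.global_index}: position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class Cell:
    """Simulation cell: rows of ``matrix`` are the lattice vectors (Angstrom)."""

    matrix: np.ndarray
    periodic_flag: str = "parallelepiped"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise GeometryError("cell matrix must be 3x3")
        object.__setattr__(self, "matrix", m)
        if self.periodic_flag not in _PERIODIC_FLAGS:
            raise GeometryError(f"unknown periodic flag {self.periodic_flag!r}")
        if self.periodic_flag != "none" and self.volume <= 0.0:
            raise GeometryError("periodic cell must have positive volume")
        if self.periodic_flag == "cubic":
            diag = np.diag(m)
            if not (np.allclose(m, np.diag(diag)) and np.allclose(diag, diag[0])):
                raise GeometryError("cubic flag requires an equal-diagonal matrix")

    @classmethod
    def cubic(cls, length: float) -> "Cell":
        return cls(np.eye(3) * float(length), "cubic")

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "Cell":
        """Classify a 3x3 matrix as cubic / orthorhombic / parallelepiped."""
        m = np.asarray(matrix, dtype=float)
        diag = np.diag(m)
        if np.allclose(m, np.diag(diag)):
            if np.allclose(diag, diag[0]):
                return cls(m, "cubic")
            return cls(m, "orthorhombic")
        return cls(m, "parallelepiped")

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.matrix)))

    def min_width(self) -> float:
        """Smallest perpendicular width: V / max cross-sectional face area."""
        m = self.matrix
        v = self.volume
        if v <= 0.0:
            raise GeometryError("degenerate cell")
        widths = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            widths.append(v / np.linalg.norm(np.cross(m[j], m[k])))
        return float(min(widths))

    @property
    def periodic(self) -> bool:
        return self.periodic_flag != "none"


@dataclass
class Frame:
    step: int
    time: float
    cell: Cell
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class Trajectory:
    frames: list[Frame]
    source: str = ""

    def __post_init__(self):
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise StructuralError("frame times must be strictly increasing")
        counts = {f.n_atoms for f in self.frames}
        if len(counts) > 1:
            raise StructuralError(f"inconsistent atom counts across frames: {counts}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)


# ---------------------------------------------------------------------------
# HISTORY dialect
# ---------------------------------------------------------------------------

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _floats(tokens: Sequence[str], lineno: int, what: str) -> list[float]:
    out = []
    for tok in tokens:
        try:
            out.append(float(tok))
        except ValueError:
            raise ParseError(f"non-numeric {what} {tok!r}", lineno) from None
    return out


def _molecule_id(index_1based: int, molecule_size: int) -> int:
    return (index_1based - 1) // molecule_size


def iter_history(path: str | Path, molecule_size: int) -> Iterator[Frame]:
    """Stream frames from a HISTORY-dialect file (plain text or gzip).

    Layout: a title line; a header line of 2-5 integers
    ``levcfg imcon natms [nframes [nrecords]]``; then per frame a
    ``timestep`` record, three cell rows, and per atom a label line followed
    by a position line (velocity/force lines skipped according to levcfg).
    """
    if molecule_size < 1:
        raise ValueError("molecule_size must be a positive integer")
    with _open_text(path) as fh:
        lineno = 0

        def nextline(required: bool = True) -> str | None:
            nonlocal lineno
            while True:
                line = fh.readline()
                if not line:
                    if required:
                        raise StructuralError(
                            f"{path}: unexpected end of file at line {lineno}"
                        )
                    return None
                lineno += 1
                if line.strip():
                    return line
                # blank lines are tolerated only between records

        nextline()  # title, arbitrary
        header = nextline()
        tokens = header.split()
        if not 2 <= len(tokens) <= 5:
            raise ParseError("header must carry 2-5 integers", lineno)
        try:
            ints = [int(t) for t in tokens]
        except ValueError:
            raise ParseError(f"non-integer header field in {header.strip()!r}", lineno)
        levcfg_hdr, imcon_hdr = ints[0], ints[1]
        natms_hdr = ints[2] if len(ints) >= 3 else None

        while True:
            line = nextline(required=False)
            if line is None:
                return
            parts = line.split()
            if parts[0].lower() != "timestep" or len(parts) < 7:
                raise ParseError(
                    f"expected 'timestep' record, got {line.strip()!r}", lineno
                )
            try:
                step = int(parts[1])
                natms = int(parts[2])
                levcfg = int(parts[3])
                imcon = int(parts[4])
            except ValueError:
                raise ParseError("malformed timestep record", lineno) from None
            _floats(parts[5:7], lineno, "timestep field")
            time = float(parts[6])
            if imcon not in (1, 2, 3):
                raise ParseError(f"unsupported imcon {imcon} (accepted: 1-3)", lineno)
            if levcfg not in (0, 1, 2):
                raise ParseError(f"unsupported levcfg {levcfg}", lineno)
            if natms_hdr is not None and natms != natms_hdr:
                raise StructuralError(
                    f"line {lineno}: frame atom count {natms} != header {natms_hdr}"
                )

            rows = []
            for _ in range(3):
                cl = nextline()
                vals = cl.split()
                if len(vals) != 3:
                    raise ParseError("cell row must carry exactly 3 numbers", lineno)
                rows.append(_floats(vals, lineno, "cell component"))
            cell = Cell.from_matrix(np.array(rows))

            atoms = []
            for i in range(natms):
                al = nextline()
                atoks = al.split()
                if len(atoks) < 2:
                    raise ParseError(f"malformed atom record {al.strip()!r}", lineno)
                label = atoks[0]
                try:
                    index = int(atoks[1])
                except ValueError:
                    raise ParseError(
                        f"non-integer atom index {atoks[1]!r}", lineno
                    ) from None
                mass = charge = 0.0
                if len(atoks) >= 3:
                    mass = _floats(atoks[2:3], lineno, "mass")[0]
                if len(atoks) >= 4:
                    charge = _floats(atoks[3:4], lineno, "charge")[0]
                pl = nextline()
                ptoks = pl.split()
                if len(ptoks) < 3:
                    raise ParseError("position line must carry 3 coordinates", lineno)
                pos = _floats(ptoks[:3], lineno, "coordinate")
                for _ in range(levcfg):  # velocity then force lines
                    nextline()
                atoms.append(
                    AtomRecord(
                        label=label,
                        global_index=index,
                        molecule_id=_molecule_id(index, molecule_size),
                        position=np.array(pos),
                        mass=mass,
                        charge=charge,
                    )
                )
            yield Frame(step=step, time=time, cell=cell, atoms=atoms)


def read_history(path: str | Path, molecule_size: int) -> Trajectory:
    """Read a whole HISTORY-dialect file into memory."""
    frames = list(iter_history(path, molecule_size))
    if not frames:
        raise StructuralError(f"{path}: no frames found")
    return Trajectory(frames=frames, source=str(path))


_IMCON_FOR_FLAG = {"cubic": 1, "orthorhombic": 2, "parallelepiped": 3}


def write_history(traj: Trajectory | Iterable[Frame], path: str | Path,
                  title: str = "generated trajectory") -> None:
    """Write frames in the dialect accepted by :func:`read_history` (levcfg=0)."""
    frames = list(traj)
    if not frames:
        raise StructuralError("cannot write an empty trajectory")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        first = frames[0]
        imcon = _IMCON_FOR_FLAG.get(first.cell.periodic_flag, 3)
        fh.write(f"{title}\n")
        fh.write(f"0 {imcon} {first.n_atoms} {len(frames)}\n")
        prev_time = None
        for fr in frames:
            dt = 0.0 if prev_time is None else fr.time - prev_time
            prev_time = fr.time
            imcon = _IMCON_FOR_FLAG.get(fr.cell.periodic_flag, 3)
            fh.write(
                f"timestep {fr.step} {fr.n_atoms} 0 {imcon} {dt:.6g} {fr.time:.10g}\n"
            )
            for row in fr.cell.matrix:
                fh.write(f"{row[0]:.10g} {row[1]:.10g} {row[2]:.10g}\n")
            for a in fr.atoms:
                fh.write(f"{a.label} {a.global_index} {a.mass:.10g} {a.charge:.10g}\n")
                p = a.position
                fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"time[\s=:]+([-+0-9.eE]+)", re.IGNORECASE)
_STEP_RE = re.compile(r"step[\s=:]+([-+0-9]+)", re.IGNORECASE)


def read_xyz(path: str | Path, cell: Cell, molecule_size: int) -> Trajectory:
    """Read multi-frame XYZ; the periodic cell is supplied externally.

    The frame time is taken from a ``time = <t>`` token on the comment line
    when present (or a bare number as the whole comment), else the frame index.
    """
    if molecule_size < 1:
        raise ValueError("molecule_size must be a positive integer")
    frames: list[Frame] = []
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        lineno = i + 1
        try:
            natms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"expected atom count, got {lines[i]!r}", lineno)
        if i + 1 >= len(lines):
            raise StructuralError(f"line {lineno}: truncated XYZ frame")
        comment = lines[i + 1]
        time = float(len(frames))
        step = len(frames)
        m = _TIME_RE.search(comment)
        if m:
            time = float(m.group(1))
        else:
            try:
                time = float(comment.strip())
            except ValueError:
                pass
        ms = _STEP_RE.search(comment)
        if ms:
            step = int(ms.group(1))
        body = lines[i + 2 : i + 2 + natms]
        if len(body) < natms:
            raise StructuralError(
                f"line {lineno}: count line promises {natms} atoms, "
                f"found {len(body)}"
            )
        atoms = []
        for k, rec in enumerate(body):
            toks = rec.split()
            if len(toks) < 4:
                raise StructuralError(
                    f"line {lineno + 2 + k}: count line inconsistent with records"
                )
            pos = _floats(toks[1:4], lineno + 2 + k, "coordinate")
            idx = k + 1
            atoms.append(
                AtomRecord(
                    label=toks[0],
                    global_index=idx,
                    molecule_id=_molecule_id(idx, molecule_size),
                    position=np.array(pos),
                )
            )
        frames.append(Frame(step=step, time=time, cell=cell, atoms=atoms))
        i += 2 + natms
    if not frames:
        raise StructuralError(f"{path}: empty XYZ file")
    return Trajectory(frames=frames, source=str(path))


def write_xyz(traj: Trajectory | Iterable[Frame], path: str | Path) -> None:
    frames = list(traj)
    if not frames:
        raise StructuralError("cannot write an empty trajectory")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"step = {fr.step}, time = {fr.time:.10g} ps\n")
            for a in fr.atoms:
                p = a.position
                fh.write(f"{a.label} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
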