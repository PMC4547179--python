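"""Multi-pose PDB input/output and trajectory selection.

A "pose" is one complete conformation of the molecule at a single time point:
one MODEL block of a multi-model PDB file, as written by MD snapshot dumps or
conformational-morph servers.  Every pose must carry the identical ordered atom
roster so that an atom's positions can be gathered across poses into a pathline
control-point set.

Parsing is fixed-column per the PDB format specification (ATOM/HETATM records,
coordinates in columns 31-54 at 0.001 A precision, poses delimited by
MODEL/ENDMDL).  MODEL serial numbers are ignored for ordering — pose order is
block order in the file, which is robust to renumbered trajectory dumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "MultiPoseStructure",
    "Trajectory",
    "PDBParseError",
    "StructuralInconsistencyError",
    "EmptySelectionError",
    "read_multipose_pdb",
    "write_multipose_pdb",
    "select_atoms",
    "subset_poses",
]


class PDBParseError(ValueError):
    """A record field could not be parsed; the message carries the line number."""


class StructuralInconsistencyError(ValueError):
    """Atom rosters differ between models; the message names the offending model."""


class EmptySelectionError(ValueError):
    """An atom selection matched nothing."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record of a single pose.

    ``serial`` and ``resseq`` keep the file's author numbering; machine indices
    into rosters and arrays are 0-based elsewhere.  ``icode`` (insertion code)
    is part of the atom identity used for cross-model roster matching.
    """

    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    coords: tuple[float, float, float]
    icode: str = ""
    element: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("atom name must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def identity(self) -> tuple[str, str, str, int, str]:
        """Roster-matching key: (name, resname, chain, resseq, icode)."""
        return (self.name, self.resname, self.chain, self.resseq, self.icode)


@dataclass
class MultiPoseStructure:
    """A time-ordered series of poses sharing one atom roster."""

    poses: list[list[AtomRecord]]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("a structure needs at least one pose")
        roster = [a.identity for a in self.poses[0]]
        for m, pose in enumerate(self.poses[1:], start=2):
            if [a.identity for a in pose] != roster:
                raise StructuralInconsistencyError(
                    f"model {m} atom roster differs from model 1 "
                    f"({len(pose)} vs {len(roster)} atoms or mismatched identities)"
                )

    @property
    def n_poses(self) -> int:
        return len(self.poses)

    @property
    def n_atoms(self) -> int:
        return len(self.poses[0])


@dataclass
class Trajectory:
    """Selected atoms x poses x xyz (Angstrom), plus the atom metadata.

    ``positions`` has shape (K, M, 3): K atoms, M poses.  M >= 2 is required to
    fit pathlines; M == 1 is permitted for structure-only scenes.
    """

    atom_meta: list[AtomRecord]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (K, M, 3)")
        if self.positions.shape[0] != len(self.atom_meta):
            raise ValueError("atom_meta length does not match positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def n_poses(self) -> int:
        return self.positions.shape[1]


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    # PDB fixed columns (1-based): serial 7-11, name 13-16, altLoc 17,
    # resName 18-20, chainID 22, resSeq 23-26, iCode 27, x/y/z 31-38/39-46/47-54.
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # serial overflow markers ('*****') are tolerated
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: unparseable coordinate field: {line.rstrip()!r}"
        ) from exc
    return AtomRecord(
        serial=serial,
        name=line[12:16].strip(),
        resname=line[17:20].strip(),
        chain=line[21:22].strip() or " ",
        resseq=int(line[22:26]),
        coords=(x, y, z),
        icode=line[26:27].strip(),
        element=line[76:78].strip() if len(line) >= 78 else "",
        hetero=line.startswith("HETATM"),
    )


def read_multipose_pdb(path, include_hetatm: bool = False) -> MultiPoseStructure:
    """Read a (possibly multi-MODEL) PDB file into a pose series.

    Poses are MODEL blocks in file order; a file without MODEL records yields
    exactly one pose.  Alternate locations other than blank or 'A' are dropped
    so the roster is deterministic across models.  HETATM records are skipped
    unless ``include_hetatm`` is set.

    Raises
    ------
    StructuralInconsistencyError
        If any model's atom roster differs from the first model's.
    PDBParseError
        If a coordinate field cannot be parsed (message carries the line number).
    """
    poses: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    saw_model = False
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                poses.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if atom.hetero and not include_hetatm:
                    continue
                altloc = line[16:17]
                if altloc not in (" ", "A"):
                    continue
                current.append(atom)
    if saw_model:
        if current:  # MODEL without closing ENDMDL
            poses.append(current)
    else:
        poses = [current]
    poses = [p for p in poses if p] or [[]]
    if not poses[0]:
        raise PDBParseError(f"no ATOM records found in {path}")
    return MultiPoseStructure(poses=poses, source_label=str(path))


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def _format_atom_line(a: AtomRecord, serial: int) -> str:
    name = a.name
    # Standard PDB name justification: 1-2 char element names start in col 14.
    if len(name) < 4 and not name[:1].isdigit():
        name = " " + name
    record = "HETATM" if a.hetero else "ATOM  "
    return (
        f"{record}{serial:5d} {name:<4s} {a.resname:>3s} {a.chain:1s}"
        f"{a.resseq:4d}{a.icode:1s}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
    )


def write_multipose_pdb(structure: MultiPoseStructure, path) -> None:
    """Write a pose series as a fixed-column PDB file.

    Multi-pose structures are wrapped in MODEL/ENDMDL blocks; a single-pose
    structure is written bare, matching the common single-structure convention.
    Coordinates round-trip through :func:`read_multipose_pdb` to 3 decimals.
    """
    multi = structure.n_poses > 1
    with open(path, "w") as fh:
        for m, pose in enumerate(structure.poses, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i, atom in enumerate(pose, start=1):
                fh.write(_format_atom_line(atom, i))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# Selection
# --------------------------------------------------------------------------

def select_atoms(
    structure: MultiPoseStructure,
    name_filter: Optional[Iterable[str]] = None,
    stride: int = 1,
    index_range: Optional[tuple[int, int]] = None,
) -> Trajectory:
    """Select atoms for pathline construction and gather positions across poses.

    Filtering order: by atom name (default {"CA"}, the alpha-carbon trace),
    then by half-open ``index_range`` over the name-filtered list, then every
    ``stride``-th atom (the first atom in range is always retained).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    names = {"CA"} if name_filter is None else {n.strip() for n in name_filter}
    roster = structure.poses[0]
    picked = [i for i, a in enumerate(roster) if a.name in names]
    if index_range is not None:
        lo, hi = index_range
        picked = picked[lo:hi]
    picked = picked[::stride]
    if not picked:
        raise EmptySelectionError(
            f"selection matched no atoms (names={sorted(names)}, "
            f"range={index_range}, stride={stride})"
        )
    meta = [roster[i] for i in picked]
    positions = np.empty((len(picked), structure.n_poses, 3), dtype=float)
    for m, pose in enumerate(structure.poses):
        for k, i in enumerate(picked):
            positions[k, m] = pose[i].coords
    return Trajectory(atom_meta=meta, positions=positions)


def subset_poses(traj: Trajectory, start: int, end: int, stride: int = 1) -> Trajectory:
    """Restrict a trajectory to poses start, start+stride, ... <= end (inclusive).

    The output pose count is floor((end-start)/stride) + 1.  Atom metadata is
    unchanged.
    """
    M = traj.n_poses
    if not (0 <= start <= end < M):
        raise IndexError(f"pose range [{start}, {end}] out of bounds for M={M}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = np.arange(start, end + 1, stride)
    return Trajectory(atom_meta=list(traj.atom_meta), positions=traj.positions[:, idx, :])
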