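"""Structure/trajectory I/O and atom selection.

Reads and writes the two formats the analysis pipeline touches — fixed-column
PDB (with multi-model support as a trajectory fallback) and CHARMM/NAMD binary
DCD — and resolves named residue-range regions to atom index lists.

Residue numbers are taken verbatim from the file (author numbering, 1-based);
region ranges are inclusive on both ends, matching the "residues a to b"
convention used when describing protein segments.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from obpdyn.errors import (
    EmptySelectionError,
    EmptyStructureError,
    PartialFileError,
    PDBParseError,
    TopologyMismatchError,
)

__all__ = [
    "Atom", "Structure", "Trajectory", "RegionSpec",
    "read_pdb", "read_pdb_models", "write_pdb",
    "read_dcd", "write_dcd",
    "select_atoms", "load_regions",
]


@dataclass
class Atom:
    """One atom of the static topology, coordinates in Å."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError("coord must be a 3-vector")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("coord components must be finite")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def label(self) -> str:
        """Pair-table label, e.g. ``N@Asp66``."""
        return f"{self.name}@{self.res_name.capitalize()}{self.res_seq}"


@dataclass
class Structure:
    """Ordered atom list plus a title; the static topology."""

    atoms: list[Atom]
    title: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique (chain, res_seq) pairs in file order."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.res_seq), None)
        return list(seen)

    def atom_index(self, name: str, res_seq: int, chain: str | None = None) -> int:
        """Index of the first atom matching name/res_seq (and chain if given)."""
        for i, a in enumerate(self.atoms):
            if a.name == name and a.res_seq == res_seq and (chain is None or a.chain == chain):
                return i
        from obpdyn.errors import LookupError_
        raise LookupError_(f"no atom {name!r} in residue {res_seq}" +
                           (f" chain {chain!r}" if chain else ""))

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, float)
        atoms = [Atom(a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain, c)
                 for a, c in zip(self.atoms, coords)]
        return Structure(atoms, self.title)


@dataclass
class Trajectory:
    """Ordered coordinate frames matching a Structure's atom order.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``dt`` is the frame
    spacing in ps.
    """

    coords: np.ndarray
    dt: float = 0.1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not self.dt > 0:
            raise ValueError("dt must be positive (ps)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class RegionSpec:
    """A named inclusive residue range on one chain."""

    name: str
    chain: str
    res_start: int
    res_end: int

    def __post_init__(self) -> None:
        if self.res_start > self.res_end:
            raise ValueError(f"region {self.name!r}: res_start > res_end")


# Default cavity-"entrance" components for a 119-residue odorant-binding
# protein: the two termini, the loop downstream of helix α2, and the
# helix-α4-to-α5 span.
DEFAULT_REGIONS: dict[str, RegionSpec] = {
    "N-ter": RegionSpec("N-ter", "A", 3, 14),
    "alpha2": RegionSpec("alpha2", "A", 28, 35),
    "alpha4-5": RegionSpec("alpha4-5", "A", 67, 89),
    "C-ter": RegionSpec("C-ter", "A", 111, 119),
}


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> Atom | None:
    """Parse one ATOM/HETATM record; returns None for skipped altlocs."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        res_name = line[17:20].strip()
        chain = line[21]
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record: {exc}", lineno) from None
    if altloc not in (" ", "A"):   # keep a single deterministic conformer
        return None
    if not element:
        element = _element_from_name(name)
    return Atom(serial, name, element, res_name, res_seq, chain, np.array([x, y, z]))


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if stripped[:2] in ("CL", "BR", "FE", "ZN", "MG", "NA"):
        return stripped[:2].capitalize()
    return stripped[:1]


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file; for multi-model files return the first model only."""
    models, title = _read_pdb_raw(path)
    structure, _ = models
    return structure


def read_pdb_models(path: str | Path, dt: float = 0.1) -> tuple[Structure, Trajectory]:
    """Read a multi-model PDB as (topology, trajectory); dt in ps."""
    (structure, frames), _ = _read_pdb_raw(path)
    return structure, Trajectory(np.array(frames), dt=dt)


def _read_pdb_raw(path: str | Path):
    path = Path(path)
    atoms: list[Atom] = []
    frames: list[np.ndarray] = []
    current: list[np.ndarray] = []
    title = ""
    in_later_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line.rstrip("\n"), lineno)
                if atom is None:
                    continue
                if in_later_model:
                    current.append(atom.coord)
                else:
                    atoms.append(atom)
                    current.append(atom.coord)
            elif rec == "ENDMDL":
                if current:
                    frames.append(np.array(current))
                    current = []
                in_later_model = True
    if current:
        frames.append(np.array(current))
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM records found")
    for fr in frames:
        if len(fr) != len(atoms):
            raise TopologyMismatchError(
                f"{path}: model with {len(fr)} atoms, expected {len(atoms)}")
    structure = Structure(atoms, title=title)
    return (structure, frames), title


def write_pdb(structure: Structure, path: str | Path,
              trajectory: Trajectory | None = None) -> None:
    """Write a Structure (optionally every frame of a trajectory as MODELs)."""
    path = Path(path)
    frames = trajectory.coords if trajectory is not None else structure.coords[None]
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        for imodel, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for atom, xyz in zip(structure.atoms, frame):
                name = atom.name
                # PDB convention: 1-3 char names start in column 14
                field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    "ATOM  {serial:5d} {name:4s}{alt}{res:<3s} {chain}{seq:4d}{icode}"
                    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n"
                    .format(serial=atom.serial % 100000, name=field, alt=" ",
                            res=atom.res_name, chain=atom.chain, seq=atom.res_seq,
                            icode=" ", x=xyz[0], y=xyz[1], z=xyz[2],
                            occ=1.00, b=0.00, el=atom.element))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# DCD (CHARMM/NAMD binary, Fortran record markers, 'CORD' magic)
# --------------------------------------------------------------------------

class _DcdReader:
    """Low-level sequential reader handling endianness and marker width."""

    def __init__(self, fh):
        self.fh = fh
        head = fh.read(12)
        if len(head) < 12:
            raise PartialFileError("file too short for a DCD header")
        # the 'CORD' magic position disambiguates 4- vs 8-byte markers
        for endian, msize in (("<", 4), (">", 4), ("<", 8), (">", 8)):
            fmt = "i" if msize == 4 else "q"
            val = struct.unpack(endian + fmt, head[:msize])[0]
            if val == 84 and head[msize:msize + 4] == b"CORD":
                self.endian, self.msize, self.mfmt = endian, msize, fmt
                fh.seek(0)
                return
        raise PDBParseError("not a DCD file: no 84-byte 'CORD' header record")

    def record(self) -> bytes | None:
        """Read one Fortran record; None at clean EOF."""
        raw = self.fh.read(self.msize)
        if not raw:
            return None
        if len(raw) < self.msize:
            raise PartialFileError("truncated record marker")
        n = struct.unpack(self.endian + self.mfmt, raw)[0]
        data = self.fh.read(n)
        tail = self.fh.read(self.msize)
        if len(data) < n or len(tail) < self.msize:
            raise PartialFileError("truncated record body")
        n2 = struct.unpack(self.endian + self.mfmt, tail)[0]
        if n2 != n:
            raise PartialFileError("mismatched Fortran record markers")
        return data


def read_dcd(path: str | Path, structure: Structure, dt: float | None = None) -> Trajectory:
    """Read a CHARMM/NAMD DCD trajectory.

    Handles little- and big-endian files and the 64-bit Fortran-marker
    dialect; unit-cell blocks are skipped.  The header atom count must equal
    ``structure.n_atoms``.  ``dt`` (ps) overrides the header time step.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        rd = _DcdReader(fh)
        header = rd.record()
        if header is None or len(header) != 84 or header[:4] != b"CORD":
            raise PDBParseError(f"{path}: bad DCD header record")
        icntrl = struct.unpack(rd.endian + "20i", header[4:])
        has_cell = icntrl[10] != 0
        delta = struct.unpack(rd.endian + "f", header[4 + 9 * 4:4 + 10 * 4])[0]
        rd.record()                       # title block (ignored)
        natom_rec = rd.record()
        if natom_rec is None or len(natom_rec) != 4:
            raise PartialFileError(f"{path}: missing atom-count record")
        natoms = struct.unpack(rd.endian + "i", natom_rec)[0]
        if natoms != structure.n_atoms:
            raise TopologyMismatchError(
                f"{path}: DCD has {natoms} atoms, structure has {structure.n_atoms}")

        frames = []
        while True:
            try:
                first = rd.record()
            except PartialFileError as exc:
                raise PartialFileError(
                    f"{path}: truncated frame after {len(frames)} complete frames "
                    f"({exc})", frames_read=len(frames)) from None
            if first is None:
                break
            try:
                if has_cell:
                    if len(first) != 48:
                        raise PartialFileError("bad unit-cell record size")
                    first = rd.record()           # advance to X block
                    if first is None:
                        break
                xs = np.frombuffer(first, dtype=rd.endian + "f4")
                ys = np.frombuffer(rd.record(), dtype=rd.endian + "f4")
                zs = np.frombuffer(rd.record(), dtype=rd.endian + "f4")
                if not (len(xs) == len(ys) == len(zs) == natoms):
                    raise PartialFileError("coordinate block length mismatch")
            except (PartialFileError, TypeError):
                raise PartialFileError(
                    f"{path}: truncated frame after {len(frames)} complete frames",
                    frames_read=len(frames)) from None
            frames.append(np.stack([xs, ys, zs], axis=1).astype(float))
    if not frames:
        raise PartialFileError(f"{path}: DCD contains no frames", frames_read=0)
    return Trajectory(np.array(frames), dt=dt if dt is not None else (delta or 0.1))


def write_dcd(path: str | Path, trajectory: Trajectory,
              byteorder: str = "little", marker64: bool = False) -> None:
    """Write a CHARMM-style DCD file.

    ``byteorder`` is "little" or "big"; ``marker64`` writes 8-byte Fortran
    record markers (the 64-bit-offset dialect).  Coordinates are stored as
    float32, the format's native precision.
    """
    endian = "<" if byteorder == "little" else ">"
    mfmt = "q" if marker64 else "i"

    def rec(payload: bytes) -> bytes:
        m = struct.pack(endian + mfmt, len(payload))
        return m + payload + m

    coords = trajectory.coords
    n_frames, natoms, _ = coords.shape
    icntrl = [0] * 20
    icntrl[0] = n_frames
    icntrl[1] = 1                  # first step
    icntrl[2] = 1                  # save frequency
    icntrl[3] = n_frames
    icntrl[19] = 24                # CHARMM version stamp
    header = b"CORD" + struct.pack(endian + "9i", *icntrl[:9]) \
        + struct.pack(endian + "f", trajectory.dt) \
        + struct.pack(endian + "10i", *icntrl[10:])
    title = b"Written by obpdyn".ljust(80)
    with open(path, "wb") as fh:
        fh.write(rec(header))
        fh.write(rec(struct.pack(endian + "i", 1) + title))
        fh.write(rec(struct.pack(endian + "i", natoms)))
        for frame in coords:
            f32 = frame.astype(endian + "f4")
            for axis in range(3):
                fh.write(rec(f32[:, axis].tobytes()))


# --------------------------------------------------------------------------
# Selection
# --------------------------------------------------------------------------

def select_atoms(structure: Structure, region: RegionSpec,
                 atom_names: Iterable[str] | None = None) -> list[int]:
    """Indices (structure order) of atoms inside a region.

    ``atom_names`` filters by atom name (e.g. ``["CA"]`` or the backbone set
    ``["N", "CA", "C", "O"]``); None keeps every atom of the residues.
    """
    names = set(atom_names) if atom_names is not None else None
    out = [i for i, a in enumerate(structure.atoms)
           if a.chain == region.chain
           and region.res_start <= a.res_seq <= region.res_end
           and (names is None or a.name in names)]
    if not out:
        raise EmptySelectionError(
            f"region {region.name!r} ({region.chain} {region.res_start}-"
            f"{region.res_end}) selects no atoms")
    return out


def load_regions(path: str | Path) -> dict[str, RegionSpec]:
    """Load region definitions from YAML or JSON.

    Accepts either a list of ``{name, chain, start, end}`` mappings or a
    mapping ``name -> {chain, start, end}``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    regions: dict[str, RegionSpec] = {}
    if isinstance(data, dict):
        items = [{"name": k, **v} for k, v in data.items()]
    else:
        items = list(data)
    for item in items:
        spec = RegionSpec(item["name"], item.get("chain", "A"),
                          int(item["start"]), int(item["end"]))
        regions[spec.name] = spec
    return regions
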