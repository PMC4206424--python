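"""Hydrogen-bond detection, per-pair occupancy, and residue-level networks.

A bond is scored geometrically: donor–acceptor heavy-atom distance at most
``max_da_distance`` (default 3.0 Å) and, when an explicit hydrogen is
present, a D–H···A angle within ``max_angle_deviation`` (default 20°) of
linear, taking the best hydrogen on the donor.  The 3.0 Å cutoff is applied
to the donor–acceptor distance by default — the common convention for this
cutoff pair — with a hydrogen–acceptor option.

Crystal structures usually lack hydrogens; in hydrogen-free mode the angle
test falls back to an antecedent-angle proxy (X–D···A ≥ 90°, X a heavy
neighbour of the donor) and the emitted records are flagged approximate.
Protonation-dependent donors (e.g. a protonated Asp side chain at low pH)
are switched on through an explicit per-residue protonation map — pKa
calculation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from obpdyn.model_io import Structure, Trajectory

__all__ = [
    "HBondCriteria", "Donor", "HBondRecord", "OccupancyRecord",
    "find_donors_acceptors", "detect_hbonds", "occupancy_table",
    "pair_distance_series", "hbond_graph",
]

# residues whose side chains carry N/O donors in heavy-atom mode
_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
    "ASN": {"ND2"}, "GLN": {"NE2"},
}
_PROTONATED_DONORS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_CTER_ALIASES = {"OT1", "OT2", "OXT"}     # carboxy-terminal acceptor names


@dataclass
class HBondCriteria:
    """Geometric cutoffs: distance in Å, angle deviation from linear in degrees."""

    max_da_distance: float = 3.0
    max_angle_deviation: float = 20.0
    distance_mode: str = "donor-acceptor"      # or "hydrogen-acceptor"

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.max_angle_deviation <= 0:
            raise ValueError("H-bond cutoffs must be positive")
        if self.distance_mode not in ("donor-acceptor", "hydrogen-acceptor"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")


@dataclass
class Donor:
    """A donor heavy atom with its attached hydrogens and exclusion set."""

    index: int
    hydrogens: list[int]
    antecedents: list[int]
    excluded: frozenset[int] = frozenset()


@dataclass
class HBondRecord:
    donor: int
    hydrogen: int | None
    acceptor: int
    da_distance: float
    angle_deviation: float
    frame: int = 0
    approximate: bool = False


@dataclass
class OccupancyRecord:
    donor_label: str
    acceptor_label: str
    occupancy: float            # percent of frames
    donor: int = -1
    acceptor: int = -1


def _bond_graph(structure: Structure) -> dict[int, set[int]]:
    """Covalent bonds inferred from interatomic distances in the structure."""
    coords = structure.coords
    elements = [a.element.upper() for a in structure.atoms]
    tree = cKDTree(coords)
    bonds: dict[int, set[int]] = {i: set() for i in range(structure.n_atoms)}
    for i, j in tree.query_pairs(2.3):
        ei, ej = elements[i], elements[j]
        d = np.linalg.norm(coords[i] - coords[j])
        if "H" in (ei, ej):
            limit = 1.25
        elif "S" in (ei, ej):
            limit = 2.3
        else:
            limit = 1.9
        if d <= limit:
            bonds[i].add(j)
            bonds[j].add(i)
    return bonds


def find_donors_acceptors(
    structure: Structure,
    protonation: Mapping[int, bool] | None = None,
    mode: str = "auto",
) -> tuple[list[Donor], list[int]]:
    """Classify donors and acceptors for a structure.

    With explicit hydrogens (``mode="explicit"`` or auto-detected), donors
    are N/O atoms covalently bonded to at least one hydrogen (bond inferred
    by proximity).  Without hydrogens (``mode="heavy"``), donors are every
    backbone N (except proline) plus the canonical side-chain N/O donors,
    with Asp/Glu side-chain oxygens added for residues marked protonated in
    ``protonation`` (res_seq -> True).  Acceptors are all oxygens plus
    His ND1/NE2 when not protonated.  Each donor carries the acceptor
    indices excluded by the same-residue and 1-2/1-3 neighbour rules.
    """
    protonation = dict(protonation or {})
    elements = [a.element.upper() for a in structure.atoms]
    has_h = any(e == "H" for e in elements)
    if mode == "auto":
        mode = "explicit" if has_h else "heavy"
    bonds = _bond_graph(structure)

    donors: list[Donor] = []
    acceptors: list[int] = []
    for i, atom in enumerate(structure.atoms):
        el = elements[i]
        if el == "O":
            acceptors.append(i)
        elif el == "N" and atom.res_name == "HIS" and atom.name in ("ND1", "NE2"):
            if not any(elements[j] == "H" for j in bonds[i]):
                acceptors.append(i)

    for i, atom in enumerate(structure.atoms):
        el = elements[i]
        if el not in ("N", "O"):
            continue
        hyds = sorted(j for j in bonds[i] if elements[j] == "H")
        antecedents = sorted(j for j in bonds[i] if elements[j] != "H")
        if mode == "explicit":
            if not hyds:
                continue
        else:
            is_backbone_n = atom.name == "N" and atom.res_name != "PRO"
            sidechain = _SIDECHAIN_DONORS.get(atom.res_name, set())
            prot = (_PROTONATED_DONORS.get(atom.res_name, set())
                    if protonation.get(atom.res_seq) else set())
            if not (is_backbone_n or atom.name in sidechain or atom.name in prot):
                continue
        donors.append(Donor(index=i, hydrogens=hyds, antecedents=antecedents))

    # exclusion sets: same residue, plus acceptors within 2 covalent bonds
    acc_set = set(acceptors)
    res_of = [(a.chain, a.res_seq) for a in structure.atoms]
    for d in donors:
        excl = {j for j in acc_set if res_of[j] == res_of[d.index]}
        one_two = bonds[d.index]
        one_three = set().union(*(bonds[j] for j in one_two)) if one_two else set()
        excl |= (one_two | one_three) & acc_set
        d.excluded = frozenset(excl)
    return donors, acceptors


def detect_hbonds(
    frame: np.ndarray,
    donors: Sequence[Donor],
    acceptors: Sequence[int],
    criteria: HBondCriteria | None = None,
    frame_index: int = 0,
) -> list[HBondRecord]:
    """All hydrogen bonds in one coordinate frame.

    ``frame`` is the full (n_atoms, 3) coordinate array; donors/acceptors
    come from :func:`find_donors_acceptors`.  A bond is emitted iff the
    distance criterion holds and either the best D–H···A angle is within the
    angle cutoff of linear (explicit hydrogens) or the X–D···A antecedent
    proxy is ≥ 90° (hydrogen-free donors, flagged approximate).
    """
    criteria = criteria or HBondCriteria()
    frame = np.asarray(frame, float)
    if not donors or not acceptors:
        return []
    acc = np.asarray(list(acceptors), int)
    dpos = frame[[d.index for d in donors]]
    apos = frame[acc]
    dmat = np.linalg.norm(dpos[:, None, :] - apos[None, :, :], axis=2)

    records: list[HBondRecord] = []
    for di, donor in enumerate(donors):
        close = np.nonzero(dmat[di] <= criteria.max_da_distance)[0]
        for ai in close:
            a_idx = int(acc[ai])
            if a_idx == donor.index or a_idx in donor.excluded:
                continue
            da = float(dmat[di, ai])
            if donor.hydrogens:
                best_h, best_angle = None, -1.0
                for h in donor.hydrogens:
                    v1 = frame[donor.index] - frame[h]
                    v2 = frame[a_idx] - frame[h]
                    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                    if n1 == 0 or n2 == 0:
                        continue
                    ang = np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1, 1)))
                    if ang > best_angle:
                        best_h, best_angle = h, ang
                if best_h is None:
                    continue
                if criteria.distance_mode == "hydrogen-acceptor":
                    if np.linalg.norm(frame[best_h] - frame[a_idx]) > criteria.max_da_distance:
                        continue
                if 180.0 - best_angle <= criteria.max_angle_deviation:
                    records.append(HBondRecord(donor.index, best_h, a_idx, da,
                                               180.0 - best_angle, frame_index))
            else:
                ok = True
                for x in donor.antecedents:
                    v1 = frame[x] - frame[donor.index]
                    v2 = frame[a_idx] - frame[donor.index]
                    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                    if n1 and n2:
                        ang = np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1, 1)))
                        if ang < 90.0:
                            ok = False
                            break
                if ok:
                    records.append(HBondRecord(donor.index, None, a_idx, da,
                                               float("nan"), frame_index,
                                               approximate=True))
    return records


def occupancy_table(
    traj: Trajectory,
    donors: Sequence[Donor],
    acceptors: Sequence[int],
    criteria: HBondCriteria | None = None,
    structure: Structure | None = None,
) -> list[OccupancyRecord]:
    """Fraction of frames each donor/acceptor atom pair is hydrogen bonded.

    Returns records sorted by descending occupancy (percent).  Pair labels
    use the ``NAME@Res3Letter+number`` convention (e.g. ``N@Asp66``) when a
    structure is supplied, else the raw atom indices.
    """
    criteria = criteria or HBondCriteria()
    counts: dict[tuple[int, int], int] = {}
    for f in range(traj.n_frames):
        for rec in detect_hbonds(traj.coords[f], donors, acceptors, criteria, f):
            counts[(rec.donor, rec.acceptor)] = counts.get((rec.donor, rec.acceptor), 0) + 1

    def label(i: int) -> str:
        return structure.atoms[i].label if structure is not None else str(i)

    records = [OccupancyRecord(label(d), label(a), 100.0 * c / traj.n_frames, d, a)
               for (d, a), c in counts.items()]
    records.sort(key=lambda r: (-r.occupancy, r.donor_label, r.acceptor_label))
    return records


def pair_distance_series(traj: Trajectory, atom_a: int, atom_b: int) -> np.ndarray:
    """Per-frame Euclidean distance (Å) between two atoms given by index."""
    n = traj.n_atoms
    for idx in (atom_a, atom_b):
        if not 0 <= idx < n:
            from obpdyn.errors import LookupError_
            raise LookupError_(f"atom index {idx} outside 0..{n - 1}")
    return np.linalg.norm(traj.coords[:, atom_a, :] - traj.coords[:, atom_b, :], axis=1)


def hbond_graph(occupancies: Iterable[OccupancyRecord],
                min_occupancy: float = 10.0) -> nx.Graph:
    """Residue-level network: nodes are residues, edge weight is occupancy (%).

    Multiple atom pairs between the same two residues collapse to the
    max-occupancy edge; edges below ``min_occupancy`` percent are dropped.
    """
    if not 0 <= min_occupancy <= 100:
        raise ValueError("min_occupancy must be within [0, 100]")
    g = nx.Graph()
    for rec in occupancies:
        if rec.occupancy < min_occupancy:
            continue
        res_d = rec.donor_label.split("@")[-1]
        res_a = rec.acceptor_label.split("@")[-1]
        if res_d == res_a:
            continue
        if g.has_edge(res_d, res_a):
            g[res_d][res_a]["weight"] = max(g[res_d][res_a]["weight"], rec.occupancy)
        else:
            g.add_edge(res_d, res_a, weight=rec.occupancy)
    return g
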