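"""Simplified 3-state secondary-structure assignment (DSSP-style).

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
dipole model,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond existing when E < -0.5 kcal/mol.  Helices (H) come from consecutive
i+4 -> i turns, strands (E) from parallel/antiparallel bridge patterns;
everything else is coil (C).  The full 8-state alphabet is deliberately
collapsed to {H, E, C}: the analyses this package supports only distinguish
helix/sheet/loop.

Amide hydrogens are reconstructed when absent, 1.01 Å from N opposite the
preceding residue's C=O direction (the DSSP convention), so crystal
structures without hydrogens are handled.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from obpdyn.errors import SingularGeometryError
from obpdyn.model_io import Structure, Trajectory

__all__ = ["ks_energy", "assign_ss", "ss_timeline"]

_KS_Q = 0.084 * 332.0           # kcal/mol·Å
KS_BOND_CUTOFF = -0.5           # kcal/mol
_CA_SEARCH = 9.0                # Å; bridge partners cannot be farther (DSSP)
_NH_LENGTH = 1.01               # Å reconstructed N-H bond


def ks_energy(c: np.ndarray, o: np.ndarray, n: np.ndarray, h: np.ndarray) -> float:
    """Kabsch–Sander H-bond energy (kcal/mol) of a C=O ... H-N geometry."""
    c, o, n, h = (np.asarray(v, float) for v in (c, o, n, h))
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        raise SingularGeometryError("coincident atoms in Kabsch-Sander geometry")
    return _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _backbone_table(structure: Structure):
    """Per-residue indices of N, CA, C, O (None when missing) in chain order."""
    table: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    for i, a in enumerate(structure.atoms):
        key = (a.chain, a.res_seq)
        if key not in table:
            table[key] = {}
            order.append(key)
        if a.name in ("N", "CA", "C", "O", "H", "HN") and a.name not in table[key]:
            table[key][a.name if a.name != "HN" else "H"] = i
    return order, table


def assign_ss(frame: np.ndarray, structure: Structure) -> list[str]:
    """Per-residue 3-state codes for one coordinate frame.

    Residues missing backbone atoms are assigned C with a warning.  Priority
    on overlap is H > E > C.
    """
    frame = np.asarray(frame, float)
    order, table = _backbone_table(structure)
    nres = len(order)
    idx = [table[key] for key in order]
    complete = np.array([all(k in d for k in ("N", "CA", "C", "O")) for d in idx])
    if not complete.all():
        missing = [order[i] for i in np.nonzero(~complete)[0]]
        warnings.warn(f"residues missing backbone atoms assigned C: {missing[:5]}"
                      + ("..." if len(missing) > 5 else ""))

    # peptide connectivity: same chain and C(i)-N(i+1) within bonding range
    connected = np.zeros(nres, dtype=bool)       # connected[i]: i-1 -> i bonded
    for i in range(1, nres):
        if order[i][0] != order[i - 1][0] or not (complete[i] and complete[i - 1]):
            continue
        d = np.linalg.norm(frame[idx[i]["N"]] - frame[idx[i - 1]["C"]])
        connected[i] = d < 2.5

    # amide H: explicit if present, else reconstructed anti to previous C=O
    h_pos = np.full((nres, 3), np.nan)
    has_h = np.zeros(nres, dtype=bool)
    for i in range(nres):
        if not complete[i]:
            continue
        if "H" in idx[i]:
            h_pos[i] = frame[idx[i]["H"]]
            has_h[i] = True
        elif connected[i]:
            c_prev = frame[idx[i - 1]["C"]]
            o_prev = frame[idx[i - 1]["O"]]
            u = c_prev - o_prev
            u /= np.linalg.norm(u)
            h_pos[i] = frame[idx[i]["N"]] + _NH_LENGTH * u
            has_h[i] = True

    # Kabsch-Sander bond matrix: hbond[i, j] = N-H of i donates to C=O of j
    ca = np.full((nres, 3), np.inf)
    for i in range(nres):
        if complete[i]:
            ca[i] = frame[idx[i]["CA"]]
    hbond = np.zeros((nres, nres), dtype=bool)
    for i in range(nres):
        if not (complete[i] and has_h[i]):
            continue
        for j in range(nres):
            if j == i or not complete[j]:
                continue
            if np.linalg.norm(ca[i] - ca[j]) > _CA_SEARCH:
                continue
            e = ks_energy(frame[idx[j]["C"]], frame[idx[j]["O"]],
                          frame[idx[i]["N"]], h_pos[i])
            hbond[i, j] = e < KS_BOND_CUTOFF

    codes = ["C"] * nres

    # strands: parallel / antiparallel bridge patterns, |i-j| > 2
    def hb(i: int, j: int) -> bool:
        return 0 <= i < nres and 0 <= j < nres and hbond[i, j]

    # bridge partners need both chain neighbours present (DSSP's guard)
    def bridge_ok(i: int) -> bool:
        return 1 <= i <= nres - 2 and connected[i] and connected[i + 1]

    is_e = np.zeros(nres, dtype=bool)
    for i in range(nres):
        if not bridge_ok(i):
            continue
        for j in range(i + 3, nres):
            if not bridge_ok(j):
                continue
            para = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if para or anti:
                is_e[i] = is_e[j] = True
    for i in np.nonzero(is_e)[0]:
        codes[i] = "E"

    # helices: two consecutive i+4 -> i turns mark residues i..i+3 (H wins)
    turn4 = np.zeros(nres, dtype=bool)
    for i in range(nres - 4):
        if hbond[i + 4, i] and connected[i + 1:i + 5].all():
            turn4[i] = True
    for i in range(1, nres - 4):
        if turn4[i - 1] and turn4[i]:
            for k in range(i, i + 4):
                codes[k] = "H"
    return codes


def ss_timeline(traj: Trajectory, structure: Structure) -> np.ndarray:
    """assign_ss mapped over frames; returns (n_frames, n_residues) of codes."""
    rows = [assign_ss(traj.coords[f], structure) for f in range(traj.n_frames)]
    return np.array(rows, dtype="<U1")
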