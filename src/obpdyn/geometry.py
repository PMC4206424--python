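"""Geometric descriptors of cavity dynamics.

Implements the centre-of-selection point (arithmetic mean of Cα positions),
the radius of gyration of a backbone selection, the per-frame distances from
each cavity-"entrance" component centre to the total-cavity centre, windowed
distributions of those distance series, and the angular fluctuation of the
plane through the three disulfide-bond midpoints — a rigidity descriptor for
compact disulfide-stapled proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from obpdyn.errors import DegeneratePlaneError, EmptySelectionError
from obpdyn.model_io import RegionSpec, Structure, Trajectory, select_atoms

__all__ = [
    "CenterPoint", "GyrationValue", "EntranceGeometry", "PlaneAngleSeries",
    "geometric_center", "radius_of_gyration", "gyration_series",
    "entrance_distance_series", "windowed_distributions", "disulfide_plane_angle",
]


@dataclass
class CenterPoint:
    """Geometric centre R = (R_x, R_y, R_z) of N selected residues' Cα atoms."""

    R: np.ndarray
    n_residues: int


@dataclass
class GyrationValue:
    """Radius of gyration (Å) about the geometric centre R_C of N atoms."""

    rg: float
    center: np.ndarray
    n_atoms: int


@dataclass
class EntranceGeometry:
    """Per-frame centre-to-centre distance series (Å).

    ``to_cavity[name]`` is the distance from component-centre C_each to the
    total-cavity centre C_total; ``to_entrance[name]`` is the distance to the
    entrance centre (the mean of the four component centres).
    """

    components: list[str]
    to_cavity: dict[str, np.ndarray]
    to_entrance: dict[str, np.ndarray]


@dataclass
class PlaneAngleSeries:
    """Per-frame angle (degrees, folded to [0, 90]) between the disulfide
    plane normal and its orientation in the reference frame."""

    angles_deg: np.ndarray
    reference_frame: int


def geometric_center(coords: np.ndarray) -> CenterPoint:
    """Component-wise arithmetic mean of a Cα coordinate set."""
    coords = np.asarray(coords, float)
    if coords.size == 0:
        raise EmptySelectionError("geometric_center: empty coordinate set")
    coords = coords.reshape(-1, 3)
    return CenterPoint(R=coords.mean(axis=0), n_residues=coords.shape[0])


def radius_of_gyration(coords: np.ndarray) -> GyrationValue:
    """Rg = sqrt( (1/N) Σ_i |r_i − R_C|² ) with R_C the geometric centre."""
    coords = np.asarray(coords, float)
    if coords.size == 0:
        raise EmptySelectionError("radius_of_gyration: empty coordinate set")
    coords = coords.reshape(-1, 3)
    center = coords.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum((coords - center) ** 2, axis=1))))
    return GyrationValue(rg=rg, center=center, n_atoms=coords.shape[0])


def gyration_series(traj: Trajectory, selection: Sequence[int]) -> np.ndarray:
    """Per-frame radius of gyration (Å) over an atom selection."""
    sel = np.asarray(list(selection), int)
    if sel.size == 0:
        raise EmptySelectionError("gyration_series: empty selection")
    sub = traj.coords[:, sel, :]
    centers = sub.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.sum((sub - centers) ** 2, axis=2), axis=1))


def entrance_distance_series(
    traj: Trajectory,
    structure: Structure,
    components: Mapping[str, RegionSpec],
    cavity: Sequence[RegionSpec] | None = None,
    fixed_cavity_frame: int | None = None,
) -> EntranceGeometry:
    """Distances from each entrance-component centre to the cavity centre.

    Per frame, C_total is the geometric centre of the Cα atoms of the cavity
    set (default: the union of the component regions) and C_each the centre
    of each component; Euclidean distances |C_each − C_total| are returned,
    together with the distance of each component centre to the entrance
    centre (the mean of the component centres).  ``fixed_cavity_frame`` pins
    C_total to one frame instead of recomputing it per frame.
    """
    if not components:
        raise EmptySelectionError("entrance_distance_series: no components given")
    comp_sel = {name: np.asarray(select_atoms(structure, region, ["CA"]), int)
                for name, region in components.items()}
    if cavity is None:
        cav_idx = sorted({i for idx in comp_sel.values() for i in idx})
    else:
        cav_idx = sorted({i for region in cavity
                          for i in select_atoms(structure, region, ["CA"])})
    cav_idx = np.asarray(cav_idx, int)

    coords = traj.coords
    c_total = coords[:, cav_idx, :].mean(axis=1)            # (n_frames, 3)
    if fixed_cavity_frame is not None:
        c_total = np.broadcast_to(c_total[fixed_cavity_frame], c_total.shape)
    c_each = {name: coords[:, idx, :].mean(axis=1) for name, idx in comp_sel.items()}
    c_entrance = np.mean(np.stack(list(c_each.values())), axis=0)

    to_cavity = {name: np.linalg.norm(c - c_total, axis=1) for name, c in c_each.items()}
    to_entrance = {name: np.linalg.norm(c - c_entrance, axis=1) for name, c in c_each.items()}
    return EntranceGeometry(components=list(components),
                            to_cavity=to_cavity, to_entrance=to_entrance)


def windowed_distributions(series: np.ndarray, n_windows: int,
                           bin_width: float = 0.25):
    """Split a per-frame series into contiguous windows and histogram each.

    Frames are split into ``n_windows`` equal contiguous blocks (any
    remainder goes to the last block).  All windows share one bin grid of
    width ``bin_width`` Å spanning the full series range; each histogram is
    normalised so its bin masses sum to 1.

    Returns ``(bin_edges, densities)`` where ``densities`` has shape
    (n_windows, n_bins) and each row sums to 1.
    """
    series = np.asarray(series, float).ravel()
    n = series.size
    if not 1 <= n_windows <= n:
        raise ValueError(f"need 1 <= n_windows <= n_frames, got {n_windows} for {n} frames")
    lo, hi = float(series.min()), float(series.max())
    if hi - lo < bin_width:                       # constant-ish series: one bin
        edges = np.array([lo - bin_width / 2, lo + bin_width / 2])
    else:
        n_bins = int(np.ceil((hi - lo) / bin_width))
        edges = lo + bin_width * np.arange(n_bins + 1)
        edges[-1] = max(edges[-1], hi)            # guard fp shortfall at the top
    block = n // n_windows
    densities = np.empty((n_windows, len(edges) - 1))
    for w in range(n_windows):
        start = w * block
        stop = (w + 1) * block if w < n_windows - 1 else n
        counts, _ = np.histogram(series[start:stop], bins=edges)
        densities[w] = counts / counts.sum()
    return edges, densities


def _plane_normal(midpoints: np.ndarray) -> np.ndarray:
    v1 = midpoints[1] - midpoints[0]
    v2 = midpoints[2] - midpoints[0]
    n = np.cross(v1, v2)
    norm = np.linalg.norm(n)
    if norm < 1e-8:
        raise DegeneratePlaneError("disulfide midpoints are collinear; plane undefined")
    return n / norm


def disulfide_plane_angle(
    traj: Trajectory,
    structure: Structure,
    pairs: Sequence[tuple[int, int]],
    reference_frame: int = 0,
    chain: str = "A",
) -> PlaneAngleSeries:
    """Angle of the disulfide plane relative to its reference-frame pose.

    ``pairs`` are three (res_seq, res_seq) cysteine pairs; each contributes
    the midpoint of its SG–SG bond.  The plane normal is the cross product
    of the midpoint difference vectors; the per-frame angle is
    arccos(|n·n_ref|) in degrees, folded to [0, 90] because the plane's
    orientation sign is arbitrary.
    """
    if len(pairs) != 3:
        raise ValueError("exactly three disulfide pairs are required")
    sg_idx = [(structure.atom_index("SG", a, chain), structure.atom_index("SG", b, chain))
              for a, b in pairs]

    def midpoints(frame: np.ndarray) -> np.ndarray:
        return np.array([(frame[i] + frame[j]) / 2 for i, j in sg_idx])

    n_ref = _plane_normal(midpoints(traj.coords[reference_frame]))
    angles = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.coords):
        n = _plane_normal(midpoints(frame))
        angles[f] = np.degrees(np.arccos(np.clip(abs(float(n @ n_ref)), 0.0, 1.0)))
    return PlaneAngleSeries(angles_deg=angles, reference_frame=reference_frame)
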