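"""Synthetic structures and trajectories with analytic ground truth.

Real MD trajectories of odorant-binding proteins are expensive and not
redistributable, so every analysis stage in this package is validated
against a generator whose statistical properties are known exactly:

* ``make_reference`` builds an idealized compact helical protein (default
  119 residues, six helix segments, three disulfide bridges, full backbone
  with amide hydrogens) from standard peptide geometry, with the four
  labelled cavity-"entrance" regions (N-ter 3-14, α2 28-35, α4-α5 67-89,
  C-ter 111-119).
* ``sample_trajectory`` adds stationary AR(1) (discretized
  Ornstein-Uhlenbeck) positional noise whose per-coordinate standard
  deviation σ differs by region, so the per-residue RMSF has the analytic
  value σ√3; scheduled donor/acceptor pairs are geometrically clamped to
  hydrogen-bonded geometry (2.9 Å, linear) in Bernoulli(p)-selected frames
  and pushed to 4.5 Å otherwise, so occupancies are known; optional global
  rigid rotations about an axis in the disulfide plane give programmed
  plane angles.
* ``make_fep_samples`` draws Gaussian ΔU windows, for which the Zwanzig
  free energy has the closed form μ − σ²/(2kT).

Two presets encode the qualitative low-vs-neutral pH contrast of the
ASP1-type system: "low_pH" is uniformly rigid with high scheduled
occupancies; "neutral_pH" inflates σ in the α2/α4-α5/C-ter entrance
regions (×2) and collapses the occupancies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from obpdyn.fep import KB_KCAL, FepLeg
from obpdyn.model_io import Atom, DEFAULT_REGIONS, RegionSpec, Structure, Trajectory

__all__ = [
    "GeneratorConfig", "GroundTruth", "make_reference", "sample_trajectory",
    "make_fep_samples", "preset", "build_chain", "ideal_helix",
    "antiparallel_sheet", "extended_chain",
]

# ideal peptide geometry (lengths Å, angles degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)
LOOP_PHI_PSI = (-75.0, 145.0)

# helix segments of the default 119-residue bundle (inclusive ranges)
_HELIX_SEGMENTS = [(15, 27), (36, 48), (53, 64), (67, 78), (81, 89), (95, 110)]
_DISULFIDE_PAIRS = [(19, 55), (51, 107), (63, 97)]

# Scheduled donor/acceptor residue pairs (backbone N_i -> O_j) with target
# occupancies per preset, modelled on the occupancy table of an ASP1-type
# pH contrast (fractions of frames).
_SCHEDULE_LOW = [(66, 58, 0.5058), (35, 119, 0.1931), (17, 111, 0.2238),
                 (4, 114, 0.0843), (48, 112, 0.1217), (116, 34, 0.1665)]
_SCHEDULE_NEUTRAL = [(66, 58, 0.0031), (35, 119, 0.0), (17, 111, 0.1707),
                     (4, 114, 0.0), (48, 112, 0.0292), (116, 34, 0.0096)]


# --------------------------------------------------------------------------
# internal-coordinate chain building (NeRF)
# --------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d given a-b-c, |c-d|, angle(b,c,d), torsion(a,b,c,d)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(torsion),
                        bond * np.sin(angle) * np.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(torsions: Sequence[tuple[float, float]]) -> dict[str, np.ndarray]:
    """Backbone coordinates (N, CA, C, O, H arrays) for a (φ, ψ) list.

    Residue i uses torsions[i] = (φ_i, ψ_i); φ of the first residue and ψ of
    the last only affect terminal O/H placement.  Amide hydrogens follow the
    planar convention (anti to the preceding C=O); the first residue gets
    none (returned as NaN).
    """
    nres = len(torsions)
    N = np.zeros((nres, 3))
    CA = np.zeros((nres, 3))
    C = np.zeros((nres, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, nres):
        psi_prev = torsions[i - 1][1]
        phi = torsions[i][0]
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)
    O = np.zeros((nres, 3))
    for i in range(nres):
        psi = torsions[i][1] if i < nres - 1 else torsions[i][1]
        # carbonyl O anti to the next amide N (psi + 180 about N-CA-C)
        O[i] = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
    H = np.full((nres, 3), np.nan)
    for i in range(1, nres):
        u = C[i - 1] - O[i - 1]
        u /= np.linalg.norm(u)
        H[i] = N[i] + _B_N_H * u
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


def _chain_structure(bb: dict[str, np.ndarray], res_names: Sequence[str],
                     chain: str = "A", first_res: int = 1,
                     title: str = "") -> Structure:
    atoms: list[Atom] = []
    serial = 1
    for i, rname in enumerate(res_names):
        res_seq = first_res + i
        for name in ("N", "CA", "C", "O", "H"):
            xyz = bb[name][i]
            if np.any(np.isnan(xyz)):
                continue
            element = name[0]
            atoms.append(Atom(serial, name, element, rname, res_seq, chain, xyz))
            serial += 1
    return Structure(atoms, title=title)


def ideal_helix(n_residues: int = 15) -> Structure:
    """Ideal α-helix (φ, ψ = −57°, −47°) with backbone and amide H."""
    bb = build_chain([HELIX_PHI_PSI] * n_residues)
    return _chain_structure(bb, ["ALA"] * n_residues, title="ideal alpha helix")


def extended_chain(n_residues: int = 10) -> Structure:
    """Fully extended isolated chain (no H-bond partners possible)."""
    bb = build_chain([(-180.0, 180.0)] * n_residues)
    return _chain_structure(bb, ["ALA"] * n_residues, title="extended chain")


def antiparallel_sheet(n_per_strand: int = 8) -> Structure:
    """Synthetic two-strand antiparallel β-sheet.

    Strand A is built from ideal strand torsions; strand B is a copy rotated
    180° about the strand axis (making it antiparallel) whose rigid offset is
    chosen by a deterministic search maximising the number of cross-strand
    Kabsch-Sander hydrogen bonds.  A constructed stand-in for a sheet taken
    from an experimental structure; geometry is idealized, not physical.
    """
    bb_a = build_chain([STRAND_PHI_PSI] * n_per_strand)
    ca = bb_a["CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    centroid = ca.mean(axis=0)
    perp1 = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp1) < 1e-6:
        perp1 = np.cross(axis, [0.0, 1.0, 0.0])
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)

    def rot180(pts: np.ndarray, about: np.ndarray) -> np.ndarray:
        # 180° rotation about an axis through the strand centroid
        rel = pts - centroid
        par = np.outer(rel @ about, about)
        return centroid + 2 * par - rel

    def ks_matrix(don: dict[str, np.ndarray], acc: dict[str, np.ndarray],
                  don_h: np.ndarray) -> np.ndarray:
        q = 0.084 * 332.0
        def inv_d(a, b):
            return 1.0 / np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        e = q * (inv_d(don["N"], acc["O"]) + inv_d(don_h, acc["C"])
                 - inv_d(don_h, acc["O"]) - inv_d(don["N"], acc["C"]))
        e[np.isnan(e)] = 0.0
        return e

    def hb_count(bb_b0: dict[str, np.ndarray], offset: np.ndarray) -> int:
        B = {k: v + offset for k, v in bb_b0.items()}
        Bh = _amide_h(B)
        return int(np.sum(ks_matrix(bb_a, B, bb_a["H"]) < -0.5)
                   + np.sum(ks_matrix(B, bb_a, Bh) < -0.5))

    best, best_off, best_bb = -1, None, None
    for flip_axis in (perp1, perp2):
        bb_b0 = {k: rot180(v, flip_axis) for k, v in bb_a.items()}
        for d1 in np.arange(3.5, 6.01, 0.25):
            for d2 in np.arange(-1.0, 1.01, 0.25):
                for along in np.arange(-3.0, 3.01, 0.25):
                    off = d1 * perp1 + d2 * perp2 + along * axis
                    c = hb_count(bb_b0, off)
                    if c > best:
                        best, best_off, best_bb = c, off, bb_b0
    for d1 in np.arange(-0.25, 0.26, 0.05):      # refine around the winner
        for d2 in np.arange(-0.25, 0.26, 0.05):
            for along in np.arange(-0.25, 0.26, 0.05):
                off = best_off + d1 * perp1 + d2 * perp2 + along * axis
                c = hb_count(best_bb, off)
                if c > best:
                    best, best_off = c, off

    bb_b = {k: v + best_off for k, v in best_bb.items()}
    bb_b["H"] = _amide_h(bb_b)
    s_a = _chain_structure(bb_a, ["ALA"] * n_per_strand, chain="A",
                           title="synthetic antiparallel sheet")
    s_b = _chain_structure(bb_b, ["ALA"] * n_per_strand, chain="B",
                           first_res=n_per_strand + 3)
    atoms = s_a.atoms + s_b.atoms
    for serial, a in enumerate(atoms, start=1):
        a.serial = serial
    return Structure(atoms, title=s_a.title)


def _amide_h(bb: dict[str, np.ndarray]) -> np.ndarray:
    nres = bb["N"].shape[0]
    H = np.full((nres, 3), np.nan)
    for i in range(1, nres):
        u = bb["C"][i - 1] - bb["O"][i - 1]
        u /= np.linalg.norm(u)
        H[i] = bb["N"][i] + _B_N_H * u
    return H


# --------------------------------------------------------------------------
# generator configuration and ground truth
# --------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic trajectory generator.

    ``region_sigma`` maps region names (keys of ``regions``) to the
    per-coordinate stationary fluctuation σ in Å; other residues use
    ``sigma_default``.  ``hbond_schedule`` lists (donor_res, acceptor_res,
    target occupancy p) triples realised with backbone N→O clamping.
    ``rotation_deg``, when set, applies a global rigid rotation per frame
    about an axis lying in the reference disulfide plane.
    """

    n_residues: int = 119
    sigma_default: float = 0.4
    region_sigma: dict[str, float] = field(default_factory=dict)
    regions: dict[str, RegionSpec] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    hbond_schedule: list[tuple[int, int, float]] = field(default_factory=list)
    disulfide_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: list(_DISULFIDE_PAIRS))
    n_frames: int = 2000
    dt: float = 0.1
    ar1_rho: float = 0.9
    rotation_deg: np.ndarray | None = None
    seed: int = 0
    state: str = "low_pH"

    def __post_init__(self) -> None:
        if self.n_residues < 20:
            raise ValueError("n_residues must be at least 20")
        if self.sigma_default < 0 or any(s < 0 for s in self.region_sigma.values()):
            raise ValueError("fluctuation sigma must be non-negative")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")
        for _, _, p in self.hbond_schedule:
            if not 0 <= p <= 1:
                raise ValueError("scheduled occupancy must lie in [0, 1]")
        if self.n_frames < 1 or self.dt <= 0:
            raise ValueError("n_frames >= 1 and dt > 0 required")


@dataclass
class GroundTruth:
    """Analytic values the analysis modules should recover."""

    rmsf_expected: dict[int, float] = field(default_factory=dict)   # res -> σ√3
    sigma_per_residue: dict[int, float] = field(default_factory=dict)
    occupancy_expected: dict[tuple[int, int], float] = field(default_factory=dict)
    occupancy_realized: dict[tuple[int, int], float] = field(default_factory=dict)
    plane_angles_deg: np.ndarray | None = None
    dg_complex: float | None = None
    dg_free: float | None = None
    ddg_bind: float | None = None

    def to_json(self, path) -> None:
        data = {
            "rmsf_expected": {str(k): v for k, v in self.rmsf_expected.items()},
            "sigma_per_residue": {str(k): v for k, v in self.sigma_per_residue.items()},
            "occupancy_expected": {f"{d}-{a}": p for (d, a), p
                                   in self.occupancy_expected.items()},
            "occupancy_realized": {f"{d}-{a}": p for (d, a), p
                                   in self.occupancy_realized.items()},
            "plane_angles_deg": (None if self.plane_angles_deg is None
                                 else list(map(float, self.plane_angles_deg))),
            "dg_complex": self.dg_complex,
            "dg_free": self.dg_free,
            "ddg_bind": self.ddg_bind,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def preset(state: str, **overrides) -> GeneratorConfig:
    """The two study conditions: "low_pH" (rigid, bonded) or "neutral_pH"
    (entrance regions twice as mobile, occupancies collapsed)."""
    if state == "low_pH":
        cfg = GeneratorConfig(state="low_pH", sigma_default=0.4,
                              region_sigma={},
                              hbond_schedule=list(_SCHEDULE_LOW))
    elif state == "neutral_pH":
        cfg = GeneratorConfig(state="neutral_pH", sigma_default=0.5,
                              region_sigma={"alpha2": 1.0, "alpha4-5": 1.0,
                                            "C-ter": 1.0},
                              hbond_schedule=list(_SCHEDULE_NEUTRAL))
    else:
        raise ValueError(f"unknown preset state {state!r}")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.__post_init__()
    return cfg


# --------------------------------------------------------------------------
# reference structure and trajectory sampling
# --------------------------------------------------------------------------

def make_reference(config: GeneratorConfig) -> Structure:
    """Idealized multi-helix protein with labelled regions and 3 disulfides.

    Helix segments use ideal α torsions, linkers polyproline-II-like
    torsions; every residue has N, CA, C, O (+ amide H from residue 2 on),
    and the six cysteines carry CB and SG atoms, the SG pairs placed
    symmetrically about their CB-CB midpoints so the three S-S midpoints are
    non-collinear.
    """
    n = config.n_residues
    helix = set()
    for lo, hi in _HELIX_SEGMENTS:
        helix.update(range(lo, min(hi, n) + 1))
    torsions = [HELIX_PHI_PSI if (i + 1) in helix else LOOP_PHI_PSI for i in range(n)]
    bb = build_chain(torsions)

    cys = sorted({r for pair in config.disulfide_pairs for r in pair})
    if any(r > n for r in cys):
        raise ValueError("disulfide residue outside the chain")
    res_names = ["CYS" if (i + 1) in set(cys) else "ALA" for i in range(n)]

    atoms: list[Atom] = []
    serial = 1
    cb_pos: dict[int, np.ndarray] = {}
    for i in range(n):
        res_seq = i + 1
        for name in ("N", "CA", "C", "O", "H"):
            xyz = bb[name][i]
            if np.any(np.isnan(xyz)):
                continue
            atoms.append(Atom(serial, name, name[0], res_names[i], res_seq, "A", xyz))
            serial += 1
        if res_names[i] == "CYS":
            u1 = bb["N"][i] - bb["CA"][i]
            u2 = bb["C"][i] - bb["CA"][i]
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            perp = np.cross(u1, u2)
            perp /= np.linalg.norm(perp)
            bis = -(u1 + u2)
            bis /= np.linalg.norm(bis)
            cb = bb["CA"][i] + 1.53 * (np.sqrt(1 / 3) * bis + np.sqrt(2 / 3) * perp)
            cb_pos[res_seq] = cb
            atoms.append(Atom(serial, "CB", "C", "CYS", res_seq, "A", cb))
            serial += 1
            atoms.append(Atom(serial, "SG", "S", "CYS", res_seq, "A", cb.copy()))
            serial += 1

    structure = Structure(atoms, title=f"synthetic helical bundle ({config.state})")
    # pair the SG atoms across each bridge
    for r1, r2 in config.disulfide_pairs:
        m = (cb_pos[r1] + cb_pos[r2]) / 2
        u = cb_pos[r2] - cb_pos[r1]
        u /= np.linalg.norm(u)
        structure.atoms[structure.atom_index("SG", r1)].coord = m - 1.025 * u
        structure.atoms[structure.atom_index("SG", r2)].coord = m + 1.025 * u
    return structure


def _sigma_per_residue(config: GeneratorConfig) -> dict[int, float]:
    out = {r: config.sigma_default for r in range(1, config.n_residues + 1)}
    for name, sigma in config.region_sigma.items():
        region = config.regions[name]
        for r in range(region.res_start, min(region.res_end, config.n_residues) + 1):
            out[r] = sigma
    return out


def sample_trajectory(ref: Structure,
                      config: GeneratorConfig) -> tuple[Trajectory, GroundTruth]:
    """Stationary AR(1) trajectory around the reference, with clamped bonds.

    Displacements follow d_t = ρ d_{t-1} + σ√(1-ρ²) ε_t per atom and
    coordinate, started from the stationary distribution, so the stationary
    per-coordinate sd is exactly the region σ and the per-residue RMSF is
    σ√3.  Scheduled pairs overwrite the acceptor O (and donor amide H) with
    bonded geometry (2.9 Å, linear D-H···A) in Bernoulli(p) frames and
    4.5 Å separation otherwise.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sigma_res = _sigma_per_residue(config)
    sigma_atom = np.array([sigma_res[a.res_seq] for a in ref.atoms])
    ref_coords = ref.coords
    n_atoms = ref.n_atoms
    nf = config.n_frames
    rho = config.ar1_rho

    coords = np.empty((nf, n_atoms, 3))
    d = sigma_atom[:, None] * rng.standard_normal((n_atoms, 3))
    innov = np.sqrt(1.0 - rho ** 2)
    for t in range(nf):
        if t > 0:
            d = rho * d + innov * sigma_atom[:, None] * rng.standard_normal((n_atoms, 3))
        coords[t] = ref_coords + d

    truth = GroundTruth(
        rmsf_expected={r: s * np.sqrt(3.0) for r, s in sigma_res.items()},
        sigma_per_residue=dict(sigma_res),
    )

    # clamp scheduled H-bond pairs
    for d_res, a_res, p in config.hbond_schedule:
        n_idx = ref.atom_index("N", d_res)
        h_idx = ref.atom_index("H", d_res)
        o_idx = ref.atom_index("O", a_res)
        u = ref_coords[o_idx] - ref_coords[n_idx]
        u = u / np.linalg.norm(u)
        on = rng.random(nf) < p
        dist = np.where(on, 2.9, 4.5)
        coords[:, h_idx, :] = coords[:, n_idx, :] + 1.0 * u
        coords[:, o_idx, :] = coords[:, n_idx, :] + dist[:, None] * u
        truth.occupancy_expected[(d_res, a_res)] = p
        truth.occupancy_realized[(d_res, a_res)] = float(on.mean())

    # optional programmed rigid rotation about an in-plane disulfide axis
    if config.rotation_deg is not None:
        angles = np.asarray(config.rotation_deg, float)
        if angles.shape != (nf,):
            raise ValueError("rotation_deg must have one angle per frame")
        mids = []
        for r1, r2 in config.disulfide_pairs:
            i1 = ref.atom_index("SG", r1)
            i2 = ref.atom_index("SG", r2)
            mids.append((ref_coords[i1] + ref_coords[i2]) / 2)
        mids = np.array(mids)
        axis = mids[1] - mids[0]
        axis /= np.linalg.norm(axis)                      # lies in the plane
        center = mids.mean(axis=0)
        for t in range(nf):
            rot = _rotation_matrix(axis, np.radians(angles[t]))
            coords[t] = (coords[t] - center) @ rot.T + center
        truth.plane_angles_deg = np.abs(angles)

    return Trajectory(coords, dt=config.dt), truth


def _rotation_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.asarray(axis, float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def make_fep_samples(mu_complex: float, sigma_complex: float,
                     mu_free: float, sigma_free: float,
                     n: int, temperature: float = 300.0, seed: int = 0,
                     n_windows: int = 1) -> tuple[FepLeg, FepLeg, GroundTruth]:
    """Two Gaussian FEP legs with analytic free energies.

    Each leg's ΔU samples are Gaussian; splitting into ``n_windows`` windows
    assigns each window mean μ/W and sd σ/√W, so the analytic leg total is
    always μ − σ²/(2kT) and the analytic ΔΔG_bind their difference.
    """
    if n < 1 or min(sigma_complex, sigma_free) < 0:
        raise ValueError("need n >= 1 and non-negative sigmas")
    rng = np.random.default_rng(seed)
    kt = KB_KCAL * temperature

    def build(name: str, mu: float, sigma: float) -> FepLeg:
        w = n_windows
        windows = []
        lams = np.linspace(0, 1, w + 1)
        for k in range(w):
            du = mu / w + (sigma / np.sqrt(w)) * rng.standard_normal(n)
            windows.append((lams[k], lams[k + 1], du))
        return FepLeg(name=name, windows=windows, temperature=temperature)

    leg_c = build("complex", mu_complex, sigma_complex)
    leg_f = build("free", mu_free, sigma_free)
    dg_c = mu_complex - sigma_complex ** 2 / (2 * kt)
    dg_f = mu_free - sigma_free ** 2 / (2 * kt)
    truth = GroundTruth(dg_complex=dg_c, dg_free=dg_f, ddg_bind=dg_c - dg_f)
    return leg_c, leg_f, truth
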