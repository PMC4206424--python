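"""Optimal rigid-body superposition, RMSD time series and per-residue RMSF.

The fit is the Kabsch/SVD solution: the proper rotation (reflections excluded
by a determinant correction) minimising the weighted squared deviation after
removing the weighted centroids.  RMSD is reported over the fitting selection;
RMSF is measured at one atom per residue (conventionally Cα) against the
iteratively refined trajectory-mean structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from obpdyn.errors import DegenerateFitError, EmptySelectionError, InsufficientFramesError
from obpdyn.model_io import Structure, Trajectory

__all__ = ["FitResult", "FluctuationProfile", "kabsch_fit", "rmsd_series", "rmsf_profile"]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class FitResult:
    """Rigid transform mapping mobile onto reference, plus the residual RMSD (Å).

    ``apply(x)`` returns ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class FluctuationProfile:
    """Per-residue RMSF in Å, indexed by author residue number."""

    res_seq: list[int]
    rmsf: np.ndarray


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               weights: np.ndarray | None = None) -> FitResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Both inputs are (n, 3) with n ≥ 3 non-collinear points.  ``weights`` are
    optional non-negative per-atom weights (e.g. masses); default unweighted.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateFitError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateFitError(f"need at least 3 atoms to fit, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise DegenerateFitError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = w @ mobile
    cr = w @ reference
    x = mobile - cm
    y = reference - cr
    cov = (x * w[:, None]).T @ y
    if np.linalg.matrix_rank(cov, tol=1e-12) < 2:
        raise DegenerateFitError("rank-deficient covariance (collinear or coincident atoms)")
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = x @ rot.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - y) ** 2)))
    trans = cr - cm @ rot.T
    return FitResult(rotation=rot, translation=trans, rmsd=rmsd)


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, reference: Structure | np.ndarray,
                selection: Sequence[int], superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) over ``selection`` after fitting each frame.

    ``reference`` is a Structure or a raw (n_atoms, 3) coordinate array in
    the same atom order as the trajectory.  With ``superpose=False`` the raw
    deviation is reported (useful for validating against closed forms).
    """
    sel = np.asarray(list(selection), int)
    if sel.size == 0:
        raise EmptySelectionError("rmsd_series: empty selection")
    ref = reference.coords if isinstance(reference, Structure) else np.asarray(reference, float)
    ref_sel = ref[sel]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        mob = frame[sel]
        if superpose:
            out[i] = kabsch_fit(mob, ref_sel).rmsd
        else:
            out[i] = _plain_rmsd(mob, ref_sel)
    return out


def rmsf_profile(traj: Trajectory, selection: Sequence[int],
                 res_seq: Sequence[int] | None = None) -> FluctuationProfile:
    """Per-atom RMSF over the trajectory, superposed on the mean structure.

    One refinement pass: frames are first fitted to frame 0 and averaged,
    then re-fitted to that average and re-averaged; RMSF_i is the root mean
    squared displacement of atom i from its final mean position.  Pass Cα
    indices in ``selection`` for the conventional per-residue profile;
    ``res_seq`` labels the profile (defaults to 1..n).
    """
    sel = np.asarray(list(selection), int)
    if sel.size == 0:
        raise EmptySelectionError("rmsf_profile: empty selection")
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    frames = traj.coords[:, sel, :]

    mean = frames[0]
    for _ in range(2):                       # initial fit + one refinement pass
        fitted = np.empty_like(frames)
        for i, fr in enumerate(frames):
            fitted[i] = kabsch_fit(fr, mean).apply(fr)
        mean = fitted.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    labels = list(res_seq) if res_seq is not None else list(range(1, sel.size + 1))
    if len(labels) != sel.size:
        raise ValueError("res_seq length must match selection length")
    return FluctuationProfile(res_seq=labels, rmsf=rmsf)
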