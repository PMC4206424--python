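"""Thermodynamic-cycle relative binding free energies from FEP windows.

Each alchemical leg (e.g. perturbing the protonation state of the complex,
or of the free protein) is a sequence of λ-windows carrying samples of the
energy difference ΔU = U(λ_to) − U(λ_from) in kcal/mol.  Window free
energies use the Zwanzig exponential-averaging estimator

    ΔG = −kT ln ⟨ exp(−ΔU / kT) ⟩,

evaluated with log-sum-exp stabilisation, and sum along the leg.  The cycle
closes as ΔΔG_bind = ΔG_complex − ΔG_free: a negative value means binding is
preferred in the perturbed (low-pH) state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = ["KB_KCAL", "FepLeg", "CycleResult", "zwanzig_dg", "leg_free_energy",
           "ddg_bind", "read_leg", "write_leg", "window_overlap_histograms"]

KB_KCAL = 0.0019872041          # Boltzmann constant, kcal/(mol·K)


@dataclass
class FepLeg:
    """One alchemical leg: ordered (λ_from, λ_to, ΔU samples) windows at T kelvin."""

    name: str
    windows: list[tuple[float, float, np.ndarray]]
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if not self.windows:
            raise ValueError(f"leg {self.name!r} has no windows")
        cleaned = []
        prev_to = None
        for lam_from, lam_to, du in self.windows:
            du = np.asarray(du, float).ravel()
            if du.size == 0:
                raise ValueError(f"leg {self.name!r}: window {lam_from}->{lam_to} empty")
            if not np.all(np.isfinite(du)):
                raise ValueError(f"leg {self.name!r}: non-finite ΔU sample")
            if lam_to <= lam_from and not (lam_from > lam_to):  # allow reverse legs
                pass
            if prev_to is not None and not np.isclose(lam_from, prev_to):
                raise ValueError(f"leg {self.name!r}: windows not contiguous in λ")
            prev_to = lam_to
            cleaned.append((float(lam_from), float(lam_to), du))
        self.windows = cleaned


@dataclass
class CycleResult:
    dg_complex: float
    dg_free: float
    ddg_bind: float             # ΔG_complex − ΔG_free, kcal/mol


def zwanzig_dg(samples: np.ndarray, temperature: float) -> float:
    """Zwanzig free-energy estimate (kcal/mol) from ΔU samples at T kelvin."""
    du = np.asarray(samples, float).ravel()
    if du.size == 0:
        raise ValueError("zwanzig_dg: no samples")
    if not np.all(np.isfinite(du)):
        raise ValueError("zwanzig_dg: non-finite sample")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    kt = KB_KCAL * temperature
    # -kT * log( mean exp(-du/kT) ), stabilised
    return float(-kt * (logsumexp(-du / kt) - np.log(du.size)))


def leg_free_energy(leg: FepLeg) -> float:
    """Sum of per-window Zwanzig estimates along a leg (kcal/mol)."""
    return float(sum(zwanzig_dg(du, leg.temperature) for _, _, du in leg.windows))


def ddg_bind(complex_leg: FepLeg, free_leg: FepLeg) -> CycleResult:
    """Close the thermodynamic cycle: ΔΔG_bind = ΔG_complex − ΔG_free."""
    if not np.isclose(complex_leg.temperature, free_leg.temperature):
        raise ValueError("legs were sampled at different temperatures")
    dgc = leg_free_energy(complex_leg)
    dgf = leg_free_energy(free_leg)
    return CycleResult(dg_complex=dgc, dg_free=dgf, ddg_bind=dgc - dgf)


def window_overlap_histograms(leg: FepLeg, n_bins: int = 40):
    """Per-window ΔU histograms (bin_edges, counts) — an overlap diagnostic."""
    out = []
    for lam_from, lam_to, du in leg.windows:
        counts, edges = np.histogram(du, bins=n_bins)
        out.append(((lam_from, lam_to), edges, counts))
    return out


def read_leg(path: str | Path, name: str | None = None,
             temperature: float = 300.0) -> FepLeg:
    """Read a leg from whitespace-delimited text: λ_from λ_to ΔU per line.

    Lines starting with '#' are comments.  Lines with a leading 'FepEnergy:'
    token (NAMD fepout style) are also accepted, taking the ΔU column (7th
    numeric field) with λ bounds from preceding '#NEW FEP WINDOW' lines.
    """
    path = Path(path)
    windows: dict[tuple[float, float], list[float]] = {}
    cur: tuple[float, float] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#NEW FEP WINDOW"):
                toks = line.replace(":", " ").split()
                vals = [float(t) for t in toks if _is_float(t)]
                if len(vals) >= 2:
                    cur = (vals[0], vals[1])
                continue
            if line.startswith("#"):
                continue
            toks = line.split()
            if toks[0] == "FepEnergy:":
                if cur is None:
                    continue
                du = float(toks[6])
                windows.setdefault(cur, []).append(du)
            else:
                lam_from, lam_to, du = float(toks[0]), float(toks[1]), float(toks[2])
                windows.setdefault((lam_from, lam_to), []).append(du)
    win_list = [(a, b, np.array(v)) for (a, b), v in sorted(windows.items())]
    return FepLeg(name=name or path.stem, windows=win_list, temperature=temperature)


def write_leg(leg: FepLeg, path: str | Path) -> None:
    """Write a leg in the three-column text format read_leg accepts."""
    with open(path, "w") as fh:
        fh.write("# lambda_from lambda_to dU_kcal_mol\n")
        for lam_from, lam_to, du in leg.windows:
            for v in du:
                fh.write(f"{lam_from:.4f} {lam_to:.4f} {v:.8f}\n")


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
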