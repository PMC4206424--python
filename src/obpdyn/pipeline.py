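"""Config-driven orchestration of the full analysis battery.

``run_analysis`` takes a topology, one trajectory per replicate and a region
definition, runs every descriptor (RMSD, RMSF, Rg, entrance distances with
windowed distributions, H-bond occupancy, secondary-structure timeline,
disulfide plane angle), and writes per-replicate and replicate-averaged TSV
tables plus a JSON manifest (config hash, inputs, package version) into the
output directory.  Reruns on identical inputs reproduce identical tables.

``compare_states`` pairs two such report directories (e.g. a low-pH and a
neutral-pH condition) into contrast tables of means, standard deviations and
occupancy drops.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

import obpdyn
from obpdyn.errors import ObpdynError
from obpdyn.geometry import (disulfide_plane_angle, entrance_distance_series,
                             gyration_series, windowed_distributions)
from obpdyn.hbonds import HBondCriteria, find_donors_acceptors, occupancy_table
from obpdyn.model_io import (DEFAULT_REGIONS, RegionSpec, Structure, Trajectory,
                             load_regions, read_dcd, read_pdb, read_pdb_models,
                             select_atoms)
from obpdyn.secondary import ss_timeline
from obpdyn.superpose import BACKBONE_NAMES, rmsd_series, rmsf_profile

__all__ = ["RunConfig", "run_analysis", "compare_states"]

log = logging.getLogger("obpdyn.pipeline")

_TABLES = ["rmsd", "rmsf", "rg", "entrance", "windows", "occupancy", "ss", "plane"]


@dataclass
class RunConfig:
    """Inputs and knobs for one analysis run (one condition, >=1 replicate)."""

    topology: str
    trajectories: list[str]
    output_dir: str
    regions_file: str | None = None
    label: str = "run"
    dt: float = 0.1
    n_windows: int = 10
    max_da_distance: float = 3.0
    max_angle_deviation: float = 20.0
    protonation: dict[int, bool] = field(default_factory=dict)
    disulfide_pairs: list[tuple[int, int]] = field(default_factory=list)
    reference_frame: int = 0

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("at least one replicate trajectory is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "disulfide_pairs" in data:
            data["disulfide_pairs"] = [tuple(p) for p in data["disulfide_pairs"]]
        if "protonation" in data:
            data["protonation"] = {int(k): bool(v) for k, v in data["protonation"].items()}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps({k: str(v) for k, v in self.__dict__.items()},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_trajectory(path: str, structure: Structure, dt: float) -> Trajectory:
    p = Path(path)
    if p.suffix.lower() == ".dcd":
        return read_dcd(p, structure, dt=dt)
    _, traj = read_pdb_models(p, dt=dt)
    if traj.n_atoms != structure.n_atoms:
        from obpdyn.errors import TopologyMismatchError
        raise TopologyMismatchError(f"{p}: {traj.n_atoms} atoms vs topology "
                                    f"{structure.n_atoms}")
    return traj


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _analyze_one(structure: Structure, traj: Trajectory, config: RunConfig,
                 regions: dict[str, RegionSpec], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    chain = structure.atoms[0].chain
    all_res = RegionSpec("all", chain, min(a.res_seq for a in structure.atoms),
                         max(a.res_seq for a in structure.atoms))
    backbone = select_atoms(structure, all_res, BACKBONE_NAMES)
    ca = select_atoms(structure, all_res, ["CA"])
    ca_res = [structure.atoms[i].res_seq for i in ca]

    stage = "rmsd"
    try:
        rmsd = rmsd_series(traj, structure, backbone)
        _write(pd.DataFrame({"frame": np.arange(traj.n_frames),
                             "time_ps": traj.times_ps(), "rmsd_A": rmsd}),
               outdir / "rmsd.tsv")

        stage = "rmsf"
        prof = rmsf_profile(traj, ca, res_seq=ca_res)
        _write(pd.DataFrame({"res_seq": prof.res_seq, "rmsf_A": prof.rmsf}),
               outdir / "rmsf.tsv")

        stage = "rg"
        rg = gyration_series(traj, backbone)
        _write(pd.DataFrame({"frame": np.arange(traj.n_frames),
                             "time_ps": traj.times_ps(), "rg_A": rg}),
               outdir / "rg.tsv")

        stage = "entrance"
        ent = entrance_distance_series(traj, structure, regions)
        rows = []
        for name in ent.components:
            for f in range(traj.n_frames):
                rows.append((f, name, ent.to_cavity[name][f], ent.to_entrance[name][f]))
        _write(pd.DataFrame(rows, columns=["frame", "component",
                                           "dist_to_cavity_A", "dist_to_entrance_A"]),
               outdir / "entrance.tsv")

        stage = "windows"
        wrows = []
        for name in ent.components:
            edges, dens = windowed_distributions(ent.to_cavity[name], config.n_windows)
            centers = 0.5 * (edges[:-1] + edges[1:])
            for w in range(dens.shape[0]):
                for c, dv in zip(centers, dens[w]):
                    wrows.append((name, w, c, dv))
        _write(pd.DataFrame(wrows, columns=["component", "window",
                                            "bin_center_A", "density"]),
               outdir / "windows.tsv")

        stage = "occupancy"
        donors, acceptors = find_donors_acceptors(structure, config.protonation)
        criteria = HBondCriteria(config.max_da_distance, config.max_angle_deviation)
        occ = occupancy_table(traj, donors, acceptors, criteria, structure)
        _write(pd.DataFrame([(r.donor_label, r.acceptor_label, r.occupancy)
                             for r in occ],
                            columns=["donor", "acceptor", "occupancy_pct"]),
               outdir / "occupancy.tsv")

        stage = "ss"
        codes = ss_timeline(traj, structure)
        res_ids = [rs for _, rs in structure.residue_ids()]
        srows = [(f, res_ids[r], codes[f, r])
                 for f in range(codes.shape[0]) for r in range(codes.shape[1])]
        _write(pd.DataFrame(srows, columns=["frame", "res_seq", "code"]),
               outdir / "ss.tsv")

        stage = "plane"
        if config.disulfide_pairs:
            pa = disulfide_plane_angle(traj, structure, config.disulfide_pairs,
                                       reference_frame=config.reference_frame,
                                       chain=chain)
            _write(pd.DataFrame({"frame": np.arange(traj.n_frames),
                                 "angle_deg": pa.angles_deg}),
                   outdir / "plane.tsv")
    except Exception as exc:
        raise ObpdynError(f"stage {stage!r} failed on {outdir.name}: {exc}") from exc


def run_analysis(config: RunConfig) -> Path:
    """Run every descriptor for every replicate; returns the output directory.

    Output layout: ``rep1/ rep2/ ...`` with one TSV per descriptor, an
    ``averaged/`` directory with replicate means (per-frame where frame
    counts align, else per-summary), and ``manifest.json``.  Any stage
    failure removes partial outputs and raises.
    """
    out = Path(config.output_dir)
    structure = read_pdb(config.topology)
    regions = (load_regions(config.regions_file) if config.regions_file
               else dict(DEFAULT_REGIONS))
    # re-home default regions onto the topology's chain id
    chain = structure.atoms[0].chain
    regions = {k: RegionSpec(v.name, chain, v.res_start, v.res_end)
               for k, v in regions.items()}

    if out.exists():
        shutil.rmtree(out)
    out.mkdir(parents=True)
    try:
        for i, tpath in enumerate(config.trajectories, start=1):
            log.info("replicate %d: %s", i, tpath)
            traj = _load_trajectory(tpath, structure, config.dt)
            _analyze_one(structure, traj, config, regions, out / f"rep{i}")
        _average_replicates(out, len(config.trajectories))
        manifest = {
            "label": config.label,
            "config_digest": config.digest(),
            "topology": str(config.topology),
            "trajectories": [str(t) for t in config.trajectories],
            "n_replicates": len(config.trajectories),
            "regions": {k: [v.chain, v.res_start, v.res_end] for k, v in regions.items()},
            "obpdyn_version": obpdyn.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out


def _average_replicates(out: Path, n_rep: int) -> None:
    avg = out / "averaged"
    avg.mkdir()
    reps = [out / f"rep{i}" for i in range(1, n_rep + 1)]
    for name in _TABLES:
        paths = [r / f"{name}.tsv" for r in reps if (r / f"{name}.tsv").exists()]
        if not paths:
            continue
        dfs = [pd.read_csv(p, sep="\t") for p in paths]
        if name == "ss":
            # categorical: per-residue helix/strand fractions across reps+frames
            cat = pd.concat(dfs)
            summary = (cat.groupby("res_seq")["code"]
                       .apply(lambda s: pd.Series({"frac_H": (s == "H").mean(),
                                                   "frac_E": (s == "E").mean(),
                                                   "frac_C": (s == "C").mean()}))
                       .unstack().reset_index())
            _write(summary, avg / "ss_summary.tsv")
            continue
        if name == "occupancy":
            cat = pd.concat(dfs)
            mean = (cat.groupby(["donor", "acceptor"], as_index=False)["occupancy_pct"]
                    .sum())
            mean["occupancy_pct"] /= len(dfs)
            mean = mean.sort_values("occupancy_pct", ascending=False)
            _write(mean, avg / "occupancy.tsv")
            continue
        shapes = {tuple(df.shape) for df in dfs}
        if len(shapes) == 1:
            key_cols = [c for c in dfs[0].columns
                        if dfs[0][c].dtype == object or c in ("frame", "window",
                                                              "res_seq", "time_ps",
                                                              "bin_center_A")]
            stacked = sum(df.drop(columns=key_cols, errors="ignore") for df in dfs) / len(dfs)
            merged = pd.concat([dfs[0][key_cols], stacked], axis=1)
            _write(merged, avg / f"{name}.tsv")
        else:
            # unequal frame counts: average scalar summaries instead
            num = [df.select_dtypes("number").mean() for df in dfs]
            _write(pd.DataFrame(num).mean().to_frame("mean").reset_index(
                names="quantity"), avg / f"{name}_summary.tsv")


def compare_states(report_a: str | Path, report_b: str | Path,
                   label_a: str = "A", label_b: str = "B") -> dict[str, pd.DataFrame]:
    """Paired descriptor summaries for two run_analysis output directories.

    Returns contrast tables: ``scalars`` (mean/sd of RMSD, Rg, plane angle),
    ``entrance`` (per-component distance mean/variance), ``occupancy``
    (pairs sorted by occupancy drop A→B).  Region definitions must match.
    """
    a, b = Path(report_a), Path(report_b)
    man_a = json.loads((a / "manifest.json").read_text())
    man_b = json.loads((b / "manifest.json").read_text())
    if man_a["regions"] != man_b["regions"]:
        raise ObpdynError("compare_states: region definitions differ between reports")

    def stats(path: Path, col: str):
        df = pd.read_csv(path, sep="\t")
        return df[col].mean(), df[col].std()

    rows = []
    for name, col in (("rmsd", "rmsd_A"), ("rg", "rg_A"), ("plane", "angle_deg")):
        pa, pb = a / "averaged" / f"{name}.tsv", b / "averaged" / f"{name}.tsv"
        if pa.exists() and pb.exists():
            ma, sa = stats(pa, col)
            mb, sb = stats(pb, col)
            rows.append((name, ma, sa, mb, sb, mb - ma))
    scalars = pd.DataFrame(rows, columns=["descriptor", f"mean_{label_a}",
                                          f"sd_{label_a}", f"mean_{label_b}",
                                          f"sd_{label_b}", "mean_diff"])

    ea = pd.read_csv(a / "averaged" / "entrance.tsv", sep="\t")
    eb = pd.read_csv(b / "averaged" / "entrance.tsv", sep="\t")
    ga = ea.groupby("component")["dist_to_cavity_A"].agg(["mean", "var"])
    gb = eb.groupby("component")["dist_to_cavity_A"].agg(["mean", "var"])
    entrance = ga.join(gb, lsuffix=f"_{label_a}", rsuffix=f"_{label_b}").reset_index()

    oa = pd.read_csv(a / "averaged" / "occupancy.tsv", sep="\t")
    ob = pd.read_csv(b / "averaged" / "occupancy.tsv", sep="\t")
    occ = oa.merge(ob, on=["donor", "acceptor"], how="outer",
                   suffixes=(f"_{label_a}", f"_{label_b}")).fillna(0.0)
    occ["drop"] = occ[f"occupancy_pct_{label_a}"] - occ[f"occupancy_pct_{label_b}"]
    occ = occ.sort_values("drop", ascending=False).reset_index(drop=True)
    return {"scalars": scalars, "entrance": entrance, "occupancy": occ}
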