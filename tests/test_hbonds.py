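import numpy as np
import pytest

from obpdyn.hbonds import (HBondCriteria, detect_hbonds, find_donors_acceptors,
                           hbond_graph, occupancy_table, pair_distance_series,
                           OccupancyRecord)
from obpdyn.model_io import Atom, Structure, Trajectory
from obpdyn.synthetic import GeneratorConfig, make_reference, sample_trajectory


def water():
    o = Atom(1, "O", "O", "HOH", 1, "W", np.array([0.0, 0, 0]))
    h1 = Atom(2, "H1", "H", "HOH", 1, "W", np.array([0.96, 0, 0]))
    h2 = Atom(3, "H2", "H", "HOH", 1, "W", np.array([-0.24, 0.93, 0]))
    return Structure([o, h1, h2])


def nh_co_pair(d_on=2.9, angle_deg=175.0):
    """Backbone N-H ... O=C fragment with controllable geometry.

    The acceptor O sits at distance d_on from N along +x; the H is placed so
    the D-H...A angle equals angle_deg.
    """
    n = np.array([0.0, 0, 0])
    o = np.array([d_on, 0.0, 0.0])
    # place H at 1.0 from N such that angle N-H-O = angle_deg
    theta = np.radians(180.0 - angle_deg)
    h = n + 1.0 * np.array([np.cos(theta), np.sin(theta), 0.0])
    atoms = [
        Atom(1, "N", "N", "ALA", 1, "A", n),
        Atom(2, "H", "H", "ALA", 1, "A", h),
        Atom(3, "CA", "C", "ALA", 1, "A", np.array([-0.8, -1.2, 0.0])),
        Atom(4, "C", "C", "GLY", 5, "A", o + np.array([0.7, 1.0, 0.0])),
        Atom(5, "O", "O", "GLY", 5, "A", o),
    ]
    return Structure(atoms)


def brute_force_hbonds(frame, donors, acceptors, criteria):
    """O(D*A) oracle with no spatial tricks; mirrors the geometric rules."""
    out = set()
    for d in donors:
        for a in acceptors:
            if a == d.index or a in d.excluded:
                continue
            if np.linalg.norm(frame[d.index] - frame[a]) > criteria.max_da_distance:
                continue
            if d.hydrogens:
                angles = []
                for h in d.hydrogens:
                    v1, v2 = frame[d.index] - frame[h], frame[a] - frame[h]
                    angles.append(np.degrees(np.arccos(np.clip(
                        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))))
                if 180.0 - max(angles) <= criteria.max_angle_deviation:
                    out.add((d.index, a))
            else:
                ok = True
                for x in d.antecedents:
                    v1, v2 = frame[x] - frame[d.index], frame[a] - frame[d.index]
                    ang = np.degrees(np.arccos(np.clip(
                        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
                    ok = ok and ang >= 90.0
                if ok:
                    out.add((d.index, a))
    return out


def test_water_is_donor_and_acceptor():
    donors, acceptors = find_donors_acceptors(water())
    assert [d.index for d in donors] == [0]
    assert len(donors[0].hydrogens) == 2
    assert acceptors == [0]


def test_backbone_fragment_classification():
    s = nh_co_pair()
    donors, acceptors = find_donors_acceptors(s)
    assert [s.atoms[d.index].name for d in donors] == ["N"]
    assert [s.atoms[a].name for a in acceptors] == ["O"]


@pytest.mark.parametrize("d_on,angle,expect", [
    (2.9, 175.0, 1),     # inside both cutoffs
    (3.5, 175.0, 0),     # distance fails
    (2.9, 150.0, 0),     # angle fails
])
def test_criteria_cutoffs(d_on, angle, expect):
    s = nh_co_pair(d_on, angle)
    donors, acceptors = find_donors_acceptors(s)
    recs = detect_hbonds(s.coords, donors, acceptors, HBondCriteria())
    assert len(recs) == expect
    if expect:
        assert recs[0].da_distance == pytest.approx(d_on, abs=1e-9)


def test_criteria_monotonicity():
    """Widening either cutoff never removes a detected bond."""
    s = nh_co_pair(2.95, 168.0)
    donors, acceptors = find_donors_acceptors(s)
    base = {(r.donor, r.acceptor) for r in
            detect_hbonds(s.coords, donors, acceptors, HBondCriteria(3.0, 20.0))}
    for dist, ang in [(3.2, 20.0), (3.0, 30.0), (3.5, 45.0)]:
        wide = {(r.donor, r.acceptor) for r in
                detect_hbonds(s.coords, donors, acceptors, HBondCriteria(dist, ang))}
        assert base <= wide


def test_heavy_atom_mode_antecedent_proxy():
    s = nh_co_pair(2.9, 175.0)
    no_h = Structure([a for a in s.atoms if a.element != "H"])
    donors, acceptors = find_donors_acceptors(no_h, mode="heavy")
    recs = detect_hbonds(no_h.coords, donors, acceptors)
    assert len(recs) == 1 and recs[0].approximate


def test_detect_matches_brute_force_oracle(reference_structure):
    cfg = GeneratorConfig(n_frames=8, seed=7, state="low_pH",
                          hbond_schedule=[(66, 58, 0.5), (17, 111, 0.5)])
    traj, _ = sample_trajectory(reference_structure, cfg)
    donors, acceptors = find_donors_acceptors(reference_structure)
    crit = HBondCriteria()
    for f in range(traj.n_frames):
        got = {(r.donor, r.acceptor)
               for r in detect_hbonds(traj.coords[f], donors, acceptors, crit)}
        assert got == brute_force_hbonds(traj.coords[f], donors, acceptors, crit)


def test_occupancy_recovery_and_extremes(reference_structure):
    cfg = GeneratorConfig(n_frames=2000, seed=13,
                          hbond_schedule=[(66, 58, 0.5), (35, 119, 0.1),
                                          (17, 111, 0.9)])
    traj, truth = sample_trajectory(reference_structure, cfg)
    donors, acceptors = find_donors_acceptors(reference_structure)
    occ = occupancy_table(traj, donors, acceptors, structure=reference_structure)
    by_pair = {(r.donor, r.acceptor): r.occupancy for r in occ}
    for (d_res, a_res), p in truth.occupancy_expected.items():
        d = reference_structure.atom_index("N", d_res)
        a = reference_structure.atom_index("O", a_res)
        # the detector recovers the realized schedule exactly ...
        realized = truth.occupancy_realized[(d_res, a_res)]
        assert by_pair.get((d, a), 0.0) == pytest.approx(100 * realized, abs=1e-9)
        # ... and the realized schedule sits near the target rate
        se = 100 * np.sqrt(p * (1 - p) / traj.n_frames)
        assert abs(by_pair.get((d, a), 0.0) - 100 * p) <= 4 * se
    assert sorted((r.occupancy for r in occ), reverse=True) == \
        [r.occupancy for r in occ]


def test_always_and_never_bonded():
    s = nh_co_pair(2.9, 178.0)
    donors, acceptors = find_donors_acceptors(s)
    traj = Trajectory(np.repeat(s.coords[None], 20, axis=0))
    occ = occupancy_table(traj, donors, acceptors, structure=s)
    assert occ[0].occupancy == 100.0
    far = s.coords.copy()
    far[4] += [10.0, 0, 0]
    occ2 = occupancy_table(Trajectory(np.repeat(far[None], 20, axis=0)),
                           donors, acceptors, structure=s)
    assert occ2 == []


def test_occupancy_labels(reference_structure):
    cfg = GeneratorConfig(n_frames=50, seed=1, hbond_schedule=[(66, 58, 1.0)])
    traj, _ = sample_trajectory(reference_structure, cfg)
    donors, acceptors = find_donors_acceptors(reference_structure)
    occ = occupancy_table(traj, donors, acceptors, structure=reference_structure)
    assert occ[0].donor_label == "N@Ala66"
    assert occ[0].acceptor_label == "O@Ala58"


def test_pair_distance_series(reference_structure):
    n = reference_structure.n_atoms
    base = reference_structure.coords
    ramp = np.linspace(2.0, 6.0, 11)
    frames = np.repeat(base[None], 11, axis=0)
    frames[:, 1, :] = frames[:, 0, :] + ramp[:, None] * np.array([1.0, 0, 0])
    traj = Trajectory(frames)
    np.testing.assert_allclose(pair_distance_series(traj, 0, 1), ramp, atol=1e-10)
    np.testing.assert_allclose(pair_distance_series(traj, 5, 5), 0.0, atol=1e-12)
    static = Trajectory(np.repeat(base[None], 3, axis=0))
    d0 = np.linalg.norm(base[0] - base[4])
    np.testing.assert_allclose(pair_distance_series(static, 0, 4), d0, atol=1e-12)


class TestGraph:
    def test_empty(self):
        g = hbond_graph([])
        assert g.number_of_edges() == 0

    def test_merging_to_max_occupancy(self):
        recs = [OccupancyRecord("N@Ala1", "O@Ala5", 60.0),
                OccupancyRecord("OD1@Ala1", "O@Ala5", 30.0),
                OccupancyRecord("N@Ala2", "O@Ala7", 20.0)]
        g = hbond_graph(recs, min_occupancy=10.0)
        assert g.number_of_edges() == 2
        assert g["Ala1"]["Ala5"]["weight"] == 60.0

    def test_scheduled_thresholding(self, reference_structure):
        cfg = GeneratorConfig(n_frames=400, seed=5,
                              hbond_schedule=[(66, 58, 0.8), (35, 119, 0.4),
                                              (17, 111, 0.05)])
        traj, _ = sample_trajectory(reference_structure, cfg)
        donors, acceptors = find_donors_acceptors(reference_structure)
        occ = occupancy_table(traj, donors, acceptors,
                              structure=reference_structure)
        scheduled = {("Ala66", "Ala58"), ("Ala35", "Ala119"), ("Ala17", "Ala111")}
        g = hbond_graph(occ, min_occupancy=10.0)
        kept = {frozenset(e) for e in g.edges} & {frozenset(s) for s in scheduled}
        assert kept == {frozenset({"Ala66", "Ala58"}),
                        frozenset({"Ala35", "Ala119"})}
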