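import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from obpdyn.errors import DegeneratePlaneError, EmptySelectionError
from obpdyn.geometry import (disulfide_plane_angle, entrance_distance_series,
                             geometric_center, radius_of_gyration,
                             windowed_distributions)
from obpdyn.model_io import Atom, RegionSpec, Structure, Trajectory
from obpdyn.synthetic import GeneratorConfig, make_reference, sample_trajectory

from conftest import rigid_transform


def running_mean(coords):
    """Independent oracle: incremental mean, one point at a time."""
    m = np.zeros(3)
    for k, p in enumerate(coords, start=1):
        m = m + (np.asarray(p, float) - m) / k
    return m


class TestCenters:
    def test_single_point(self):
        c = geometric_center(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(c.R, [1, 2, 3])
        assert c.n_residues == 1

    def test_midpoint(self):
        c = geometric_center(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        np.testing.assert_allclose(c.R, [1, 0, 0])

    def test_matches_running_mean_oracle(self):
        pts = np.random.default_rng(0).normal(size=(5, 3)) * 10
        np.testing.assert_allclose(geometric_center(pts).R, running_mean(pts),
                                   atol=1e-12)

    def test_empty_raises(self):
        with pytest.raises(EmptySelectionError):
            geometric_center(np.empty((0, 3)))


class TestGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.array([[4.0, 4, 4]])).rg == 0.0

    def test_two_atoms_half_separation(self):
        rg = radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]])).rg
        assert rg == pytest.approx(1.0, abs=1e-12)

    def test_cube_sqrt3(self):
        cube = np.array([[i, j, k] for i in (0, 2) for j in (0, 2) for k in (0, 2)],
                        float)
        assert radius_of_gyration(cube).rg == pytest.approx(np.sqrt(3), abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000), st.integers(2, 20))
    def test_pairwise_distance_identity(self, seed, n):
        """Rg^2 equals mean squared pairwise distance / 2 (independent formula)."""
        pts = np.random.default_rng(seed).normal(size=(n, 3)) * 5
        diff = pts[:, None, :] - pts[None, :, :]
        msd = np.sum(diff ** 2, axis=2).sum() / (2 * n * n)
        assert radius_of_gyration(pts).rg ** 2 == pytest.approx(msd, abs=1e-10)

    def test_rigid_invariance(self):
        pts = np.random.default_rng(1).normal(size=(9, 3))
        moved = rigid_transform(pts, [1, 2, 3], 77.0, [10, -4, 2])
        assert radius_of_gyration(moved).rg == pytest.approx(
            radius_of_gyration(pts).rg, abs=1e-10)


def _star_structure():
    """Four single-residue 'components' at distance 10 from a symmetric core."""
    atoms = []
    serial = 1
    core = [[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]]
    for i, xyz in enumerate(core):
        atoms.append(Atom(serial, "CA", "C", "GLY", i + 1, "A", np.array(xyz)))
        serial += 1
    tips = [[10.0, 0, 0], [-10.0, 0, 0], [0, 10.0, 0], [0, -10.0, 0]]
    for i, xyz in enumerate(tips):
        atoms.append(Atom(serial, "CA", "C", "GLY", 10 + i, "A", np.array(xyz)))
        serial += 1
    return Structure(atoms)


class TestEntranceDistances:
    def setup_method(self):
        self.structure = _star_structure()
        self.components = {f"c{i}": RegionSpec(f"c{i}", "A", 10 + i, 10 + i)
                           for i in range(4)}
        self.cavity = [RegionSpec("core", "A", 1, 4)]

    def test_constructed_symmetric_distances(self):
        traj = Trajectory(self.structure.coords[None])
        ent = entrance_distance_series(traj, self.structure, self.components,
                                       cavity=self.cavity)
        for name in ent.components:
            assert ent.to_cavity[name][0] == pytest.approx(10.0, abs=1e-12)

    def test_translation_invariance(self):
        coords = self.structure.coords
        frames = np.stack([coords, coords + np.array([7.0, -3.0, 11.0])])
        ent = entrance_distance_series(Trajectory(frames), self.structure,
                                       self.components, cavity=self.cavity)
        for name in ent.components:
            assert ent.to_cavity[name][0] == pytest.approx(ent.to_cavity[name][1],
                                                           abs=1e-10)

    def test_matches_brute_force(self, reference_structure):
        cfg = GeneratorConfig(n_frames=5, seed=3)
        traj, _ = sample_trajectory(reference_structure, cfg)
        ent = entrance_distance_series(traj, reference_structure, cfg.regions)
        # brute force from raw coordinates
        ca = {(a.chain, a.res_seq): i for i, a in enumerate(reference_structure.atoms)
              if a.name == "CA"}
        union = sorted({i for r in cfg.regions.values()
                        for s in range(r.res_start, r.res_end + 1)
                        for i in [ca[("A", s)]]})
        for name, region in cfg.regions.items():
            idx = [ca[("A", s)] for s in range(region.res_start, region.res_end + 1)]
            for f in range(traj.n_frames):
                c_each = traj.coords[f, idx].mean(axis=0)
                c_tot = traj.coords[f, union].mean(axis=0)
                expect = np.linalg.norm(c_each - c_tot)
                assert ent.to_cavity[name][f] == pytest.approx(expect, abs=1e-10)

    def test_entrance_center_is_mean_of_component_centers(self):
        traj = Trajectory(self.structure.coords[None])
        ent = entrance_distance_series(traj, self.structure, self.components,
                                       cavity=self.cavity)
        # star is symmetric: entrance centre coincides with the core centre
        for name in ent.components:
            assert ent.to_entrance[name][0] == pytest.approx(10.0, abs=1e-12)


class TestWindows:
    def test_integer_split_and_mass(self):
        series = np.random.default_rng(0).normal(size=200)
        edges, dens = windowed_distributions(series, 10)
        assert dens.shape[0] == 10
        np.testing.assert_allclose(dens.sum(axis=1), 1.0, atol=1e-12)

    def test_constant_series_single_bin(self):
        edges, dens = windowed_distributions(np.full(100, 3.3), 5)
        assert dens.shape == (5, 1)
        np.testing.assert_allclose(dens, 1.0)

    def test_step_series_modes(self):
        series = np.concatenate([np.full(100, 2.0), np.full(100, 6.0)])
        series += np.random.default_rng(1).normal(0, 0.05, 200)
        edges, dens = windowed_distributions(series, 10)
        centers = 0.5 * (edges[:-1] + edges[1:])
        modes = centers[np.argmax(dens, axis=1)]
        assert np.all(np.abs(modes[:5] - 2.0) < 0.3)
        assert np.all(np.abs(modes[5:] - 6.0) < 0.3)

    def test_remainder_goes_to_last_block(self):
        edges, dens = windowed_distributions(np.arange(23.0), 4)
        assert dens.shape[0] == 4
        np.testing.assert_allclose(dens.sum(axis=1), 1.0, atol=1e-12)

    def test_too_many_windows(self):
        with pytest.raises(ValueError):
            windowed_distributions(np.arange(5.0), 6)


class TestPlaneAngle:
    def test_reference_vs_itself_zero(self, reference_structure):
        traj = Trajectory(np.repeat(reference_structure.coords[None], 3, axis=0))
        pa = disulfide_plane_angle(traj, reference_structure,
                                   [(19, 55), (51, 107), (63, 97)])
        np.testing.assert_allclose(pa.angles_deg, 0.0, atol=1e-9)

    @pytest.mark.parametrize("angle", [5.0, 15.0, 40.0])
    def test_programmed_in_plane_rotation(self, reference_structure, angle):
        cfg = GeneratorConfig(sigma_default=0.0, n_frames=3, seed=0,
                              rotation_deg=np.array([0.0, angle, angle]))
        traj, truth = sample_trajectory(reference_structure, cfg)
        pa = disulfide_plane_angle(traj, reference_structure, cfg.disulfide_pairs)
        assert pa.angles_deg[1] == pytest.approx(angle, abs=1e-6)
        np.testing.assert_allclose(pa.angles_deg[1:], truth.plane_angles_deg[1:],
                                   atol=1e-6)

    def test_pure_translation_zero(self, reference_structure):
        coords = reference_structure.coords
        frames = np.stack([coords, coords + np.array([20.0, -7.0, 4.0])])
        pa = disulfide_plane_angle(Trajectory(frames), reference_structure,
                                   [(19, 55), (51, 107), (63, 97)])
        assert pa.angles_deg[1] == pytest.approx(0.0, abs=1e-9)

    def test_collinear_midpoints_raise(self):
        atoms = []
        serial = 1
        for r, x in zip((1, 2, 11, 12, 21, 22), (0, 1, 5, 6, 10, 11)):
            atoms.append(Atom(serial, "SG", "S", "CYS", r, "A",
                              np.array([float(x), 0, 0])))
            serial += 1
        s = Structure(atoms)
        traj = Trajectory(s.coords[None])
        with pytest.raises(DegeneratePlaneError):
            disulfide_plane_angle(traj, s, [(1, 2), (11, 12), (21, 22)])
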