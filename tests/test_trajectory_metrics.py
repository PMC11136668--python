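"""Superposition, adaptability, RMSF, ligand RMSD, COM distance, SASA."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import ligdyn as ld
from ligdyn.trajectory_metrics import shrake_rupley_sasa

from conftest import make_fixed_frame_complex


def random_cloud(rng, n=20, spread=5.0):
    return rng.normal(0.0, spread, (n, 3))


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        cloud = random_cloud(rng)
        fit = ld.superpose(cloud, cloud)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-10)

    def test_pure_translation_recovered(self):
        rng = np.random.default_rng(1)
        cloud = random_cloud(rng)
        fit = ld.superpose(cloud + np.array([5.0, 0, 0]), cloud)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            fit.translation, [-5.0, 0.0, 0.0], atol=1e-8
        )

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(2)
        cloud = random_cloud(rng, n=20)
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        mobile = cloud @ rot.T
        fit = ld.superpose(mobile, cloud)
        np.testing.assert_allclose(fit.rotation @ rot, np.eye(3), atol=1e-8)
        assert fit.rmsd < 1e-8

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(3)
        fit = ld.superpose(random_cloud(rng), random_cloud(rng))
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)

    def test_degenerate_selection_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ld.AlignmentError):
            ld.superpose(line, line + 1.0)
        with pytest.raises(ld.AlignmentError):
            ld.superpose(line[:2], line[:2])

    @given(st.integers(0, 10_000))
    def test_apply_then_recover_random_rigid(self, seed):
        rng = np.random.default_rng(seed)
        cloud = random_cloud(rng, n=12)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-10, 10, 3)
        fit = ld.superpose(cloud @ rot.T + shift, cloud)
        np.testing.assert_allclose(fit.transform(cloud @ rot.T + shift), cloud, atol=1e-8)


class TestAdaptability:
    def test_static_trajectory_gamma_zero(self, toy_complex):
        coords = np.repeat(toy_complex.coordinates[None], 5, axis=0)
        traj = ld.TrajectoryRecord(entry_id="S", coordinates=coords)
        profile = ld.adaptability(traj, toy_complex)
        np.testing.assert_allclose(profile.gamma, 0.0, atol=1e-12)

    def test_two_frame_hand_computation(self):
        # 4 fixed alignment atoms + 1 atom displaced by exactly 1 Å
        base = np.array(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3], [1, 1, 1]], float
        )
        frame1 = base.copy()
        frame1[4, 0] += 1.0
        traj = ld.TrajectoryRecord(
            entry_id="H", coordinates=np.stack([base, frame1])
        )
        align = np.arange(4)
        prof = ld.adaptability(traj, align_selection=align)
        # mean of 0 (reference frame) and 1 -> 0.5
        assert prof.gamma[4] == pytest.approx(0.5, abs=1e-12)
        prof_excl = ld.adaptability(
            traj, align_selection=align, include_reference_frame=False
        )
        assert prof_excl.gamma[4] == pytest.approx(1.0, abs=1e-12)

    def test_gamma_nonnegative_and_zero_iff_static(self, toy_trajectory, toy_complex):
        prof = ld.adaptability(toy_trajectory, toy_complex)
        assert np.all(prof.gamma >= 0)
        assert np.all(prof.gamma > 0)  # every atom moves in this fixture

    def test_reference_frame_out_of_range(self, toy_trajectory, toy_complex):
        with pytest.raises(IndexError):
            ld.adaptability(toy_trajectory, toy_complex, reference_frame=999)

    def test_matches_naive_double_loop(self, toy_complex):
        """Vectorized gamma equals a per-atom/per-frame python loop."""
        sigma = np.zeros(toy_complex.n_atoms)
        sigma[toy_complex.ligand_indices] = 0.4
        profile = ld.MobilityProfile(sigma=sigma)
        traj = ld.generate_trajectory(toy_complex, profile, n_frames=20, seed=3)
        align = toy_complex.heavy_indices(toy_complex.protein_indices)
        prof = ld.adaptability(traj, toy_complex, align_selection=align)
        # independent oracle: explicit loops over frames and atoms
        ref = traj.coordinates[0]
        naive = np.zeros(traj.n_atoms)
        for f in range(traj.n_frames):
            fit = ld.superpose(traj.coordinates[f], ref, align)
            moved = fit.transform(traj.coordinates[f])
            for x in range(traj.n_atoms):
                naive[x] += np.sqrt(((ref[x] - moved[x]) ** 2).sum())
        naive /= traj.n_frames
        np.testing.assert_allclose(prof.gamma, naive[prof.atom_indices], atol=1e-10)


class TestRmsf:
    def test_static_zero(self, toy_complex):
        coords = np.repeat(toy_complex.coordinates[None], 4, axis=0)
        traj = ld.TrajectoryRecord(entry_id="S", coordinates=coords)
        np.testing.assert_allclose(ld.rmsf(traj), 0.0, atol=1e-12)

    def test_alternating_displacement_closed_form(self):
        # alignment atoms fixed; one atom alternates ±d about its mean
        d = 0.7
        base = np.array(
            [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [2, 2, 2]], float
        )
        frames = []
        for i in range(40):
            f = base.copy()
            f[4, 0] += d if i % 2 == 0 else -d
            frames.append(f)
        traj = ld.TrajectoryRecord(entry_id="A", coordinates=np.stack(frames))
        out = ld.rmsf(traj, align_selection=np.arange(4))
        assert out[4] == pytest.approx(d, abs=1e-10)

    def test_single_frame_rejected(self, toy_complex):
        traj = ld.TrajectoryRecord(
            entry_id="S", coordinates=toy_complex.coordinates[None]
        )
        with pytest.raises(ld.ValidationError):
            ld.rmsf(traj)

    def test_matches_two_pass_loop_oracle(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(0, 3, (50, 30, 3))
        traj = ld.TrajectoryRecord(entry_id="R", coordinates=coords)
        align = np.arange(30)
        out = ld.rmsf(traj, align_selection=align)
        # naive two-pass oracle on the aligned frames
        aligned = np.stack(
            [
                ld.superpose(coords[f], coords[0], align).transform(coords[f])
                for f in range(50)
            ]
        )
        naive = np.zeros(30)
        for x in range(30):
            mean = aligned[:, x].mean(axis=0)
            acc = 0.0
            for f in range(50):
                acc += ((aligned[f, x] - mean) ** 2).sum()
            naive[x] = np.sqrt(acc / 50)
        np.testing.assert_allclose(out, naive, atol=1e-10)


def test_rigid_motion_invariance(toy_complex):
    """gamma and RMSF are unchanged when one global rigid motion is applied
    uniformly to all frames: the alignment removes it."""
    sigma = np.zeros(toy_complex.n_atoms)
    sigma[toy_complex.ligand_indices] = 0.3
    profile = ld.MobilityProfile(sigma=sigma)
    traj = ld.generate_trajectory(toy_complex, profile, n_frames=15, seed=5)
    rng = np.random.default_rng(6)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-20, 20, 3)
    moved = ld.TrajectoryRecord(
        entry_id="M",
        coordinates=traj.coordinates @ rot.T + shift,
        frame_times=traj.frame_times,
    )
    align = toy_complex.heavy_indices(toy_complex.protein_indices)
    g1 = ld.adaptability(traj, toy_complex, align_selection=align).gamma
    g2 = ld.adaptability(moved, toy_complex, align_selection=align).gamma
    np.testing.assert_allclose(g1, g2, atol=1e-8)
    np.testing.assert_allclose(
        ld.rmsf(traj, align), ld.rmsf(moved, align), atol=1e-8
    )


class TestLigandRmsd:
    def test_reference_frame_zero(self, toy_trajectory, toy_complex):
        assert ld.ligand_rmsd(toy_trajectory, toy_complex)[0] == pytest.approx(
            0.0, abs=1e-10
        )

    def test_rigid_ligand_shift(self, toy_complex):
        base = toy_complex.coordinates
        shifted = base.copy()
        shifted[toy_complex.ligand_indices] += np.array([0, 0, 2.0])
        traj = ld.TrajectoryRecord(
            entry_id="L", coordinates=np.stack([base, shifted])
        )
        out = ld.ligand_rmsd(traj, toy_complex)
        assert out[1] == pytest.approx(2.0, abs=1e-10)

    def test_matches_direct_formula(self, toy_complex):
        profile = ld.MobilityProfile(
            sigma=np.full(toy_complex.n_atoms, 0.2)
        )
        traj = ld.generate_trajectory(toy_complex, profile, n_frames=10, seed=8)
        out = ld.ligand_rmsd(traj, toy_complex)
        protein = toy_complex.heavy_indices(toy_complex.protein_indices)
        lig = toy_complex.ligand_indices
        ref_fit = ld.superpose(traj.coordinates[0], traj.coordinates[0], protein)
        ref = ref_fit.transform(traj.coordinates[0])[lig]
        for f in range(10):
            fit = ld.superpose(traj.coordinates[f], traj.coordinates[0], protein)
            moved = fit.transform(traj.coordinates[f])[lig]
            expected = np.sqrt(((moved - ref) ** 2).sum(axis=1).mean())
            assert out[f] == pytest.approx(expected, abs=1e-10)


class TestComDistance:
    def test_two_single_atoms(self):
        complex_ = make_fixed_frame_complex(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [7, 0, 0]],
            ["C", "C", "C", "O"],
            n_protein=3,
        )
        traj = ld.TrajectoryRecord(
            entry_id="T", coordinates=complex_.coordinates[None]
        )
        # unweighted: protein centroid (1/3, 1/3, 0), ligand (7,0,0)
        out = ld.com_distance(traj, complex_, mass_weighted=False)
        expected = np.linalg.norm([7 - 1 / 3, -1 / 3, 0])
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_coincident_centers(self):
        complex_ = make_fixed_frame_complex(
            [[-1, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 1 / 3, 0]],
            ["C", "C", "C", "C", "C"],
            n_protein=4,
        )
        traj = ld.TrajectoryRecord(
            entry_id="T", coordinates=complex_.coordinates[None]
        )
        out = ld.com_distance(traj, complex_, mass_weighted=False)
        assert out[0] == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_weighted_mean_oracle(self, toy_complex, toy_trajectory):
        out = ld.com_distance(toy_trajectory, toy_complex)
        masses = toy_complex.masses
        for f in [0, 10, 49]:
            coords = toy_trajectory.coordinates[f]
            p = toy_complex.protein_indices
            l = toy_complex.ligand_indices
            com_p = (coords[p] * masses[p, None]).sum(0) / masses[p].sum()
            com_l = (coords[l] * masses[l, None]).sum(0) / masses[l].sum()
            assert out[f] == pytest.approx(
                np.linalg.norm(com_p - com_l), abs=1e-12
            )


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        area = shrake_rupley_sasa(
            np.zeros((1, 3)), np.array(["C"]), probe_radius=1.4,
            n_sphere_points=960,
        )[0]
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_two_sphere_spherical_cap_closed_form(self):
        # two carbons: expanded radii R = 1.70 + 1.4 = 3.10, distance 3.0
        d = 3.0
        R = 1.70 + 1.4
        coords = np.array([[0, 0, 0], [d, 0, 0]], float)
        areas = shrake_rupley_sasa(coords, np.array(["C", "C"]))
        # cap height on each sphere: h = R - d/2 (equal radii)
        h = R - d / 2
        expected_each = 4 * np.pi * R**2 - 2 * np.pi * R * h
        np.testing.assert_allclose(areas, expected_each, rtol=0.015)

    def test_buried_sasa_zero_when_far(self):
        complex_ = make_fixed_frame_complex(
            [[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [100, 0, 0], [101.5, 0, 0]],
            ["C", "C", "C", "C", "O"],
            n_protein=3,
        )
        assert ld.buried_sasa(complex_) == pytest.approx(0.0, abs=1e-9)

    def test_buried_sasa_monotone_along_ray(self, toy_complex):
        values = []
        base = toy_complex.coordinates
        for offset in [0.0, 3.0, 8.0]:
            coords = base.copy()
            coords[toy_complex.ligand_indices] += np.array([0, 0, offset])
            values.append(ld.buried_sasa(toy_complex, coordinates=coords))
        assert values[0] >= values[1] >= values[2]
        assert values[0] > 0

    def test_missing_radius_is_configuration_error(self):
        with pytest.raises(ld.ConfigurationError):
            shrake_rupley_sasa(
                np.zeros((1, 3)), np.array(["C"]), radii={"N": 1.55}
            )

    def test_against_mdtraj_oracle(self):
        """Independent Shrake-Rupley implementation as cross-check."""
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(9)
        n = 8
        coords = rng.uniform(0, 6, (n, 3))
        elements = np.array(["C"] * n)
        mine = shrake_rupley_sasa(coords, elements).sum()
        topo = mdtraj.Topology()
        chain = topo.add_chain()
        res = topo.add_residue("LIG", chain)
        for i in range(n):
            topo.add_atom(f"C{i}", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory(coords[None] / 10.0, topo)  # nm
        theirs = mdtraj.shrake_rupley(traj, n_sphere_points=960).sum() * 100.0
        assert mine == pytest.approx(theirs, rel=0.02)


def test_gamma_rmsf_maxwell_ratio(rigid_alignment_trajectory, toy_complex):
    """With i.i.d. isotropic Gaussian displacements the ratio of
    adaptability to RMSF approaches sqrt(8/(3*pi)) ~ 0.921."""
    traj = rigid_alignment_trajectory
    align = toy_complex.heavy_indices(toy_complex.protein_indices)
    lig = toy_complex.ligand_indices
    gamma = ld.adaptability(traj, align_selection=align, drop_hydrogens=False).gamma
    fluct = ld.rmsf(traj, align_selection=align)
    ratio = gamma[lig].mean() / fluct[lig].mean()
    assert ratio == pytest.approx(np.sqrt(8 / (3 * np.pi)), rel=0.03)
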