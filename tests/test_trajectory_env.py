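"""Frame ingestion, rigid-body fitting and Coulomb potential/field."""

import numpy as np
import pytest

from pmmkit import fixtures, units
from pmmkit.trajectory_env import (
    ClashError,
    EnvironmentSnapshot,
    TrajectoryError,
    assign_charges,
    compute_perturbation,
    electric_field,
    electric_potential,
    fit_rototranslation,
    load_system,
    parse_selection,
    potentials_at_nuclei,
)
from conftest import make_multistate_qc


def rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestSelectionAndLoading:
    @pytest.mark.parametrize("expr,expected", [
        ("1-2", [0, 1]),
        ("1,3", [0, 2]),
        ("2", [1]),
        ("1-2,3", [0, 1, 2]),
        ([3, 1], [0, 2]),
    ])
    def test_parse_selection(self, expr, expected):
        assert parse_selection(expr, 3).tolist() == expected

    def test_selection_out_of_range(self):
        with pytest.raises(TrajectoryError, match="outside 1..3"):
            parse_selection("5", 3)

    def test_three_atom_split(self, tmp_path):
        pdb = tmp_path / "three.pdb"
        lines = [
            "ATOM      1  A   MOL A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  B   MOL A   2       1.000   0.000   0.000  1.00  0.00           C",
            "ATOM      3  C   MOL A   3       0.000   2.000   0.000  1.00  0.00           O",
            "END",
        ]
        pdb.write_text("\n".join(lines) + "\n")
        snaps = list(load_system(pdb, qc_selection="1-2",
                                 charge_source=np.array([0.1, 0.2, -0.3])))
        assert len(snaps) == 1
        assert snaps[0].qc_coords.shape == (2, 3)
        assert snaps[0].env_coords.shape == (1, 3)
        assert snaps[0].env_charges.tolist() == [-0.3]
        # angstrom -> bohr conversion applied
        assert snaps[0].env_coords[0, 1] == pytest.approx(
            units.angstrom_to_bohr(2.0), rel=1e-6)

    def test_frames_yielded_in_order(self, tmp_path):
        traj = fixtures.make_point_charge_trajectory(
            tmp_path, 10, 1.0, ("ramp", 3.0, 6.0))
        snaps = list(load_system(traj.topology, qc_selection="1",
                                 charge_source=traj.charges))
        assert [s.frame_index for s in snaps] == list(range(10))
        dists = [np.linalg.norm(s.env_coords[0] - s.qc_coords[0])
                 for s in snaps]
        assert np.allclose(dists, traj.distances, atol=1e-6)

    def test_charge_length_mismatch(self, tmp_path):
        f = tmp_path / "q.txt"
        f.write_text("0.0\n0.1\n0.2\n0.3\n")
        with pytest.raises(TrajectoryError, match="4 entries.*3 atoms"):
            assign_charges(f, n_atoms=3)

    def test_charges_from_text(self, tmp_path):
        f = tmp_path / "q.txt"
        f.write_text("0.0 -0.5\n0.5\n")
        assert assign_charges(f, n_atoms=3).tolist() == [0.0, -0.5, 0.5]


class TestFit:
    def test_identity(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 2]])
        m = np.array([1.0, 12, 16, 14])
        rot, origin, rmsd = fit_rototranslation(ref, m, ref)
        assert np.abs(rot - np.eye(3)).max() < 1e-10
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        w = m / m.sum()
        assert np.allclose(origin, w @ ref)

    def test_recovers_known_rotation_and_translation(self):
        ref = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1, 0], [0.3, 0.2, 2]])
        m = np.array([1.0, 12, 16, 14])
        applied = rotation_z(np.deg2rad(30.0))
        shift = np.array([2.0, -1.0, 0.5])
        frame = ref @ applied.T + shift
        rot, origin, rmsd = fit_rototranslation(ref, m, frame)
        assert np.abs(rot - applied).max() < 1e-8
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_mirror_image_keeps_proper_rotation(self):
        # chiral 4-atom reference: no proper rotation can match its mirror
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        m = np.array([1.0, 12, 14, 16])
        mirror = ref * np.array([1.0, 1.0, -1.0])
        rot, _, rmsd = fit_rototranslation(ref, m, mirror)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-8)
        assert rmsd > 0.1

    def test_collinear_is_underdetermined(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(TrajectoryError, match="non-collinear"):
            fit_rototranslation(ref, np.ones(3), ref)


class TestCoulomb:
    def test_unit_charge_unit_distance(self):
        v = electric_potential(np.array([[1.0, 0, 0]]), [1.0], np.zeros(3))
        assert v == pytest.approx(1.0)

    def test_symmetric_pair_cancels_potential(self):
        env = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert electric_potential(env, [1.0, -1.0], np.zeros(3)) == \
            pytest.approx(0.0, abs=1e-14)

    def test_charge_two_distance_two(self):
        v = electric_potential(np.array([[2.0, 0, 0]]), [2.0], np.zeros(3))
        assert v == pytest.approx(1.0)

    def test_field_single_charge(self):
        e = electric_field(np.array([[1.0, 0, 0]]), [1.0], np.zeros(3))
        assert np.allclose(e, [-1.0, 0.0, 0.0])

    def test_field_symmetric_pair_adds(self):
        env = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        e = electric_field(env, [1.0, -1.0], np.zeros(3))
        # both contributions point along -x: (-1) + (-1)
        assert np.allclose(e, [-2.0, 0.0, 0.0])

    def test_field_is_negative_gradient_of_potential(self, rng):
        env = rng.normal(scale=4.0, size=(20, 3))
        q = rng.normal(size=20)
        for _ in range(10):
            p = rng.normal(size=3)
            if np.linalg.norm(env - p, axis=1).min() < 0.5:
                continue
            h = 1e-5
            grad = np.empty(3)
            for k in range(3):
                dp = np.zeros(3)
                dp[k] = h
                grad[k] = (electric_potential(env, q, p + dp)
                           - electric_potential(env, q, p - dp)) / (2 * h)
            e = electric_field(env, q, p)
            assert np.abs(e + grad).max() < 1e-6 * max(1.0, np.abs(e).max())

    def test_clash_names_atom(self):
        env = np.array([[0.0, 0, 0], [1e-9, 0, 0]])
        with pytest.raises(ClashError, match="atom 0"):
            electric_potential(env, [1.0, 1.0], np.zeros(3))

    def test_far_field_scaling(self):
        near = electric_potential(np.array([[2.0, 0, 0]]), [1.0], np.zeros(3))
        far = electric_potential(np.array([[4.0, 0, 0]]), [1.0], np.zeros(3))
        assert far == pytest.approx(near / 2)
        e_near = np.linalg.norm(
            electric_field(np.array([[2.0, 0, 0]]), [1.0], np.zeros(3)))
        e_far = np.linalg.norm(
            electric_field(np.array([[4.0, 0, 0]]), [1.0], np.zeros(3)))
        assert e_far == pytest.approx(e_near / 4)


class TestNuclearPotentials:
    def test_zero_environment(self):
        snap = EnvironmentSnapshot(0, np.zeros((2, 3)),
                                   np.array([[5.0, 0, 0]]), [0.0])
        assert np.all(potentials_at_nuclei(snap, np.zeros((2, 3))) == 0)

    def test_equidistant_symmetry(self):
        qc = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        snap = EnvironmentSnapshot(0, qc, np.array([[0.0, 3.0, 0]]), [0.7])
        vn = potentials_at_nuclei(snap, qc)
        assert vn[0] == pytest.approx(vn[1])

    def test_matches_brute_force_sum(self):
        qc = np.array([[0.5, 0, 0], [-0.5, 0.2, 0]])
        env = np.array([[3.0, 1.0, 0.0], [-2.0, -1.0, 1.0]])
        q = np.array([0.4, -0.9])
        snap = EnvironmentSnapshot(0, qc, env, q)
        vn = potentials_at_nuclei(snap, qc)
        for n in range(2):
            manual = sum(q[i] / np.linalg.norm(env[i] - qc[n])
                         for i in range(2))
            assert vn[n] == pytest.approx(manual, rel=1e-12)


class TestPerturbationInvariants:
    def test_global_rotation_invariance(self, rng):
        qc = make_multistate_qc(n_states=3, n_atoms=4, seed=3)
        env = rng.normal(scale=8.0, size=(6, 3))
        q = rng.normal(size=6)
        snap = EnvironmentSnapshot(0, qc.geometry.copy(), env, q)
        base = compute_perturbation(qc, snap)

        rot = rotation_z(0.83) @ np.array(
            [[1, 0, 0], [0, np.cos(0.4), -np.sin(0.4)],
             [0, np.sin(0.4), np.cos(0.4)]])
        snap_rot = EnvironmentSnapshot(
            0, qc.geometry @ rot.T, env @ rot.T, q)
        rotated = compute_perturbation(qc, snap_rot)

        assert rotated.v0 == pytest.approx(base.v0, abs=1e-8)
        assert np.abs(rotated.vn - base.vn).max() < 1e-8
        # reference-frame field is invariant under a global rigid rotation
        assert np.abs(rotated.e0 - base.e0).max() < 1e-8

    def test_zero_charges_give_zero_terms(self):
        qc = make_multistate_qc(n_states=3, n_atoms=4, seed=3)
        snap = EnvironmentSnapshot(
            0, qc.geometry.copy(),
            np.array([[9.0, 0, 0], [0, 9.0, 0]]), [0.0, 0.0])
        terms = compute_perturbation(qc, snap)
        assert terms.v0 == 0.0
        assert np.all(terms.e0 == 0.0)
        assert np.all(terms.vn == 0.0)
        assert np.linalg.det(terms.rotation) == pytest.approx(1.0, abs=1e-8)


class TestPeriodicBoundaries:
    def test_minimum_image_not_double_counted(self, tmp_path):
        # env charge written near the far box face wraps to a short distance
        box = 12.0  # angstrom
        d_written = units.angstrom_to_bohr(11.0)
        traj = fixtures.make_point_charge_trajectory(
            tmp_path, 1, 1.0, d_written, box_angstrom=box)
        snap = next(load_system(traj.topology, qc_selection="1",
                                charge_source=traj.charges))
        assert snap.box is not None
        v = electric_potential(snap.env_coords, snap.env_charges,
                               snap.qc_coords[0], box=snap.box)
        d_image = units.angstrom_to_bohr(box - 11.0)
        # exactly the single-image Coulomb term: the image replaces the
        # written position, it is not added to it
        assert v == pytest.approx(1.0 / d_image, rel=1e-6)

    def test_no_box_means_no_wrapping(self, tmp_path):
        d_written = units.angstrom_to_bohr(11.0)
        traj = fixtures.make_point_charge_trajectory(
            tmp_path, 1, 1.0, d_written)
        snap = next(load_system(traj.topology, qc_selection="1",
                                charge_source=traj.charges))
        assert snap.box is None
        v = electric_potential(snap.env_coords, snap.env_charges,
                               snap.qc_coords[0])
        assert v == pytest.approx(1.0 / traj.distances[0], rel=1e-10)


def test_gro_xtc_round_trip(tmp_path):
    """A real GRO+XTC pair written on the fly loads identically to PDB."""
    import MDAnalysis as mda

    traj = fixtures.make_point_charge_trajectory(
        tmp_path, 5, 1.0, ("ramp", 3.0, 5.0))
    u = mda.Universe(str(traj.topology))
    gro = tmp_path / "sys.gro"
    xtc = tmp_path / "sys.xtc"
    u.atoms.write(str(gro))
    with mda.Writer(str(xtc), n_atoms=len(u.atoms)) as w:
        for ts in u.trajectory:
            w.write(u.atoms)
    snaps = list(load_system(gro, xtc, qc_selection="1",
                             charge_source=traj.charges))
    assert len(snaps) == 5
    dists = [np.linalg.norm(s.env_coords[0] - s.qc_coords[0]) for s in snaps]
    # XTC stores coordinates with ~1e-3 angstrom precision
    assert np.allclose(dists, traj.distances, atol=1e-2)
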