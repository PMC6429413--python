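import numpy as np
import pytest

from hingewatch import nma, structio
from hingewatch.errors import ModeError, ParseError
from hingewatch.essdyn import essential_dynamics
from hingewatch.nma import (
    KB_KJ_PER_MOL_K,
    build_enm_hessian,
    eigendecompose,
    export_hessian,
    frequencies,
    harmonic_trajectory,
    import_hessian,
    mass_weight,
    split_trivial,
    thermal_ensemble,
)
from hingewatch.nmd import read_nmd, write_nmd
from hingewatch.structio import AtomIndexSet

from _oracles import chain_1d_eigenvalues
from conftest import toy_structure


def diatomic(d=3.0, elements=("C", "C")):
    from hingewatch.structio import Atom, Structure, element_mass

    return Structure(
        [
            Atom("A1", elements[0], 1, "ALA", "A", np.array([0.0, 0, 0]), element_mass(elements[0])),
            Atom("A2", elements[1], 2, "ALA", "A", np.array([d, 0, 0]), element_mass(elements[1])),
        ]
    )


class TestEnmHessian:
    def test_diatomic_has_one_stretch_mode(self):
        h = build_enm_hessian(diatomic(), cutoff=5.0, k=1.0)
        lam = np.linalg.eigvalsh(h.matrix)
        assert np.sum(np.abs(lam) < 1e-10) == 5
        # the single stretch eigenvalue of k[[1,-1],[-1,1]] is 2k
        assert lam[-1] == pytest.approx(2.0, abs=1e-10)

    def test_row_sums_vanish(self, small_dimer, small_ca):
        h = build_enm_hessian(small_dimer, small_ca, cutoff=13.0)
        n = h.n_atoms
        # translation invariance: H annihilates uniform translations exactly
        for axis in range(3):
            t = np.zeros(3 * n)
            t[axis::3] = 1.0
            assert np.abs(h.matrix @ t).max() < 1e-10

    def test_collinear_chain_matches_1d_solution(self):
        # 3 collinear atoms, springs between neighbours only: the x-subspace
        # is a 1-D chain; transverse directions contribute zero modes
        s = toy_structure([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        h = mass_weight(build_enm_hessian(s, cutoff=3.0, k=2.5))
        lam = np.sort(np.linalg.eigvalsh(h.matrix))
        oracle = chain_1d_eigenvalues(2.5, s.masses)
        np.testing.assert_allclose(lam[-2:], oracle[-2:], atol=1e-8)
        np.testing.assert_allclose(lam[:7], 0.0, atol=1e-8)

    def test_isolated_atom_warns(self):
        s = toy_structure([[0.0, 0, 0], [1.0, 0, 0], [100.0, 0, 0]])
        with pytest.warns(UserWarning, match="no neighbour"):
            build_enm_hessian(s, cutoff=5.0)


class TestMassWeighting:
    def test_unit_masses_leave_matrix_unchanged(self):
        h = build_enm_hessian(diatomic(), cutoff=5.0)
        hw = mass_weight(h, np.ones(2))
        np.testing.assert_array_equal(hw.matrix, h.matrix)

    def test_uniform_mass_scales_inversely(self):
        h = build_enm_hessian(diatomic(), cutoff=5.0)
        hw = mass_weight(h, np.full(2, 4.0))
        np.testing.assert_allclose(hw.matrix, h.matrix / 4.0, atol=1e-14)

    def test_mixed_masses_give_reduced_mass_eigenvalue(self):
        k = 1.0
        s = diatomic(elements=("C", "O"))
        hw = mass_weight(build_enm_hessian(s, cutoff=5.0, k=k))
        lam = np.linalg.eigvalsh(hw.matrix)
        m1, m2 = s.masses
        mu = m1 * m2 / (m1 + m2)
        assert lam[-1] == pytest.approx(k / mu, abs=1e-8)

    def test_double_weighting_is_an_error(self):
        hw = mass_weight(build_enm_hessian(diatomic(), cutoff=5.0))
        with pytest.raises(ModeError):
            mass_weight(hw)


class TestEigendecomposition:
    def test_diagonal_matrix_recovers_axes(self):
        h = nma.HessianModel(
            matrix=np.diag([1.0, 2.0, 3.0]),
            origin="imported",
            reference_coords=np.zeros((1, 3)),
            masses=np.ones(1),
            mass_weighted=True,
        )
        ms = eigendecompose(h)
        np.testing.assert_allclose(ms.eigenvalues, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(np.abs(ms.eigenvectors), np.eye(3), atol=1e-12)

    def test_diatomic_stretch_vector_is_along_bond(self):
        ms = eigendecompose(mass_weight(build_enm_hessian(diatomic(), cutoff=5.0)))
        stretch = ms.eigenvectors[:, -1].reshape(2, 3)
        # both atomic displacement components lie on the bond (x) axis
        np.testing.assert_allclose(stretch[:, 1:], 0.0, atol=1e-10)

    def test_random_symmetric_matrix_reconstructs(self, rng):
        m = rng.normal(size=(12, 12))
        m = (m + m.T) / 2
        h = nma.HessianModel(
            matrix=m,
            origin="imported",
            reference_coords=rng.normal(size=(4, 3)),
            masses=np.ones(4),
            mass_weighted=True,
        )
        ms = eigendecompose(h)
        rec = ms.eigenvectors @ np.diag(ms.eigenvalues) @ ms.eigenvectors.T
        assert np.abs(rec - m).max() / np.abs(m).max() < 1e-10
        gram = ms.eigenvectors.T @ ms.eigenvectors
        np.testing.assert_allclose(gram, np.eye(12), atol=1e-6)

    def test_eigenvalues_ascending_and_frequencies_monotone(self, small_modes):
        assert np.all(np.diff(small_modes.eigenvalues) >= -1e-12)
        assert np.all(np.diff(small_modes.frequencies) >= -1e-12)


class TestFrequencies:
    def test_closed_forms(self):
        ms = nma.ModeSet(
            eigenvalues=np.array([0.0, 4 * np.pi**2]),
            eigenvectors=np.eye(2),
            reference_coords=np.zeros((1, 3)),
            masses=np.ones(1),
            mass_weighted=True,
        )
        nu = frequencies(ms, unit="native")
        assert nu[0] == 0.0
        assert nu[1] == pytest.approx(1.0, abs=1e-12)

    def test_oscillator_limit(self):
        # k = 1, m = 1: nu = sqrt(k/m) / 2pi
        ms = nma.ModeSet(
            eigenvalues=np.array([1.0]),
            eigenvectors=np.eye(1),
            reference_coords=np.zeros((1, 3)),
            masses=np.ones(1),
            mass_weighted=True,
        )
        assert frequencies(ms)[0] == pytest.approx(1.0 / (2 * np.pi), abs=1e-12)

    def test_large_negative_eigenvalue_rejected(self):
        ms = nma.ModeSet(
            eigenvalues=np.array([-1.0, 1.0]),
            eigenvectors=np.eye(2),
            reference_coords=np.zeros((1, 3)),
            masses=np.ones(1),
            mass_weighted=True,
        )
        with pytest.raises(ModeError):
            frequencies(ms)


class TestTrivialModes:
    def test_connected_network_has_six_null_modes(self, small_modes):
        lam = small_modes.eigenvalues
        assert np.abs(lam[:6]).max() <= 1e-8 * lam[-1]
        assert lam[6] > 1e-6 * lam[-1]

    def test_rigid_body_overlap_of_removed_modes(self, small_modes):
        trivial, nontrivial = split_trivial(small_modes)
        assert np.all(trivial.rigid_body_overlap >= 0.99)
        assert nontrivial.n_modes == small_modes.n_modes - 6

    def test_diatomic_nontrivial_set_has_one_mode(self):
        ms = eigendecompose(mass_weight(build_enm_hessian(diatomic(), cutoff=5.0)))
        _, nontrivial = split_trivial(ms, n_trivial=5)
        assert nontrivial.n_modes == 1


class TestHarmonicTrajectory:
    def test_zero_amplitude_is_static(self, small_dimer, small_ca, small_modes):
        _, nt = split_trivial(small_modes)
        traj = harmonic_trajectory(small_dimer, small_ca, nt, 0, amplitude=0.0, n_frames=8)
        np.testing.assert_array_equal(traj.frames, np.repeat(traj.frames[:1], 8, axis=0))

    def test_quarter_period_displacement_equals_amplitude(self, small_dimer, small_ca, small_modes):
        _, nt = split_trivial(small_modes)
        amp = 2.5
        traj = harmonic_trajectory(small_dimer, small_ca, nt, 0, amplitude=amp, n_frames=40)
        d = nt.cartesian_mode(0)
        np.testing.assert_allclose(traj.frames[10] - nt.reference_coords, amp * d, atol=1e-9)

    def test_pca_of_harmonic_frames_recovers_the_mode(self, small_dimer, small_ca, small_modes):
        from hingewatch.modecmp import inner_product

        _, nt = split_trivial(small_modes)
        traj = harmonic_trajectory(small_dimer, small_ca, nt, 0, amplitude=1.5, n_frames=60)
        pc = essential_dynamics(traj, AtomIndexSet(np.arange(traj.n_atoms)), align=False)
        assert inner_product(pc.eigenvectors[:, 0], nt.cartesian_mode(0).ravel()) > 0.999


class TestThermalEnsemble:
    def test_frame_count_and_reproducibility(self, small_dimer, small_ca, small_modes):
        _, nt = split_trivial(small_modes)
        a = thermal_ensemble(small_dimer, small_ca, nt, 300.0, 250, seed=9)
        b = thermal_ensemble(small_dimer, small_ca, nt, 300.0, 250, seed=9)
        assert a.n_frames == 250
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_zero_temperature_limit_is_static(self, small_dimer, small_ca, small_modes):
        _, nt = split_trivial(small_modes)
        traj = thermal_ensemble(small_dimer, small_ca, nt, 0.0, 10, seed=0)
        assert np.abs(traj.frames - nt.reference_coords[None]).max() <= 1e-12

    def test_single_mode_variance_obeys_equipartition(self, small_dimer, small_ca, small_modes):
        _, nt = split_trivial(small_modes)
        temperature, n_conf = 300.0, 5000
        traj = thermal_ensemble(
            small_dimer, small_ca, nt, temperature, n_conf, seed=11, mode_indices=np.array([0])
        )
        # project displacements back onto the mass-weighted eigenvector
        disp = (traj.frames - nt.reference_coords).reshape(n_conf, -1)
        q_cart = np.sqrt(np.repeat(nt.masses, 3)) * nt.eigenvectors[:, 0]
        var = (disp @ q_cart).var()
        expected = KB_KJ_PER_MOL_K * temperature / nt.eigenvalues[0]
        assert var == pytest.approx(expected, rel=0.05)

    def test_trivial_modes_are_rejected(self, small_dimer, small_ca, small_modes):
        with pytest.raises(ModeError):
            thermal_ensemble(small_dimer, small_ca, small_modes, 300.0, 10, seed=0)


class TestHessianImportExport:
    def test_round_trip_preserves_mode_set(self, tmp_path, small_dimer, small_ca):
        h = build_enm_hessian(small_dimer, small_ca, cutoff=13.0)
        path = tmp_path / "h.txt"
        export_hessian(h, path)
        back = import_hessian(path, small_dimer, small_ca)
        ms_a = eigendecompose(mass_weight(h))
        ms_b = eigendecompose(mass_weight(back))
        np.testing.assert_allclose(ms_b.eigenvalues, ms_a.eigenvalues, atol=1e-10)

    def test_wrong_size_is_an_error(self, tmp_path, small_dimer, small_ca):
        path = tmp_path / "h.txt"
        structio.write_matrix(np.eye(5), path)
        with pytest.raises(ParseError, match="expected"):
            import_hessian(path, small_dimer, small_ca)

    def test_asymmetry_beyond_tolerance_is_an_error(self, tmp_path):
        s = toy_structure([[0.0, 0, 0], [3.0, 0, 0]])
        m = np.eye(6)
        m[0, 1] = 0.5
        path = tmp_path / "h.txt"
        structio.write_matrix(m, path)
        with pytest.raises(ParseError, match="asymmetry"):
            import_hessian(path, s)


class TestNmdExport:
    def test_round_trip_recovers_vectors(self, tmp_path, small_dimer, small_ca, small_modes):
        _, nt = split_trivial(small_modes)
        sub = structio.substructure(small_dimer, small_ca)
        modes = [
            (7 + i, float(1.0 / np.sqrt(nt.eigenvalues[i])), nt.cartesian_mode(i))
            for i in range(3)
        ]
        path = tmp_path / "modes.nmd"
        write_nmd(path, "toy modes", nt.reference_coords, modes, structure=sub)
        back = read_nmd(path)
        np.testing.assert_allclose(back["coordinates"], nt.reference_coords, atol=1e-6)
        assert [m[0] for m in back["modes"]] == [7, 8, 9]
        for (_, _, vec), (_, _, orig) in zip(back["modes"], modes):
            np.testing.assert_allclose(vec, orig, atol=1e-6)
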