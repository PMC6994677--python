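import numpy as np
import pytest

import nsefold.rigid_body_modes as rb
from nsefold.nse_core import EffectiveDiffusionCurve
from nsefold.synthetic_data import write_synthetic_pdb


def mc_first_cumulant(system, q_values, n_samples=100_000, seed=7):
    """Monte-Carlo orientation-average oracle for the rigid-body cumulant."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_samples, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pos, b, dmat = system.positions, system.b, system.diffusion_matrix
    out = []
    for qi in np.atleast_1d(q_values):
        qvec = qi * dirs
        phase = np.exp(1j * (qvec @ pos.T))
        cross = np.cross(qvec[:, None, :], pos[None, :, :])
        v = np.concatenate([np.broadcast_to(qvec[:, None, :], cross.shape),
                            cross], axis=-1)
        w = np.einsum("oj,ojk->ok", b * phase, v)
        num = np.einsum("ok,kl,ol->o", np.conj(w), dmat, w).real
        den = np.mean(np.abs(phase @ b) ** 2)
        out.append(np.mean(num) / (qi**2 * den))
    return np.array(out)


class TestReadCoordinates:
    def test_minimal_fixture(self, tmp_path):
        path = tmp_path / "wm.pdb"
        write_synthetic_pdb(path, "water_methane")
        centers = rb.read_coordinates(path, include_hetero=True)
        assert len(centers) == 4
        assert centers[0].b == pytest.approx(rb.COHERENT_B["O"])
        assert centers[1].b == pytest.approx(rb.COHERENT_B["H"])

    def test_labile_hydrogen_deuterated(self, tmp_path):
        path = tmp_path / "wm.pdb"
        write_synthetic_pdb(path, "water_methane")
        centers = rb.read_coordinates(path, deuterate_labile=True,
                                      include_hetero=True)
        # the O-bound hydrogen exchanges, the C-bound one does not
        assert centers[1].b == pytest.approx(rb.COHERENT_B["D"])
        assert centers[3].b == pytest.approx(rb.COHERENT_B["H"])

    def test_residue_coarse_graining(self, tmp_path):
        path = tmp_path / "helix.pdb"
        write_synthetic_pdb(path, "mini_helix")
        centers = rb.read_coordinates(path, coarse_grain_residues=True)
        assert len(centers) == 12
        expected_b = (rb.COHERENT_B["N"] + 2 * rb.COHERENT_B["C"]
                      + rb.COHERENT_B["O"])
        assert centers[0].b == pytest.approx(expected_b)

    def test_empty_pdb_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            rb.read_coordinates(path)

    def test_unknown_element_reported(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  XX  UNK A   1       0.000   0.000   0.000"
            "  1.00  0.00           X\nEND\n")
        with pytest.raises(ValueError, match="unknown element"):
            rb.read_coordinates(path)


class TestFormFactor:
    def test_single_center_is_b_squared(self):
        c = [rb.ScatteringCenter(np.zeros(3), 6.6)]
        ft = rb.form_factor(c, np.linspace(0.01, 0.5, 10))
        np.testing.assert_allclose(ft.F, 6.6**2, rtol=1e-12)

    def test_dumbbell_closed_form(self, fixtures):
        centers = fixtures.coordinates("dumbbell", b=2.0)
        q = np.linspace(0.01, 0.4, 30)
        ft = rb.form_factor(centers, q)
        d = 20.0
        expected = 2 * 4.0 * (1 + np.sin(q * d) / (q * d))
        np.testing.assert_allclose(ft.F, expected, rtol=1e-12)

    def test_forward_limit(self, fixtures):
        centers = fixtures.coordinates("tetrahedron", b=3.0)
        ft = rb.form_factor(centers, np.array([1e-6]))
        assert ft.F[0] == pytest.approx((4 * 3.0) ** 2, rel=1e-8)

    def test_quadrature_agrees_with_debye(self, fixtures):
        centers = fixtures.coordinates("tetrahedron")
        q = np.linspace(0.02, 0.3, 8)
        exact = rb.form_factor(centers, q)
        quad = rb.form_factor(centers, q, n_orientations=4000)
        np.testing.assert_allclose(quad.F, exact.F, rtol=5e-3)


class TestRigidBodyCumulant:
    def test_isotropic_translation_is_flat(self, fixtures):
        system = rb.RigidBodySystem(
            fixtures.coordinates("dumbbell"),
            fixtures.diffusion_matrix("isotropic", d_trans=2.5))
        q = np.linspace(0.02, 0.25, 6)
        d0 = rb.rigid_body_Dq(system, q, n_orientations=300,
                              convergence_check=False)
        np.testing.assert_allclose(d0, 2.5, rtol=1e-10)

    def test_low_q_limit_is_mean_translation(self, fixtures):
        dmat = fixtures.diffusion_matrix("axial_dumbbell", d_trans=2.0,
                                         d_rot=0.01)
        system = rb.RigidBodySystem(fixtures.coordinates("dumbbell"), dmat)
        d0 = rb.rigid_body_Dq(system, np.array([1e-4]),
                              n_orientations=400, convergence_check=False)
        assert d0[0] == pytest.approx(np.trace(dmat[:3, :3]) / 3.0,
                                      rel=1e-4)

    def test_matches_monte_carlo_oracle(self, fixtures):
        system = rb.RigidBodySystem(
            fixtures.coordinates("dumbbell"),
            fixtures.diffusion_matrix("axial_dumbbell", d_trans=2.0,
                                      d_rot=0.01))
        q = np.array([0.05, 0.1, 0.2])
        quad = rb.rigid_body_Dq(system, q, n_orientations=500,
                                convergence_check=False)
        mc = mc_first_cumulant(system, q)
        np.testing.assert_allclose(quad, mc, rtol=5e-3)

    def test_rotation_adds_apparent_mobility(self, fixtures):
        centers = fixtures.coordinates("dumbbell")
        base = fixtures.diffusion_matrix("isotropic", d_trans=2.0)
        rot = base.copy()
        rot[3:, 3:] = 0.02 * np.eye(3)
        q = np.linspace(0.05, 0.25, 5)
        d_rot = rb.rigid_body_Dq(rb.RigidBodySystem(centers, rot), q,
                                 n_orientations=300,
                                 convergence_check=False)
        assert np.all(d_rot > 2.0)

    def test_coarse_quadrature_warns(self, fixtures):
        system = rb.RigidBodySystem(
            fixtures.coordinates("dumbbell"),
            fixtures.diffusion_matrix("axial_dumbbell", d_trans=2.0,
                                      d_rot=0.05))
        with pytest.warns(UserWarning, match="quadrature"):
            rb.rigid_body_Dq(system, np.array([0.3]), n_orientations=4)


class TestElasticNetwork:
    def test_six_zero_modes_for_connected_cluster(self, fixtures):
        modes = rb.enm_modes(fixtures.coordinates("tetrahedron"),
                             cutoff=40.0)
        assert np.all(modes.eigenvalues[:6] < 1e-8 * modes.eigenvalues[6])
        assert modes.eigenvalues[6] > 0

    def test_two_bead_analytic_frequency(self):
        centers = [rb.ScatteringCenter([0.0, 0.0, 0.0], 1.0),
                   rb.ScatteringCenter([0.0, 0.0, 5.0], 1.0)]
        k, m = 3.0, 110.0
        modes = rb.enm_modes(centers, cutoff=10.0, spring_constant=k,
                             mean_mass=m)
        nonzero = modes.eigenvalues[modes.eigenvalues > 1e-10]
        assert len(nonzero) == 1
        assert nonzero[0] == pytest.approx(2 * k / m, rel=1e-10)

    def test_eigenvectors_orthonormal(self, fixtures):
        modes = rb.enm_modes(fixtures.coordinates("chain20"), cutoff=20.0)
        mat = modes.eigenvectors.reshape(len(modes.eigenvalues), -1)
        np.testing.assert_allclose(mat @ mat.T,
                                   np.eye(len(modes.eigenvalues)),
                                   atol=1e-10)

    def test_disconnected_network_raises(self):
        centers = [rb.ScatteringCenter([0, 0, 0], 1.0),
                   rb.ScatteringCenter([0, 0, 3.0], 1.0),
                   rb.ScatteringCenter([0, 0, 100.0], 1.0),
                   rb.ScatteringCenter([0, 3.0, 100.0], 1.0)]
        with pytest.raises(ValueError, match="disconnected"):
            rb.enm_modes(centers, cutoff=10.0)


class TestModeDiffusion:
    def test_zero_amplitude_gives_zero(self, fixtures):
        centers = fixtures.coordinates("tetrahedron")
        modes = rb.enm_modes(centers, cutoff=40.0)
        q = np.linspace(0.05, 0.3, 5)
        d = rb.mode_effective_diffusion(centers, modes.vector(7), 1.0, 0.0,
                                        q, n_orientations=200)
        np.testing.assert_array_equal(d, 0.0)

    def test_single_center_translation_reduces_analytically(self):
        # one center at the origin: D = λ·k·⟨(q̂·e)²⟩ = λk/3, q-independent
        centers = [rb.ScatteringCenter(np.zeros(3), 5.0)]
        e = np.array([[0.0, 0.0, 1.0]])
        q = np.linspace(0.05, 0.3, 5)
        d = rb.mode_effective_diffusion(centers, e, 2.0, 3.0, q,
                                        n_orientations=20000)
        np.testing.assert_allclose(d, 2.0 * 3.0 / 3.0, rtol=2e-3)

    def test_sign_flip_invariance(self, fixtures):
        centers = fixtures.coordinates("tetrahedron")
        modes = rb.enm_modes(centers, cutoff=40.0)
        q = np.linspace(0.05, 0.3, 5)
        d_plus = rb.mode_effective_diffusion(centers, modes.vector(7),
                                             1.0, 1.0, q, 300)
        d_minus = rb.mode_effective_diffusion(centers, -modes.vector(7),
                                              1.0, 1.0, q, 300)
        np.testing.assert_allclose(d_plus, d_minus, rtol=1e-12)

    def test_matches_monte_carlo_oracle(self, fixtures):
        centers = fixtures.coordinates("tetrahedron")
        modes = rb.enm_modes(centers, cutoff=40.0)
        e = modes.vector(7)
        pos = np.stack([c.position for c in centers])
        b = np.array([c.b for c in centers])
        q = np.array([0.08, 0.15, 0.25])
        quad = rb.mode_effective_diffusion(centers, e, 1.5, 2.0, q,
                                           n_orientations=500)
        rng = np.random.default_rng(11)
        dirs = rng.normal(size=(100_000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        mc = []
        for qi in q:
            qv = qi * dirs
            acc = np.zeros(len(dirs), dtype=complex)
            for j in range(len(centers)):
                acc += b[j] * np.exp(-1j * (qv @ pos[j])) * (qv @ e[j])
            num = np.mean(np.abs(acc) ** 2)
            den = np.mean(np.abs(
                np.exp(1j * (qv @ pos.T)) @ b) ** 2)
            mc.append(1.5 * 2.0 * num / (qi**2 * den))
        np.testing.assert_allclose(quad, mc, rtol=5e-3)


class TestInternalResidual:
    def test_identical_curves_give_zero(self):
        q = np.linspace(0.05, 0.2, 8)
        d0 = 2.0 + 3.0 * q
        measured = EffectiveDiffusionCurve(q, d0, 0.1 * np.ones_like(q))
        delta, _, frac = rb.internal_dynamics_residual(measured, q, d0)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)
        assert frac == pytest.approx(0.0, abs=1e-12)

    def test_twenty_percent_excess(self):
        q = np.linspace(0.05, 0.2, 8)
        d0 = 2.0 + 3.0 * q
        measured = EffectiveDiffusionCurve(q, 1.2 * d0,
                                           0.1 * np.ones_like(q))
        _, _, frac = rb.internal_dynamics_residual(measured, q, d0)
        assert frac == pytest.approx(1.0 / 6.0, rel=1e-10)

    def test_mode_injection_closure(self, fixtures):
        system = rb.RigidBodySystem(
            fixtures.coordinates("tetrahedron"),
            fixtures.diffusion_matrix("globular", d_trans=6.0, d_rot=0.01))
        q = np.linspace(0.05, 0.25, 10)
        d0 = rb.rigid_body_Dq(system, q, n_orientations=400,
                              convergence_check=False)
        modes = rb.enm_modes(fixtures.coordinates("tetrahedron"),
                             cutoff=40.0)
        d7 = rb.mode_effective_diffusion(
            fixtures.coordinates("tetrahedron"), modes.vector(7), 1.0,
            modes.amplitude(7), q, n_orientations=400)
        d7 = d7 * (0.2 * d0.mean() / d7.mean())
        measured = EffectiveDiffusionCurve(q, d0 + d7,
                                           0.01 * np.ones_like(q))
        delta, _, _ = rb.internal_dynamics_residual(measured, q, d0)
        np.testing.assert_allclose(delta, d7, rtol=1e-8)


class TestDiffusionMatrixIO:
    def test_roundtrip(self, tmp_path, fixtures):
        mat = fixtures.diffusion_matrix("axial_dumbbell")
        path = tmp_path / "dmat.dat"
        np.savetxt(path, mat, header="units = A^2/ns, rad^2/ns")
        back = rb.read_diffusion_matrix(path)
        np.testing.assert_allclose(back, mat)

    def test_wrong_shape_rejected(self, tmp_path):
        path = tmp_path / "bad.dat"
        np.savetxt(path, np.eye(3))
        with pytest.raises(ValueError):
            rb.read_diffusion_matrix(path)

    def test_asymmetric_matrix_rejected(self, fixtures):
        mat = fixtures.diffusion_matrix("isotropic")
        mat[0, 1] = 0.5
        with pytest.raises(ValueError):
            rb.RigidBodySystem(fixtures.coordinates("dumbbell"), mat)
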