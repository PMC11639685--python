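"""Structural kernels: frames, Lee-Sacks energy, penalties, contact, friction."""

import numpy as np
import pytest

from thvforge import kernels as K
from thvforge import nurbs
from thvforge.config import LeeSacksParams


LEAFLET = LeeSacksParams(
    c0=117.1375, c1=41.4347, c2=109.7423, c3=132.4545, w=0.9883, fiber_angle_deg=45
)
SKIRT = LeeSacksParams(c0=117.1375, c1=60.3991, c2=92.4784, w=1.0)


def straight_radial_curve():
    pts = np.array([[13, 0, 0], [13, 0, 1], [13, 0, 2], [13, 0, 3.0]])
    return nurbs.interpolate_curve(pts)


class TestPhiHat:
    def test_reference_azimuths(self):
        np.testing.assert_allclose(K.phi_hat(0), [0, 1, 0], atol=1e-15)
        np.testing.assert_allclose(K.phi_hat(90), [-1, 0, 0], atol=1e-15)

    @pytest.mark.parametrize("phi", [-180, -37.5, 0, 12, 90, 123.4])
    def test_unit_norm(self, phi):
        assert np.linalg.norm(K.phi_hat(phi)) == pytest.approx(1.0, abs=1e-15)


class TestSectionFrame:
    def test_vertical_tangent_at_phi_zero(self):
        v1, v2, v3 = K.section_frame(straight_radial_curve(), 0.5)
        np.testing.assert_allclose(v1, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(v2, [-1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(v3, [0, -1, 0], atol=1e-12)

    def test_orthonormal_along_fixture_stents(self, stent_curve_a, stent_curve_b):
        for curve in (stent_curve_a, stent_curve_b):
            for u in np.linspace(0.01, 0.99, 200):
                v1, v2, v3 = K.section_frame(curve, u)
                M = np.array([v1, v2, v3])
                np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-10)

    def test_azimuthal_tangent_is_degenerate(self):
        # tangent along phi_hat at the evaluation point
        pts = np.array([[1, -1, 0], [1, 0, 0], [1, 1, 0], [1, 2, 0.0]])
        c = nurbs.interpolate_curve(pts)
        # the curve crosses y = 0 at u = 1/3 with tangent along +y = phi_hat(0)
        with pytest.raises(K.DegenerateFrameError):
            K.section_frame(c, 1.0 / 3.0)


class TestMappingOperator:
    def test_identity(self):
        np.testing.assert_allclose(
            K.mapping_operator([1, 0, 0], [1, 0, 0]), np.eye(3), atol=1e-15
        )

    def test_quarter_rotation_about_e3(self):
        R = K.mapping_operator([1, 0, 0], [0, 1, 0])
        expected = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        np.testing.assert_allclose(R, expected, atol=1e-15)

    def test_maps_a_to_b_for_random_unit_pairs(self, rng):
        for _ in range(50):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
            R = K.mapping_operator(a, b)
            assert np.linalg.norm(R @ a - b) <= 1e-12
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)

    def test_antiparallel_rejected(self):
        with pytest.raises(ValueError, match="antiparallel"):
            K.mapping_operator([1, 0, 0], [-1, 0, 0])


class TestPropagateFrames:
    def test_straight_curve_constant_frame(self):
        c = straight_radial_curve()
        ff = K.propagate_frames(c, np.linspace(0, 1, 20))
        assert np.abs(ff.v2 - ff.v2[0]).max() < 1e-12
        assert np.abs(ff.v3 - ff.v3[0]).max() < 1e-12

    def test_planar_arc_parallel_transport(self):
        arc = nurbs.arc_through_points(
            [1, 0, 0], [np.cos(np.pi / 4), np.sin(np.pi / 4), 0], [0, 1, 0]
        )
        ff = K.propagate_frames(arc, np.linspace(0, 1, 200))
        # a 90-degree planar sweep rotates the transported frame by 90 degrees
        # about the plane normal
        R = K.rotation_about([0, 0, 1], 90.0)
        np.testing.assert_allclose(ff.v2[-1], R @ ff.v2[0], atol=1e-6)
        np.testing.assert_allclose(ff.v3[-1], R @ ff.v3[0], atol=1e-6)

    def test_theta_180_flips_section_vectors(self):
        c = straight_radial_curve()
        base = K.propagate_frames(c, np.linspace(0, 1, 5))
        flip = K.propagate_frames(c, np.linspace(0, 1, 5), theta0_deg=180.0)
        np.testing.assert_allclose(flip.v2, -base.v2, atol=1e-12)
        np.testing.assert_allclose(flip.v3, -base.v3, atol=1e-12)

    def test_orthonormal_along_fixture_stents(self, stent_curve_a, stent_curve_b):
        for curve in (stent_curve_a, stent_curve_b):
            ff = K.propagate_frames(curve, np.linspace(0, 1, 10_000))
            assert ff.orthonormality_residual() <= 1e-10


class TestLeeSacks:
    def test_zero_at_reference_state(self):
        assert K.lee_sacks_energy(3.0, 1.0, LEAFLET) == 0.0
        assert K.lee_sacks_energy(3.0, 1.0, SKIRT) == 0.0

    def test_leaflet_energy_frozen_value(self):
        # independent scalar evaluation of the energy formula:
        # 117.1375/2*0.1 + 41.4347/2*(0.9883 e^{109.7423*0.01} + 0.0117 - 1)
        assert K.lee_sacks_energy(3.1, 1.0, LEAFLET) == pytest.approx(
            46.733780529646, rel=1e-12
        )

    def test_isotropic_limit_has_no_fiber_dependence(self):
        d1a, d4a = K.lee_sacks_derivatives(3.2, 1.1, SKIRT)
        d1b, d4b = K.lee_sacks_derivatives(3.2, 1.7, SKIRT)
        assert d4a == 0.0 and d4b == 0.0
        assert K.lee_sacks_energy(3.2, 1.1, SKIRT) == K.lee_sacks_energy(3.2, 1.7, SKIRT)

    @pytest.mark.parametrize("I1, I4", [(3.05, 1.02), (3.2, 0.95), (3.3, 1.15)])
    def test_analytic_derivatives_match_finite_differences(self, I1, I4):
        h = 1e-6
        d1, d4 = K.lee_sacks_derivatives(I1, I4, LEAFLET)
        fd1 = (
            K.lee_sacks_energy(I1 + h, I4, LEAFLET)
            - K.lee_sacks_energy(I1 - h, I4, LEAFLET)
        ) / (2 * h)
        fd4 = (
            K.lee_sacks_energy(I1, I4 + h, LEAFLET)
            - K.lee_sacks_energy(I1, I4 - h, LEAFLET)
        ) / (2 * h)
        assert d1 == pytest.approx(fd1, rel=1e-6)
        assert d4 == pytest.approx(fd4, rel=1e-6)

    def test_invariant_caps_warn(self):
        with pytest.warns(UserWarning, match="caps"):
            K.lee_sacks_energy(20.0, 1.0, LEAFLET)


class TestShellStiffness:
    def test_incompressible_value(self):
        assert K.effective_shell_stiffness(117.1375, 0.5) == pytest.approx(351.4125)

    def test_nu_zero(self):
        assert K.effective_shell_stiffness(10.0, 0.0) == 20.0

    def test_monotone(self):
        assert K.effective_shell_stiffness(2.0, 0.3) > K.effective_shell_stiffness(1.0, 0.3)
        assert K.effective_shell_stiffness(1.0, 0.4) > K.effective_shell_stiffness(1.0, 0.3)


class TestPenalties:
    def test_unit_inputs(self):
        a_d, a_r = K.penalty_ss(1.0, 1.0, 1.0, 0.0, 1000.0)
        assert a_d == pytest.approx(1000.0)
        assert a_r == pytest.approx(1000.0 / 12.0)

    def test_rotation_displacement_ratio_identity(self, rng):
        for _ in range(20):
            E, H, h, nu, al = rng.uniform(0.1, 10, 5)
            nu = min(nu / 12, 0.49)
            a_d, a_r = K.penalty_ss(E, H, h, nu, al)
            assert a_r / a_d == pytest.approx(H**2 / 12.0, rel=1e-14)

    def test_incompressible_shell_case(self):
        a_d, _ = K.penalty_ss(2.0, 3.0, 4.0, 0.5, 10.0)
        assert a_d == pytest.approx(10.0 * 2.0 * 3.0 / (0.75 * 4.0))

    def test_homogeneous_degree_one_in_modulus(self):
        a1 = K.penalty_ss(1.0, 0.33, 0.5, 0.5, 1e3)[0]
        a2 = K.penalty_ss(7.0, 0.33, 0.5, 0.5, 1e3)[0]
        assert a2 == pytest.approx(7 * a1, rel=1e-14)
        b1 = K.penalty_sb(1.0, 0.33, 1.0, 0.5, 1.0, 0.1134, 1.0, 0.33, 1e4)[0]
        b2 = K.penalty_sb(7.0, 0.33, 1.0, 0.5, 7.0, 0.1134, 1.0, 0.33, 1e4)[0]
        assert b2 == pytest.approx(7 * b1, rel=1e-14)

    def test_soft_shell_branch_selected(self):
        E_sh = K.effective_shell_stiffness(117.1375, 0.5)  # tissue scale, kPa
        val, branch = K.penalty_sb(
            E_sh, 0.33, 1.0, 0.5, 58.0e6, 0.54 * 0.21, 1.0, 0.33, 1e4
        )
        assert branch == "shell"
        beam_branch = 58.0e6 * np.sqrt(0.1134) / (1.0 * (1 - 0.33**2))
        shell_branch = E_sh * 0.33 / (1.0 * 0.75)
        assert beam_branch / shell_branch > 1e4  # orders of magnitude apart
        assert val == pytest.approx(1e4 * shell_branch)

    def test_equal_branches_give_same_value(self):
        val, _ = K.penalty_sb(1.0, 1.0, 1.0, 0.0, 1.0, 1.0, 1.0, 0.0, 5.0)
        assert val == pytest.approx(5.0)


class TestContactFriction:
    def test_linear_ramp_value(self):
        assert K.contact_kernel(0.4, 2.0, 1.0) == pytest.approx(-1.2)

    def test_zero_at_and_beyond_cutoff(self):
        assert K.contact_kernel(1.0, 2.0, 1.0) == 0.0
        assert K.contact_kernel(5.0, 2.0, 1.0) == 0.0

    def test_piecewise_linear_nonpositive_nonincreasing(self):
        rs = np.linspace(0, 1, 21)
        vals = np.array([K.contact_kernel(r, 2.0, 1.0) for r in rs])
        assert np.all(vals <= 0)
        assert np.all(np.diff(vals) >= -1e-15 + 0)  # nondecreasing toward zero
        slopes = np.diff(vals) / np.diff(rs)
        np.testing.assert_allclose(slopes, 2.0, atol=1e-12)

    def test_no_slip_since_deployment_gives_zero(self):
        x_be, x_so = [0.3, 0.1, 0.0], [0.0, 0.0, 0.0]
        n = np.array([0, 0, 1.0])
        f = K.friction_force(x_be, x_so, x_be, x_so, n, n, 1e11, 2.0, 1.0)
        np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_inactive_beyond_cutoff(self):
        f = K.friction_force(
            [5, 0, 0], [0, 0, 0], [5.1, 0, 0], [0, 0, 0], [0, 0, 1], [0, 0, 1],
            1e11, 2.0, 1.0,
        )
        np.testing.assert_allclose(f, 0.0)

    def test_force_perpendicular_to_wall_normal(self):
        n = np.array([0, 0, 1.0])
        f = K.friction_force(
            [0.3, 0.2, 0.1], [0, 0, 0], [0.1, 0.05, 0.1], [0, 0, 0], n, n,
            1e11, 2.0, 1.0,
        )
        assert abs(np.dot(f, n)) <= 1e-12 * np.linalg.norm(f)
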