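"""Eigenvectors, bilinear normalization, g-coefficients and the Hopf
classification, validated against derivative oracles applied to the raw
sigmoid vector field and against direct delay simulation."""

import numpy as np
import pytest

import betaloop as bl
from betaloop.model_core import Linearization
from betaloop.normal_form import (
    bilinear_pairing,
    center_manifold_terms,
    classify_hopf,
    g21_coefficient,
    g_second_order,
    hopf_eigenvectors,
    normal_form_coefficients,
)

from conftest import char_matrix, dir2c, dir3c


@pytest.fixture(scope="module")
def ev3(lin3, report3):
    return hopf_eigenvectors(lin3, report3.delays.T0, report3.delays.omega0)


@pytest.fixture(scope="module")
def nf3(report3):
    rep = bl.extend_report(report3)
    return rep.normal_form


class TestEigenvectors:
    def test_right_eigen_identity(self, ev3, lin3, report3):
        M = char_matrix(1j * report3.delays.omega0, report3.delays.T0, lin3)
        assert np.linalg.norm(M @ ev3.q0) < 1e-9

    def test_adjoint_identity(self, ev3, lin3, report3):
        """v-bar is a left null vector of the characteristic matrix."""
        M = char_matrix(1j * report3.delays.omega0, report3.delays.T0, lin3)
        res = np.linalg.norm(np.conj(ev3.v) @ M) / np.linalg.norm(ev3.v)
        assert res < 1e-9

    def test_bg_crossing_has_silent_cortex(self, ev3):
        """For the STN-GPe crossing the cortical components of the right
        eigenvector vanish (the cortex receives no BG feedback)."""
        assert ev3.loop == 1
        assert abs(ev3.beta) < 1e-8
        assert abs(ev3.gamma) < 1e-8

    def test_normalization(self, ev3, lin3):
        one = bilinear_pairing(ev3, lin3, ev3.q0, ev3.omega0)
        zero = bilinear_pairing(ev3, lin3, np.conj(ev3.q0), -ev3.omega0)
        scale = np.linalg.norm(ev3.v) * np.linalg.norm(ev3.q0) / abs(ev3.rho_bar)
        assert one == pytest.approx(1.0, abs=1e-9 * max(1.0, scale))
        assert abs(zero) < 1e-9 * max(1.0, scale)

    def test_svd_nullspace_oracle(self, ev3, lin3, report3):
        """q0 is parallel to the smallest singular vector of the
        characteristic matrix."""
        M = char_matrix(1j * report3.delays.omega0, report3.delays.T0, lin3)
        _, s, Vh = np.linalg.svd(M)
        assert s[-1] < 1e-9
        vnull = np.conj(Vh[-1])
        vnull = vnull / vnull[0] if abs(vnull[0]) > 1e-12 else vnull
        q = ev3.q0 / ev3.q0[0]
        # compare directions (components 3,4 are ~0 for a BG crossing)
        assert np.allclose(q[:2], vnull[:2], atol=1e-7)


class TestSecondOrder:
    def test_g_coefficients_match_directional_derivatives(self, p3, ev3, lin3, report3):
        """g20/g11/g02 from the closed quadratic forms equal the projected
        second directional derivatives of the raw sigmoid vector field."""
        eq = bl.solve_equilibrium(p3)
        T0, w0 = report3.delays.T0, report3.delays.omega0
        qd = ev3.q0 * np.exp(-1j * w0 * T0)
        wts = ev3.weights
        g20, g11, g02 = g_second_order(ev3, lin3)
        d_qq = dir2c(p3, eq.u0, qd, qd)
        d_qqb = dir2c(p3, eq.u0, qd, np.conj(qd))
        d_qbqb = dir2c(p3, eq.u0, np.conj(qd), np.conj(qd))
        assert g20 == pytest.approx(T0 * np.sum(wts * d_qq), rel=1e-5)
        assert g11 == pytest.approx(T0 * np.sum(wts * d_qqb), rel=1e-5)
        assert g02 == pytest.approx(T0 * np.sum(wts * d_qbqb), rel=1e-5)

    def test_conjugation_rule(self, ev3, lin3):
        """The z-bar^2 coefficient is the conjugate of the z^2 one
        population-wise, hence g02 = conj(g20) up to the projection
        weights; with the common weight factored the identity is exact
        per component."""
        rows = lin3.input_rows
        a = rows @ (ev3.q0 * np.exp(-1j * ev3.omega0 * ev3.T0))
        per_pop_z2 = 2.0 * lin3.c_vec * a * a
        per_pop_zb2 = 2.0 * lin3.c_vec * np.conj(a) * np.conj(a)
        assert np.allclose(per_pop_zb2, np.conj(per_pop_z2), rtol=1e-12)


def _zero_quadratic(lin: Linearization) -> Linearization:
    import dataclasses

    return dataclasses.replace(lin, c_S=0.0, c_G=0.0, c_E=0.0, c_I=0.0)


class TestCenterManifold:
    def test_zero_curvature_gives_zero_corrections(self, ev3, lin3):
        lin0 = _zero_quadratic(lin3)
        g20, g11, g02 = g_second_order(ev3, lin0)
        assert g20 == g11 == g02 == 0
        E1, E2, W20m1, W11m1 = center_manifold_terms(ev3, lin0, g20, g11, g02)
        assert np.allclose(E1, 0) and np.allclose(E2, 0)
        assert np.allclose(W20m1, 0) and np.allclose(W11m1, 0)

    def test_linear_solve_residuals(self, ev3, lin3, report3):
        g20, g11, g02 = g_second_order(ev3, lin3)
        E1, E2, _, _ = center_manifold_terms(ev3, lin3, g20, g11, g02)
        T0, w0 = report3.delays.T0, report3.delays.omega0
        rows = lin3.input_rows
        a0 = rows @ ev3.q0
        F2 = lin3.c_vec * a0 * a0
        F11 = (lin3.c_vec * a0 * np.conj(a0)).real
        e2 = np.exp(-2j * w0 * T0)
        M1 = 2j * w0 * np.eye(4) - lin3.B1 - lin3.B2 * e2
        assert np.linalg.norm(M1 @ E1 - 2.0 * e2 * F2) < 1e-10
        assert np.linalg.norm(-(lin3.B1 + lin3.B2) @ E2 - 2.0 * F11) < 1e-10

    def test_w11_is_real(self, ev3, lin3):
        g20, g11, g02 = g_second_order(ev3, lin3)
        _, _, _, W11m1 = center_manifold_terms(ev3, lin3, g20, g11, g02)
        assert np.max(np.abs(W11m1.imag)) < 1e-9 * max(1.0, np.max(np.abs(W11m1.real)))


class TestG21:
    def test_zero_nonlinearity_gives_zero(self, ev3, lin3):
        import dataclasses

        lin0 = dataclasses.replace(
            lin3, c_S=0.0, c_G=0.0, c_E=0.0, c_I=0.0, e_S=0.0, e_G=0.0, e_E=0.0, e_I=0.0
        )
        g20, g11, g02 = g_second_order(ev3, lin0)
        E1, E2, W20m1, W11m1 = center_manifold_terms(ev3, lin0, g20, g11, g02)
        assert g21_coefficient(ev3, lin0, W20m1, W11m1) == 0

    def test_cubic_part_matches_third_directional_derivative(self, p3, ev3, lin3, report3):
        """With curvature suppressed, g21 reduces to the pure cubic term,
        which must match the projected third directional derivative
        (coefficient of z^2 z-bar carries the multinomial factor 3)."""
        eq = bl.solve_equilibrium(p3)
        T0, w0 = report3.delays.T0, report3.delays.omega0
        lin0 = _zero_quadratic(lin3)
        g20, g11, g02 = g_second_order(ev3, lin0)
        _, _, W20m1, W11m1 = center_manifold_terms(ev3, lin0, g20, g11, g02)
        g21 = g21_coefficient(ev3, lin0, W20m1, W11m1)
        qd = ev3.q0 * np.exp(-1j * w0 * T0)
        # D^3 f[qd, qd, conj(qd)]_X = 6 e_X a_X^2 conj(a_X), which equals
        # the cubic g21 contribution divided by T0 and the weights
        d3 = dir3c(p3, eq.u0, qd, qd, np.conj(qd))
        expected = T0 * np.sum(ev3.weights * d3)
        assert g21 == pytest.approx(expected, rel=1e-4)


class TestClassification:
    def test_formula_arithmetic(self):
        """g20 = g11 = g02 = 0 and g21 = -2 give c1 = -1, beta2 = -2,
        mu2 = 1/Re lambda'."""
        lamp = 0.02 - 0.01j
        nf = classify_hopf(0j, 0j, 0j, -2.0 + 0j, omega0=0.2, T0=4.0, lam_prime=lamp)
        assert nf.c1 == pytest.approx(-1.0 + 0j)
        assert nf.beta2 == pytest.approx(-2.0)
        assert nf.mu2 == pytest.approx(1.0 / 0.02)
        assert nf.T2 == pytest.approx(-(0.0 + nf.mu2 * (-0.01)) / 0.2)

    def test_internal_identities(self, nf3):
        assert nf3.mu2 == pytest.approx(-nf3.c1.real / nf3.lam_prime.real, rel=1e-12)
        assert nf3.beta2 == pytest.approx(2 * nf3.c1.real, rel=1e-12)
        assert nf3.T2 == pytest.approx(
            -(nf3.c1.imag + nf3.mu2 * nf3.lam_prime.imag) / nf3.omega0, rel=1e-12
        )

    def test_transversality_zero_rejected(self):
        with pytest.raises(ZeroDivisionError):
            classify_hopf(0j, 0j, 0j, -2.0 + 0j, omega0=0.2, T0=4.0, lam_prime=0.0 - 0.01j)

    def test_section3_classification(self, nf3):
        """Supercritical, orbitally stable, period growing with delay."""
        assert nf3.mu2 > 0
        assert nf3.beta2 < 0
        assert nf3.T2 > 0
        assert nf3.direction == "supercritical"
        assert nf3.orbit_stability == "stable"
        assert nf3.period_trend == "increasing"


class TestSimulationCrossValidation:
    """The normal form must predict what the Euler integrator does."""

    def test_amplitude_scaling_matches_mu2_amp(self, p3, report3, nf3):
        """Stationary center-coordinate amplitude: |xi|^2 ~ (T-T0)/mu2_amp,
        with |xi| = peak-to-peak of S divided by 4 for a BG-loop crossing."""
        T0 = report3.delays.T0
        mus = np.array([0.15, 0.25, 0.35])
        r2 = []
        hist = None
        for mu in mus:
            pi = p3.replace(T=T0 + mu)
            tr = bl.integrate(pi, duration=25000.0, h=0.01, history=hist)
            hist = tr.y[-4000:]
            s = bl.summarize_attractor(tr, transient_fraction=0.6)
            assert s.kind == "oscillation"
            r2.append((s.amplitude / 4.0) ** 2)
        slope = np.polyfit(mus, r2, 1)[0]
        assert slope == pytest.approx(1.0 / nf3.mu2_amp, rel=0.25)

    def test_period_at_onset(self, p3, report3):
        """Oscillation period just above onset approaches 2 pi / omega0."""
        T0, w0 = report3.delays.T0, report3.delays.omega0
        tr = bl.integrate(p3.replace(T=T0 + 0.08), duration=25000.0, h=0.01)
        s = bl.summarize_attractor(tr, transient_fraction=0.7)
        assert s.kind == "oscillation"
        f_lin = 1000.0 * w0 / (2 * np.pi)
        assert s.frequency == pytest.approx(f_lin, rel=0.02)

    def test_orbit_is_attracting(self, p3, report3):
        """beta2 < 0: a strongly perturbed orbit reconverges to the same
        amplitude as a mildly perturbed one."""
        T0 = report3.delays.T0
        pi = p3.replace(T=T0 + 0.4)
        eq = bl.solve_equilibrium(pi)
        amps = []
        for kick in (1.0, 40.0):
            u = eq.u0.copy()
            u[0] += kick
            u[2] += kick / 4
            tr = bl.integrate(pi, duration=20000.0, h=0.01, history=u)
            amps.append(bl.summarize_attractor(tr, transient_fraction=0.7).amplitude)
        assert amps[0] == pytest.approx(amps[1], rel=0.02)
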