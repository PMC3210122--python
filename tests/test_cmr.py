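"""Center-manifold reduction: basis, amplitude equations, CGL, death."""

import warnings

import numpy as np
import pytest

from delayosc.model import ModelParams, CouplingMatrix
from delayosc.stability import find_hopf, char_derivative
from delayosc import cmr
from delayosc.experiments import detuned_partner

from conftest import nrmse


@pytest.fixture(scope="module")
def basisA(hopfA, pA):
    return cmr.build_center_basis(hopfA, pA)


class TestCenterBasis:
    def test_normalization_matrix_is_identity(self, basisA):
        np.testing.assert_allclose(basisA.normalization_matrix, np.eye(2),
                                   atol=1e-8)

    def test_quadrature_pairing_matches_closed_form(self, basisA, hopfA, pA):
        """<psi_raw, phi> computed by numerical quadrature equals
        Delta'(i omega_c), the closed-form Hale pairing."""
        crit = pA.with_gain_b(hopfA.gain_critical)
        w = hopfA.omega_c
        p_raw = np.array([1j * w + 2.0 * crit.damping, 1.0])
        psi_raw = lambda s: np.exp(-1j * w * np.asarray(s, dtype=float))[..., None] * p_raw
        val = cmr.hale_pairing(psi_raw, basisA.phi, crit)
        assert val == pytest.approx(char_derivative(1j * w, crit), abs=1e-8)

    def test_phi_at_zero_is_the_linearization_eigenvector(self, basisA, hopfA, pA):
        """[i w I - L0 - L1 e^{-i w tau}] q = 0 for q = phi(0)."""
        crit = pA.with_gain_b(hopfA.gain_critical)
        g, a, b, tau = (crit.damping, crit.gain_a, crit.gain_b, crit.delay)
        w = hopfA.omega_c
        L0 = np.array([[0.0, 1.0], [-(g * g - a), -2.0 * g]])
        L1 = np.array([[0.0, 0.0], [-b, 0.0]])
        q = basisA.phi(0.0)
        resid = (1j * w * q - L0 @ q - L1 @ q * np.exp(-1j * w * tau))
        assert np.max(np.abs(resid)) < 1e-10

    def test_nonzero_quadratic_coefficient_rejected(self, pA):
        bad = ModelParams(delay=pA.delay, damping=pA.damping, gain_a=pA.gain_a,
                          gain_b=pA.gain_b, nl2=0.3, nl3=1.0)
        with pytest.raises(cmr.UnsupportedCase):
            cmr.amplitude_equation([bad])


class TestAmplitudeEquation:
    def test_pure_rotation_at_criticality(self, hopfA, pA):
        crit = pA.with_gain_b(hopfA.gain_critical)
        amp = cmr.amplitude_equation([crit])
        M = amp.linear_matrix_real()
        lam = np.linalg.eigvals(M)
        np.testing.assert_allclose(sorted(lam.imag), [-hopfA.omega_c,
                                                      hopfA.omega_c], atol=1e-10)
        np.testing.assert_allclose(lam.real, 0.0, atol=1e-10)

    def test_supercritical_throughout_reference_region(self, sets):
        for lbl in ("A", "B", "C"):
            amp = cmr.amplitude_equation([sets[lbl].params])
            assert amp.oscillators[0].c.real < 0

    def test_planar_cycle_amplitude_matches_dde(self, pA, cycleA):
        amp = cmr.amplitude_equation([pA])
        t, z = amp.simulate(np.array([0.05 + 0j]),
                            t_end=14.0 / amp.oscillators[0].mu)
        tail = np.abs(z[t > 0.8 * t[-1], 0])
        assert 2 * tail.max() == pytest.approx(cycleA.amplitude, rel=0.10)

    def test_in_phase_manifold_is_invariant(self, pA):
        amp = cmr.amplitude_equation([pA, pA],
                                     CouplingMatrix.pair(eps_u=0.01, eps_v=0.004))
        z = np.array([0.1 + 0.05j, 0.1 + 0.05j])
        dz = amp.rhs(z)
        assert dz[0] == pytest.approx(dz[1], rel=1e-14)


class TestCGL:
    def test_stationary_amplitude_and_frequency_closed_form(self, cglA):
        mu, c = cglA.mu[0], cglA.c[0]
        R = cglA.stationary_amplitude()
        assert R == pytest.approx(np.sqrt(-mu / c.real), rel=1e-12)
        assert cglA.oscillation_frequency() == pytest.approx(
            cglA.omega[0] + c.imag * R ** 2, rel=1e-12)

    def test_averaged_and_planar_envelopes_agree(self, pA):
        """Simulating the planar system and its averaged CGL from matched
        initial data gives the same amplitude envelope to 5%."""
        amp = cmr.amplitude_equation([pA])
        cgl = cmr.cgl_reduce(amp)
        T = 2 * np.pi / cgl.omega[0]
        z0 = np.array([0.3 * cgl.stationary_amplitude() + 0j])
        t_end = 50 * T
        t1, z1 = amp.simulate(z0, t_end)
        t2, z2 = cgl.simulate(z0, t_end)
        grid = np.linspace(5 * T, t_end, 40)
        e1 = np.interp(grid, t1, np.abs(z1[:, 0]))
        e2 = np.interp(grid, t2, np.abs(z2[:, 0]))
        # the planar envelope wobbles at 2 omega; compare period-averaged
        assert nrmse(e1, e2) < 0.05


class TestAnalyticPhase:
    def test_Z_is_a_pure_sinusoid(self, cglA, basisA):
        prc = cmr.analytic_Z(cglA, basisA, n_phase=128)
        c = np.abs(np.fft.rfft(prc.Z))
        assert c[2:].max() ** 2 < 1e-10 * c[1] ** 2

    def test_Z_uses_the_quadrature_projection(self, cglA, basisA, hopfA, pA):
        """The sinusoid's complex amplitude equals the dual-basis
        projection with kappa recomputed by quadrature."""
        crit = pA.with_gain_b(hopfA.gain_critical)
        w = hopfA.omega_c
        p_raw = np.array([1j * w + 2.0 * crit.damping, 1.0])
        psi_raw = lambda s: np.exp(-1j * w * np.asarray(s, dtype=float))[..., None] * p_raw
        kappa_quad = 1.0 / cmr.hale_pairing(psi_raw, basisA.phi, crit)
        chi = cglA.c[0].imag / cglA.c[0].real
        R0 = cglA.stationary_amplitude()
        prc = cmr.analytic_Z(cglA, basisA, n_phase=64)
        theta = prc.theta_grid
        expect = np.real((-1j - chi) * np.exp(-1j * (theta - np.pi / 2))
                         * kappa_quad) / R0
        np.testing.assert_allclose(prc.Z, expect, atol=1e-8)

    def test_below_onset_raises(self, pA, hopfA, basisA):
        sub = pA.with_gain_b(hopfA.gain_critical - 0.01)
        cgl = cmr.cgl_reduce(cmr.amplitude_equation([sub]))
        with pytest.raises(cmr.NoCycle):
            cmr.analytic_Z(cgl, basisA)

    def test_v_channel_gamma_is_even(self, cglA):
        g = cmr.analytic_gamma(cglA, "v", n_phi=128)
        assert np.max(np.abs(g.gamma_a)) < 1e-12
        assert np.max(np.abs(g.gamma)) > 0

    def test_u_channel_gamma_vanishes_at_zero_lag(self, cglA):
        g = cmr.analytic_gamma(cglA, "u", n_phi=128)
        assert g.gamma[0] == pytest.approx(0.0, abs=1e-12)

    def test_u_channel_gamma_stabilizes_in_phase(self, cglA):
        """Diffusive u coupling must make the in-phase state attracting:
        gamma_a slope at 0 negative."""
        g = cmr.analytic_gamma(cglA, "u", n_phi=256)
        slope = (g.gamma_a[1] - g.gamma_a[-1]) / (2 * (g.phi_grid[1]))
        assert slope < 0


@pytest.fixture(scope="module")
def cglAB(pA, pB):
    amp = cmr.amplitude_equation([pA, pB])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cmr.cgl_reduce(amp)


class TestDeath:
    def test_uncoupled_eigenvalues_are_the_growth_rates(self, cglAB):
        de = cmr.death_eigenvalues(cglAB, 0.0, "u")
        np.testing.assert_allclose(sorted(de.lambdas.real),
                                   sorted(np.repeat(cglAB.mu, 2)), atol=1e-12)

    def test_perturbative_matches_exact_for_small_mismatch(self, pA):
        partner = detuned_partner(pA, 0.004)
        amp = cmr.amplitude_equation([pA, partner])
        cgl = cmr.cgl_reduce(amp)
        for eps in (0.005, 0.02, 0.05):
            de = cmr.death_eigenvalues(cgl, eps, "u")
            # the real 4-D spectrum repeats each real part for the
            # conjugate partner; compare the two distinct values
            exact = np.sort(de.lambdas.real)[::-1][[0, 2]]
            pert = np.sort(de.lambdas_cgl.real)[::-1]
            scale = max(np.abs(exact).max(), 1e-6)
            assert np.max(np.abs(exact - pert)) / scale < 0.05

    def test_death_region_monotone_on_grid(self, cglAB):
        th = cmr.death_threshold(cglAB, "u")
        assert np.isfinite(th) and th > 0
        grid = np.linspace(1.001 * th, 2.0 * th, 25)
        maxre = [cmr.death_eigenvalues(cglAB, e, "u").max_real for e in grid]
        assert all(m < 0 for m in maxre)

    def test_threshold_bisection_consistent_with_eigenvalues(self, cglAB):
        th = cmr.death_threshold(cglAB, "u")
        assert cmr.death_eigenvalues(cglAB, 0.99 * th, "u").max_real > 0
        assert cmr.death_eigenvalues(cglAB, 1.01 * th, "u").max_real < 0
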