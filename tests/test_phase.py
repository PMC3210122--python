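"""Direct-method PRC, coupling-function convolution, locking analysis."""

import numpy as np
import pytest

from delayosc.ddesim import DDESystem, find_limit_cycle
from delayosc.fixtures import StuartLandauSystem
from delayosc.phase import (prc_direct, gamma_convolution, locking_analysis,
                            critical_coupling, CouplingFunction,
                            NoLockingChannel)
from delayosc import cmr

from conftest import nrmse


class TestPRCDirect:
    def test_stuart_landau_matches_closed_form(self):
        """On the planar normal-form fixture the measured sensitivity to
        kicks in Re z reproduces the exact isochron gradient."""
        sl = StuartLandauSystem(mu=0.08, omega=1.0, c=-1.0 + 0.3j)
        traj = sl.integrate(0.05, t_end=420.0)
        cyc = find_limit_cycle(traj, transient=300.0)
        prc = prc_direct(sl, cyc, n_phase=24, component="u", relax_periods=40)
        expect = sl.analytic_Z_u(prc.theta_grid)
        assert nrmse(prc.Z, expect) < 0.02

    def test_linearity_in_the_impulse(self, pA, cycleA):
        sys = DDESystem(pA)
        base = 1e-3 * cycleA.amplitude
        z1 = prc_direct(sys, cycleA, impulse=base, n_phase=8,
                        relax_periods=50).Z
        z2 = prc_direct(sys, cycleA, impulse=0.5 * base, n_phase=8,
                        relax_periods=50).Z
        assert np.max(np.abs(z1 - z2)) / np.max(np.abs(z1)) < 0.02

    def test_near_onset_Z_is_dominated_by_the_first_harmonic(self, prcA):
        assert prcA.first_harmonic_power_fraction() > 0.95

    def test_far_from_onset_Z_has_higher_harmonics(self, prcC):
        assert prcC.first_harmonic_power_fraction() < 0.9


class TestGammaConvolution:
    def test_antisymmetric_part_is_odd_by_construction(self, gammaC_u):
        n = len(gammaC_u.phi_grid)
        ga = gammaC_u.gamma_a
        ga_rev = ga[(-np.arange(n)) % n]
        assert np.max(np.abs(ga + ga_rev)) < 1e-12

    def test_gamma_a_vanishes_at_zero_lag(self, gammaA_u, gammaC_u):
        assert gammaA_u.gamma_a[0] == 0.0
        assert gammaC_u.gamma_a[0] == 0.0

    def test_trapezoid_matches_refined_quadrature(self, prcA, cycleA):
        """The uniform-grid (trapezoid) average vs adaptive high-order
        quadrature of a periodic spline through the same integrand."""
        from scipy.interpolate import CubicSpline
        from scipy.integrate import simpson
        gam = gamma_convolution(prcA, cycleA, "u")
        th = prcA.theta_grid
        scale = np.max(np.abs(gam.gamma))
        for k in (3, 17, 40):
            phi = gam.phi_grid[k]
            h = prcA.Z * (cycleA.eval_u(th - phi) - cycleA.eval_u(th))
            spl = CubicSpline(np.append(th, 2 * np.pi), np.append(h, h[0]),
                              bc_type="periodic")
            fine = np.linspace(0, 2 * np.pi, 8193)
            val = simpson(spl(fine), x=fine) / (2 * np.pi)
            assert gam.gamma[k] == pytest.approx(val, abs=1e-4 * scale)

    def test_numerical_v_channel_is_nearly_even_near_onset(self, gammaA_v):
        asym = np.max(np.abs(gammaA_v.gamma_a))
        sym = np.max(np.abs(gammaA_v.gamma))
        assert asym < 0.05 * sym


class TestLockingAnalysis:
    @staticmethod
    def minus_sine():
        phi = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        ga = -np.sin(phi)
        return CouplingFunction(phi_grid=phi, gamma=ga, gamma_a=ga, channel="u")

    def test_textbook_attractive_case(self):
        diag = locking_analysis(self.minus_sine(), 0.0, 0.1)
        pts = dict((round(p, 6), s) for p, s in diag.fixed_points)
        assert pts[0.0] == "stable"
        assert pts[round(np.pi, 6)] == "unstable"
        # every initial condition flows to 0
        assert all(abs(v) < 1e-6 or abs(v - 2 * np.pi) < 1e-6
                   for v in diag.basins.values())

    def test_drift_regime_flagged(self):
        diag = locking_analysis(self.minus_sine(), delta_omega=0.5, eps=0.1)
        assert diag.drifting and diag.fixed_points == []

    def test_stable_and_unstable_alternate(self, gammaC_u):
        diag = locking_analysis(gammaC_u, 0.0, 0.05)
        kinds = [s for _, s in diag.fixed_points]
        for a, b in zip(kinds, kinds[1:] + kinds[:1]):
            assert a != b

    def test_basins_match_forward_flow(self, gammaC_u):
        """Forward integration of dpsi/dt = eps gamma_a reaches the
        attractor the basin map assigns, for 100 uniform initial values."""
        eps = 0.05
        diag = locking_analysis(gammaC_u, 0.0, eps, n_basin=100)
        stable = np.array([p for p, s in diag.fixed_points if s == "stable"])
        f = lambda p: eps * gammaC_u.eval_a(p)
        for phi0, target in diag.basins.items():
            if abs(f(phi0)) < 1e-14:
                continue            # starts exactly on a fixed point: stays
            phi = phi0
            dt = 0.5 / eps / max(np.abs(gammaC_u.gamma_a).max(), 1e-9) / 50
            for _ in range(40000):
                k1 = f(phi)
                k2 = f(phi + 0.5 * dt * k1)
                k3 = f(phi + 0.5 * dt * k2)
                k4 = f(phi + dt * k3)
                step = dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                phi += step
                if abs(step) < 1e-12:
                    break
            d = np.abs((stable - phi + np.pi) % (2 * np.pi) - np.pi)
            reached = stable[np.argmin(d)]
            dt_ = np.abs((reached - target + np.pi) % (2 * np.pi) - np.pi)
            assert dt_ < 1e-3

    def test_eps_must_be_positive(self, gammaC_u):
        with pytest.raises(ValueError):
            locking_analysis(gammaC_u, 0.0, 0.0)


class TestCriticalCoupling:
    def test_zero_mismatch_means_zero_threshold(self, gammaA_u):
        assert critical_coupling(gammaA_u, 0.0) == 0.0

    def test_homogeneity_in_the_mismatch(self, gammaA_u):
        e1 = critical_coupling(gammaA_u, 0.003)
        e2 = critical_coupling(gammaA_u, 0.006)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_locking_exists_exactly_above_threshold(self, gammaA_u):
        dw = 0.004
        ec = critical_coupling(gammaA_u, dw)
        assert locking_analysis(gammaA_u, dw, 1.05 * ec).fixed_points
        assert locking_analysis(gammaA_u, dw, 0.95 * ec).drifting

    def test_flat_gamma_raises(self):
        phi = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        flat = CouplingFunction(phi_grid=phi, gamma=np.cos(phi) - 1,
                                gamma_a=np.zeros_like(phi), channel="v")
        with pytest.raises(NoLockingChannel):
            critical_coupling(flat, 0.01)
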