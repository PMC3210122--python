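"""Integrator correctness and limit-cycle extraction."""

import numpy as np
import pytest

from delayosc.model import ModelParams
from delayosc.stability import find_hopf
from delayosc.ddesim import (integrate, find_limit_cycle, DivergenceError,
                             harmonic_distortion, History)
from delayosc.fixtures import LinearDDEReference, sine_trajectory
from delayosc import cmr

LINEAR_FIXTURE = ModelParams(delay=1.0, damping=1.0, gain_a=0.25, gain_b=1.0,
                             nl2=0.0, nl3=0.0)


class TestIntegrator:
    def test_zero_history_stays_at_rest(self):
        traj = integrate(ModelParams(), None, 0.0, t_end=20.0)
        assert np.all(traj.u == 0.0)
        assert np.all(traj.v == 0.0)

    def test_delay_free_damped_oscillator_matches_closed_form(self):
        """b = 0, a = -w0^2: u'' = -2g u' - (g^2 + w0^2) u, an explicitly
        solvable damped oscillation."""
        g, w0 = 1.0, 2.0
        p = ModelParams(delay=1.0, damping=g, gain_a=-w0 ** 2, gain_b=0.0,
                        nl2=0.0, nl3=0.0)
        traj = integrate(p, None, 1.0, t_end=10.0, steps_per_delay=40)
        t = 10.0
        # u(0)=1, v(0)=0: u = e^{-g t} (cos w0 t + (g/w0) sin w0 t)
        exact = np.exp(-g * t) * (np.cos(w0 * t) + (g / w0) * np.sin(w0 * t))
        assert traj.eval_u(t)[0] == pytest.approx(exact, abs=1e-8)

    def test_linear_dde_matches_symbolic_method_of_steps(self):
        ref = LinearDDEReference(LINEAR_FIXTURE, u0=1.0, n_intervals=3)
        traj = integrate(LINEAR_FIXTURE, None, 1.0, t_end=3.0,
                         steps_per_delay=40)
        ts = np.linspace(0.05, 2.95, 50)
        num = np.array([traj.eval_u(t)[0] for t in ts])
        assert np.max(np.abs(num - ref.u(ts))) < 1e-8

    def test_observed_convergence_order_is_four(self):
        ref = LinearDDEReference(LINEAR_FIXTURE, u0=1.0, n_intervals=3)
        ts = np.linspace(0.05, 2.95, 50)
        errs = []
        for spd in (20, 40):
            traj = integrate(LINEAR_FIXTURE, None, 1.0, t_end=3.0,
                             steps_per_delay=spd)
            num = np.array([traj.eval_u(t)[0] for t in ts])
            errs.append(np.max(np.abs(num - ref.u(ts))))
        order = np.log2(errs[0] / errs[1])
        assert 3.5 <= order <= 4.5

    def test_incommensurate_step_rejected(self):
        with pytest.raises(ValueError):
            integrate(ModelParams(delay=1.0), None, 0.01, t_end=5.0, dt=0.3)
        with pytest.raises(ValueError):  # m < 20
            integrate(ModelParams(delay=1.0), None, 0.01, t_end=5.0, dt=0.1)

    def test_divergence_guard_reports_blowup_time(self):
        p = ModelParams(gain_a=5.0, gain_b=0.0, nl2=0.0, nl3=-0.5)
        with pytest.raises(DivergenceError) as exc:
            integrate(p, None, 1.0, t_end=100.0)
        assert exc.value.t_blowup > 0

    def test_determinism(self, pC):
        t1 = integrate(pC, None, 0.01, t_end=30.0)
        t2 = integrate(pC, None, 0.01, t_end=30.0)
        assert np.array_equal(t1.u, t2.u)
        assert np.array_equal(t1.v, t2.v)


class TestLimitCycle:
    def test_pure_sine_period_recovered(self):
        T0 = 3.7
        traj = sine_trajectory(period=T0, t_end=80.0)
        cyc = find_limit_cycle(traj, transient=10.0)
        assert abs(cyc.period - T0) < 1e-6 * T0

    def test_near_onset_cycle_is_nearly_sinusoidal(self, cycleA):
        assert not cycleA.quiescent
        assert harmonic_distortion(cycleA) < 0.05

    def test_far_from_onset_cycle_has_strong_harmonics(self, cycleC):
        assert not cycleC.quiescent
        assert harmonic_distortion(cycleC) > 0.05

    def test_rest_state_reported_quiescent_not_error(self):
        p = ModelParams()
        hp = find_hopf(p)
        # well inside the stable region the transient decays completely
        traj = integrate(p.with_gain_b(0.3 * hp.gain_critical), None, 0.05,
                         t_end=300.0)
        cyc = find_limit_cycle(traj, transient=250.0)
        assert cyc.quiescent
        assert np.isnan(cyc.period)

    def test_samples_close_a_loop(self, cycleC):
        du = abs(cycleC.eval_u(np.array([0.0]))[0]
                 - cycleC.eval_u(np.array([2 * np.pi - 1e-9]))[0])
        assert du < 0.02 * cycleC.amplitude


@pytest.fixture(scope="module")
def onset_sweep(pA, hopfA):
    nus = np.array([0.004, 0.008, 0.016, 0.04])
    amps, periods, mus = [], [], []
    for nu in nus:
        p = pA.with_gain_b(hopfA.gain_critical + nu)
        cgl = cmr.cgl_reduce(cmr.amplitude_equation([p]))
        mu = cgl.mu[0]
        T = 2 * np.pi / cgl.oscillation_frequency()
        transient = 200.0 + 14.0 / mu
        traj = integrate(p, None, 0.05, t_end=transient + 25 * T)
        cyc = find_limit_cycle(traj, transient=transient)
        amps.append(cyc.amplitude)
        periods.append(cyc.period)
        mus.append(mu)
    return np.array(mus), np.array(amps), np.array(periods)


class TestScalingNearOnset:
    """Amplitude ~ sqrt(mu) and period -> 2 pi / omega_c as mu -> 0."""

    def test_amplitude_scales_as_sqrt_mu(self, onset_sweep):
        mus, amps, _ = onset_sweep
        slope = np.polyfit(np.log(mus), np.log(amps), 1)[0]
        assert 0.45 <= slope <= 0.55

    def test_period_approaches_hopf_period(self, onset_sweep, hopfA):
        """The period extrapolates to 2 pi / omega_c as mu -> 0 (the
        offset and shear shift it linearly in mu at finite distance)."""
        mus, _, periods = onset_sweep
        T_hopf = 2 * np.pi / hopfA.omega_c
        intercept = np.polyfit(mus, periods, 1)[1]
        assert abs(intercept - T_hopf) < 0.01 * T_hopf

    def test_relaxation_rate_matches_reduction(self, pA, cglA, cycleA):
        """An orbit kicked off the cycle returns at the CGL rate 2 mu."""
        from delayosc.ddesim import DDESystem
        T = cycleA.period
        hist = cycleA.history_at_phase(0.0)
        base_u = hist.u_fn

        def u_fn(t):
            return 1.25 * np.atleast_2d(base_u(t))      # 25% amplitude kick

        kicked = History(u_fn=u_fn, v_fn=lambda t: 1.25 * np.atleast_2d(hist.v_fn(t)),
                         n=1)
        sys = DDESystem(pA)
        tr = sys.integrate(kicked, t_end=40 * T)
        # envelope of |u| maxima per period
        peaks = []
        for k in range(2, 38):
            sel = (tr.times >= k * T) & (tr.times < (k + 1) * T)
            peaks.append(np.max(np.abs(tr.u[sel, 0])))
        dev = np.abs(np.array(peaks) - cycleA.amplitude)
        good = dev > 1e-6
        ks = np.arange(len(peaks))[good]
        rate = -np.polyfit(ks * T, np.log(dev[good]), 1)[0]
        assert rate == pytest.approx(cglA.relaxation_rate(), rel=0.10)
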