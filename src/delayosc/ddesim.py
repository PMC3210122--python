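"""Constant-delay DDE integration by the method of steps, and limit-cycle extraction.

The network is advanced with a classical explicit Runge-Kutta scheme of
order 4.  The step size must divide the delay exactly (``dt = tau / m``,
``m >= 20``) so that the derivative discontinuities that propagate from the
initial time land on grid nodes and every stage's delayed argument falls on
a stored node or segment midpoint, where a cubic Hermite interpolant built
from the stored values and derivatives is exact to the scheme's order.
Delayed lookups always interpolate, never extrapolate.

Limit-cycle descriptors (period, amplitude, one period of samples on a
uniform phase grid) are extracted from the trajectory after a transient.
The phase origin is the upward ``u = 0`` crossing on the cycle; far from
onset the waveform may cross zero several times per period, so crossings
are grouped into families by an FFT period estimate and the family holding
the steepest crossing defines the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import ModelParams, CouplingMatrix, rhs

__all__ = [
    "Trajectory",
    "History",
    "LimitCycle",
    "DDESystem",
    "integrate",
    "find_limit_cycle",
    "harmonic_distortion",
    "DivergenceError",
]

OVERFLOW_GUARD = 1e6
AMPLITUDE_FLOOR = 1e-9


class DivergenceError(RuntimeError):
    def __init__(self, t_blowup: float):
        super().__init__(f"state norm exceeded overflow guard at t = {t_blowup:g}")
        self.t_blowup = t_blowup


@dataclass
class History:
    """An initial function on [t_ref - delay, t_ref], evaluable for u and v."""

    u_fn: Callable[[np.ndarray], np.ndarray]
    v_fn: Callable[[np.ndarray], np.ndarray]
    n: int

    @classmethod
    def constant(cls, value: float | np.ndarray, n: int | None = None) -> "History":
        val = np.atleast_1d(np.asarray(value, dtype=float))
        if n is None:
            n = val.shape[0]
        val = np.broadcast_to(val, (n,)).copy()
        zero = np.zeros(n)
        return cls(u_fn=lambda t: np.broadcast_to(val, np.shape(t) + (n,)).copy(),
                   v_fn=lambda t: np.broadcast_to(zero, np.shape(t) + (n,)).copy(),
                   n=n)



@dataclass
class Trajectory:
    """Dense DDE solution on a uniform grid including the history segment.

    ``times[0] = t0 - delay``; the integration itself starts at ``t0``
    (index ``m = delay/dt``).  ``u``, ``v`` and the acceleration ``acc`` are
    stored at every node, which makes the cubic Hermite interpolant for both
    u (nodes + v) and v (nodes + acc) exact at the nodes.
    """

    times: np.ndarray           # (K,)
    u: np.ndarray               # (K, n)
    v: np.ndarray               # (K, n)
    acc: np.ndarray             # (K, n)
    dt: float
    delay: float
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.u.shape[1]

    @property
    def t0(self) -> float:
        return float(self.times[0] + self.delay)

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def _locate(self, t: float) -> tuple[int, float]:
        x = (t - self.times[0]) / self.dt
        k = int(np.floor(x))
        k = min(max(k, 0), len(self.times) - 2)
        s = x - k
        return k, s

    def eval_u(self, t: float) -> np.ndarray:
        k, s = self._locate(t)
        return _hermite(self.u[k], self.u[k + 1], self.v[k], self.v[k + 1], self.dt, s)

    def eval_v(self, t: float) -> np.ndarray:
        k, s = self._locate(t)
        return _hermite(self.v[k], self.v[k + 1], self.acc[k], self.acc[k + 1], self.dt, s)

    def segment(self, t_ref: float) -> History:
        """The functional state at time t_ref, as a History on [-delay, 0]."""
        if t_ref - self.delay < self.times[0] - 1e-12 or t_ref > self.t_end + 1e-12:
            raise ValueError("segment outside stored trajectory")

        def u_fn(th):
            th = np.atleast_1d(np.asarray(th, dtype=float))
            return np.stack([self.eval_u(t_ref + x) for x in th])

        def v_fn(th):
            th = np.atleast_1d(np.asarray(th, dtype=float))
            return np.stack([self.eval_v(t_ref + x) for x in th])

        return History(u_fn=u_fn, v_fn=v_fn, n=self.n)


def _hermite(y0, y1, d0, d1, dt, s):
    """Cubic Hermite on one segment; s in [0,1]."""
    h00 = (1 + 2 * s) * (1 - s) ** 2
    h10 = s * (1 - s) ** 2
    h01 = s * s * (3 - 2 * s)
    h11 = s * s * (s - 1)
    return h00 * y0 + h10 * dt * d0 + h01 * y1 + h11 * dt * d1


def integrate(params: list[ModelParams] | ModelParams,
              coupling: CouplingMatrix | None,
              history: History | float | np.ndarray,
              t_end: float,
              dt: float | None = None,
              steps_per_delay: int = 40) -> Trajectory:
    """Integrate the delayed network from an initial history up to ``t_end``.

    ``dt`` must equal ``delay / m`` for an integer ``m >= 20``; if omitted it
    is set from ``steps_per_delay``.  The run is deterministic: identical
    inputs reproduce the trajectory bitwise.
    """
    if isinstance(params, ModelParams):
        plist = [params]
        if coupling is not None:
            plist = [params] * coupling.n
    else:
        plist = list(params)
    n = len(plist)
    delays = {p.delay for p in plist}
    if len(delays) != 1:
        raise ValueError("all oscillators must share the same delay")
    tau = plist[0].delay

    if dt is None:
        m = int(steps_per_delay)
    else:
        m = int(round(tau / dt))
        if m < 20 or abs(m * dt - tau) > 1e-9 * tau:
            raise ValueError(f"dt must be delay/m with integer m >= 20 "
                             f"(got dt={dt:g}, delay={tau:g})")
    dt = tau / m

    if not isinstance(history, History):
        history = History.constant(history, n=n)
    if history.n != n:
        raise ValueError(f"history is for {history.n} oscillators, model has {n}")

    nsteps = int(np.ceil(t_end / dt - 1e-9))
    K = m + nsteps + 1
    times = (np.arange(K) - m) * dt
    U = np.empty((K, n))
    V = np.empty((K, n))
    A = np.empty((K, n))

    th = times[: m + 1]
    U[: m + 1] = np.atleast_2d(history.u_fn(th)).reshape(m + 1, n)
    V[: m + 1] = np.atleast_2d(history.v_fn(th)).reshape(m + 1, n)
    # accelerations on the history segment: from the model where defined,
    # only needed for dense output of v before t0; use rhs with the delayed
    # value unavailable -> approximate by finite differences of v.
    A[: m + 1] = np.gradient(V[: m + 1], dt, axis=0)

    eu = ev = None
    rs_u = rs_v = None
    if coupling is not None:
        if coupling.n != n:
            raise ValueError("coupling size mismatch")
        eu, ev = coupling.eps_u, coupling.eps_v
        rs_u, rs_v = eu.sum(axis=1), ev.sum(axis=1)

    gamma = np.array([p.damping for p in plist])
    a_ = np.array([p.gain_a for p in plist])
    b_ = np.array([p.gain_b for p in plist])
    c2 = np.array([p.nl2 for p in plist])
    c3 = np.array([p.nl3 for p in plist])

    def acc_of(u, v, ud):
        out = (-2.0 * gamma * v - (gamma * gamma - a_) * u - b_ * ud
               - c2 * u * u - c3 * u * u * u)
        if eu is not None:
            out = out + eu @ u - rs_u * u + ev @ v - rs_v * v
        return out

    u = U[m].copy()
    v = V[m].copy()
    A[m] = acc_of(u, v, U[0])

    half = 0.5 * dt
    for k in range(m, K - 1):
        j = k - m                       # delayed node for stage 1
        ud0 = U[j]
        ud1 = U[j + 1]
        # Hermite midpoint of u on the delayed segment
        udm = 0.5 * (ud0 + ud1) + (dt / 8.0) * (V[j] - V[j + 1])

        a1 = acc_of(u, v, ud0)
        u2 = u + half * v
        v2 = v + half * a1
        a2 = acc_of(u2, v2, udm)
        u3 = u + half * v2
        v3 = v + half * a2
        a3 = acc_of(u3, v3, udm)
        u4 = u + dt * v3
        v4 = v + dt * a3
        a4 = acc_of(u4, v4, ud1)

        u = u + (dt / 6.0) * (v + 2.0 * v2 + 2.0 * v3 + v4)
        v = v + (dt / 6.0) * (a1 + 2.0 * a2 + 2.0 * a3 + a4)

        if np.max(np.abs(u)) > OVERFLOW_GUARD:
            raise DivergenceError(times[k + 1])
        U[k + 1] = u
        V[k + 1] = v
        A[k + 1] = acc_of(u, v, U[j + 1])

    meta = {"solver": "rk4-method-of-steps", "dt": dt, "steps_per_delay": m,
            "delay": tau, "n_oscillators": n, "t_end": float(times[-1])}
    return Trajectory(times=times, u=U, v=V, acc=A, dt=dt, delay=tau, meta=meta)


@dataclass
class DDESystem:
    """A parameter set + coupling bundled with an ``integrate`` method.

    This is the object the phase-reduction machinery perturbs; fixtures such
    as the Stuart-Landau oscillator expose the same interface.
    """

    params: list[ModelParams] | ModelParams
    coupling: CouplingMatrix | None = None
    steps_per_delay: int = 40

    @property
    def delay(self) -> float:
        p = self.params if isinstance(self.params, ModelParams) else self.params[0]
        return p.delay

    def integrate(self, history, t_end, dt=None) -> Trajectory:
        return integrate(self.params, self.coupling, history, t_end,
                         dt=dt, steps_per_delay=self.steps_per_delay)


# ---------------------------------------------------------------------------
# limit-cycle extraction


@dataclass
class LimitCycle:
    """One period of a stable limit cycle plus descriptors.

    ``quiescent`` marks trajectories that settled to the rest state
    (amplitude death); that is a valid outcome, not an error.
    """

    period: float
    amplitude: float
    phase_grid: np.ndarray          # n_phase uniform phases in [0, 2pi)
    u_samples: np.ndarray
    v_samples: np.ndarray
    crossing_times: np.ndarray      # phase-origin events (ascending)
    quiescent: bool = False
    oscillator_index: int = 0
    traj: Trajectory | None = None
    t_origin: float = np.nan        # a phase-origin time usable for segments

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period

    def history_at_phase(self, phase: float) -> History:
        """Functional state on the cycle at the given phase (radians)."""
        if self.traj is None or not np.isfinite(self.t_origin):
            raise ValueError("cycle does not carry its source trajectory")
        t_ref = self.t_origin + (phase % (2 * np.pi)) / (2 * np.pi) * self.period
        return self.traj.segment(t_ref)

    def eval_u(self, phase: np.ndarray) -> np.ndarray:
        """Interpolate u on the cycle at arbitrary phases (periodic)."""
        return _periodic_interp(self.phase_grid, self.u_samples, phase)

    def eval_v(self, phase: np.ndarray) -> np.ndarray:
        return _periodic_interp(self.phase_grid, self.v_samples, phase)


def _periodic_interp(grid, values, phase):
    phase = np.asarray(phase, dtype=float) % (2 * np.pi)
    ext_g = np.concatenate([grid, [2 * np.pi]])
    ext_v = np.concatenate([values, values[:1]])
    return np.interp(phase, ext_g, ext_v)


def _quiescent(n_phase: int, idx: int, amplitude: float) -> LimitCycle:
    g = np.linspace(0, 2 * np.pi, n_phase, endpoint=False)
    z = np.zeros(n_phase)
    return LimitCycle(period=np.nan, amplitude=amplitude, phase_grid=g,
                      u_samples=z, v_samples=z.copy(),
                      crossing_times=np.array([]), quiescent=True,
                      oscillator_index=idx)


def _fft_period(t: np.ndarray, x: np.ndarray, dt: float) -> float | None:
    x = x - x.mean()
    if np.max(np.abs(x)) < AMPLITUDE_FLOOR:
        return None
    w = np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x * w))
    freqs = np.fft.rfftfreq(len(x), dt)
    k = int(np.argmax(spec[1:])) + 1
    if spec[k] == 0:
        return None
    # quadratic refinement of the peak
    if 1 <= k < len(spec) - 1:
        y0, y1, y2 = spec[k - 1], spec[k], spec[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = np.clip(delta, -0.5, 0.5)
    else:
        delta = 0.0
    f = freqs[k] + delta * (freqs[1] - freqs[0])
    return 1.0 / f if f > 0 else None


def upward_crossings(traj: Trajectory, t_start: float, idx: int = 0) -> np.ndarray:
    """Times of upward u=0 crossings of oscillator ``idx`` after ``t_start``."""
    sel = traj.times >= t_start
    t = traj.times[sel]
    u = traj.u[sel, idx]
    v = traj.v[sel, idx]
    out = []
    s0 = u[:-1] <= 0
    s1 = u[1:] > 0
    for k in np.nonzero(s0 & s1)[0]:
        # refine on the Hermite cubic by bisection
        lo, hi = t[k], t[k + 1]
        flo = u[k]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fm = traj.eval_u(mid)[idx]
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
            if hi - lo < 1e-13 * max(1.0, abs(hi)):
                break
        tc = 0.5 * (lo + hi)
        if traj.eval_v(tc)[idx] > 0:
            out.append(tc)
    return np.array(out)


def find_limit_cycle(traj: Trajectory, transient: float, oscillator_index: int = 0,
                     n_phase: int = 128) -> LimitCycle:
    """Extract period, amplitude and one period of samples after a transient.

    Robust to waveforms with several upward zero crossings per period: the
    period is first estimated from the dominant FFT peak of the tail, the
    crossings are grouped into families modulo that estimate, and the family
    containing the steepest crossing (largest u') defines the phase origin.
    """
    idx = oscillator_index
    t_start = traj.t0 + transient
    if t_start >= traj.t_end:
        raise ValueError("transient longer than trajectory")
    sel = traj.times >= t_start
    tail_u = traj.u[sel, idx]
    amplitude = float(np.max(np.abs(tail_u)))
    if amplitude < AMPLITUDE_FLOOR:
        return _quiescent(n_phase, idx, amplitude)

    crossings = upward_crossings(traj, t_start, idx)
    if len(crossings) < 3:
        return _quiescent(n_phase, idx, amplitude)

    T_est = _fft_period(traj.times[sel], tail_u, traj.dt)
    if T_est is None:
        return _quiescent(n_phase, idx, amplitude)

    # group crossings into families modulo the FFT period
    v_at = np.array([traj.eval_v(tc)[idx] for tc in crossings])
    anchor = crossings[int(np.argmax(v_at))]
    resid = (crossings - anchor + 0.5 * T_est) % T_est - 0.5 * T_est
    family = crossings[np.abs(resid) < 0.2 * T_est]
    if len(family) < 3:
        family = crossings

    # period by least squares on the family times (robust to jitter), then
    # geometric extrapolation of the slowly converging crossing intervals
    # (near onset the Floquet rate ~ 2*mu is small and the interval sequence
    # approaches its limit as d_k ~ T + C r^k)
    kidx = np.round((family - family[0]) / T_est)
    A = np.vstack([kidx, np.ones_like(kidx)]).T
    slope, _ = np.linalg.lstsq(A, family, rcond=None)[0]
    period = float(slope)
    diffs = np.diff(family)
    if len(diffs) >= 6:
        dec = np.diff(diffs[-6:])
        if np.all(dec > 0) or np.all(dec < 0):
            ratios = dec[1:] / dec[:-1]
            r = float(np.median(ratios))
            if 0.0 < r < 0.98:
                period = float(diffs[-1] + dec[-1] * r / (1.0 - r))

    # sample one period ending at the last usable origin crossing
    t_last = family[-1]
    if t_last + 1e-9 > traj.t_end:
        t_last = family[-2]
    t_first = t_last - period
    if t_first < traj.times[0] + traj.delay:
        raise ValueError("trajectory too short to sample one period")
    grid = np.linspace(0, 2 * np.pi, n_phase, endpoint=False)
    ts = t_first + grid / (2 * np.pi) * period
    u_s = np.array([traj.eval_u(t)[idx] for t in ts])
    v_s = np.array([traj.eval_v(t)[idx] for t in ts])

    # choose a t_origin whose full history segment exists and that leaves at
    # least one period of trajectory after it
    t_origin = np.nan
    for tc in family[::-1]:
        if tc - traj.delay >= traj.times[0] and tc + period <= traj.t_end + 1e-9:
            t_origin = tc
            break

    return LimitCycle(period=period, amplitude=amplitude, phase_grid=grid,
                      u_samples=u_s, v_samples=v_s, crossing_times=family,
                      quiescent=False, oscillator_index=idx, traj=traj,
                      t_origin=t_origin)


def harmonic_distortion(cycle: LimitCycle) -> float:
    """Total harmonic distortion of u over one period.

    Ratio of the RMS power in harmonics above the fundamental to the
    fundamental; near the Hopf onset the waveform is sinusoidal and the
    ratio is small, far from onset it grows.
    """
    if cycle.quiescent:
        return np.nan
    c = np.fft.rfft(cycle.u_samples - cycle.u_samples.mean())
    mags = np.abs(c)
    fund = mags[1]
    if fund == 0:
        return np.inf
    return float(np.sqrt(np.sum(mags[2:] ** 2)) / fund)
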