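"""Numerical phase reduction: direct-method PRCs, coupling functions, locking.

Valid arbitrarily far from the Hopf point as long as the limit cycle is
stable and the coupling weak.  The phase convention is theta in [0, 2pi)
with theta = 0 at the upward u = 0 crossing of the cycle, advancing at the
constant rate 2 pi / T.

Conventions
-----------
Both coupling channels force the acceleration equation, so the relevant
sensitivity is the response to impulses in ``v`` (``component='v'``); the
response to ``u`` impulses is also available for diagnostics.

The phase coupling function is stored as a function of *own phase minus
partner phase*:

    Gamma(phi) = (1/2pi) \\int Z(theta) [s(theta - phi) - s(theta)] d theta,

so that for a symmetric pair the phase difference psi = theta_1 - theta_2
obeys  d psi / dt = delta_omega + eps * gamma_a(psi)  with
gamma_a(phi) = Gamma(phi) - Gamma(-phi), and a root with negative slope is
a stable locked state.  Under diffusive u-coupling the in-phase state is
then stable, as it must be for a linearly attractive interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ddesim import DDESystem, LimitCycle, upward_crossings

__all__ = [
    "PRC",
    "CouplingFunction",
    "LockingDiagram",
    "prc_direct",
    "gamma_convolution",
    "locking_analysis",
    "critical_coupling",
    "BasinEscape",
    "NoLockingChannel",
]


class BasinEscape(RuntimeError):
    pass


class NoLockingChannel(RuntimeError):
    pass


@dataclass
class PRC:
    """Phase sensitivity on a uniform phase grid (shift per unit impulse)."""

    theta_grid: np.ndarray
    Z: np.ndarray
    impulse: float
    component: str              # 'u' or 'v'
    relax_periods: int
    meta: dict = field(default_factory=dict)

    def eval(self, theta: np.ndarray) -> np.ndarray:
        th = np.asarray(theta, dtype=float) % (2 * np.pi)
        g = np.concatenate([self.theta_grid, [2 * np.pi]])
        z = np.concatenate([self.Z, self.Z[:1]])
        return np.interp(th, g, z)

    def first_harmonic_power_fraction(self) -> float:
        c = np.abs(np.fft.rfft(self.Z - self.Z.mean()))
        tot = np.sum(c[1:] ** 2)
        return float(c[1] ** 2 / tot) if tot > 0 else np.nan


@dataclass
class CouplingFunction:
    """Phase coupling function Gamma and its antisymmetric part gamma_a."""

    phi_grid: np.ndarray
    gamma: np.ndarray
    gamma_a: np.ndarray
    channel: str                # 'u' or 'v'
    meta: dict = field(default_factory=dict)

    def eval_a(self, phi: np.ndarray) -> np.ndarray:
        ph = np.asarray(phi, dtype=float) % (2 * np.pi)
        g = np.concatenate([self.phi_grid, [2 * np.pi]])
        z = np.concatenate([self.gamma_a, self.gamma_a[:1]])
        return np.interp(ph, g, z)

    def eval(self, phi: np.ndarray) -> np.ndarray:
        ph = np.asarray(phi, dtype=float) % (2 * np.pi)
        g = np.concatenate([self.phi_grid, [2 * np.pi]])
        z = np.concatenate([self.gamma, self.gamma[:1]])
        return np.interp(ph, g, z)


@dataclass
class LockingDiagram:
    fixed_points: list[tuple[float, str]]       # (phi*, 'stable'|'unstable')
    basins: dict                                 # initial phi -> attracting phi*
    delta_omega: float
    eps: float
    drifting: bool = False


def prc_direct(system: DDESystem, cycle: LimitCycle, impulse: float | None = None,
               n_phase: int = 64, component: str = "v",
               relax_periods: int = 20) -> PRC:
    """Measure the phase sensitivity by the direct (impulse) method.

    For each grid phase the oscillator is started on the converged cycle,
    the impulse is added to the *current* value of the chosen component only
    (the history segment is untouched, modelling an additive delta forcing),
    the system is integrated for ``relax_periods`` periods, and the
    asymptotic phase shift is read off from the offset of the late
    phase-origin crossing times relative to the unperturbed cycle.
    Z = shift / impulse; a phase advance is positive.
    """
    if cycle.quiescent:
        raise ValueError("cannot measure a PRC on a quiescent state")
    if component not in ("u", "v"):
        raise ValueError("component must be 'u' or 'v'")
    if relax_periods < 1:
        raise ValueError("relax_periods must be >= 1")
    T = cycle.period
    if impulse is None:
        impulse = 1e-3 * cycle.amplitude
    theta_grid = np.linspace(0, 2 * np.pi, n_phase, endpoint=False)
    t_len = (relax_periods + 3) * T
    Z = np.empty(n_phase)
    n_avg = 3

    # unperturbed control run from the phase origin; its measured crossing
    # comb (c0 + k*T_run) is the reference, which cancels any residual
    # convergence of the source cycle shared by all starts
    ctrl = _integrate_kicked(system, cycle.history_at_phase(0.0), t_len, 0.0, 0.0)
    cc = _origin_crossings(ctrl, cycle, t_min=2 * T)
    if len(cc) < n_avg:
        raise BasinEscape("control run lost the oscillation")
    kk = np.round((cc - cc[0]) / T)
    T_run, c0 = np.polyfit(kk, cc, 1)

    for i, th in enumerate(theta_grid):
        hist = cycle.history_at_phase(th)
        kick_u = impulse if component == "u" else 0.0
        kick_v = impulse if component == "v" else 0.0
        traj = _integrate_kicked(system, hist, t_len, kick_u, kick_v)
        pert = _origin_crossings(traj, cycle, t_min=2 * T)
        if len(pert) < n_avg:
            raise BasinEscape(f"no phase-origin crossings resumed at theta={th:g}")
        # a run started at phase th crosses the origin th/(2pi)*T earlier
        ref0 = c0 - th / (2 * np.pi) * T_run
        shifts = []
        for tc in pert:
            d = (ref0 - tc) % T_run         # reference minus perturbed
            if d > T_run / 2:
                d -= T_run
            shifts.append(d)
        Z[i] = (2 * np.pi / T_run) * _asymptotic_shift(np.array(shifts)) / impulse
    meta = {"impulse": impulse, "relax_periods": relax_periods,
            "period": T, "n_phase": n_phase}
    return PRC(theta_grid=theta_grid, Z=Z, impulse=impulse,
               component=component, relax_periods=relax_periods, meta=meta)


def _asymptotic_shift(shifts: np.ndarray) -> float:
    """Limit of an exponentially settling sequence of crossing-time shifts.

    The deviation of the perturbed orbit from the cycle decays geometrically
    (Floquet), so the shifts obey d_k ~ d_inf + C r^k; Aitken's delta-squared
    on the tail removes the leading transient.  Falls back to the tail mean
    when the sequence is already flat.
    """
    tail = shifts[-8:] if len(shifts) >= 8 else shifts
    d = np.diff(tail)
    if len(tail) >= 3 and np.max(np.abs(d)) > 1e-14:
        x0, x1, x2 = tail[-3], tail[-2], tail[-1]
        denom = x2 - 2 * x1 + x0
        if abs(denom) > 1e-15 and abs((x2 - x1) / denom) < 10:
            return float(x2 - (x2 - x1) ** 2 / denom)
    return float(np.mean(tail[-3:]))


def _integrate_kicked(system, hist, t_len, kick_u, kick_v):
    from .ddesim import History
    if kick_u == 0.0 and kick_v == 0.0:
        return system.integrate(hist, t_len)
    base_u, base_v = hist.u_fn, hist.v_fn

    def u_fn(t):
        out = np.array(base_u(t), dtype=float)
        tarr = np.atleast_1d(np.asarray(t, dtype=float))
        mask = np.abs(tarr) < 1e-15
        if out.ndim == 1:
            out = out[None, :] if out.shape[0] == hist.n and tarr.shape[0] == 1 else out
        out = np.atleast_2d(out)
        out[mask, :] += kick_u
        return out

    def v_fn(t):
        out = np.atleast_2d(np.array(base_v(t), dtype=float))
        tarr = np.atleast_1d(np.asarray(t, dtype=float))
        out[np.abs(tarr) < 1e-15, :] += kick_v
        return out

    return system.integrate(History(u_fn=u_fn, v_fn=v_fn, n=hist.n), t_len)


def _origin_crossings(traj, cycle: LimitCycle, t_min: float, idx: int = 0) -> np.ndarray:
    """Upward u=0 crossings belonging to the cycle's phase-origin family.

    Far from onset the waveform may have secondary upward crossings per
    period; crossings are matched to the origin family by the value of v at
    the crossing (the origin is the steepest one).
    """
    cr = upward_crossings(traj, t_min, idx)
    if len(cr) == 0:
        return cr
    # v at the cycle's own origin crossing
    v0 = cycle.eval_v(np.array([0.0]))[0]
    if v0 <= 0:       # defensive; origin has positive slope by construction
        return cr
    v_at = np.array([traj.eval_v(t)[idx] for t in cr])
    # all v-values the cycle attains at its upward crossings
    keep = np.abs(v_at - v0) <= 0.3 * abs(v0)
    if keep.sum() >= 3:
        return cr[keep]
    return cr


def gamma_convolution(prc: PRC, cycle: LimitCycle, channel: str = "u",
                      n_phi: int | None = None) -> CouplingFunction:
    """Phase coupling function by convolving Z with the diffusive signal.

    Gamma(phi) = (1/2pi) int Z(theta) [s(theta - phi) - s(theta)] d theta,
    per unit coupling intensity, where s is the cycle's u (or v) waveform
    and phi is own phase minus partner phase (see module docstring).
    Trapezoid rule on the common grid; gamma_a(phi) = Gamma(phi) - Gamma(-phi).
    """
    if channel not in ("u", "v"):
        raise ValueError("channel must be 'u' or 'v'")
    theta = prc.theta_grid
    n = len(theta)
    if n_phi is None:
        n_phi = n
    Z = prc.Z
    s = cycle.eval_u(theta) if channel == "u" else cycle.eval_v(theta)
    phi_grid = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    gamma = np.empty(n_phi)
    base = float(np.mean(Z * s))
    for k, phi in enumerate(phi_grid):
        s_shift = (cycle.eval_u(theta - phi) if channel == "u"
                   else cycle.eval_v(theta - phi))
        gamma[k] = float(np.mean(Z * s_shift)) - base
    # antisymmetric part on the same grid: gamma(-phi) = gamma[(n-k) % n]
    gamma_rev = gamma[(-np.arange(n_phi)) % n_phi]
    gamma_a = gamma - gamma_rev
    return CouplingFunction(phi_grid=phi_grid, gamma=gamma, gamma_a=gamma_a,
                            channel=channel,
                            meta={"n_phase": n, "impulse": prc.impulse})


def locking_analysis(gamma_a: CouplingFunction | np.ndarray,
                     delta_omega: float, eps: float,
                     phi_grid: np.ndarray | None = None,
                     n_basin: int = 100) -> LockingDiagram:
    """Fixed points, stability and basins of dpsi/dt = delta_omega + eps*gamma_a.

    Roots are bracketed on the grid and polished by bisection on the
    interpolant; a root with negative slope of the right-hand side is
    stable.  Basins of the 1-D circle flow are delimited by the unstable
    points.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if isinstance(gamma_a, CouplingFunction):
        ga = gamma_a.eval_a
        grid = gamma_a.phi_grid
    else:
        if phi_grid is None:
            raise ValueError("phi_grid required with a raw gamma_a array")
        arr = np.asarray(gamma_a, dtype=float)
        grid = np.asarray(phi_grid)
        g = np.concatenate([grid, [2 * np.pi]])
        z = np.concatenate([arr, arr[:1]])
        ga = lambda p: np.interp(np.asarray(p) % (2 * np.pi), g, z)

    f = lambda p: delta_omega + eps * np.asarray(ga(p))
    dense = np.linspace(0, 2 * np.pi, 4 * len(grid), endpoint=False)
    vals = f(dense)
    roots = []
    for k in range(len(dense)):
        a, b = dense[k], dense[(k + 1) % len(dense)] + (0 if k + 1 < len(dense) else 2 * np.pi)
        fa, fb = vals[k], vals[(k + 1) % len(dense)]
        if fa == 0.0:
            roots.append(a)
            continue
        if fa * fb < 0:
            lo, hi = a, b
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            roots.append(0.5 * (lo + hi) % (2 * np.pi))
    roots = sorted(set(np.round(roots, 12)))
    if not roots:
        return LockingDiagram(fixed_points=[], basins={}, delta_omega=delta_omega,
                              eps=eps, drifting=True)
    h = 1e-4
    fixed_points = []
    for r in roots:
        slope = (f(r + h) - f(r - h)) / (2 * h)
        fixed_points.append((float(r), "stable" if slope < 0 else "unstable"))

    # basins: between consecutive unstable points the flow converges to the
    # single stable point they enclose
    stable = [p for p, s in fixed_points if s == "stable"]
    unstable = [p for p, s in fixed_points if s == "unstable"]
    basins = {}
    init = np.linspace(0, 2 * np.pi, n_basin, endpoint=False)
    for phi0 in init:
        basins[float(phi0)] = _attractor_of(phi0, f, stable, unstable)
    return LockingDiagram(fixed_points=fixed_points, basins=basins,
                          delta_omega=delta_omega, eps=eps, drifting=False)


def _attractor_of(phi0, f, stable, unstable):
    if not stable:
        return np.nan
    sign = np.sign(f(phi0))
    if sign == 0:
        # started on a fixed point
        allp = stable + unstable
        return float(min(allp, key=lambda p: _circ_dist(p, phi0)))
    # move in the direction of the flow to the first stable point not blocked
    # by an unstable one
    cands = []
    for p in stable:
        d = (p - phi0) % (2 * np.pi) if sign > 0 else (phi0 - p) % (2 * np.pi)
        cands.append((d, p))
    for d, p in sorted(cands):
        blocked = False
        for q in unstable:
            dq = (q - phi0) % (2 * np.pi) if sign > 0 else (phi0 - q) % (2 * np.pi)
            if 1e-12 < dq < d:
                blocked = True
                break
        if not blocked:
            return float(p)
    return float(min(stable, key=lambda p: _circ_dist(p, phi0)))


def _circ_dist(a, b):
    d = abs(a - b) % (2 * np.pi)
    return min(d, 2 * np.pi - d)


def critical_coupling(gamma_a: CouplingFunction, delta_omega: float) -> float:
    """Smallest eps for which a locked state of dpsi/dt = dw + eps*gamma_a exists.

    eps_c = |delta_omega| / max(-sign(delta_omega) * gamma_a); the
    denominator is the excursion of gamma_a opposing the detuning.  Zero for
    identical oscillators.
    """
    ga = np.asarray(gamma_a.gamma_a, dtype=float)
    if np.max(np.abs(ga)) < 1e-15:
        raise NoLockingChannel("gamma_a vanishes identically: no locking through "
                               "this channel")
    if delta_omega == 0:
        return 0.0
    opposing = np.max(-np.sign(delta_omega) * ga)
    if opposing <= 0:
        return np.inf
    return float(abs(delta_omega) / opposing)
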