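"""Test fixtures with independent closed-form references.

Each fixture couples a generator (something the package's machinery can
run) with a reference evaluator derived by a route independent of the
integrator: the Stuart-Landau oscillator has an exact radial/phase
solution and an exact phase sensitivity; the linear delayed oscillator is
solved interval-by-interval in closed form with sympy; the sine signal is
its own reference; population samples are plain seeded draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .ddesim import Trajectory, History
from .model import ModelParams

__all__ = ["make_fixture", "StuartLandauSystem", "LinearDDEReference",
           "sine_trajectory", "population_sample"]


# ---------------------------------------------------------------------------
# Stuart-Landau planar oscillator


@dataclass
class StuartLandauSystem:
    """Planar normal-form oscillator dz/dt = (mu + i w) z + c z |z|^2.

    Presented through the same surface as the delay system: ``integrate``
    returns a :class:`Trajectory` whose stored components are u = Re z and
    v = du/dt, so the phase-origin machinery (upward u = 0 crossings) and
    the direct PRC measurement work unchanged.  Impulses can therefore be
    applied to the u component; the closed-form sensitivity for such kicks
    is :meth:`analytic_Z_u`.
    """

    mu: float = 0.05
    omega: float = 1.0
    c: complex = -1.0 + 0.5j
    delay: float = 0.0          # interface compatibility; no delay here

    @property
    def R_inf(self) -> float:
        if self.mu <= 0 or self.c.real >= 0:
            return 0.0
        return float(np.sqrt(-self.mu / self.c.real))

    @property
    def Omega(self) -> float:
        """Frequency on the limit cycle."""
        return float(self.omega + self.c.imag * self.R_inf ** 2)

    def _zdot(self, z: complex) -> complex:
        return (self.mu + 1j * self.omega) * z + self.c * z * abs(z) ** 2

    def _y_from_uv(self, u: float, v: float) -> float:
        """Recover Im z from (u = Re z, v = d Re z / dt)."""
        def f(y):
            return self._zdot(complex(u, y)).real - v
        R = max(2.0 * self.R_inf, abs(u) + 1.0, 1.0)
        span = 4.0 * R * (abs(self.omega) + abs(self.c.imag) * R * R + 1.0)
        lo, hi = -span, span
        return brentq(f, lo, hi, xtol=1e-14)

    def integrate(self, history: History | float, t_end: float,
                  dt: float | None = None) -> Trajectory:
        if dt is None:
            dt = 2 * np.pi / abs(self.Omega if self.Omega != 0 else self.omega) / 200
        if isinstance(history, History):
            # Impulse protocols kick u at t = 0 only, so Im z must be
            # reconstructed from the smooth pre-kick state: recover (x, y)
            # a moment before zero, advance to zero, then add whatever jump
            # the history carries at t = 0.
            delta = dt / 4.0
            um = float(np.atleast_2d(history.u_fn(np.array([-delta])))[-1, 0])
            vm = float(np.atleast_2d(history.v_fn(np.array([-delta])))[-1, 0])
            ym = self._y_from_uv(um, vm)
            z = complex(um, ym)
            k1 = self._zdot(z)
            k2 = self._zdot(z + 0.5 * delta * k1)
            k3 = self._zdot(z + 0.5 * delta * k2)
            k4 = self._zdot(z + delta * k3)
            z = z + delta / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            u0 = float(np.atleast_2d(history.u_fn(np.array([0.0])))[-1, 0])
            z = complex(u0, z.imag)     # any jump at t=0 lands in Re z
        else:
            z = complex(float(history), 0.0)
        nsteps = int(np.ceil(t_end / dt))
        K = nsteps + 1
        times = np.arange(K) * dt
        U = np.empty((K, 1))
        V = np.empty((K, 1))
        A = np.empty((K, 1))

        for k in range(K):
            dz = self._zdot(z)
            U[k, 0] = z.real
            V[k, 0] = dz.real
            # d2u/dt2 = Re[ dF/dz * dz + dF/dzbar * conj(dz) ] via complex step
            h = 1e-6
            d2 = (self._zdot(z + h * dz) - self._zdot(z - h * dz)).real / (2 * h)
            A[k, 0] = d2
            if k < K - 1:
                k1 = self._zdot(z)
                k2 = self._zdot(z + 0.5 * dt * k1)
                k3 = self._zdot(z + 0.5 * dt * k2)
                k4 = self._zdot(z + dt * k3)
                z = z + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        return Trajectory(times=times, u=U, v=V, acc=A, dt=dt, delay=0.0,
                          meta={"system": "stuart_landau"})

    # ---- closed forms -----------------------------------------------------

    def radial_solution(self, R0: float, t: np.ndarray) -> np.ndarray:
        """|z|(t) from |z|(0) = R0, exact logistic-in-R^2 solution."""
        t = np.asarray(t, dtype=float)
        mu, cr = self.mu, self.c.real
        if mu == 0:
            return R0 / np.sqrt(1.0 - 2.0 * cr * R0 * R0 * t)
        y0 = R0 * R0
        e = np.exp(2.0 * mu * t)
        y = (y0 * e) / (1.0 + (-cr) * y0 * (e - 1.0) / mu)
        return np.sqrt(y)

    def analytic_Z_u(self, theta: np.ndarray) -> np.ndarray:
        """Phase sensitivity to kicks in u = Re z, theta = 0 at upward u = 0.

        Isochron gradient of the normal form: for a kick (dx, dy),
        dTheta = [(-sin phi - chi cos phi) dx + (cos phi - chi sin phi) dy]/R
        with chi = Im c / Re c; theta = phi + pi/2.
        """
        chi = self.c.imag / self.c.real
        R = self.R_inf
        phi = np.asarray(theta, dtype=float) - np.pi / 2.0
        return (-np.sin(phi) - chi * np.cos(phi)) / R


# ---------------------------------------------------------------------------
# linear delayed oscillator, symbolic method-of-steps reference


def _integrate_poly_exp(expr, s, lo, hi):
    """Exact definite integral of a sum of c * s^k * exp(sigma s) terms.

    Deterministic replacement for the general symbolic integrator, which
    is all the variation-of-parameters construction below needs.
    """
    import sympy as sp
    expr = sp.expand(expr)
    total = sp.S.Zero
    for term in sp.Add.make_args(expr):
        coeff, rest = term.as_independent(s)
        poly = sp.S.One
        sigma = sp.S.Zero
        for f in sp.Mul.make_args(rest):
            if isinstance(f, sp.exp):
                arg = sp.expand(f.args[0])
                sig = arg.coeff(s, 1)
                if sp.simplify(arg - sig * s) != 0:
                    raise ValueError(f"unexpected exponential argument {arg}")
                sigma += sig
            else:
                poly *= f
        k = sp.degree(sp.Poly(poly, s))
        if sp.expand(poly - s ** k) != 0:
            raise ValueError(f"unexpected non-monomial factor {poly}")
        if sigma == 0:
            anti = s ** (k + 1) / (k + 1)
        else:
            # repeated integration by parts of s^k e^{sigma s}
            anti = sp.S.Zero
            for j in range(k + 1):
                anti += ((-1) ** j * sp.factorial(k) / sp.factorial(k - j)
                         * s ** (k - j) / sigma ** (j + 1))
            anti *= sp.exp(sigma * s)
        total += coeff * (anti.subs(s, hi) - anti.subs(s, lo))
    return sp.expand(total)


class LinearDDEReference:
    """Exact solution of u'' = -2 g u' - (g^2 - a) u - b u(t - tau).

    Starting from a constant history u = u0, v = 0 the solution on each
    interval [k tau, (k+1) tau] satisfies a constant-coefficient linear ODE
    forced by the (already known) solution one delay earlier; sympy solves
    the intervals recursively, so the reference is independent of any
    numerical integrator.
    """

    def __init__(self, params: ModelParams, u0: float = 1.0, n_intervals: int = 3):
        import sympy as sp
        t, s = sp.symbols("t s")
        # exact rational coefficients keep the interval-by-interval algebra
        # well conditioned; the homogeneous roots -g +- sqrt(a) should be
        # rational for fast symbolic quadrature (e.g. a = 1/4)
        g = sp.Rational(str(params.damping))
        a = sp.Rational(str(params.gain_a))
        b = sp.Rational(str(params.gain_b))
        tau = sp.Rational(str(params.delay))
        r1 = -g + sp.sqrt(a)
        r2 = -g - sp.sqrt(a)
        if r1 == r2:
            raise ValueError("degenerate homogeneous roots; pick gain_a != 0")
        pieces = [sp.Rational(str(u0)) + 0 * t]       # on [-tau, 0]
        left_u, left_v = sp.Rational(str(u0)), sp.Integer(0)
        for k in range(n_intervals):
            t0 = k * tau
            forcing = -b * pieces[-1].subs(t, s - tau)
            # variation of parameters: Green kernel of y'' + 2g y' + (g^2-a) y
            kern = (sp.exp(r1 * (t - s)) - sp.exp(r2 * (t - s))) / (r1 - r2)
            u_p = _integrate_poly_exp(sp.expand(kern * forcing), s, t0, t)
            A, B = sp.symbols("A B")
            sol = (u_p + A * sp.exp(r1 * (t - t0)) + B * sp.exp(r2 * (t - t0)))
            cs = sp.solve([sp.Eq(A + B, left_u),
                           sp.Eq(A * r1 + B * r2, left_v)], [A, B])
            sol = sp.expand(sol.subs(cs))
            pieces.append(sol)
            t1 = (k + 1) * tau
            left_u = sol.subs(t, t1)
            left_v = sol.diff(t).subs(t, t1)
        self._t = t
        self._tau = float(params.delay)
        self._pieces = pieces
        self._lamb = [None] + [sp.lambdify(t, p, "numpy") for p in pieces[1:]]
        self.n_intervals = n_intervals

    def u(self, times: np.ndarray) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.empty_like(times)
        for i, tt in enumerate(times):
            k = int(np.floor(tt / self._tau)) + 1
            k = min(max(k, 1), self.n_intervals)
            out[i] = float(self._lamb[k](tt))
        return out


# ---------------------------------------------------------------------------
# simple signals and population draws


def sine_trajectory(period: float, amplitude: float = 1.0, t_end: float = 50.0,
                    dt: float = 0.01, phase0: float = 0.0) -> Trajectory:
    """A pure sine presented as a Trajectory (u = A sin, v = u', acc = u'')."""
    K = int(np.ceil(t_end / dt)) + 1
    times = np.arange(K) * dt
    w = 2 * np.pi / period
    U = amplitude * np.sin(w * times + phase0)[:, None]
    V = amplitude * w * np.cos(w * times + phase0)[:, None]
    A = -amplitude * w * w * np.sin(w * times + phase0)[:, None]
    return Trajectory(times=times, u=U, v=V, acc=A, dt=dt, delay=0.0,
                      meta={"system": "sine", "period": period})


def population_sample(n: int, seed: int, mu_center: float, mu_width: float,
                      omega_center: float, omega_width: float) -> np.ndarray:
    """Seeded draws of per-oscillator (mu_j, omega_j), uniform and independent.

    Returns an (n, 2) array; identical seeds give identical draws.
    """
    rng = np.random.default_rng(seed)
    mu = mu_center + mu_width * (rng.random(n) - 0.5) * 2.0
    om = omega_center + omega_width * (rng.random(n) - 0.5) * 2.0
    return np.column_stack([mu, om])


_KINDS = ("stuart_landau_ode", "linear_dde", "sine_signal", "population_sample")


@dataclass
class Fixture:
    kind: str
    generator: object
    reference: Callable | None
    params: dict = field(default_factory=dict)


def make_fixture(kind: str, params: dict | None = None, seed: int = 0) -> Fixture:
    """Build a named fixture; unknown kinds raise with the list of valid ones."""
    params = dict(params or {})
    if kind == "stuart_landau_ode":
        sl = StuartLandauSystem(**params)
        return Fixture(kind, sl, sl.analytic_Z_u, params)
    if kind == "linear_dde":
        mp = params.pop("params", ModelParams(delay=1.0, damping=1.0, gain_a=1.0,
                                              gain_b=1.0, nl2=0.0, nl3=0.0))
        ref = LinearDDEReference(mp, **params)
        return Fixture(kind, mp, ref.u, {"params": mp, **params})
    if kind == "sine_signal":
        traj = sine_trajectory(**params)
        period = params.get("period", 1.0)
        return Fixture(kind, traj, lambda t: np.sin(2 * np.pi * np.asarray(t) / period),
                       params)
    if kind == "population_sample":
        draws = population_sample(seed=seed, **params)
        return Fixture(kind, draws, None, params)
    raise ValueError(f"unknown fixture kind {kind!r}; valid kinds: {_KINDS}")
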