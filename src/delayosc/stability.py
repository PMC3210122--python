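"""Linear stability of the rest state and the Hopf bifurcation curve.

Linearizing the single-oscillator equation about ``u = 0`` with the ansatz
``u ~ exp(lambda t)`` gives the transcendental characteristic equation

.. math::

    \\Delta(\\lambda) = \\lambda^2 + 2\\gamma\\lambda + (\\gamma^2 - a)
                       + b\\, e^{-\\lambda\\tau} = 0 .

The rest state loses stability through a Hopf bifurcation when the delayed
feedback gain ``b`` crosses a critical value ``b_c(a)``: a conjugate pair of
roots crosses the imaginary axis at ``\\pm i \\omega_c``.  On the lowest
branch ``\\omega_c \\tau \\in (0, \\pi)`` and ``b_c = 2\\gamma\\omega_c /
\\sin(\\omega_c\\tau) > 0``.  Only this slow-wave branch is traced here;
higher delay-induced branches are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams

__all__ = [
    "char_residual",
    "char_derivative",
    "find_hopf",
    "hopf_curve",
    "leading_roots",
    "HopfPoint",
    "SpectrumReport",
    "RootNotFound",
    "DegenerateBifurcation",
]

RESIDUAL_POLISH_TOL = 1e-12
RESIDUAL_ACCEPT_TOL = 1e-10
DEDUP_RADIUS = 1e-8


class RootNotFound(RuntimeError):
    pass


class DegenerateBifurcation(RuntimeError):
    pass


@dataclass(frozen=True)
class HopfPoint:
    """One point on the Hopf bifurcation curve b = b_c(a)."""

    gain_critical: float    # critical delayed-feedback gain b_c
    omega_c: float          # Hopf frequency (rad / time)
    residual: float         # |Delta(i omega_c)| at (a, b_c)
    second_gain: float      # the instantaneous gain a (curve coordinate)


@dataclass
class SpectrumReport:
    roots: list[complex]    # sorted by descending real part, conjugates included
    stable: bool


def char_residual(lam: complex, params: ModelParams) -> complex:
    """Characteristic function Delta(lambda); zero iff lambda is a root."""
    g, a, b, tau = params.damping, params.gain_a, params.gain_b, params.delay
    lam = complex(lam)
    return lam * lam + 2.0 * g * lam + (g * g - a) + b * np.exp(-lam * tau)


def char_derivative(lam: complex, params: ModelParams) -> complex:
    """d Delta / d lambda (used by Newton polish and by the Hale pairing)."""
    g, b, tau = params.damping, params.gain_b, params.delay
    lam = complex(lam)
    return 2.0 * lam + 2.0 * g - b * tau * np.exp(-lam * tau)


def _omega_equation(omega: float, params: ModelParams) -> float:
    """Real part of Delta(i omega) after eliminating b via the imaginary part.

    Im Delta(i w) = 0 with b = 2 g w / sin(w tau); substituting into the real
    part gives  g^2 - a - w^2 + 2 g w cot(w tau) = 0.
    """
    g, a, tau = params.damping, params.gain_a, params.delay
    s = np.sin(omega * tau)
    c = np.cos(omega * tau)
    return (g * g - a - omega * omega) * s + 2.0 * g * omega * c


def find_hopf(params_template: ModelParams,
              omega_bracket: tuple[float, float] | None = None) -> HopfPoint:
    """Locate the Hopf point (omega_c, b_c) at fixed second gain a.

    Solves Re and Im of ``Delta(i omega) = 0`` simultaneously for
    ``(omega, b)``: the imaginary part fixes ``b(omega)`` in closed form and
    the real part becomes a scalar root problem in ``omega`` on the lowest
    branch ``omega tau in (0, pi)``.  Transversality
    ``d Re(lambda)/db > 0`` is verified before returning.
    """
    tau = params_template.delay
    if omega_bracket is None:
        omega_bracket = (1e-6 / tau, np.pi * (1.0 - 1e-9) / tau)
    lo, hi = omega_bracket
    f = lambda w: _omega_equation(w, params_template)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise RootNotFound(
            f"no sign change of the Hopf condition in omega bracket ({lo:g}, {hi:g})")
    omega_c = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    g = params_template.damping
    b_c = 2.0 * g * omega_c / np.sin(omega_c * tau)
    at_crit = params_template.with_gain_b(b_c)
    res = abs(char_residual(1j * omega_c, at_crit))

    # transversality: d lambda / d b = -exp(-lambda tau) / Delta'(lambda)
    dlam_db = -np.exp(-1j * omega_c * tau) / char_derivative(1j * omega_c, at_crit)
    if not dlam_db.real > 0:
        raise DegenerateBifurcation(
            f"transversality failed at a={params_template.gain_a:g}: "
            f"d Re(lambda)/db = {dlam_db.real:g}")
    return HopfPoint(gain_critical=b_c, omega_c=omega_c, residual=res,
                     second_gain=params_template.gain_a)


def hopf_curve(second_gain_values: np.ndarray,
               params_template: ModelParams) -> list[HopfPoint]:
    """Trace the stability boundary b_c(a) over the given a values.

    Each point is continued from the previous solution (the previous
    ``omega_c`` seeds a local bracket); if continuation loses the branch the
    partial result is returned with a warning.
    """
    values = np.asarray(second_gain_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 second-gain values")
    if np.any(np.diff(values) <= 0):
        raise ValueError("second-gain values must be sorted ascending")
    out: list[HopfPoint] = []
    prev_omega = None
    tau = params_template.delay
    for i, a in enumerate(values):
        tpl = params_template.with_gain_a(a)
        bracket = None
        if prev_omega is not None:
            # local bracket around the previous frequency, widened until the
            # sign changes; falls back to the full branch bracket
            for width in (0.1, 0.3, 1.0):
                lo = max(1e-6 / tau, prev_omega * (1 - width))
                hi = min(np.pi * (1 - 1e-9) / tau, prev_omega * (1 + width))
                if _omega_equation(lo, tpl) * _omega_equation(hi, tpl) < 0:
                    bracket = (lo, hi)
                    break
        try:
            hp = find_hopf(tpl, bracket)
        except RootNotFound:
            import warnings
            warnings.warn(f"Hopf continuation lost the branch at index {i} "
                          f"(a={a:g}); returning {len(out)} points")
            return out
        if hp.residual > RESIDUAL_ACCEPT_TOL:
            import warnings
            warnings.warn(f"residual {hp.residual:g} above tolerance at index {i}")
            return out
        out.append(hp)
        prev_omega = hp.omega_c
    return out


def _newton_polish(lam: complex, params: ModelParams,
                   maxit: int = 60) -> complex | None:
    for _ in range(maxit):
        f = char_residual(lam, params)
        if abs(f) < RESIDUAL_POLISH_TOL:
            return lam
        df = char_derivative(lam, params)
        if df == 0:
            return None
        step = f / df
        lam = lam - step
        if not np.isfinite(lam.real) or not np.isfinite(lam.imag):
            return None
        if abs(step) < 1e-16 * max(1.0, abs(lam)):
            break
    return lam if abs(char_residual(lam, params)) < RESIDUAL_POLISH_TOL else None


def leading_roots(params: ModelParams, real_floor: float = -5.0,
                  n_max: int = 20, grid: int = 40) -> SpectrumReport:
    """Characteristic roots with Re(lambda) > real_floor.

    Newton refinement from a grid of seeds over the complex window
    ``Re in [real_floor, re_max]``, ``Im in [0, 3 pi / tau]`` (the delay sets
    the spectral density scale); conjugates are added by symmetry and
    duplicates removed.  An empty list with ``stable=True`` is a valid
    outcome.
    """
    if real_floor >= 0:
        raise ValueError("real_floor must be negative")
    tau = params.delay
    re_max = max(1.0, 2.0 * params.damping)
    res = np.linspace(real_floor, re_max, grid)
    ims = np.linspace(0.0, 3.0 * np.pi / tau, grid)
    found: list[complex] = []
    for re in res:
        for im in ims:
            lam = _newton_polish(complex(re, im), params)
            if lam is None:
                continue
            if lam.real <= real_floor or lam.real > re_max + 1.0:
                continue
            if lam.imag < -DEDUP_RADIUS or lam.imag > 3.0 * np.pi / tau + 1.0:
                continue
            lam = complex(lam.real, abs(lam.imag))
            if any(abs(lam - r) < DEDUP_RADIUS * max(1.0, abs(r)) for r in found):
                continue
            found.append(lam)
    roots: list[complex] = []
    for r in found:
        roots.append(r)
        if r.imag > DEDUP_RADIUS:
            roots.append(r.conjugate())
    roots.sort(key=lambda z: (-z.real, abs(z.imag), -z.imag))
    roots = roots[:n_max]
    stable = all(r.real < 0 for r in roots)
    return SpectrumReport(roots=roots, stable=stable)
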