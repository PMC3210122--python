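"""Center-manifold reduction of the delay oscillator near its Hopf point.

Following Hale's theory, the infinite-dimensional state (the history
segment) is decomposed into a two-dimensional center-eigenspace component
and its complement.  With the critical eigenfunction
``phi(theta) = q exp(i w theta)`` on [-tau, 0] and the dual eigenfunction
``psi(s) = p exp(-i w s)`` on [0, tau], normalized so that the Hale
bilinear pairing ``<psi, phi> = 1``, the center coordinate is
``z(t) = <psi, x_t>`` and ``u(t) = 2 Re z(t)`` at lowest order.

Treating the bifurcation offset ``nu = b - b_c`` as a third, frozen
dynamical variable of the same order as ``|z|^2`` (the extended-system
trick), every perturbation that enters the acceleration equation is
projected through the complex scalar ``kappa = 1 / Delta'(i w)``:

* offset (unfolding):  -nu kappa (E z + conj(E) conj(z)),  E = exp(-i w tau)
* cubic nonlinearity:  -c3 kappa (z + conj(z))^3
* diffusive coupling:  kappa [eps_u (u_k - u_j) + eps_v (v_k - v_j)]

Keeping all terms gives the coupled planar amplitude equations; rotating
at the critical frequency and averaging away the non-resonant terms gives
the network complex Ginzburg-Landau (Stuart-Landau) equations

    dz_j/dt = (mu_j + i Omega_j) z_j + c z_j |z_j|^2
              + sum_k (eps_u_jk kappa + eps_v_jk i w kappa) (z_k - z_j),

with growth rate ``mu_j = nu_j Re(dlambda/db)`` and cubic coefficient
``c = -3 c3 kappa`` (supercritical iff Re c < 0).  The analytic phase
sensitivity, the analytic phase coupling functions and the amplitude-death
eigenvalues all follow from these coefficients in closed form.

The reduction requires the quadratic model coefficient ``nl2`` to vanish:
only then does the second-order center-manifold correction drop out of the
third-order equation.  A nonzero quadratic coefficient is rejected
explicitly rather than silently approximated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelParams, CouplingMatrix
from .stability import HopfPoint, char_derivative, find_hopf
from .phase import PRC, CouplingFunction

__all__ = [
    "CenterBasis",
    "OscillatorReduction",
    "AmplitudeSystem",
    "CGLParams",
    "DeathEigenvalues",
    "build_center_basis",
    "amplitude_equation",
    "cgl_reduce",
    "analytic_Z",
    "analytic_gamma",
    "death_eigenvalues",
    "death_threshold",
    "UnsupportedCase",
    "NoCycle",
    "DegenerateEigenpair",
]


class UnsupportedCase(ValueError):
    pass


class NoCycle(ValueError):
    pass


class DegenerateEigenpair(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# center basis and Hale pairing


@dataclass
class CenterBasis:
    """Basis and dual basis of the center eigenspace at the Hopf point.

    ``phi(theta)``, theta in [-tau, 0], spans the eigenspace of +i omega_c
    (the conjugate pair is implicit); ``psi(s)``, s in [0, tau], is the dual
    eigenfunction, normalized so the Hale pairing matrix of (psi, conj(psi))
    against (phi, conj(phi)) is the identity.  The bifurcation-offset
    direction is a trivial third basis element (eigenvalue 0 of the frozen
    parameter) and is represented implicitly by the unfolding coefficient.
    """

    omega_c: float
    gain_critical: float
    params_crit: ModelParams
    q: np.ndarray                   # right eigenvector (1, i omega)
    p: np.ndarray                   # dual eigenvector, normalized
    kappa: complex                  # p[1]; projection of acceleration forcing
    normalization_matrix: np.ndarray

    def phi(self, theta):
        theta = np.asarray(theta, dtype=float)
        return np.exp(1j * self.omega_c * theta)[..., None] * self.q

    def psi(self, s):
        s = np.asarray(s, dtype=float)
        return np.exp(-1j * self.omega_c * s)[..., None] * self.p


def hale_pairing(psi_fn, phi_fn, params: ModelParams, n_quad: int = 20001) -> complex:
    """<psi, phi> = psi(0) phi(0) + int_{-tau}^{0} psi(s+tau) L1 phi(s) ds.

    L1 is the delayed part of the linearization, which acts only on the u
    component with weight -b.  Composite trapezoid quadrature.
    """
    tau, b = params.delay, params.gain_b
    s = np.linspace(-tau, 0.0, n_quad)
    psi_v = np.atleast_2d(psi_fn(s + tau))
    phi_v = np.atleast_2d(phi_fn(s))
    integrand = psi_v[..., 1] * (-b) * phi_v[..., 0]
    integral = np.trapezoid(integrand, s)
    return complex(np.dot(np.atleast_1d(psi_fn(0.0)).ravel(),
                          np.atleast_1d(phi_fn(0.0)).ravel()) + integral)


def build_center_basis(hopf: HopfPoint, params: ModelParams) -> CenterBasis:
    """Construct and normalize the center eigenspace basis and its dual."""
    if hopf.residual > 1e-8:
        raise ValueError("HopfPoint residual too large for a reliable basis")
    w = hopf.omega_c
    p_crit = params.with_gain_b(hopf.gain_critical)
    g = p_crit.damping
    q = np.array([1.0, 1j * w])
    p_raw = np.array([1j * w + 2.0 * g, 1.0])
    norm = char_derivative(1j * w, p_crit)       # equals <p_raw psi, q phi>
    if abs(norm) < 1e-12:
        raise DegenerateEigenpair("Hale pairing matrix is singular "
                                  "(double Hopf or defective eigenpair)")
    p = p_raw / norm
    basis = CenterBasis(omega_c=w, gain_critical=hopf.gain_critical,
                        params_crit=p_crit, q=q, p=p, kappa=p[1],
                        normalization_matrix=np.eye(2))
    # normalization matrix from the closed-form pairing:
    # <psi, phi> = 1 by construction, <psi, conj(phi)> = 0 by orthogonality
    m11 = hale_pairing(basis.psi, basis.phi, p_crit)
    m12 = hale_pairing(basis.psi, lambda th: np.conj(basis.phi(th)), p_crit)
    basis.normalization_matrix = np.array([[m11, m12],
                                           [np.conj(m12), np.conj(m11)]])
    return basis


# ---------------------------------------------------------------------------
# amplitude equations (planar, non-averaged)


@dataclass
class OscillatorReduction:
    """Reduction data of one oscillator about its own Hopf point."""

    params: ModelParams
    omega_c: float
    gain_critical: float
    nu: float                   # bifurcation offset b - b_c
    kappa: complex              # 1 / Delta'(i omega_c)
    E: complex                  # exp(-i omega_c tau)
    dlam_db: complex            # -E / Delta'(i omega_c)
    c: complex                  # cubic coefficient -3 c3 kappa

    @property
    def mu(self) -> float:
        """Linear growth rate of the amplitude."""
        return self.nu * self.dlam_db.real

    @property
    def omega(self) -> float:
        """Linear frequency including the offset-induced shift."""
        return self.omega_c + self.nu * self.dlam_db.imag


def _reduce_oscillator(p: ModelParams) -> OscillatorReduction:
    if p.nl2 != 0.0:
        raise UnsupportedCase(
            "analytic reduction is implemented for nl2 = 0 only; the "
            "second-order center-manifold correction does not vanish otherwise")
    hp = find_hopf(p)
    crit = p.with_gain_b(hp.gain_critical)
    w = hp.omega_c
    dchar = char_derivative(1j * w, crit)
    kappa = 1.0 / dchar
    E = np.exp(-1j * w * p.delay)
    return OscillatorReduction(params=p, omega_c=w,
                               gain_critical=hp.gain_critical,
                               nu=p.gain_b - hp.gain_critical,
                               kappa=kappa, E=E, dlam_db=-E * kappa,
                               c=-3.0 * p.nl3 * kappa)


@dataclass
class AmplitudeSystem:
    """Coupled planar amplitude equations (complex form, non-averaged).

    For each oscillator, in the lab frame,

        dz_j/dt = i w_j z_j + kappa_j [ -nu_j (E_j z_j + conj(E_j z_j))
                   - c3 (z_j + conj z_j)^3
                   + sum_k eps_u_jk ((z_k + conj z_k) - (z_j + conj z_j))
                   + sum_k eps_v_jk i ( w_k z_k - conj(w_k z_k)
                                      - w_j z_j + conj(w_j z_j) ) ]

    with u_j = 2 Re z_j.  This keeps the non-resonant terms that the
    averaged Ginzburg-Landau form drops.
    """

    oscillators: list[OscillatorReduction]
    coupling: CouplingMatrix | None = None

    @property
    def n(self) -> int:
        return len(self.oscillators)

    def rhs(self, z: np.ndarray) -> np.ndarray:
        oscs = self.oscillators
        out = np.empty(self.n, dtype=complex)
        u = 2.0 * z.real
        vlin = np.array([2.0 * (1j * o.omega_c * zj).real
                         for o, zj in zip(oscs, z)])
        for j, o in enumerate(oscs):
            f = -o.nu * (o.E * z[j] + np.conj(o.E * z[j]))
            f = f - o.params.nl3 * (z[j] + np.conj(z[j])) ** 3
            if self.coupling is not None:
                f = f + np.dot(self.coupling.eps_u[j], u) \
                      - self.coupling.eps_u[j].sum() * u[j]
                f = f + np.dot(self.coupling.eps_v[j], vlin) \
                      - self.coupling.eps_v[j].sum() * vlin[j]
            out[j] = 1j * o.omega_c * z[j] + o.kappa * f
        return out

    def linear_matrix_real(self, eps: float | None = None,
                           channel: str | None = None) -> np.ndarray:
        """Real 2n x 2n matrix of the linearization at the origin.

        If ``eps``/``channel`` are given they override the stored coupling
        with a symmetric pair coupling of that strength (n must be 2).
        """
        n = self.n
        alpha = np.zeros((n, n), dtype=complex)   # coefficient of z_k
        beta = np.zeros((n, n), dtype=complex)    # coefficient of conj(z_k)
        for j, o in enumerate(self.oscillators):
            alpha[j, j] = 1j * o.omega_c - o.nu * o.kappa * o.E
            beta[j, j] = -o.nu * o.kappa * np.conj(o.E)
        if eps is not None:
            if n != 2:
                raise ValueError("eps/channel override is for pairs only")
            eps_u = eps if channel == "u" else 0.0
            eps_v = eps if channel == "v" else 0.0
            cpl = CouplingMatrix.pair(eps_u=eps_u, eps_v=eps_v)
        else:
            cpl = self.coupling
        if cpl is not None:
            for j, o in enumerate(self.oscillators):
                for k, ok in enumerate(self.oscillators):
                    eu = cpl.eps_u[j, k]
                    ev = cpl.eps_v[j, k]
                    if j == k:
                        eu = -cpl.eps_u[j].sum()
                        ev = -cpl.eps_v[j].sum()
                    alpha[j, k] += o.kappa * (eu + 1j * ok.omega_c * ev)
                    beta[j, k] += o.kappa * (eu - 1j * ok.omega_c * ev)
        M = np.zeros((2 * n, 2 * n))
        for j in range(n):
            for k in range(n):
                al, be = alpha[j, k], beta[j, k]
                M[2 * j, 2 * k] = al.real + be.real
                M[2 * j, 2 * k + 1] = be.imag - al.imag
                M[2 * j + 1, 2 * k] = al.imag + be.imag
                M[2 * j + 1, 2 * k + 1] = al.real - be.real
        return M

    def simulate(self, z0: np.ndarray, t_end: float, rtol: float = 1e-9,
                 atol: float = 1e-11, max_step: float = np.inf):
        """Integrate the planar system; returns (t, z) with z shape (nt, n)."""
        z0 = np.asarray(z0, dtype=complex)
        y0 = np.concatenate([z0.real, z0.imag])

        def f(t, y):
            z = y[: self.n] + 1j * y[self.n:]
            dz = self.rhs(z)
            return np.concatenate([dz.real, dz.imag])

        sol = solve_ivp(f, (0.0, t_end), y0, rtol=rtol, atol=atol,
                        max_step=max_step, dense_output=False)
        z = sol.y[: self.n].T + 1j * sol.y[self.n:].T
        return sol.t, z


def amplitude_equation(params_list: list[ModelParams],
                       coupling: CouplingMatrix | None = None,
                       hopf: HopfPoint | None = None) -> AmplitudeSystem:
    """Reduce each oscillator about its own Hopf point and couple them.

    ``hopf`` may supply a precomputed critical point shared by identical
    oscillators; otherwise each oscillator's critical gain and frequency are
    located from its own second gain.  Coupling intensities are assumed to
    be of the same order as the bifurcation offsets.
    """
    if isinstance(params_list, ModelParams):
        params_list = [params_list]
    oscs = []
    for p in params_list:
        if (hopf is not None and abs(hopf.second_gain - p.gain_a) < 1e-12):
            crit = p.with_gain_b(hopf.gain_critical)
            w = hopf.omega_c
            kappa = 1.0 / char_derivative(1j * w, crit)
            E = np.exp(-1j * w * p.delay)
            if p.nl2 != 0.0:
                raise UnsupportedCase("analytic reduction requires nl2 = 0")
            oscs.append(OscillatorReduction(
                params=p, omega_c=w, gain_critical=hopf.gain_critical,
                nu=p.gain_b - hopf.gain_critical, kappa=kappa, E=E,
                dlam_db=-E * kappa, c=-3.0 * p.nl3 * kappa))
        else:
            oscs.append(_reduce_oscillator(p))
    return AmplitudeSystem(oscillators=oscs, coupling=coupling)


# ---------------------------------------------------------------------------
# averaged network Ginzburg-Landau equations


@dataclass
class CGLParams:
    """Coefficients of the averaged (Stuart-Landau / CGL) network equations.

    ``mu[j]`` linear growth rates, ``omega[j]`` linear frequencies (absolute,
    including the offset-induced shift), ``c[j]`` cubic coefficients (shared
    up to O(mu) differences across near-identical oscillators; ``c_mean``
    gives the network value), and per-channel projected coupling
    coefficients per unit intensity: ``d_u[j] = kappa_j`` and
    ``d_v[j] = i omega_j kappa_j``.
    """

    mu: np.ndarray
    omega: np.ndarray
    c: np.ndarray
    d_u: np.ndarray
    d_v: np.ndarray
    coupling: CouplingMatrix | None
    amplitude_system: AmplitudeSystem | None = None

    @property
    def n(self) -> int:
        return len(self.mu)

    @property
    def c_mean(self) -> complex:
        return complex(np.mean(self.c))

    def stationary_amplitude(self, j: int = 0) -> float:
        """|z|* of the uncoupled oscillator j (its u amplitude is twice this)."""
        if self.mu[j] <= 0:
            return 0.0
        return float(np.sqrt(-self.mu[j] / self.c[j].real))

    def oscillation_frequency(self, j: int = 0) -> float:
        """Frequency on the limit cycle, omega + Im(c) |z|*^2."""
        R2 = self.stationary_amplitude(j) ** 2
        return float(self.omega[j] + self.c[j].imag * R2)

    def relaxation_rate(self, j: int = 0) -> float:
        """Decay rate of amplitude perturbations towards the cycle (2 mu)."""
        return float(2.0 * self.mu[j])

    def rhs(self, z: np.ndarray) -> np.ndarray:
        out = (self.mu + 1j * self.omega) * z + self.c * z * np.abs(z) ** 2
        if self.coupling is not None:
            for j in range(self.n):
                d = (self.coupling.eps_u[j] * self.d_u[j]
                     + self.coupling.eps_v[j] * self.d_v[j])
                out[j] += np.dot(d, z) - d.sum() * z[j]
        return out

    def simulate(self, z0: np.ndarray, t_end: float, rtol: float = 1e-9,
                 atol: float = 1e-11):
        z0 = np.asarray(z0, dtype=complex)
        y0 = np.concatenate([z0.real, z0.imag])

        def f(t, y):
            z = y[: self.n] + 1j * y[self.n:]
            dz = self.rhs(z)
            return np.concatenate([dz.real, dz.imag])

        sol = solve_ivp(f, (0.0, t_end), y0, rtol=rtol, atol=atol)
        return sol.t, sol.y[: self.n].T + 1j * sol.y[self.n:].T


def cgl_reduce(amp: AmplitudeSystem,
               frequency_offsets: np.ndarray | None = None,
               warn_factor: float = 10.0) -> CGLParams:
    """Rotating-frame averaging of the planar system to the CGL network form.

    ``frequency_offsets`` optionally overrides the linear frequency shifts
    (they default to the offset-induced shifts ``nu Im(dlambda/db)``).  A
    warning is issued when the frequency spread exceeds ``warn_factor``
    times the mean growth rate, where the narrow-distribution assumption
    behind the averaging becomes doubtful.
    """
    oscs = amp.oscillators
    mu = np.array([o.mu for o in oscs])
    omega = np.array([o.omega for o in oscs])
    if frequency_offsets is not None:
        omega = np.array([o.omega_c for o in oscs]) + np.asarray(frequency_offsets)
    c = np.array([o.c for o in oscs])
    d_u = np.array([o.kappa for o in oscs])
    d_v = np.array([1j * o.omega_c * o.kappa for o in oscs])
    spread = omega.max() - omega.min()
    mean_mu = np.mean(np.abs(mu))
    if mean_mu > 0 and spread > warn_factor * mean_mu:
        import warnings
        warnings.warn(f"frequency spread {spread:g} large compared to growth "
                      f"rates {mean_mu:g}; averaging may be inaccurate")
    return CGLParams(mu=mu, omega=omega, c=c, d_u=d_u, d_v=d_v,
                     coupling=amp.coupling, amplitude_system=amp)


# ---------------------------------------------------------------------------
# analytic phase sensitivity and coupling functions


def _shear(cgl: CGLParams, j: int) -> float:
    c = cgl.c[j]
    if c.real >= 0:
        raise UnsupportedCase("subcritical cubic coefficient; no stable cycle")
    return c.imag / c.real


def analytic_Z(cgl: CGLParams, basis: CenterBasis | None = None,
               n_phase: int = 256, component: str = "v", j: int = 0) -> PRC:
    """Closed-form phase sensitivity of the CGL reduction, on a phase grid.

    A state kick (du, dv) maps to a center-coordinate kick
    dz = kappa [(i w + 2 gamma) du + dv]; the Stuart-Landau isochron
    gradient is (i - chi) e^{i phi} / R0 with shear chi = Im c / Re c, and
    theta = 0 is pinned to the upward u = 0 crossing (phi = -pi/2).  The
    result is a pure sinusoid whose amplitude scales as 1/R0 ~ 1/sqrt(mu).
    """
    if cgl.mu[j] <= 0:
        raise NoCycle(f"oscillator {j} is below onset (mu = {cgl.mu[j]:g})")
    osc = (cgl.amplitude_system.oscillators[j]
           if cgl.amplitude_system is not None else None)
    kappa = cgl.d_u[j]
    if basis is not None:
        kappa = basis.kappa
    w = osc.omega_c if osc is not None else cgl.omega[j]
    gamma = (osc.params.damping if osc is not None else 1.0)
    chi = _shear(cgl, j)
    R0 = cgl.stationary_amplitude(j)
    cv = kappa
    cu = (1j * w + 2.0 * gamma) * kappa
    ckick = cu if component == "u" else cv
    theta = np.linspace(0, 2 * np.pi, n_phase, endpoint=False)
    phi = theta - np.pi / 2.0
    # dTheta = Re[ conj((i - chi) e^{i phi}) ckick ] / R0
    Z = np.real((-1j - chi) * np.exp(-1j * phi) * ckick) / R0
    return PRC(theta_grid=theta, Z=Z, impulse=0.0, component=component,
               relax_periods=0,
               meta={"analytic": True, "R0": R0, "chi": chi})


def analytic_gamma(cgl: CGLParams, channel: str = "u", n_phi: int = 256,
                   j: int = 0) -> CouplingFunction:
    """Closed-form phase coupling function of the CGL reduction.

    With W = (-i - chi) kappa and Omega the cycle frequency,

        Gamma_u(phi) = Re[ W (e^{-i phi} - 1) ]
        Gamma_v(phi) = Re[ i Omega W (e^{-i phi} - 1) ]

    per unit coupling intensity (phi = own phase minus partner phase).  For
    this model W is purely imaginary, so the u-channel function is odd
    (it governs the phase-difference dynamics) while the v-channel function
    is even and drops out of the phase-difference equation entirely.
    """
    if channel not in ("u", "v"):
        raise ValueError("channel must be 'u' or 'v'")
    chi = _shear(cgl, j)
    kappa = cgl.d_u[j]
    W = (-1j - chi) * kappa
    Omega = cgl.oscillation_frequency(j)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    fac = W if channel == "u" else 1j * Omega * W
    gamma = np.real(fac * (np.exp(-1j * phi) - 1.0))
    gamma_rev = gamma[(-np.arange(n_phi)) % n_phi]
    return CouplingFunction(phi_grid=phi, gamma=gamma, gamma_a=gamma - gamma_rev,
                            channel=channel, meta={"analytic": True})


# ---------------------------------------------------------------------------
# amplitude death


@dataclass
class DeathEigenvalues:
    """Stability of the coupled rest state of an A-B style pair."""

    lambdas: np.ndarray             # exact eigenvalues of the 4-D planar system
    lambdas_cgl: np.ndarray         # closed-form eigenvalues of the averaged pair
    eps: float
    channel: str

    @property
    def max_real(self) -> float:
        return float(np.max(self.lambdas.real))

    @property
    def dead(self) -> bool:
        return self.max_real < 0


def death_eigenvalues(cgl: CGLParams, eps: float, channel: str = "u") -> DeathEigenvalues:
    """Eigenvalues of the origin of a diffusively coupled pair.

    Computes both the exact eigenvalues of the 4-dimensional real
    linearization of the planar amplitude equations and the closed-form
    eigenvalues of the averaged pair,

        lambda_pm = mean(m) - d eps +/- sqrt((d eps)^2 + (dm/2)^2),

    m_j = mu_j + i omega_j, dm = m_1 - m_2, obtained by splitting the
    coupled matrix into its symmetric part (eigenvectors (1,1) and (1,-1))
    and the mismatch perturbation.
    """
    if cgl.n != 2:
        raise ValueError("death analysis is defined for a pair")
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    if cgl.amplitude_system is None:
        raise ValueError("CGLParams must carry its amplitude system")
    M = cgl.amplitude_system.linear_matrix_real(eps=eps, channel=channel)
    lam_exact = np.linalg.eigvals(M)
    lam_exact = lam_exact[np.argsort(-lam_exact.real)]

    m = cgl.mu + 1j * cgl.omega
    d = 0.5 * (cgl.d_u if channel == "u" else cgl.d_v).sum()  # mean projection
    dm = m[0] - m[1]
    mean = 0.5 * (m[0] + m[1])
    root = np.sqrt((d * eps) ** 2 + (dm / 2.0) ** 2)
    lam_cgl = np.array([mean - d * eps + root, mean - d * eps - root])
    return DeathEigenvalues(lambdas=lam_exact, lambdas_cgl=lam_cgl,
                            eps=eps, channel=channel)


def death_threshold(cgl: CGLParams, channel: str = "u", eps_max: float = 10.0,
                    tol: float = 1e-8, use: str = "exact") -> float:
    """Smallest eps at which the coupled rest state becomes stable.

    Bisection on max Re(lambda) of the exact planar linearization (or of
    the averaged closed form with ``use='cgl'``).  Returns inf if the rest
    state never stabilizes below ``eps_max``.
    """

    def maxre(eps):
        de = death_eigenvalues(cgl, eps, channel)
        lam = de.lambdas if use == "exact" else de.lambdas_cgl
        return float(np.max(lam.real))

    if maxre(0.0) <= 0:
        return 0.0
    # find a bracket by geometric scan
    lo, hi = 0.0, None
    eps = 1e-3
    while eps <= eps_max:
        if maxre(eps) < 0:
            hi = eps
            break
        lo = eps
        eps *= 1.4
    if hi is None:
        return np.inf
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if maxre(mid) < 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
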