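"""End-to-end studies comparing the three levels of description.

Each experiment pits the full delay model against its reductions:

* critical coupling for synchronization of a detuned pair (full DDE vs
  planar amplitude equations vs the phase-coupling-function formula),
* amplitude death of the A-B pair (full DDE vs the eigenvalue threshold of
  the reduced pair),
* multimodal phase locking of an identical pair far from onset (full DDE
  basins vs the phase-difference flow),
* collective synchronization of an all-to-all population near onset
  (full DDE ensemble vs the reduced phase model, Kuramoto order parameter).

Every experiment is deterministic given (config, seed); grid points are
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams, CouplingMatrix
from .stability import find_hopf
from .ddesim import (integrate, find_limit_cycle, DDESystem, History,
                     LimitCycle, Trajectory)
from .phase import (prc_direct, gamma_convolution, locking_analysis,
                    critical_coupling, CouplingFunction, _origin_crossings)
from . import cmr
from .fixtures import population_sample

__all__ = [
    "ExperimentConfig",
    "PopulationEnsemble",
    "detuned_partner",
    "params_for_target",
    "pair_history",
    "measure_frequencies",
    "exp_critical_coupling",
    "exp_amplitude_death",
    "exp_multimodal",
    "exp_population",
    "kuramoto_order_parameter",
]

LOCK_TOL_FACTOR = 2 * np.pi * 1e-4      # lock when |f1-f2| < this / T
DEATH_AMP_FACTOR = 1e-6                 # dead when amp < this x uncoupled amp


@dataclass
class ExperimentConfig:
    """Common knobs shared by the experiment drivers."""

    experiment: str = ""
    labels: tuple = ("A", "B")
    channel: str = "u"
    sweep: np.ndarray | list = field(default_factory=list)
    seed: int = 0
    steps_per_delay: int = 40
    n_rotations: int = 1000          # frequency-averaging window for locking
    outdir: str | None = None

    def __post_init__(self):
        self.sweep = np.asarray(self.sweep, dtype=float)
        if self.sweep.size and np.any(np.diff(self.sweep) < 0):
            raise ValueError("sweep grid must be sorted")


# ---------------------------------------------------------------------------
# pair construction helpers


def params_for_target(template: ModelParams, mu_target: float,
                      omega_target: float,
                      a_bracket: tuple[float, float]) -> ModelParams:
    """Invert the reduction for (a, b) giving a prescribed cycle.

    Finds the second gain ``a`` and offset ``nu`` such that the reduced
    oscillator has growth rate ``mu_target`` (hence a prescribed amplitude
    up to the slowly varying cubic coefficient) and full nonlinear
    frequency ``omega_target`` (including both the offset-induced linear
    shift and the amplitude-dependent shift).
    """

    def osc_for(a):
        hp = find_hopf(template.with_gain_a(a))
        tpl = template.with_gain_a(a).with_gain_b(hp.gain_critical)
        o = cmr.amplitude_equation([tpl], hopf=hp).oscillators[0]
        nu = mu_target / o.dlam_db.real
        p = template.with_gain_a(a).with_gain_b(hp.gain_critical + nu)
        return p

    def freq_err(a):
        p = osc_for(a)
        amp = cmr.amplitude_equation([p])
        cgl = cmr.cgl_reduce(amp)
        return cgl.oscillation_frequency(0) - omega_target

    a_star = brentq(freq_err, *a_bracket, xtol=1e-12)
    return osc_for(a_star)


def detuned_partner(ref: ModelParams, delta_omega: float,
                    a_bracket: tuple[float, float] | None = None) -> ModelParams:
    """A second oscillator with equal growth rate and detuned frequency."""
    amp = cmr.amplitude_equation([ref])
    cgl = cmr.cgl_reduce(amp)
    mu = float(cgl.mu[0])
    om = cgl.oscillation_frequency(0) + delta_omega
    if a_bracket is None:
        a0 = ref.gain_a
        a_bracket = (a0 - 0.4, a0 + 0.4)
    return params_for_target(ref, mu, om, a_bracket)


def pair_history(cycles: tuple[LimitCycle, LimitCycle],
                 phases: tuple[float, float]) -> History:
    """Initial two-oscillator history from cycle segments at given phases."""
    h1 = cycles[0].history_at_phase(phases[0])
    h2 = cycles[1].history_at_phase(phases[1])

    def u_fn(t):
        return np.column_stack([np.atleast_2d(h1.u_fn(t))[:, 0],
                                np.atleast_2d(h2.u_fn(t))[:, 0]])

    def v_fn(t):
        return np.column_stack([np.atleast_2d(h1.v_fn(t))[:, 0],
                                np.atleast_2d(h2.v_fn(t))[:, 0]])

    return History(u_fn=u_fn, v_fn=v_fn, n=2)


def _single_cycle(p: ModelParams, steps_per_delay: int = 40,
                  transient: float | None = None,
                  n_periods: int = 40) -> LimitCycle:
    amp = cmr.amplitude_equation([p])
    mu = max(amp.oscillators[0].mu, 1e-4)
    T_guess = 2 * np.pi / amp.oscillators[0].omega
    if transient is None:
        transient = 200.0 + 10.0 / mu
    t_end = transient + n_periods * T_guess
    traj = integrate(p, None, 0.01, t_end=t_end, steps_per_delay=steps_per_delay)
    return find_limit_cycle(traj, transient=transient)


def measure_frequencies(traj: Trajectory, cycles, t_min: float) -> np.ndarray:
    """Mean angular frequency of each oscillator from origin-crossing combs."""
    out = []
    for idx in range(traj.n):
        cyc = cycles[idx] if not isinstance(cycles, LimitCycle) else cycles
        cr = _origin_crossings(traj, cyc, t_min=t_min, idx=idx)
        if len(cr) < 3:
            out.append(np.nan)
            continue
        out.append(2 * np.pi * (len(cr) - 1) / (cr[-1] - cr[0]))
    return np.array(out)


# ---------------------------------------------------------------------------
# critical coupling


def _locked_dde(pair, cycles, eps, channel, n_rot, steps_per_delay, transient):
    T = np.nanmean([c.period for c in cycles])
    cpl = CouplingMatrix.pair(eps_u=eps if channel == "u" else 0.0,
                              eps_v=eps if channel == "v" else 0.0)
    t_end = transient + (n_rot + 5) * T
    h = pair_history(cycles, (0.0, 0.0))
    tr = integrate(list(pair), cpl, h, t_end=t_end,
                   steps_per_delay=steps_per_delay)
    f = measure_frequencies(tr, cycles, t_min=transient)
    if np.any(np.isnan(f)):
        return False
    return abs(f[0] - f[1]) < LOCK_TOL_FACTOR / T


def _locked_amplitude(amp_sys, eps, channel, n_rot, omega_ref):
    amp_sys.coupling = CouplingMatrix.pair(
        eps_u=eps if channel == "u" else 0.0,
        eps_v=eps if channel == "v" else 0.0)
    T = 2 * np.pi / omega_ref
    t_end = (n_rot + 50) * T
    R0 = [cmr.cgl_reduce(amp_sys).stationary_amplitude(j) for j in (0, 1)]
    z0 = np.array([R0[0] * 1j ** 0, R0[1] * np.exp(0.3j)])
    t, z = amp_sys.simulate(z0, t_end, rtol=1e-7, atol=1e-9)
    sel = t > 50 * T
    ph = np.unwrap(np.angle(z[sel]), axis=0)
    dur = t[sel][-1] - t[sel][0]
    f = (ph[-1] - ph[0]) / dur
    return abs(f[0] - f[1]) < LOCK_TOL_FACTOR / T


def _bisect_eps(locked_fn, eps_hi0=0.1, eps_cap=20.0, rel_tol=0.04):
    """Smallest eps with locking, by bracket expansion + bisection."""
    eps_hi = eps_hi0
    while not locked_fn(eps_hi):
        eps_hi *= 2.0
        if eps_hi > eps_cap:
            return np.nan
    lo, hi = 0.0, eps_hi
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if locked_fn(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def exp_critical_coupling(ref: ModelParams, delta_omegas: np.ndarray,
                          gamma_a: CouplingFunction,
                          channel: str = "u",
                          n_rotations: int = 1000,
                          steps_per_delay: int = 40,
                          methods: tuple = ("dde", "amplitude", "phase")) -> dict:
    """Critical coupling strength vs frequency mismatch, three ways.

    For each detuning a partner with matched growth rate is constructed by
    inverting the reduction, then the lock/drift boundary is found by
    bisection on full-DDE runs and on the planar amplitude equations, and
    compared with  eps_c = |delta_omega| / max(-+ gamma_a)  from the phase
    coupling function of the reference oscillator.
    """
    rows = {"delta_omega": [], "eps_c_dde": [], "eps_c_amplitude": [],
            "eps_c_phase": [], "delta_omega_measured": []}
    amp_ref = cmr.amplitude_equation([ref])
    mu = amp_ref.oscillators[0].mu
    cyc_ref = _single_cycle(ref, steps_per_delay)
    for dw in np.asarray(delta_omegas, dtype=float):
        partner = detuned_partner(ref, dw)
        cyc2 = _single_cycle(partner, steps_per_delay)
        dw_meas = 2 * np.pi / cyc2.period - 2 * np.pi / cyc_ref.period
        rows["delta_omega"].append(dw)
        rows["delta_omega_measured"].append(dw_meas)
        transient = 15.0 / max(mu, 1e-4)
        if "dde" in methods and dw != 0:
            fn = lambda e: _locked_dde((ref, partner), (cyc_ref, cyc2), e,
                                       channel, n_rotations, steps_per_delay,
                                       transient)
            rows["eps_c_dde"].append(_bisect_eps(fn, eps_hi0=4 * abs(dw)))
        else:
            rows["eps_c_dde"].append(0.0 if dw == 0 else np.nan)
        if "amplitude" in methods and dw != 0:
            amp_sys = cmr.amplitude_equation([ref, partner])
            om = amp_ref.oscillators[0].omega
            fn = lambda e: _locked_amplitude(amp_sys, e, channel,
                                             n_rotations, om)
            rows["eps_c_amplitude"].append(_bisect_eps(fn, eps_hi0=4 * abs(dw)))
        else:
            rows["eps_c_amplitude"].append(0.0 if dw == 0 else np.nan)
        if "phase" in methods:
            rows["eps_c_phase"].append(critical_coupling(gamma_a, dw_meas))
        else:
            rows["eps_c_phase"].append(np.nan)
    return {k: np.array(v) for k, v in rows.items()}


# ---------------------------------------------------------------------------
# amplitude death


def exp_amplitude_death(pA: ModelParams, pB: ModelParams,
                        eps_grid: np.ndarray, channel: str = "u",
                        steps_per_delay: int = 40,
                        find_sim_threshold: bool = True) -> dict:
    """Bifurcation table of the coupled A-B pair vs coupling strength.

    For each eps the pair is integrated from its uncoupled cycles; the
    asymptotic amplitudes decide death (amplitude below 1e-6 of the
    uncoupled value).  The reduced-pair eigenvalue threshold is attached,
    and optionally the simulated death onset from bisection.
    """
    amp_sys = cmr.amplitude_equation([pA, pB])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cgl = cmr.cgl_reduce(amp_sys)
    eps_th = cmr.death_threshold(cgl, channel=channel)
    mu = max(min(cgl.mu), 1e-4)
    cycA = _single_cycle(pA, steps_per_delay)
    cycB = _single_cycle(pB, steps_per_delay)
    amps0 = (cycA.amplitude, cycB.amplitude)
    T = max(cycA.period, cycB.period)
    # near the threshold the decay rate vanishes linearly, so the
    # classification window must be long compared with 1/mu
    t_end = 30.0 / mu
    transient = 8.0 / mu

    def run_at(eps):
        cpl = CouplingMatrix.pair(eps_u=eps if channel == "u" else 0.0,
                                  eps_v=eps if channel == "v" else 0.0)
        h = pair_history((cycA, cycB), (0.0, 0.0))
        return integrate([pA, pB], cpl, h, t_end=t_end,
                         steps_per_delay=steps_per_delay)

    def amps_of(tr):
        # asymptotic amplitudes: the final 20% of the run
        sel = tr.times > max(transient, 0.8 * tr.t_end)
        return np.max(np.abs(tr.u[sel]), axis=0)

    def is_dying(tr):
        """Death classifier robust near threshold: the norm of the state
        decays between the two halves of the post-transient window, or has
        already reached the amplitude floor."""
        sel = tr.times > transient
        u = np.abs(tr.u[sel])
        amps = np.max(u, axis=0)
        if np.all(amps < DEATH_AMP_FACTOR * np.array(amps0)):
            return True
        half = u.shape[0] // 2
        a1 = np.max(u[:half], axis=0)
        a2 = np.max(u[half:], axis=0)
        return bool(np.all(a2 < 0.6 * a1))

    rows = {"eps": [], "amp_A": [], "amp_B": [], "dead": []}
    for eps in np.asarray(eps_grid, dtype=float):
        aa = amps_of(run_at(eps))
        dead = bool(np.all(aa < DEATH_AMP_FACTOR * np.array(amps0)))
        rows["eps"].append(eps)
        rows["amp_A"].append(aa[0])
        rows["amp_B"].append(aa[1])
        rows["dead"].append(dead)
    out = {k: np.array(v) for k, v in rows.items()}
    out["eps_threshold_theory"] = eps_th
    out["uncoupled_amps"] = np.array(amps0)
    if find_sim_threshold:
        def is_dead(eps):
            return is_dying(run_at(eps))
        lo, hi = 0.0, None
        eps = max(eps_th, 1e-3)
        for _ in range(12):
            if is_dead(eps):
                hi = eps
                break
            lo = eps
            eps *= 1.3
        if hi is None:
            out["eps_threshold_sim"] = np.nan
        else:
            while hi - lo > 0.02 * hi:
                mid = 0.5 * (lo + hi)
                if is_dead(mid):
                    hi = mid
                else:
                    lo = mid
            out["eps_threshold_sim"] = 0.5 * (lo + hi)
    return out


# ---------------------------------------------------------------------------
# multimodal locking


def exp_multimodal(pC: ModelParams, eps: float, gamma_a: CouplingFunction,
                   n_init: int = 20, steps_per_delay: int = 40,
                   t_settle: float | None = None,
                   settle_tol: float = 1e-3, cluster_tol: float = 0.3,
                   cycle: LimitCycle | None = None,
                   init_offset: float = 0.1) -> dict:
    """Identical pair far from onset: initial vs final phase differences.

    Initial conditions are time-shifted copies of the converged cycle on a
    uniform grid of initial differences; each run settles when the
    difference changes by less than ``settle_tol`` over 50 periods.  Final
    differences are clustered and matched against the basins predicted by
    the phase-difference flow.
    """
    if cycle is None:
        cycle = _single_cycle(pC, max(steps_per_delay, 60),
                              transient=450.0, n_periods=30)
    T = cycle.period
    diag = locking_analysis(gamma_a, 0.0, eps)
    stable_pts = np.array([p for p, s in diag.fixed_points if s == "stable"])
    cpl = CouplingMatrix.pair(eps_u=eps)
    if t_settle is None:
        ga_slope = 5.0 * np.max(np.abs(gamma_a.gamma_a))
        t_settle = min(40.0 / max(eps * ga_slope, 1e-6), 3000.0)

    # a uniform grid, offset so no run starts exactly on the separatrix at 0
    # (the in-phase state is an unstable equilibrium of an identical pair
    # in the multimodal regime and would simply stay put)
    inits = (np.linspace(0, 2 * np.pi, n_init, endpoint=False)
             + init_offset) % (2 * np.pi)
    rows = {"phi_init": [], "phi_final": [], "attractor_id": [],
            "predicted_id": [], "settled": []}

    def run(dphi0):
        h = pair_history((cycle, cycle), (0.0, -dphi0))
        t_end = t_settle + 60 * T
        tr = integrate([pC, pC], cpl, h, t_end=t_end,
                       steps_per_delay=steps_per_delay)
        dseq = _dphi_series(tr, cycle, t_min=t_end - 55 * T)
        if len(dseq) < 4:
            return np.nan, False
        drift = abs(dseq[-1] - dseq[max(0, len(dseq) - 50)])
        settled = drift < settle_tol * 50
        return float(dseq[-1] % (2 * np.pi)), settled

    for d0 in inits:
        pf, settled = run(d0)
        rows["phi_init"].append(d0)
        rows["phi_final"].append(pf)
        rows["settled"].append(settled)
        if np.isnan(pf) or len(stable_pts) == 0:
            rows["attractor_id"].append(-1)
            rows["predicted_id"].append(-1)
            continue
        dist = np.abs((stable_pts - pf + np.pi) % (2 * np.pi) - np.pi)
        rows["attractor_id"].append(int(np.argmin(dist)))
        pred = diag.basins.get(float(min(diag.basins,
                                         key=lambda q: abs(q - d0))), np.nan)
        if np.isnan(pred):
            rows["predicted_id"].append(-1)
        else:
            dp = np.abs((stable_pts - pred + np.pi) % (2 * np.pi) - np.pi)
            rows["predicted_id"].append(int(np.argmin(dp)))
    out = {k: np.array(v) for k, v in rows.items()}
    out["diagram"] = diag
    out["n_stable_theory"] = len(stable_pts)
    finals = out["phi_final"][out["settled"].astype(bool)]
    out["n_clusters_sim"] = _count_clusters(finals, cluster_tol)
    ok = out["settled"].astype(bool)
    out["basin_agreement"] = float(np.mean(
        out["attractor_id"][ok] == out["predicted_id"][ok])) if ok.any() else np.nan
    return out


def _dphi_series(tr: Trajectory, cycle: LimitCycle, t_min: float) -> np.ndarray:
    c1 = _origin_crossings(tr, cycle, t_min=t_min, idx=0)
    c2 = _origin_crossings(tr, cycle, t_min=t_min, idx=1)
    T = cycle.period
    if len(c1) < 2 or len(c2) < 2:
        return np.array([])
    out = []
    prev = None
    for t1 in c1:
        t2 = c2[np.argmin(np.abs(c2 - t1))]
        # osc2 lagging osc1 by psi crosses the origin psi/omega later, so
        # psi = theta_1 - theta_2 = 2 pi (t2 - t1) / T
        d = 2 * np.pi * ((t2 - t1) / T)
        # unwrap against the previous sample
        if prev is not None:
            d += 2 * np.pi * np.round((prev - d) / (2 * np.pi))
        out.append(d)
        prev = d
    return np.array(out)


def _count_clusters(finals: np.ndarray, tol: float) -> int:
    fs = np.sort(finals[~np.isnan(finals)] % (2 * np.pi))
    if fs.size == 0:
        return 0
    clusters = [[fs[0]]]
    for f in fs[1:]:
        if f - clusters[-1][-1] > tol:
            clusters.append([f])
        else:
            clusters[-1].append(f)
    if len(clusters) > 1 and (2 * np.pi - clusters[-1][-1] + clusters[0][0]) < tol:
        clusters[0] = clusters.pop() + clusters[0]
    return len(clusters)


# ---------------------------------------------------------------------------
# population dynamics


@dataclass
class PopulationEnsemble:
    """All-to-all ensemble of near-onset oscillators.

    Per-oscillator (mu_j, omega_j) are drawn around a reference operating
    point and inverted to model parameters; coupling is uniform u-channel
    diffusive, normalized by n.
    """

    params: list[ModelParams]
    targets: np.ndarray          # (n, 2) drawn (mu_j, omega_j)
    seed: int

    @property
    def n(self) -> int:
        return len(self.params)

    @classmethod
    def around(cls, ref: ModelParams, n: int, seed: int,
               mu_width_rel: float = 0.1,
               omega_width: float = 0.0015) -> "PopulationEnsemble":
        """Uniform, independent spreads.  The frequency half-width is kept
        well below mu / Re(kappa) so the synchronization transition sits
        far from the collective death regime of strong mean-field
        contraction."""
        import warnings
        if n < 10:
            warnings.warn("n < 10: order parameter will be noisy")
        amp = cmr.amplitude_equation([ref])
        cgl = cmr.cgl_reduce(amp)
        mu0 = float(cgl.mu[0])
        om0 = cgl.oscillation_frequency(0)
        draws = population_sample(n, seed, mu_center=mu0,
                                  mu_width=mu_width_rel * mu0,
                                  omega_center=om0, omega_width=omega_width)
        plist = [params_for_target(ref, mu, om,
                                   (ref.gain_a - 0.4, ref.gain_a + 0.4))
                 for mu, om in draws]
        return cls(params=plist, targets=draws, seed=seed)


def phases_from_crossings(tr: Trajectory, cycles, t_grid: np.ndarray) -> np.ndarray:
    """Linear-interpolated phases theta_j(t) from origin-crossing combs."""
    n = tr.n
    out = np.full((len(t_grid), n), np.nan)
    for j in range(n):
        cyc = cycles[j] if not isinstance(cycles, LimitCycle) else cycles
        cr = _origin_crossings(tr, cyc, t_min=t_grid[0] - 3 * cyc.period, idx=j)
        if len(cr) < 2:
            continue
        k = np.arange(len(cr))
        out[:, j] = np.interp(t_grid, cr, 2 * np.pi * k)
    return out


def kuramoto_order_parameter(phases: np.ndarray) -> np.ndarray:
    """R(t) = |mean_j exp(i theta_j(t))| for an (nt, n) phase array."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("empty phase array")
    return np.abs(np.mean(np.exp(1j * phases), axis=-1))


def exp_population(ens: PopulationEnsemble, eps_grid: np.ndarray,
                   gamma: CouplingFunction | None = None,
                   steps_per_delay: int = 40,
                   t_transient: float | None = None,
                   t_measure: float | None = None,
                   mode: str = "sync") -> dict:
    """Sweep the coupling of the population; report time-averaged R.

    ``mode='sync'`` computes the Kuramoto order parameter from
    crossing-time phases (and, when ``gamma`` is given, co-simulates the
    reduced phase model on the same drawn frequencies for comparison);
    ``mode='death'`` reports the fraction of quiescent oscillators.
    """
    n = ens.n
    amp = cmr.amplitude_equation([ens.params[0]])
    cgl0 = cmr.cgl_reduce(amp)
    mu0 = float(cgl0.mu[0])
    T0 = 2 * np.pi / cgl0.oscillation_frequency(0)
    if t_transient is None:
        t_transient = 30.0 / mu0
    if t_measure is None:
        t_measure = 150 * T0
    cyc_ref = _single_cycle(ens.params[0], steps_per_delay)

    # uncoupled frequencies for the reduced phase model
    omegas = np.array([cmr.cgl_reduce(cmr.amplitude_equation([p]))
                       .oscillation_frequency(0) for p in ens.params])
    amps0 = None

    rows = {"eps": [], "R_dde": [], "R_phase": [], "dead_fraction": []}
    for eps in np.asarray(eps_grid, dtype=float):
        cpl = CouplingMatrix.all_to_all(n, eps_u=eps, normalize=True)
        h = History.constant(0.01 + 0.001 * np.sin(np.arange(n)), n=n)
        tr = integrate(ens.params, cpl, h, t_end=t_transient + t_measure,
                       steps_per_delay=steps_per_delay)
        sel = tr.times >= t_transient
        if amps0 is None and eps == 0.0:
            amps0 = np.max(np.abs(tr.u[sel]), axis=0)
        rows["eps"].append(eps)
        if mode == "death":
            amps = np.max(np.abs(tr.u[sel]), axis=0)
            ref_amp = np.median(amps0) if amps0 is not None else cyc_ref.amplitude
            rows["dead_fraction"].append(float(np.mean(amps < 1e-3 * ref_amp)))
            rows["R_dde"].append(np.nan)
            rows["R_phase"].append(np.nan)
            continue
        t_grid = np.linspace(t_transient + 5 * T0,
                             t_transient + t_measure - 5 * T0, 400)
        ph = phases_from_crossings(tr, cyc_ref, t_grid)
        valid = ~np.isnan(ph).any(axis=0)
        R = kuramoto_order_parameter(ph[:, valid])
        rows["R_dde"].append(float(np.mean(R)))
        rows["dead_fraction"].append(float(np.mean(~valid)))
        if gamma is not None:
            Rp = _phase_model_R(omegas, gamma, eps, ens.seed,
                                t_transient + t_measure, t_transient, T0)
            rows["R_phase"].append(Rp)
        else:
            rows["R_phase"].append(np.nan)
    return {k: np.array(v) for k, v in rows.items()}


def _phase_model_R(omegas: np.ndarray, gamma: CouplingFunction, eps: float,
                   seed: int, t_end: float, t_transient: float,
                   T0: float) -> float:
    """Reduced phase model: dtheta_j/dt = w_j + (eps/n) sum_k Gamma(th_j - th_k)."""
    n = len(omegas)
    rng = np.random.default_rng(seed + 1)
    th = rng.uniform(0, 2 * np.pi, n)
    dt = T0 / 50.0
    nsteps = int(np.ceil(t_end / dt))
    Rs = []
    g = gamma.eval

    def vel(th):
        diff = th[:, None] - th[None, :]
        return omegas + (eps / n) * np.sum(g(diff), axis=1)

    for k in range(nsteps):
        k1 = vel(th)
        k2 = vel(th + 0.5 * dt * k1)
        k3 = vel(th + 0.5 * dt * k2)
        k4 = vel(th + dt * k3)
        th = th + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (k + 1) * dt
        if t >= t_transient:
            Rs.append(np.abs(np.mean(np.exp(1j * th))))
    return float(np.mean(Rs))
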