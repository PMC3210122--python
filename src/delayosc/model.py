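"""Corticothalamic delay-oscillator network: parameters, coupling, right-hand side.

Each local cortical area is modelled by a mean firing-rate deviation
``u_i(t)`` obeying a second-order scalar delay differential equation

.. math::

    \\ddot u_i = -2\\gamma \\dot u_i - (\\gamma^2 - a_i)\\, u_i
                - b_i\\, u_i(t-\\tau)
                - c_2 u_i^2 - c_3 u_i^3
                + \\sum_j \\bigl[\\varepsilon^u_{ij} (u_j - u_i)
                               + \\varepsilon^v_{ij} (v_j - v_i)\\bigr],

with ``v_i = \\dot u_i``.  Here ``gamma`` is the damping rate, ``a``
parameterizes the strength of instantaneous cortico-cortical excitation,
``b`` the delayed cortico-thalamic feedback (the Hopf control parameter),
``tau`` the corticothalamic transmission delay, and ``c2``/``c3`` the
quadratic/cubic nonlinearities of the neuronal response.  Pairwise coupling
is diffusive (linearly attractive) through the state (``u``) and derivative
(``v``) components separately and vanishes identically on the synchronized
manifold.

Internally the equation is treated as a first-order system in ``(u_i, v_i)``
with the delay acting on ``u`` only; that reduction is shared by the
integrator, the linear stability analysis and the center-manifold machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "NamedParamSet",
    "CouplingMatrix",
    "NetworkState",
    "rhs",
    "single_rhs",
    "load_param_sets",
    "default_param_sets",
    "dump_param_sets",
]


class ConfigError(ValueError):
    """A parameter file is missing a field or violates an invariant."""


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of one delay-induced oscillator.

    Times are measured in units of the damping time ``1/gamma`` of the
    packaged defaults; the equations themselves are dimensionally
    consistent for any positive ``gamma`` and ``delay``.
    """

    delay: float = 1.0          # corticothalamic transmission delay tau (s)
    damping: float = 1.0        # damping rate gamma (1/s)
    gain_a: float = 1.0         # instantaneous cortico-cortical gain a
    gain_b: float = 3.0         # delayed cortico-thalamic feedback b (control)
    nl2: float = 0.0            # quadratic nonlinearity c2
    nl3: float = 1.0            # cubic nonlinearity c3

    def __post_init__(self) -> None:
        vals = asdict(self)
        for key, val in vals.items():
            if not np.isfinite(val):
                raise ConfigError(f"non-finite model parameter {key!r}: {val}")
        if self.delay <= 0:
            raise ConfigError(f"delay must be positive, got {self.delay}")
        if self.damping <= 0:
            raise ConfigError(f"damping must be positive, got {self.damping}")

    def with_gain_b(self, gain_b: float) -> "ModelParams":
        return replace(self, gain_b=float(gain_b))

    def with_gain_a(self, gain_a: float) -> "ModelParams":
        return replace(self, gain_a=float(gain_a))


@dataclass(frozen=True)
class NamedParamSet:
    """A labelled operating point (the reference points A, B, C)."""

    label: str
    params: ModelParams


@dataclass
class CouplingMatrix:
    """Diffusive pairwise coupling intensities for the u and v channels.

    ``eps_u[i, j]`` multiplies ``(u_j - u_i)`` in oscillator i's equation;
    likewise ``eps_v`` for the derivative channel.  Both matrices are
    symmetric with zero diagonal.
    """

    eps_u: np.ndarray
    eps_v: np.ndarray

    def __post_init__(self) -> None:
        self.eps_u = np.asarray(self.eps_u, dtype=float)
        self.eps_v = np.asarray(self.eps_v, dtype=float)
        if self.eps_u.shape != self.eps_v.shape or self.eps_u.ndim != 2:
            raise ValueError("eps_u and eps_v must be square matrices of equal shape")
        n = self.eps_u.shape[0]
        if self.eps_u.shape != (n, n):
            raise ValueError("coupling matrices must be square")
        for name, m in (("eps_u", self.eps_u), ("eps_v", self.eps_v)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} must have zero diagonal")
            if np.any(m < 0):
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n(self) -> int:
        return self.eps_u.shape[0]

    @classmethod
    def none(cls, n: int) -> "CouplingMatrix":
        z = np.zeros((n, n))
        return cls(z, z.copy())

    @classmethod
    def pair(cls, eps_u: float = 0.0, eps_v: float = 0.0) -> "CouplingMatrix":
        off = np.array([[0.0, 1.0], [1.0, 0.0]])
        return cls(eps_u * off, eps_v * off)

    @classmethod
    def all_to_all(cls, n: int, eps_u: float = 0.0, eps_v: float = 0.0,
                   normalize: bool = True) -> "CouplingMatrix":
        """Uniform all-to-all coupling; intensities divided by n if requested."""
        off = np.ones((n, n)) - np.eye(n)
        scale = 1.0 / n if normalize else 1.0
        return cls(eps_u * scale * off, eps_v * scale * off)

    def permuted(self, perm: np.ndarray) -> "CouplingMatrix":
        p = np.asarray(perm)
        return CouplingMatrix(self.eps_u[np.ix_(p, p)], self.eps_v[np.ix_(p, p)])


@dataclass
class NetworkState:
    """Instantaneous network state plus the delayed u values it needs.

    The full functional state of a DDE is a segment of history; for
    evaluating the right-hand side only ``u_i(t - tau)`` is required, so the
    integrator passes that slice explicitly.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have equal shapes")


def rhs(u: np.ndarray, v: np.ndarray, u_delayed: np.ndarray,
        params: list[ModelParams] | ModelParams,
        coupling: CouplingMatrix | None = None) -> np.ndarray:
    """Second derivatives d^2 u_i / dt^2 for the whole network.

    Parameters
    ----------
    u, v : arrays of the current values and derivatives, one per oscillator.
    u_delayed : array of u_i(t - tau_i).
    params : per-oscillator parameters (a single ``ModelParams`` is broadcast).
    coupling : diffusive intensities; ``None`` means uncoupled.

    The coupling contribution is linear in the pairwise differences and is
    exactly zero whenever all oscillators share the same state.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    ud = np.atleast_1d(np.asarray(u_delayed, dtype=float))
    n = u.shape[0]
    if v.shape[0] != n or ud.shape[0] != n:
        raise ValueError("u, v and u_delayed must have one entry per oscillator")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v)) and np.all(np.isfinite(ud))):
        raise FloatingPointError("non-finite state passed to rhs")
    if isinstance(params, ModelParams):
        params = [params] * n
    if len(params) != n:
        raise ValueError(f"expected {n} parameter sets, got {len(params)}")

    gamma = np.array([p.damping for p in params])
    a = np.array([p.gain_a for p in params])
    b = np.array([p.gain_b for p in params])
    c2 = np.array([p.nl2 for p in params])
    c3 = np.array([p.nl3 for p in params])

    acc = (-2.0 * gamma * v - (gamma**2 - a) * u - b * ud
           - c2 * u**2 - c3 * u**3)
    if coupling is not None:
        if coupling.n != n:
            raise ValueError(f"coupling is for {coupling.n} oscillators, state has {n}")
        # Diffusive: sum_j eps[i,j] (x_j - x_i) = (eps @ x)_i - x_i * rowsum_i
        acc = acc + coupling.eps_u @ u - coupling.eps_u.sum(axis=1) * u
        acc = acc + coupling.eps_v @ v - coupling.eps_v.sum(axis=1) * v
    return acc


def single_rhs(u: float, v: float, u_delayed: float, params: ModelParams) -> float:
    """Uncoupled single-oscillator right-hand side (scalar convenience)."""
    return float(rhs(np.array([u]), np.array([v]), np.array([u_delayed]), params)[0])


# ---------------------------------------------------------------------------
# parameter files

_REQUIRED_FIELDS = ("delay", "damping", "gain_a", "gain_b", "nl2", "nl3")


def _params_from_dict(d: dict, where: str) -> ModelParams:
    missing = [k for k in _REQUIRED_FIELDS if k not in d]
    if missing:
        raise ConfigError(f"{where}: missing required field(s) {missing}")
    return ModelParams(**{k: float(d[k]) for k in _REQUIRED_FIELDS})


def load_param_sets(config_path: str | Path) -> list[NamedParamSet]:
    """Read labelled parameter sets from a YAML file.

    Expected layout::

        sets:
          - label: A
            delay: 1.0
            damping: 1.0
            ...
    """
    path = Path(config_path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "sets" not in doc:
        raise ConfigError(f"{path}: missing required field 'sets'")
    out = []
    for i, entry in enumerate(doc["sets"]):
        if "label" not in entry:
            raise ConfigError(f"{path} set #{i}: missing required field 'label'")
        out.append(NamedParamSet(label=str(entry["label"]),
                                 params=_params_from_dict(entry, f"{path} set {entry['label']}")))
    return out


def dump_param_sets(sets: list[NamedParamSet], path: str | Path) -> None:
    doc = {"sets": [dict(label=s.label, **asdict(s.params)) for s in sets]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_param_sets() -> dict[str, NamedParamSet]:
    """The packaged reference operating points A, B and C keyed by label.

    A and B sit at the same distance ``b - b_c(a)`` above the stability
    boundary (equal amplitudes, B at higher frequency); C lies far above
    onset where the waveform develops strong higher harmonics.
    """
    with resources.files("delayosc.data").joinpath("params_default.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for entry in doc["sets"]:
        ps = NamedParamSet(label=str(entry["label"]),
                           params=_params_from_dict(entry, f"defaults set {entry['label']}"))
        out[ps.label] = ps
    return out
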