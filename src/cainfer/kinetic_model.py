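"""Li-Rinzel-type kinetics of intracellular calcium in astrocytes.

The model tracks three variables: cytosolic calcium ``c_cs`` (uM), the
IP3-receptor (InsPR) recovery variable ``q`` (dimensionless, in [0, 1]) and
the IP3 concentration ``p`` (uM).  Calcium exchanges between the cytosol and
the endoplasmic reticulum (ER) through three fluxes: release through the
InsPR channel, uptake by the SERCA pump, and a ligand-independent leak.
ER calcium is not an independent variable; it follows from conservation of
the total cell calcium ``C0`` and the ER/cytosol volume ratio ``c1``.

Time stepping uses explicit forward Euler on a "microtime" grid finer than
the acquisition grid (default 0.1 s sub-steps for 1 s frames), with
post-step clamping of the state to its physical domain; the scheme is
validated against a fine-step Runge-Kutta reference in the test suite.

All concentrations are in uM, all times in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "KineticState",
    "KineticParams",
    "FluxSet",
    "Trajectory",
    "er_calcium",
    "compute_fluxes",
    "state_derivative",
    "evolve_step",
    "simulate",
    "DEFAULT_FREE_PARAMETERS",
]

logger = logging.getLogger(__name__)

#: Extensive parameters varied in the Bayesian inversion: the rate constants
#: of the three calcium fluxes and of IP3 production/degradation, plus the
#: SERCA half-activation. Everything else is held at its literature value.
DEFAULT_FREE_PARAMETERS: tuple[str, ...] = ("vs", "v1", "v2", "tau", "vp", "ks")

#: Lower clamp (uM) keeping concentrations strictly positive after a coarse
#: explicit step.
_EPS = 1e-9

#: Relative tolerance when checking that the frame interval is an integer
#: multiple of the micro-step.
_DIV_RTOL = 1e-9

#: Numeric ceiling on IP3 (uM), far above any physical value; prevents float
#: overflow when the integrator is probed at extreme rate constants.
_P_MAX = 1e4


@dataclass(frozen=True)
class KineticState:
    """Hidden state of the calcium kinetic model.

    Attributes
    ----------
    c_cs : float
        Cytosolic calcium concentration, uM.
    q : float
        InsPR recovery variable (fraction of non-inactivated receptors),
        dimensionless in [0, 1].
    p : float
        IP3 concentration, uM.
    """

    c_cs: float
    q: float
    p: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c_cs, self.q, self.p], dtype=float)

    @staticmethod
    def from_array(x: np.ndarray) -> "KineticState":
        return KineticState(float(x[0]), float(x[1]), float(x[2]))

    def validate(self, params: "KineticParams") -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError(f"non-finite kinetic state {self}")
        if self.c_cs < 0 or self.p < 0:
            raise ValueError(f"negative concentration in state {self}")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"recovery variable q={self.q} outside [0, 1]")
        ceiling = params.C0 * (1.0 + params.c1)
        if self.c_cs > ceiling * (1.0 + _DIV_RTOL):
            raise ValueError(
                f"c_cs={self.c_cs} uM exceeds the conservation ceiling "
                f"C0*(1+c1)={ceiling} uM (ER calcium would be negative)"
            )


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the calcium kinetic model with literature defaults.

    Rates are per second, concentrations in uM. ``c1`` is the dimensionless
    ER/cytosol volume ratio and ``C0`` the total cell calcium. Fields may
    hold numpy arrays for vectorised batch evaluation; ``validate`` applies
    to scalar parameter sets.
    """

    vs: float = 0.9      #: max SERCA pump rate, uM/s
    C0: float = 2.0      #: total cell calcium, uM
    v2: float = 0.11     #: ER leak rate constant, 1/s
    ks: float = 0.1      #: SERCA half-activation, uM
    a2: float = 0.2      #: InsPR inactivation rate coefficient, 1/(uM s)
    d1: float = 0.13     #: InsPR IP3 dissociation constant, uM
    d2: float = 1.049    #: InsPR inhibitory Ca dissociation constant, uM
    d5: float = 0.08234  #: InsPR activating Ca dissociation constant, uM
    v1: float = 6.0      #: max InsPR channel flux rate, 1/s
    c1: float = 0.185    #: ER/cytosol volume ratio, dimensionless
    tau: float = 7.14    #: IP3 lifetime, s
    p0: float = 0.16     #: baseline IP3, uM
    vp: float = 0.13     #: max IP3 production rate, uM/s
    kp: float = 1.1      #: IP3 production half-activation, uM
    free_mask: tuple[str, ...] = field(default=DEFAULT_FREE_PARAMETERS)

    def validate(self) -> None:
        for name in ("vs", "C0", "v2", "ks", "a2", "d1", "d2", "d5",
                     "v1", "tau", "p0", "vp", "kp"):
            value = getattr(self, name)
            if not np.all(np.asarray(value) > 0):
                raise ValueError(f"kinetic parameter {name}={value} must be > 0")
        if not np.all((np.asarray(self.c1) > 0) & (np.asarray(self.c1) < 1)):
            raise ValueError(f"volume ratio c1={self.c1} must lie in (0, 1)")
        unknown = set(self.free_mask) - set(DEFAULT_FREE_PARAMETERS) - {
            "C0", "c1", "a2", "d1", "d2", "d5", "p0", "kp"}
        if unknown:
            raise ValueError(f"unknown free parameters {sorted(unknown)}")

    def ceiling(self) -> float:
        """Upper bound on cytosolic calcium imposed by conservation, uM."""
        return self.C0 * (1.0 + self.c1)

    def with_values(self, **kwargs) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name))
             for name in ("vs", "C0", "v2", "ks", "a2", "d1", "d2", "d5",
                          "v1", "c1", "tau", "p0", "vp", "kp")}
        d["free_mask"] = list(self.free_mask)
        return d

    @staticmethod
    def from_dict(d: dict) -> "KineticParams":
        d = dict(d)
        free = tuple(d.pop("free_mask", DEFAULT_FREE_PARAMETERS))
        params = KineticParams(free_mask=free, **d)
        params.validate()
        return params


@dataclass(frozen=True)
class FluxSet:
    """Calcium fluxes between ER and cytosol, uM/s.

    ``j_c`` InsPR channel release, ``j_s`` SERCA uptake (always >= 0),
    ``j_l`` passive ER leak. ``j_c`` and ``j_l`` carry the sign of the
    ER-cytosol concentration difference.
    """

    j_c: float
    j_s: float
    j_l: float


def er_calcium(c_cs, params: KineticParams):
    """ER calcium concentration (uM) from conservation of total calcium.

    C_ER = [C0*(1+c1) - C_CS] / c1. Raises ``ValueError`` when ``c_cs``
    exceeds the conservation ceiling beyond numerical tolerance (the ER
    concentration would be negative). Accepts scalars or arrays.
    """
    c_cs = np.asarray(c_cs, dtype=float)
    ceiling = params.C0 * (1.0 + params.c1)
    if np.any(c_cs > ceiling * (1.0 + _DIV_RTOL) + _EPS):
        raise ValueError(
            f"cytosolic calcium {np.max(c_cs)} uM exceeds the conservation "
            f"ceiling {np.max(np.asarray(ceiling))} uM"
        )
    cer = (ceiling - c_cs) / params.c1
    cer = np.maximum(cer, 0.0)
    return cer if cer.ndim else float(cer)


def _fluxes(c, q, p, params: KineticParams):
    """Vectorised flux kernel; no domain checks."""
    cer = (params.C0 * (1.0 + params.c1) - c) / params.c1
    drive = cer - c
    j_c = params.v1 * (p / (p + params.d1)) ** 3 \
        * (c / (c + params.d5)) ** 3 * q ** 3 * drive
    j_s = params.vs * c * c / (c * c + params.ks * params.ks)
    j_l = params.v2 * drive
    return j_c, j_s, j_l


def compute_fluxes(state: KineticState, params: KineticParams) -> FluxSet:
    """InsPR, SERCA and leak fluxes for a given state, uM/s."""
    state.validate(params)
    er_calcium(state.c_cs, params)  # domain check
    j_c, j_s, j_l = _fluxes(state.c_cs, state.q, state.p, params)
    return FluxSet(float(j_c), float(j_s), float(j_l))


def _derivative(c, q, p, params: KineticParams):
    """Vectorised time derivative of (c_cs, q, p)."""
    j_c, j_s, j_l = _fluxes(c, q, p, params)
    dc = j_c - j_s + j_l
    dq = params.a2 * params.d2 * (p + params.d1) / (p + params.d2) * (1.0 - q) \
        - params.a2 * c * q
    dp = -(p - params.p0) / params.tau \
        + params.vp * (c + 0.2 * params.kp) / (c + params.kp)
    return dc, dq, dp


def state_derivative(state: KineticState, params: KineticParams):
    """Time derivative (dC_CS/dt, dq/dt, dp/dt) in (uM/s, 1/s, uM/s)."""
    state.validate(params)
    dc, dq, dp = _derivative(state.c_cs, state.q, state.p, params)
    return float(dc), float(dq), float(dp)


def _n_substeps(frame_dt: float, micro_dt: float) -> int:
    if micro_dt <= 0:
        raise ValueError(f"micro_dt={micro_dt} must be positive")
    if frame_dt == 0:
        return 0
    if frame_dt < 0:
        raise ValueError(f"frame_dt={frame_dt} must be non-negative")
    ratio = frame_dt / micro_dt
    n = int(round(ratio))
    if n < 1 or abs(ratio - n) > _DIV_RTOL * max(1.0, ratio):
        raise ValueError(
            f"frame interval {frame_dt} s is not an integer multiple of the "
            f"micro-step {micro_dt} s"
        )
    return n


def _evolve_batch(x: np.ndarray, params: KineticParams, frame_dt: float,
                  micro_dt: float) -> tuple[np.ndarray, int]:
    """Advance a (k, 3) batch of states by one frame of forward-Euler
    micro-steps with post-step clamping to the physical domain.

    Parameter fields may be (k,) arrays to evolve each row under its own
    parameter set. Returns the new batch and the number of clamped
    components (stiffness diagnostic).
    """
    n_sub = _n_substeps(frame_dt, micro_dt)
    c = x[:, 0].copy()
    q = x[:, 1].copy()
    p = x[:, 2].copy()
    hi = params.C0 * (1.0 + params.c1) - _EPS
    n_clamped = 0
    for _ in range(n_sub):
        dc, dq, dp = _derivative(c, q, p, params)
        c += micro_dt * dc
        q += micro_dt * dq
        p += micro_dt * dp
        c_new = np.clip(c, _EPS, hi)
        q_new = np.clip(q, 0.0, 1.0)
        p_new = np.clip(p, _EPS, _P_MAX)
        n_clamped += int(np.sum(c_new != c) + np.sum(q_new != q)
                         + np.sum(p_new != p))
        c, q, p = c_new, q_new, p_new
    out = np.stack([c, q, p], axis=1)
    return out, n_clamped


def evolve_step(state: KineticState, params: KineticParams,
                frame_dt: float = 1.0, micro_dt: float = 0.1) -> KineticState:
    """Advance the state by one acquisition frame.

    The frame interval is covered by ``frame_dt / micro_dt`` explicit Euler
    sub-steps ("microtime" integration); after each sub-step the state is
    clamped to its physical domain, which guards against non-physical
    excursions of the coarse explicit scheme on this comparatively stiff
    system. ``frame_dt == 0`` returns the input state unchanged.
    """
    state.validate(params)
    if frame_dt == 0:
        return state
    out, n_clamped = _evolve_batch(state.as_array()[None, :], params,
                                   frame_dt, micro_dt)
    if n_clamped:
        logger.warning("evolve_step clamped %d state component(s)", n_clamped)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite state after evolve_step: {out}")
    return KineticState.from_array(out[0])


@dataclass
class Trajectory:
    """Simulated state trajectory on the acquisition grid.

    ``times`` has shape (n,), ``states`` shape (n, 3) with columns
    (c_cs, q, p). ``n_clamped`` counts state components clamped back into
    the physical domain during integration.
    """

    times: np.ndarray
    states: np.ndarray
    n_clamped: int = 0

    @property
    def c_cs(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def q(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def p(self) -> np.ndarray:
        return self.states[:, 2]

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> KineticState:
        return KineticState.from_array(self.states[i])

    def __iter__(self) -> Iterator[KineticState]:
        return (self[i] for i in range(len(self)))


def _simulate_batch(x0: np.ndarray, params: KineticParams, n_frames: int,
                    frame_dt: float, micro_dt: float) -> tuple[np.ndarray, int]:
    """Simulate a (k, 3) batch over ``n_frames`` frames.

    Returns an (n_frames + 1, k, 3) array including the initial state, and
    the clamp count. Parameter fields may be (k,) arrays.
    """
    k = x0.shape[0]
    out = np.empty((n_frames + 1, k, 3), dtype=float)
    out[0] = x0
    x = np.asarray(x0, dtype=float)
    n_clamped = 0
    for i in range(n_frames):
        x, nc = _evolve_batch(x, params, frame_dt, micro_dt)
        n_clamped += nc
        out[i + 1] = x
    return out, n_clamped


def simulate(state0: KineticState, params: KineticParams, duration: float,
             frame_dt: float = 1.0, micro_dt: float = 0.1) -> Trajectory:
    """Simulate the kinetics over ``duration`` seconds on the frame grid.

    Returns states at t = 0, frame_dt, ..., n*frame_dt with
    n = round(duration / frame_dt); the first element is ``state0``.
    """
    if duration <= 0:
        raise ValueError(f"duration={duration} must be positive")
    state0.validate(params)
    n_frames = int(round(duration / frame_dt))
    if n_frames < 1:
        raise ValueError(
            f"duration {duration} s shorter than one frame ({frame_dt} s)")
    out, n_clamped = _simulate_batch(state0.as_array()[None, :], params,
                                     n_frames, frame_dt, micro_dt)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite state during simulation")
    if n_clamped:
        logger.warning("simulate clamped %d state component(s)", n_clamped)
    times = np.arange(n_frames + 1, dtype=float) * frame_dt
    return Trajectory(times=times, states=out[:, 0, :], n_clamped=n_clamped)
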