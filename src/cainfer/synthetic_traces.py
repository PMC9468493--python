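"""Synthetic fluorescence traces with known ground truth.

Generates per-ROI traces with the statistical structure the inversion
assumes: forward-simulated calcium kinetics (optionally perturbed by
per-frame Gaussian state noise), mapped through the saturating indicator
function, with i.i.d. mean-zero Gaussian observation noise added on top.
Cohorts emulate the output of an upstream trace-extraction pipeline over a
group of regions of interest, with per-trace parameter jitter and optional
multiplicative group-level shifts of the free kinetic parameters (the
wild-type versus deletion style contrast).

Defaults emulate the acquisition protocol the pipeline targets: 180 frames
at 1 Hz (3 min), observation noise at 2% of the noiseless trace range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kinetic_model import (KineticParams, KineticState, _evolve_batch,
                            simulate)
from .observation_model import ObservationParams, predict_trace

__all__ = [
    "Trace",
    "TraceTruth",
    "SyntheticCohort",
    "generate_trace",
    "generate_cohort",
    "write_traces",
    "write_truth",
]

logger = logging.getLogger(__name__)

#: Default acquisition geometry: 3 min at 1 Hz.
DEFAULT_DURATION_S = 180.0
DEFAULT_FRAME_DT_S = 1.0

#: Default observation noise as a fraction of the noiseless trace range.
DEFAULT_OBS_NOISE_FRAC = 0.02

#: Default across-ROI log-normal jitter (sd of the log) on free parameters.
DEFAULT_JITTER_SD = 0.1

#: Default initial state (the inversion's prior-mean initial state).
DEFAULT_STATE0 = KineticState(0.1, 0.5, 0.5)

#: Default observation parameters for synthesis (arbitrary units).
DEFAULT_OBS = ObservationParams(kappa_f=1.0, d_f=0.1)


@dataclass
class Trace:
    """One ROI's fluorescence time series on a uniform grid."""

    roi_id: str
    times: np.ndarray
    fluorescence: np.ndarray
    frame_dt: float = DEFAULT_FRAME_DT_S

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise ValueError(
                f"trace {self.roi_id}: times and fluorescence lengths differ")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError(
                    f"trace {self.roi_id}: times must be strictly increasing")
            if np.max(np.abs(dt - self.frame_dt)) > 1e-6 * max(1.0, self.frame_dt):
                raise ValueError(
                    f"trace {self.roi_id}: non-uniform sampling "
                    f"(expected frame_dt={self.frame_dt} s)")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TraceTruth:
    """Ground-truth generating settings for one synthetic trace."""

    params: KineticParams
    obs: ObservationParams
    state0: KineticState
    obs_noise_sd: float
    state_noise_sd: float
    group: str = ""


@dataclass
class SyntheticCohort:
    """A set of synthetic traces with matching ground-truth records."""

    traces: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)  # roi_id -> TraceTruth

    def __post_init__(self):
        missing = [t.roi_id for t in self.traces if t.roi_id not in self.truth]
        if missing:
            raise ValueError(f"traces without truth records: {missing}")

    def group_of(self, roi_id: str) -> str:
        return self.truth[roi_id].group

    def groups(self) -> tuple[str, ...]:
        seen = dict.fromkeys(t.group for t in self.truth.values())
        return tuple(seen)

    def true_values(self, name: str, group: Optional[str] = None) -> np.ndarray:
        """True values of one kinetic parameter across the cohort."""
        vals = [getattr(t.params, name) for t in self.truth.values()
                if group is None or t.group == group]
        return np.asarray(vals, dtype=float)


def generate_trace(params: Optional[KineticParams] = None,
                   obs: Optional[ObservationParams] = None,
                   state0: KineticState = DEFAULT_STATE0,
                   obs_noise_sd: float = 0.0,
                   state_noise_sd: float = 0.0,
                   duration: float = DEFAULT_DURATION_S,
                   frame_dt: float = DEFAULT_FRAME_DT_S,
                   micro_dt: float = 0.1,
                   seed: Optional[int] = None,
                   roi_id: str = "roi") -> Trace:
    """Generate one synthetic fluorescence trace.

    The kinetics are integrated on the microtime grid; when
    ``state_noise_sd`` > 0, mean-zero Gaussian noise (per-component sd) is
    added to the state once per frame and the state re-clamped to its
    physical domain. The noiseless trajectory is mapped through the
    observation function and i.i.d. Gaussian observation noise with sd
    ``obs_noise_sd`` is added. Fully reproducible for a fixed seed.
    """
    params = params or KineticParams()
    obs = obs or DEFAULT_OBS
    params.validate()
    obs.validate()
    if obs_noise_sd < 0 or state_noise_sd < 0:
        raise ValueError("noise standard deviations must be >= 0")
    n_frames = int(round(duration / frame_dt))  # samples at t = 0 .. n-1
    if n_frames < 2:
        raise ValueError("duration must cover at least two frames")
    rng = np.random.default_rng(seed)

    if state_noise_sd > 0:
        ceiling = params.ceiling()
        x = state0.as_array()[None, :]
        states = [x[0].copy()]
        for _ in range(n_frames - 1):
            x, _ = _evolve_batch(x, params, frame_dt, micro_dt)
            x = x + rng.normal(0.0, state_noise_sd, size=(1, 3))
            x[0, 0] = np.clip(x[0, 0], 1e-9, ceiling - 1e-9)
            x[0, 1] = np.clip(x[0, 1], 0.0, 1.0)
            x[0, 2] = max(x[0, 2], 1e-9)
            states.append(x[0].copy())
        c_series = np.asarray(states)[:, 0]
    else:
        traj = simulate(state0, params, (n_frames - 1) * frame_dt,
                        frame_dt, micro_dt)
        c_series = traj.c_cs

    y = predict_trace(c_series, obs)
    if obs_noise_sd > 0:
        y = y + rng.normal(0.0, obs_noise_sd, size=y.shape)
    times = np.arange(n_frames, dtype=float) * frame_dt
    return Trace(roi_id=roi_id, times=times, fluorescence=y,
                 frame_dt=frame_dt)


def _noiseless_range(params: KineticParams, obs: ObservationParams,
                     state0: KineticState, duration: float, frame_dt: float,
                     micro_dt: float) -> float:
    traj = simulate(state0, params, duration, frame_dt, micro_dt)
    y = predict_trace(traj.c_cs, obs)
    return float(np.max(y) - np.min(y))


def generate_cohort(n_per_group: int = 10,
                    group_effects: Optional[dict] = None,
                    base_params: Optional[KineticParams] = None,
                    obs: Optional[ObservationParams] = None,
                    state0: KineticState = DEFAULT_STATE0,
                    jitter_sd: float = DEFAULT_JITTER_SD,
                    obs_noise_frac: float = DEFAULT_OBS_NOISE_FRAC,
                    state_noise_sd: float = 0.0,
                    duration: float = DEFAULT_DURATION_S,
                    frame_dt: float = DEFAULT_FRAME_DT_S,
                    micro_dt: float = 0.1,
                    seed: Optional[int] = None) -> SyntheticCohort:
    """Generate a cohort of synthetic traces with per-trace ground truth.

    ``group_effects`` maps a group label to multiplicative shifts of the
    free kinetic parameters (either a scalar applied to all, or a dict
    parameter -> factor); the default is a single unshifted group "A".
    Each trace draws its free parameters log-normally around the group
    means (sd of the log = ``jitter_sd``) with a per-trace sub-seed derived
    deterministically from the master seed, so regeneration is bitwise
    identical.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    base_params = base_params or KineticParams()
    base_params.validate()
    obs = obs or DEFAULT_OBS
    if group_effects is None:
        group_effects = {"A": 1.0}
    free = base_params.free_mask

    # normalise effects to dict[group] -> dict[param] -> factor
    effects = {}
    for group, eff in group_effects.items():
        if np.isscalar(eff):
            eff = {name: float(eff) for name in free}
        else:
            eff = {name: float(eff.get(name, 1.0)) for name in free}
        if any(v <= 0 for v in eff.values()):
            raise ValueError(f"group {group}: shifts must be > 0")
        effects[group] = eff

    master = np.random.SeedSequence(seed)
    n_total = n_per_group * len(effects)
    children = master.spawn(n_total)

    traces, truth = [], {}
    i = 0
    for group, eff in effects.items():
        for j in range(n_per_group):
            ss = children[i]
            i += 1
            rng = np.random.default_rng(ss)
            factors = {name: eff[name] * float(np.exp(
                rng.normal(0.0, jitter_sd))) for name in free}
            params = base_params.with_values(
                **{name: getattr(base_params, name) * factors[name]
                   for name in free})
            noise_sd = obs_noise_frac * _noiseless_range(
                params, obs, state0, duration, frame_dt, micro_dt) \
                if obs_noise_frac > 0 else 0.0
            roi_id = f"{group}_r{j:03d}"
            trace = generate_trace(
                params=params, obs=obs, state0=state0,
                obs_noise_sd=noise_sd, state_noise_sd=state_noise_sd,
                duration=duration, frame_dt=frame_dt, micro_dt=micro_dt,
                seed=ss.spawn(1)[0], roi_id=roi_id)
            traces.append(trace)
            truth[roi_id] = TraceTruth(
                params=params, obs=obs, state0=state0,
                obs_noise_sd=noise_sd, state_noise_sd=state_noise_sd,
                group=group)
    return SyntheticCohort(traces=traces, truth=truth)


def write_traces(traces, path) -> None:
    """Write traces in the pipeline's tidy CSV dialect
    (``roi_id,time_s,fluorescence``)."""
    frames = [pd.DataFrame({"roi_id": t.roi_id, "time_s": t.times,
                            "fluorescence": t.fluorescence})
              for t in traces]
    out = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["roi_id", "time_s", "fluorescence"])
    out.to_csv(path, index=False)


def write_truth(cohort: SyntheticCohort, path) -> None:
    """Write the per-trace ground-truth table as CSV."""
    rows = []
    for roi_id, t in cohort.truth.items():
        row = {"roi_id": roi_id, "group": t.group,
               "obs_noise_sd": t.obs_noise_sd,
               "state_noise_sd": t.state_noise_sd,
               "kappa_f": t.obs.kappa_f, "d_f": t.obs.d_f, "k_d": t.obs.k_d,
               "c_cs0": t.state0.c_cs, "q0": t.state0.q, "p0_state": t.state0.p}
        row.update({name: getattr(t.params, name)
                    for name in t.params.free_mask})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
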