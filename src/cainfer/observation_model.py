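"""Saturating indicator observation model.

Maps cytosolic calcium to GCaMP-type indicator fluorescence through a
hyperbolic (single-site binding) function

    g(C_CS) = kappa_f * C_CS / (C_CS + K_d) + d_f

where ``K_d`` is the indicator dissociation constant (0.167 uM for GCaMP6m
under the imaging conditions this pipeline targets) and ``kappa_f``/``d_f``
are per-recording scale and offset absorbing gain and background levels.
Fluorescence is treated as an instantaneous function of calcium; indicator
binding/decay kinetics are deliberately outside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ObservationParams", "observe", "predict_trace", "invert_observe"]

#: GCaMP6m dissociation constant, uM (167 nM).
DEFAULT_KD_UM = 0.167


@dataclass(frozen=True)
class ObservationParams:
    """Indicator observation parameters.

    ``k_d`` in uM; ``kappa_f`` (scale) and ``d_f`` (offset) in the arbitrary
    fluorescence units of the recording.
    """

    k_d: float = DEFAULT_KD_UM
    kappa_f: float = 1.0
    d_f: float = 0.0

    def validate(self) -> None:
        if not self.k_d > 0:
            raise ValueError(f"dissociation constant k_d={self.k_d} must be > 0")
        if not self.kappa_f > 0:
            raise ValueError(f"fluorescence scale kappa_f={self.kappa_f} must be > 0")
        for name in ("k_d", "kappa_f", "d_f"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite observation parameter {name}")

    @staticmethod
    def with_kd_nanomolar(kd_nm: float, **kwargs) -> "ObservationParams":
        """Build from a dissociation constant quoted in nM."""
        return ObservationParams(k_d=kd_nm / 1000.0, **kwargs)

    def with_values(self, **kwargs) -> "ObservationParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {"k_d": self.k_d, "kappa_f": self.kappa_f, "d_f": self.d_f}

    @staticmethod
    def from_dict(d: dict) -> "ObservationParams":
        obs = ObservationParams(**d)
        obs.validate()
        return obs


def observe(c_cs, obs: ObservationParams):
    """Fluorescence (arbitrary units) for cytosolic calcium ``c_cs`` (uM).

    Strictly increasing in ``c_cs``; ranges over [d_f, kappa_f + d_f), with
    half-saturation (midpoint between baseline and plateau) at
    ``c_cs = k_d``. Accepts scalars or arrays; negative calcium raises.
    """
    c = np.asarray(c_cs, dtype=float)
    if np.any(c < 0):
        raise ValueError(f"negative cytosolic calcium {np.min(c)} uM")
    y = obs.kappa_f * c / (c + obs.k_d) + obs.d_f
    return y if y.ndim else float(y)


def predict_trace(c_cs_series, obs: ObservationParams) -> np.ndarray:
    """Elementwise observation of a calcium series; preserves length."""
    c = np.asarray(c_cs_series, dtype=float)
    if c.size == 0:
        return np.empty(0, dtype=float)
    return np.asarray(observe(c, obs), dtype=float).reshape(c.shape)


def invert_observe(y, obs: ObservationParams):
    """Calcium concentration (uM) producing fluorescence ``y``.

    Exact inverse of :func:`observe` for ``y`` strictly inside
    (d_f, kappa_f + d_f); values at or outside the range raise.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr <= obs.d_f) or np.any(y_arr >= obs.kappa_f + obs.d_f):
        raise ValueError(
            f"fluorescence outside the open range "
            f"({obs.d_f}, {obs.kappa_f + obs.d_f}) is not invertible"
        )
    c = obs.k_d * (y_arr - obs.d_f) / (obs.kappa_f + obs.d_f - y_arr)
    return c if c.ndim else float(c)
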