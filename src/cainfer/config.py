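"""Flat key-value (YAML/JSON) serialisation of parameter sets and settings."""

from __future__ import annotations

import hashlib
import json

import yaml

from .kinetic_model import KineticParams
from .observation_model import ObservationParams
from .vb_inversion import InversionConfig

__all__ = ["load_config", "dump_config", "config_hash"]


def load_config(path) -> dict:
    """Load a run configuration.

    Recognised top-level sections: ``kinetic`` (model parameter values,
    keys named after the model symbols), ``observation`` (``k_d`` in uM or
    ``k_d_nm`` in nM, ``kappa_f``, ``d_f``) and ``inversion`` (solver
    settings). Missing sections fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    obs_raw = dict(raw.get("observation", {}))
    if "k_d_nm" in obs_raw:
        obs_raw["k_d"] = obs_raw.pop("k_d_nm") / 1000.0
    return {
        "kinetic": KineticParams.from_dict(raw.get("kinetic", {})),
        "observation": ObservationParams.from_dict(obs_raw),
        "inversion": InversionConfig.from_dict(raw.get("inversion", {})),
    }


def dump_config(config: dict, path) -> None:
    raw = {
        "kinetic": config["kinetic"].to_dict(),
        "observation": config["observation"].to_dict(),
        "inversion": config["inversion"].to_dict(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration, for provenance logs."""
    raw = {
        "kinetic": config["kinetic"].to_dict(),
        "observation": config["observation"].to_dict(),
        "inversion": config["inversion"].to_dict(),
    }
    blob = json.dumps(raw, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
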