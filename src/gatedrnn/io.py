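"""Result serialization, tables and run configuration.

Artifacts are self-describing: every file embeds the exact resolved
parameters.  Arrays go into NumPy ``.npz`` containers with a JSON metadata
entry (bit-exact round trip); tables are tab-separated text with a
``#``-prefixed metadata header.  Writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from typing import Optional

import numpy as np

from .network import Trajectory
from .params import NetworkParams

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "write_table",
    "read_table",
    "load_config",
    "params_from_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


def _atomic_write(path: str, writer) -> None:
    d = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_trajectory(path: str, traj: Trajectory) -> None:
    """Serialize a trajectory with its full parameter metadata."""
    meta = {
        "params": traj.params.as_dict(),
        "inputs": list(traj.inputs),
        "dt": traj.dt,
        "record_every": traj.record_every,
    }

    def writer(fh):
        np.savez(fh, times=traj.times, h=traj.h, z=traj.z, r=traj.r,
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    _atomic_write(path, writer)


def load_trajectory(path: str) -> Trajectory:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        return Trajectory(
            times=data["times"], h=data["h"], z=data["z"], r=data["r"],
            dt=float(meta["dt"]), params=NetworkParams.from_dict(meta["params"]),
            inputs=tuple(meta["inputs"]), record_every=int(meta["record_every"]),
        )


def write_table(path: str, frame, metadata: Optional[dict] = None) -> None:
    """Tab-separated table with a '#'-prefixed JSON metadata header."""
    header = ""
    if metadata:
        header = "".join(f"# {line}\n" for line in
                         json.dumps(metadata, indent=None, sort_keys=True).splitlines())
    body = frame.to_csv(sep="\t", index=False)

    def writer(fh):
        fh.write(header.encode())
        fh.write(body.encode())

    _atomic_write(path, writer)


def read_table(path: str):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")


# configuration keys mirror NetworkParams one-to-one, plus run settings
_PARAM_KEYS = {"n_units", "g_h", "alpha_z", "alpha_r", "beta_h", "beta_z",
               "beta_r", "tau_z", "tau_r", "seed"}
_RUN_KEYS = {"t_final", "dt", "record_every", "burn_in", "t_total",
             "t_transient", "k", "reorth_interval", "output", "sigma_h"}


def load_config(path: str) -> dict:
    """Flat key-value configuration (YAML subset); unknown keys are errors."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a flat key-value mapping")
    unknown = set(cfg) - _PARAM_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def params_from_config(cfg: dict) -> NetworkParams:
    kw = {k: v for k, v in cfg.items() if k in _PARAM_KEYS}
    for key in ("alpha_z", "alpha_r"):
        if isinstance(kw.get(key), str):
            if kw[key] not in ("inf", "Infinity"):
                raise ConfigError(f"{key} must be a number or 'inf'")
            kw[key] = math.inf
    return NetworkParams(**kw)
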