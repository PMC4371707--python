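"""Configuration loading: arm geometry, controller/olive/cerebellum parameters.

The shipped default configuration (``data/default.yaml``) holds the full
description of the simulated system: anthropometrics, the 11-muscle layout,
controller gains and delays, inferior-olive population parameters and the
cerebellar store settings for each model variant.  User configs are merged
over the defaults key by key, so a config file only needs the entries it
overrides.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .kinematics import ArmGeometry, MuscleGeometry

__all__ = [
    "default_config",
    "load_config",
    "build_geometry",
    "load_targets",
    "standard_targets",
]


def _data_path(name: str):
    return resources.files("cbreach.data").joinpath(name)


def default_config() -> dict:
    """The shipped default configuration as a nested dict."""
    with _data_path("default.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def _merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Default config, optionally overridden by a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def build_geometry(config: dict | None = None) -> ArmGeometry:
    """Construct an :class:`ArmGeometry` from a config dict."""
    cfg = config if config is not None else default_config()
    arm = cfg["arm"]
    muscles = []
    for spec in arm["muscles"]:
        kw = dict(spec)
        bl = kw.pop("bending_line", None)
        muscles.append(
            MuscleGeometry(
                name=kw.pop("name"),
                origin=np.array(kw.pop("origin"), dtype=float),
                insertion=np.array(kw.pop("insertion"), dtype=float),
                origin_frame=kw.pop("origin_frame", "world"),
                insertion_frame=kw.pop("insertion_frame", "upper"),
                bending_line=None if bl is None else np.array(bl, dtype=float),
                bending_frame=kw.pop("bending_frame", "world"),
                wrap_normal=(
                    np.array(kw.pop("wrap_normal"), dtype=float)
                    if "wrap_normal" in kw
                    else None
                ),
                **kw,
            )
        )
    return ArmGeometry(
        l_arm=arm["l_arm"],
        l_farm=arm["l_farm"],
        m_arm=arm["m_arm"],
        m_farm=arm["m_farm"],
        r_arm=arm["r_arm"],
        r_farm=arm["r_farm"],
        muscles=muscles,
    )


def load_targets(path: str | Path | None = None) -> np.ndarray:
    """Target coordinates in meters, shape (n, 3).

    The file is a CSV with columns ``target,x_cm,y_cm,z_cm`` (centimeters,
    as conventionally printed); values are converted to meters.
    """
    if path is None:
        src = _data_path("targets.csv").open("r")
    else:
        src = open(path)
    vals = []
    with src as fh:
        for line in fh:
            parts = line.strip().split(",")
            if len(parts) < 4:
                continue
            try:
                vals.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                continue  # header line
    return np.array(vals) / 100.0


def standard_targets() -> np.ndarray:
    """The 8 standard test-reach targets, in meters."""
    return load_targets(None)
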