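"""Config parsing and result serialization for reproducible runs.

Configs are YAML (or JSON, a YAML subset) mappings. Every run writes a
manifest recording the resolved parameters, seed, and package version, so an
output directory is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dga_engine import Smoothing
from .promoter_models import (
    FourStateParams,
    TwoStateParams,
    build_four_state,
    build_two_state,
)
from .reaction_core import ReactionSystem, SimConfig


class ConfigError(ValueError):
    pass


def load_config(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return cfg


def _require(cfg, field, typ=None):
    if field not in cfg:
        raise ConfigError(f"missing required config field: {field!r}")
    val = cfg[field]
    if typ is not None and not isinstance(val, typ):
        raise ConfigError(f"config field {field!r} must be {typ}, got {type(val)}")
    return val


def system_from_config(cfg):
    """Build a ReactionSystem from the ``system`` section.

    Either ``builder: two_state|four_state`` with a ``params`` mapping, or
    ``file: path`` pointing at a serialized reaction-system YAML.
    """
    sec = _require(cfg, "system", dict)
    if "file" in sec:
        path = Path(sec["file"])
        if not path.exists():
            raise ConfigError(f"system file not found: {path}")
        return ReactionSystem.from_dict(load_config(path))
    builder = _require(sec, "builder", str)
    params = sec.get("params", {})
    if builder == "two_state":
        return build_two_state(TwoStateParams(**params))
    if builder == "four_state":
        c = sec.get("concentration", 1.0)
        return build_four_state(FourStateParams(**params), c)
    raise ConfigError(f"unknown system builder {builder!r}")


def sim_config_from_config(cfg, seed):
    sec = cfg.get("simulation", {})
    return SimConfig(
        t_end=float(sec.get("t_end", 10.0)),
        n_traj=int(sec.get("n_traj", 2000)),
        max_steps=int(sec.get("max_steps", 100_000)),
        seed=int(seed),
    )


def smoothing_from_config(cfg):
    sec = cfg.get("smoothing", {})
    return Smoothing.from_inverse(
        inv_a=float(sec.get("inv_a", 200.0)), inv_b=float(sec.get("inv_b", 20.0))
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(out_dir, subcommand, cfg, seed, extra=None):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "dga",
        "version": __version__,
        "subcommand": subcommand,
        "seed": int(seed),
        "config": _jsonable(cfg),
    }
    if extra:
        manifest.update(_jsonable(extra))
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def write_table(path, array, header):
    np.savetxt(path, np.asarray(array), delimiter="\t", header=header, comments="# ")


def write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
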