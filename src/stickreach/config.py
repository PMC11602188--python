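"""Experiment configuration files (YAML) and reproducibility helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .geometry import StickGeometry
from .perturbation import PerturbationSpec
from .simulate import EXPERIMENTS, Protocol, make_protocol

__all__ = ["default_config", "load_config", "config_hash", "build_run"]


def default_config() -> dict:
    """Config with every default spelled out, ready to serialise."""
    return {
        "experiment": "E1A",
        "seed": 1,
        "geometry": {
            "stick_length_cm": 40.0,
            "grip_separation_cm": 15.0,
            "left_to_tip_cm": 40.0,
            "right_to_tip_cm": 25.0,
        },
        "protocol": {
            "baseline_trials": 360,
            "adaptation_trials": 240,
            "target_distance_cm": 10.0,
        },
        "perturbation": None,  # derived from `experiment` unless overridden
        "population": {
            "n": 10,
            "slope_mean": 0.2,
            "slope_sd": 0.07,
            "noise_sd_deg": 1.0,
        },
        "learner": {
            "eta_tmd": 0.1,
            "eta_sta": 0.1,
            "retention_loss": 0.0,
        },
    }


def load_config(path: str | Path) -> dict:
    """Load a YAML config, overlaying it on the defaults, with validation."""
    base = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
    for key, value in user.items():
        if key not in base:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            unknown = set(value) - set(base[key])
            if unknown:
                raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
            base[key].update(value)
        else:
            base[key] = value
    if base["experiment"] not in EXPERIMENTS:
        raise ValueError(f"experiment must be one of {EXPERIMENTS}, got {base['experiment']!r}")
    return base


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def build_run(cfg: dict, seed: int | None = None) -> tuple[Protocol, PerturbationSpec, StickGeometry, dict]:
    """Resolve a config into run objects; ``seed`` overrides the config seed."""
    seed = cfg["seed"] if seed is None else seed
    protocol, spec = make_protocol(cfg["experiment"], seed=seed)
    pcfg = cfg["protocol"]
    protocol = Protocol(
        baseline_trials=int(pcfg["baseline_trials"]),
        adaptation_trials=int(pcfg["adaptation_trials"]),
        target_distance=float(pcfg["target_distance_cm"]),
        order_seed=seed,
    )
    if cfg.get("perturbation"):
        spec = PerturbationSpec.from_dict(cfg["perturbation"])
    g = cfg["geometry"]
    geom = StickGeometry(
        stick_length=float(g["stick_length_cm"]),
        grip_separation=float(g["grip_separation_cm"]),
        left_to_tip=float(g["left_to_tip_cm"]),
        right_to_tip=float(g["right_to_tip_cm"]),
    )
    return protocol, spec, geom, {**cfg, "seed": seed}
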