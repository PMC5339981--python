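"""Run configuration: one YAML/JSON document with sections
``cohort / phantom / encoding / unwrap / quantify / stats / output``.

All defaults are embedded here and the fully resolved configuration is dumped
into the run manifest for provenance.  Validation reports violations with the
offending key path (e.g. ``encoding.fixed_venc: must be > 0``).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "ConfigError", "load_config", "validate_config",
           "config_hash"]


DEFAULT_CONFIG: dict = {
    "cohort": {
        # Severity mix follows the study population (3/7/9/4 of 23).
        "n_subjects": 23,
        "severity_mix": {"none": 0.13, "mild": 0.30, "moderate": 0.39,
                         "severe": 0.17},
    },
    "phantom": {
        "grid_nx": 96,
        "grid_ny": 96,
        "pixel_size_mm": 1.95,
        "n_frames": 20,
        "frame_dt_ms": 40.0,
        "lumen_radius_mm": 15.0,
        "tilt_max_deg": 30.0,
        "second_jet_prob": 0.2,
        "tte_windows": 3,
        "tte_max_misalignment_deg": 15.0,
    },
    "encoding": {
        "scout_vencs": [200.0, 300.0, 400.0],
        "venc_step": 100.0,
        "fixed_venc": None,  # cm/s; null -> scout per subject
        "noise_sigma": 0.03,
        "background_phase": 0.0,
    },
    "unwrap": {
        "method": "temporal",
        "anchor_frac": 0.9,
    },
    "quantify": {
        "mag_frac": 0.15,
        "flow_floor_frac": 0.05,
        "vmean_window": "ejection",
        "ejection_floor_frac": 0.01,
    },
    "stats": {
        "compare_r_method": "steiger_dependent",
        "min_subjects": 4,
    },
    "output": {
        "plots": True,
        "save_fields": False,
    },
}


class ConfigError(ValueError):
    """Configuration schema violation, message names the key path."""


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        key_path = f"{path}.{k}" if path else k
        if k not in base:
            raise ConfigError(f"{key_path}: unknown key")
        if isinstance(base[k], dict) and isinstance(v, dict):
            out[k] = _merge(base[k], v, key_path)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a config file merged over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError("config root must be a mapping")
        cfg = _merge(cfg, user)
    validate_config(cfg)
    return cfg


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {msg}")


def validate_config(cfg: dict) -> None:
    c = cfg["cohort"]
    _require(isinstance(c["n_subjects"], int) and c["n_subjects"] >= 1,
             "cohort.n_subjects", "must be an integer >= 1")
    mix = c["severity_mix"]
    _require(isinstance(mix, dict) and mix, "cohort.severity_mix",
             "must be a non-empty mapping")
    from .phantom import SEVERITY_PEAK_RANGES
    for k, v in mix.items():
        _require(k in SEVERITY_PEAK_RANGES, f"cohort.severity_mix.{k}",
                 f"unknown severity (expected {sorted(SEVERITY_PEAK_RANGES)})")
        _require(v >= 0, f"cohort.severity_mix.{k}", "must be >= 0")
    _require(sum(mix.values()) > 0, "cohort.severity_mix", "must sum to > 0")

    p = cfg["phantom"]
    _require(p["grid_nx"] >= 16 and p["grid_ny"] >= 16, "phantom.grid_nx",
             "grid dimensions must be >= 16")
    _require(p["pixel_size_mm"] > 0, "phantom.pixel_size_mm", "must be > 0")
    _require(p["n_frames"] >= 8, "phantom.n_frames", "must be >= 8")
    _require(p["frame_dt_ms"] > 0, "phantom.frame_dt_ms", "must be > 0")
    _require(p["lumen_radius_mm"] > 0, "phantom.lumen_radius_mm", "must be > 0")
    _require(0 <= p["tilt_max_deg"] < 90, "phantom.tilt_max_deg",
             "must be in [0, 90)")
    _require(0 <= p["second_jet_prob"] <= 1, "phantom.second_jet_prob",
             "must be in [0, 1]")
    _require(p["tte_windows"] >= 1, "phantom.tte_windows", "must be >= 1")

    e = cfg["encoding"]
    vs = e["scout_vencs"]
    _require(isinstance(vs, (list, tuple)) and len(vs) >= 1,
             "encoding.scout_vencs", "must be a non-empty list")
    _require(all(v > 0 for v in vs), "encoding.scout_vencs",
             "all values must be > 0")
    _require(list(vs) == sorted(vs), "encoding.scout_vencs",
             "must be sorted ascending")
    _require(e["venc_step"] > 0, "encoding.venc_step", "must be > 0")
    if e["fixed_venc"] is not None:
        _require(e["fixed_venc"] > 0, "encoding.fixed_venc", "must be > 0")
    _require(e["noise_sigma"] >= 0, "encoding.noise_sigma", "must be >= 0")

    u = cfg["unwrap"]
    _require(u["method"] in ("temporal", "spatial", "hybrid"), "unwrap.method",
             "must be temporal, spatial or hybrid")
    _require(0 < u["anchor_frac"] <= 1, "unwrap.anchor_frac",
             "must be in (0, 1]")

    q = cfg["quantify"]
    _require(0 <= q["mag_frac"] < 1, "quantify.mag_frac", "must be in [0, 1)")
    _require(q["flow_floor_frac"] >= 0, "quantify.flow_floor_frac",
             "must be >= 0")
    _require(q["vmean_window"] in ("ejection", "full_cycle"),
             "quantify.vmean_window", "must be ejection or full_cycle")
    _require(0 <= q["ejection_floor_frac"] < 1, "quantify.ejection_floor_frac",
             "must be in [0, 1)")

    s = cfg["stats"]
    _require(s["compare_r_method"] in ("steiger_dependent", "fisher_independent"),
             "stats.compare_r_method",
             "must be steiger_dependent or fisher_independent")
    _require(s["min_subjects"] >= 4, "stats.min_subjects", "must be >= 4")


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
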