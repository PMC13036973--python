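"""Run configuration: one YAML document with per-module sections.

``validate_config`` fills every omitted key with the framework's default
constants (risk threshold 0.6, GP variances 1.24 / 0.58, 50-observation GP
window, replay capacity 10,000, epsilon 0.1 -> 0.01 over 1,000 steps,
200 ms / 50 % windows at 200 Hz, 20 Hz low-pass cutoff, prune ratio 0.4),
rejects unknown keys, and range-checks every value it knows about.
"""

from __future__ import annotations

import copy

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "runs",
    "simulation": {
        "n_subjects": 6,
        "session_s": 60.0,
        "injury_rate": 3.0,
        "sample_rate_hz": 200.0,
        "bilateral": False,
        "include_mag": False,
        "type_proportions": [0.625, 0.168, 0.126, 0.080],
    },
    "preprocessing": {
        "cutoff_hz": 20.0,
        "filter_order": 4,
        "window_s": 0.2,
        "overlap": 0.5,
        "blend": 0.02,
        "smote_ratio": 1.0,
        "smote_k": 5,
    },
    "models": {
        "prune_ratio": 0.4,
        "dropout": 0.2,
        "cnn_epochs": 8,
        "lstm_epochs": 8,
        "lr": 0.001,
        "batch_size": 64,
        "patience": 3,
        "conv_order": "as_printed",
        "quantized_cnn": True,
    },
    "gp": {
        "sigma_f_sq": 1.24,
        "sigma_p_sq": 0.58,
        "matern_length": 0.5,
        "periodic_length": 0.3,
        "periodic_period": 0.7,
        "noise_var": 0.05,
        "buffer_capacity": 50,
        "horizon_s": 0.150,
        "fit_hyperparameters": False,
    },
    "rl": {
        "tau": 0.6,
        "lambda1": 1.0,
        "lambda2": 0.01,
        "lambda3": 0.01,
        "lambda4": 0.5,
        "eps_start": 0.1,
        "eps_end": 0.01,
        "eps_decay_steps": 1000,
        "replay_capacity": 10000,
        "gamma": 0.95,
        "target_sync": 100,
        "hidden": 32,
        "passes": 2,
    },
    "runtime": {
        "default_alpha": 0.5,
        "default_beta": 0.4,
        "latency_ref_ms": 26.4,
        "energy_ref_mj": 4.8,
    },
    "evaluation": {
        "lead_threshold_ms": 150.0,
        "match_before_s": 1.0,
        "match_after_s": 0.1,
        "merge_gap_s": 0.2,
        "far_denominator": "alert",
        "alpha": 0.01,
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, doc: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (doc or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def _check_ranges(cfg: dict) -> None:
    def req(cond, msg):
        if not cond:
            raise ConfigError(msg)

    req(0.0 < cfg["rl"]["tau"] < 1.0, "rl.tau must lie in (0, 1)")
    req(0.0 <= cfg["preprocessing"]["overlap"] < 1.0,
        "preprocessing.overlap must lie in [0, 1)")
    req(cfg["gp"]["sigma_f_sq"] > 0 and cfg["gp"]["sigma_p_sq"] > 0,
        "gp variances must be positive")
    req(cfg["gp"]["noise_var"] >= 0, "gp.noise_var must be non-negative")
    req(0.0 <= cfg["models"]["prune_ratio"] < 1.0,
        "models.prune_ratio must lie in [0, 1)")
    req(cfg["simulation"]["session_s"] > 0, "simulation.session_s must be > 0")
    req(cfg["simulation"]["sample_rate_hz"] >
        2 * cfg["preprocessing"]["cutoff_hz"],
        "sample rate must exceed twice the filter cutoff")
    req(cfg["rl"]["eps_start"] >= cfg["rl"]["eps_end"] >= 0,
        "epsilon schedule must be non-increasing")
    req(abs(sum(cfg["simulation"]["type_proportions"]) - 1.0) < 0.01,
        "simulation.type_proportions must sum to ~1")


def validate_config(document: dict | str | None = None) -> dict:
    """Parse/merge a config document onto the defaults; reject bad values."""
    if isinstance(document, str):
        document = yaml.safe_load(document) or {}
    cfg = _merge(DEFAULTS, document or {})
    _check_ranges(cfg)
    return cfg


def serialize_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True)


def load_config(path=None) -> dict:
    if path is None:
        return validate_config({})
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})
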