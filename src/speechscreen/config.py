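"""YAML experiment configuration: defaults, loading, deep merge.

Sections: ``cohort`` (synthetic generation; disable it and point
``data.manifest`` at real recordings instead), ``extraction``, ``split``,
``model``, ``pso`` (candidate sets), ``training``, ``evaluation``, ``seed``.
"""

from __future__ import annotations

import copy
import os
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "DESK_SCALE_CONFIG", "load_config", "merge_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "enabled": True,
        "n_participants": 46,
        "prevalence": 7 / 46,
        "effect_size": 1.0,
        "clip_duration_s": 10.0,
        "sample_rate": 44100,
        "control_profile": {},
        "positive_profile": {},
    },
    "data": {"manifest": None},
    "extraction": {
        "n_mfcc": 13,
        "n_fft": 2048,
        "hop_length": 512,
        "pre_emphasis": 0.97,
        "n_mels": 128,
        "frames_per_segment": 100,
    },
    "split": {"fractions": [0.60, 0.20, 0.20]},
    "model": {
        "bilstm_units_total": 512,
        "lstm_units": 256,
        "attention_units": 512,
        "dense1_units": 128,
        "dropout_rate": 0.6,
        "dense2_units": 64,
        "unit_scale": 1.0,
    },
    "pso": {
        "enabled": False,
        "particles": 15,
        "iterations": 30,
        "patience": 10,
        "epochs_per_eval": 5,
        "space": {
            "learning_rate": [0.0001, 0.001, 0.01, 0.1],
            "batch_size": [32, 64, 128],
            "momentum": [0.0, 0.5, 0.9],
        },
    },
    "training": {
        "learning_rate": 0.0001,
        "batch_size": 128,
        "max_epochs": 89,
        "momentum": 0.9,
        "early_stop_patience": 10,
    },
    "evaluation": {"granularity": "segment", "threshold": 0.5},
}

# One-CPU desk-scale variant: small cohort, short clips, 1/8-width model.
DESK_SCALE_CONFIG: dict = {
    "cohort": {
        "n_participants": 40,
        "prevalence": 0.25,
        "effect_size": 1.0,
        "clip_duration_s": 3.0,
        "sample_rate": 16000,
    },
    "extraction": {"frames_per_segment": 36, "hop_length": 256, "n_mels": 40},
    "model": {"unit_scale": 0.125},
    "training": {
        "learning_rate": 0.05,
        "batch_size": 32,
        "max_epochs": 30,
        "momentum": 0.9,
        "early_stop_patience": 10,
    },
}


def merge_config(base: dict, override: dict) -> dict:
    """Recursive dict merge; override wins leaf-by-leaf."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | os.PathLike | None = None) -> dict:
    """Defaults overlaid with a user YAML file (if given)."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(Path(path)) as fh:
            user = yaml.safe_load(fh) or {}
        config = merge_config(config, user)
    return config


def desk_scale_config() -> dict:
    """Defaults overlaid with the desk-scale overrides."""
    return merge_config(DEFAULT_CONFIG, DESK_SCALE_CONFIG)
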