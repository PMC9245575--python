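"""Versioned YAML configuration.

Every tunable threshold in the toolkit lives here, with the published
defaults, so a run is fully described by its config plus a seed.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .io import ConfigError

SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict = {
    "schema_version": SCHEMA_VERSION,
    "tags": {"cell_barcode": "CB", "umi": "UB", "gene": "GN", "strict": False},
    "cell_calling": {
        "knee_window": 5,          # running-median window on log10 totals
        "boundary": "inclusive",   # keep barcodes with total >= inflection count
        "use": "inflection",       # or "knee"
    },
    "dbec": {
        "select_log2max_gt": 8.0,
        "depth_mode": "shallow",   # shallow: mean>5.5, diff>5; deep: >6, >5.5
        "comp_mean_gt": None,      # override depth-mode default
        "diff_gt": None,
        "k_range": [1, 2, 3],
        "threshold_scale": "log2",  # or "transformed"
        "include_zeros": False,
        "em": {"max_iter": 500, "tol": 1e-8, "n_restarts": 5, "seed": 0},
    },
    "hashtag": {"min_total": 10, "singlet_ratio": 3.0},
    "qc": {
        "min_cells": 5,
        "min_genes": 500,
        "mito_threshold": 0.25,
        "gene_sets": {
            "mito": ["^mt-", "^MT-"],
            "ribo_protein": ["^Rp[sl]", "^RP[SL]"],
            "rrna": ["^Rn[0-9]*s", "rRNA"],
        },
    },
    "normalize": {"scale_factor": 1_000_000.0},
    "hvg": {"mean_cutoff": [0.1, None], "dispersion_cutoff": [0.5, None],
            "n_bins": 20},
    "compare": {"delta_threshold": 0.10, "kl_bins": 100, "kl_epsilon": 1e-9},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown config key '{path}{key}'")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, f"{path}{key}.")
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, merged over the defaults and schema-checked."""
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    version = user.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: schema_version {version} unsupported (expected {SCHEMA_VERSION})")
    return _merge(DEFAULT_CONFIG, user)


def save_config(config: dict, path: str | Path) -> Path:
    p = Path(path)
    p.write_text(yaml.safe_dump(config, sort_keys=False))
    return p
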