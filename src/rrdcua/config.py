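"""Run configuration: one YAML/JSON mapping drives a whole analysis."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .econ import BootstrapSettings, default_wtp_grid
from .errors import SchemaError
from .qaly import EconParams

__all__ = ["DEFAULT_CONFIG", "load_config", "build_run"]

DEFAULT_CONFIG = {
    "discount_rate": 0.03,
    "bootstrap_reps": 1000,
    "seed": 0,
    "wtp_grid_max": 150_000.0,
    "wtp_grid_step": 1_000.0,
    "exchange_rate_cny_per_usd": 6.29,
    "gdp_per_capita_cny": 38_354.0,
    "first_year_model": "linear_ramp",
}


def load_config(path=None) -> dict:
    """Read a YAML or JSON config file, merged over the defaults."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        unknown = set(data) - set(DEFAULT_CONFIG)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        config.update(data)
    return config


def build_run(config: dict) -> tuple[EconParams, BootstrapSettings, np.ndarray]:
    """Materialise parameter objects and the WTP grid from a config dict."""
    params = EconParams(
        discount_rate=float(config["discount_rate"]),
        first_year_model=config["first_year_model"],
        gdp_per_capita_cny=float(config["gdp_per_capita_cny"]),
        exchange_rate_cny_per_usd=float(config["exchange_rate_cny_per_usd"]),
    )
    settings = BootstrapSettings(
        replications=int(config["bootstrap_reps"]),
        seed=int(config["seed"]),
    )
    grid = default_wtp_grid(float(config["wtp_grid_max"]),
                            float(config["wtp_grid_step"]))
    return params, settings, grid
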