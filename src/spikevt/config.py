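"""Structured-text configuration for experiments (YAML, JSON-compatible).

A config file is a mapping with the sections shown below; every key is
optional except ``time_constant.family``, and omitted keys take the
built-in defaults (the standard LIF constants, 1000 steps of 1 ms,
mu = 20 ms, family-appropriate sigma).  Unknown keys are rejected by name.

.. code-block:: yaml

    lif: {v_rest: -65.0, v_reset: -65.0, v_init: -65.0, theta: -55.0,
          r: 1.0, i_ext: 12.0, dt: 1.0, n_steps: 1000}
    time_constant: {family: exponential, mu: 20.0, sigma: 5.0,
                    convention: literal}
    synapse: {tau_s: 2.0, i_s0: 1.0, enabled: true}
    mode: direct
    trials_m: 10000
    master_seed: 0
    fit: {family: gumbel, method: histogram_ls}
    bin_width: 1.0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiment import ExperimentConfig, config_to_dict
from .lif import LIFParameters, SynapseModel
from .sampling import TimeConstantModel

__all__ = ["ConfigError", "load_config", "save_config", "config_from_dict", "config_to_dict"]

# family-specific default for sigma when the config omits it
_DEFAULT_SIGMA = {"exponential": 5.0, "pareto": 20.0, "fixed": 1.0}


class ConfigError(ValueError):
    """A configuration file violated the schema; the message names the key."""


def _section(raw: dict, name: str, allowed: set[str]) -> dict:
    sub = raw.get(name, {})
    if sub is None:
        sub = {}
    if not isinstance(sub, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    unknown = set(sub) - allowed
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in section {name!r}")
    return sub


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Validate a plain dict against the schema and build a config."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_allowed = {"lif", "time_constant", "synapse", "mode", "trials_m",
                   "master_seed", "fit", "bin_width", "allow_family_mismatch"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level key {sorted(unknown)[0]!r}")

    lif_raw = _section(raw, "lif", {"v_rest", "v_reset", "v_init", "theta",
                                    "r", "i_ext", "dt", "n_steps"})
    tc_raw = _section(raw, "time_constant", {"family", "mu", "sigma", "convention"})
    syn_raw = _section(raw, "synapse", {"tau_s", "i_s0", "enabled"})
    fit_raw = _section(raw, "fit", {"family", "method"})

    if "family" not in tc_raw:
        raise ConfigError("time_constant.family is required")
    family = tc_raw["family"]
    tc_kwargs = dict(tc_raw)
    tc_kwargs.setdefault("mu", 20.0)
    tc_kwargs.setdefault("sigma", _DEFAULT_SIGMA.get(family, 1.0))
    try:
        tc = TimeConstantModel(**tc_kwargs)
        lif = LIFParameters(**lif_raw)
        syn = SynapseModel(**syn_raw)
        return ExperimentConfig(
            tc=tc, lif=lif, syn=syn,
            mode=raw.get("mode", "direct"),
            trials_m=raw.get("trials_m", 10_000),
            master_seed=raw.get("master_seed", 0),
            fit_family=fit_raw.get("family", ""),
            fit_method=fit_raw.get("method", "histogram_ls"),
            bin_width=raw.get("bin_width", 1.0),
            allow_family_mismatch=raw.get("allow_family_mismatch", False),
        )
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML (or JSON) experiment configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigError(f"{path}: empty configuration")
    return config_from_dict(raw)


def save_config(cfg: ExperimentConfig, path) -> None:
    """Write a config as YAML; loading it back yields an identical config."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
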