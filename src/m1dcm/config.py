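"""Loading of the versioned default configuration.

The package ships a single YAML file declaring the prior means of the
biophysical parameters (rate constants, baseline connection strengths,
observation mixing, input noise), the prior variances of the fitted
log-scale parameters, and the defaults of the synthetic-data generator.
All of it can be overridden by passing a user configuration dictionary of
the same shape.
"""

from __future__ import annotations

import copy
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .model_space import ModelSpec, Population
from .params import FullParams, NoiseSpec, ObservationParams, SynapticParams

__all__ = [
    "load_default_config",
    "load_config",
    "default_frequency_grid",
    "default_params",
    "prior_variances",
]


@lru_cache(maxsize=1)
def _default_config_cached() -> dict:
    text = resources.files("m1dcm").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_default_config() -> dict:
    """A deep copy of the packaged default configuration."""
    return copy.deepcopy(_default_config_cached())


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path_or_dict=None) -> dict:
    """Default configuration, optionally merged with a user override
    (a mapping, or a path to a YAML file)."""
    config = load_default_config()
    if path_or_dict is None:
        return config
    if isinstance(path_or_dict, dict):
        return _merge(config, path_or_dict)
    with open(path_or_dict) as fh:
        return _merge(config, yaml.safe_load(fh) or {})


def default_frequency_grid(config: dict | None = None) -> np.ndarray:
    """The analysis grid: 5-45 Hz at 0.5 Hz resolution by default."""
    config = config or load_default_config()
    g = config["frequency_grid"]
    n = int(round((g["stop_hz"] - g["start_hz"]) / g["step_hz"])) + 1
    return g["start_hz"] + g["step_hz"] * np.arange(n)


def _family_block(model: ModelSpec, config: dict) -> dict:
    try:
        return config[model.architecture_family]
    except KeyError:
        raise KeyError(
            f"no default parameters for family {model.architecture_family!r}"
        ) from None


def default_params(model: ModelSpec, config: dict | None = None) -> FullParams:
    """Prior-mean parameters for ``model`` from the (merged) configuration."""
    config = config or load_default_config()
    block = _family_block(model, config)

    tau = block["time_constant_ms"]
    kappa = np.array([1.0 / tau[p.value] for p in model.populations])

    strengths = block["base_strength"]
    base = np.array(
        [strengths[f"{c.source.code}->{c.target.code}"] for c in model.connections]
    )
    delays = np.full(
        len(model.inter_connection_indices), float(config["priors"]["delay_ms"])
    )
    synaptic = SynapticParams(
        kappa=kappa,
        base_strength=base,
        gamma=np.zeros(model.n_connections),
        delays=delays,
        sigmoid_slope=float(config["sigmoid_slope"]),
    )

    obs_block = block["observation"]
    contributions = np.array(
        [obs_block["contributions"][p.value] for p in model.populations]
    )
    observation = ObservationParams(
        contributions=contributions,
        gain=float(obs_block["gain"]),
        channel_noise_white=float(obs_block["channel_noise_white"]),
        channel_noise_pink=float(obs_block["channel_noise_pink"]),
    )

    noise_block = block["noise"]
    noise = NoiseSpec(
        white_amplitude=float(noise_block["white_amplitude"]),
        pink_amplitude=float(noise_block["pink_amplitude"]),
        pink_exponent=float(noise_block["pink_exponent"]),
        input_gains=np.array(
            [noise_block["input_gains"][label] for label in model.inputs]
        ),
    )
    return FullParams(synaptic=synaptic, observation=observation, noise=noise)


def prior_variances(config: dict | None = None) -> dict:
    config = config or load_default_config()
    return dict(config["priors"]["variance"])
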