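"""Parameter containers for the neural-mass forward model.

Connectivity is parameterised on a log scale: each connection has a fixed
signed prior baseline (``base_strength`` with the sign carried by the
connection) and a dimensionless log-scaling coefficient gamma, so the
effective strength is ``sign * base_strength * exp(gamma)`` — always
preserving the sign of the baseline.  Condition-specific changes enter as
additional log-scaling coefficients (beta) on top of gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError
from .model_space import ModelSpec

__all__ = [
    "SynapticParams",
    "ObservationParams",
    "NoiseSpec",
    "ConditionBeta",
    "FullParams",
    "effective_connectivity",
    "input_matrix",
]


@dataclass
class SynapticParams:
    """Synaptic rate constants, connectivity and conduction delays.

    Parameters
    ----------
    kappa : array, shape (n_populations,)
        Per-population synaptic rate constant, 1/ms (the inverse of the
        lumped membrane/dendritic time constant).
    base_strength : array, shape (n_connections,)
        Positive prior baseline of each connection's strength (synaptic
        units); the connection's sign is applied separately.
    gamma : array, shape (n_connections,)
        Log-scaling of each connection relative to its baseline.
    delays : array, shape (n_inter_connections,)
        Conduction delay of each inter-population connection, ms
        (self-connections are instantaneous).
    sigmoid_slope : float
        Rate parameter of the voltage-to-firing sigmoid (default 2/3).
    """

    kappa: np.ndarray
    base_strength: np.ndarray
    gamma: np.ndarray
    delays: np.ndarray
    sigmoid_slope: float = 2.0 / 3.0

    def __post_init__(self):
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        self.base_strength = np.atleast_1d(np.asarray(self.base_strength, float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.delays = np.atleast_1d(np.asarray(self.delays, dtype=float))
        if np.any(self.kappa <= 0):
            raise ParameterError("kappa must be positive elementwise")
        if np.any(self.base_strength < 0):
            raise ParameterError("base_strength magnitudes must be nonnegative")
        if np.any(self.delays < 0):
            raise ParameterError("delays must be nonnegative")
        if self.sigmoid_slope <= 0:
            raise ParameterError("sigmoid slope must be positive")

    def validate_for(self, model: ModelSpec) -> None:
        if self.kappa.shape != (model.n_populations,):
            raise ShapeError("kappa length must equal the number of populations")
        if self.base_strength.shape != (model.n_connections,):
            raise ShapeError("base_strength length must equal the number of connections")
        if self.gamma.shape != (model.n_connections,):
            raise ShapeError("gamma length must equal the number of connections")
        if self.delays.shape != (len(model.inter_connection_indices),):
            raise ShapeError(
                "delays length must equal the number of inter-population connections"
            )


@dataclass
class ObservationParams:
    """Laminar mixing of population voltages into the measured channel.

    ``contributions`` weights each population's mean voltage in the
    observed signal; prior means are 0.2 / 0.2 / 0.6 for superficial,
    middle and deep pyramidal layers and 0 for interneurons, reflecting
    the dominant dipole moment of deep-layer Betz cells.
    """

    contributions: np.ndarray
    gain: float = 1.0
    channel_noise_white: float = 0.0
    channel_noise_pink: float = 0.0

    def __post_init__(self):
        self.contributions = np.atleast_1d(np.asarray(self.contributions, float))
        if np.any(self.contributions < 0):
            raise ParameterError("observation contributions must be nonnegative")
        if self.channel_noise_white < 0 or self.channel_noise_pink < 0:
            raise ParameterError("channel noise densities must be nonnegative")


@dataclass
class NoiseSpec:
    """Endogenous input: a mixture of white and 1/f (pink) noise.

    The one-sided spectral density of the input to layer l is
    ``input_gains[l]**2 * (white_amplitude + pink_amplitude / f**pink_exponent)``.
    """

    white_amplitude: float = 1.0
    pink_amplitude: float = 1.0
    pink_exponent: float = 1.0
    input_gains: np.ndarray = field(default_factory=lambda: np.ones(3))
    seed: int = 0
    #: band limit (Hz) of the synthesised forcing in time-domain simulation;
    #: keeps fixed-step integration free of aliased high-frequency power.
    #: None means no cutoff.  Irrelevant to the 5-45 Hz band either way.
    cutoff_hz: float | None = 150.0

    def __post_init__(self):
        self.input_gains = np.atleast_1d(np.asarray(self.input_gains, dtype=float))
        if self.white_amplitude < 0 or self.pink_amplitude < 0:
            raise ParameterError("noise amplitudes must be nonnegative")
        if self.pink_exponent <= 0:
            raise ParameterError("pink exponent must be positive")

    def input_psd(self, freqs: np.ndarray) -> np.ndarray:
        """One-sided input spectral density per layer, shape (n_inputs, n_freqs)."""
        freqs = np.asarray(freqs, dtype=float)
        shape = self.white_amplitude + self.pink_amplitude / freqs ** self.pink_exponent
        return self.input_gains[:, None] ** 2 * shape[None, :]


@dataclass
class ConditionBeta:
    """Log-scale condition-specific modulators (relative to rest)."""

    connections: np.ndarray
    inputs: np.ndarray

    def __post_init__(self):
        self.connections = np.atleast_1d(np.asarray(self.connections, float))
        self.inputs = np.atleast_1d(np.asarray(self.inputs, dtype=float))


@dataclass
class FullParams:
    """Everything the spectral forward model needs for one subject."""

    synaptic: SynapticParams
    observation: ObservationParams
    noise: NoiseSpec
    condition_betas: dict[str, ConditionBeta] = field(default_factory=dict)

    def beta_for(self, model: ModelSpec, condition: str) -> ConditionBeta:
        if condition in self.condition_betas:
            return self.condition_betas[condition]
        return ConditionBeta(
            np.zeros(model.n_connections), np.zeros(len(model.inputs))
        )


def effective_connectivity(
    model: ModelSpec,
    params: SynapticParams,
    beta: np.ndarray | None = None,
) -> np.ndarray:
    """Signed effective connectivity matrix G, shape (n_pop, n_pop), with
    G[target, source] = sign * base_strength * exp(gamma + beta)."""
    n = model.n_populations
    G = np.zeros((n, n))
    log_scale = params.gamma if beta is None else params.gamma + beta
    strengths = params.base_strength * np.exp(log_scale)
    for c, s in zip(model.connections, strengths):
        G[model.population_index(c.target), model.population_index(c.source)] += (
            c.sign_value * s
        )
    return G


def input_matrix(model: ModelSpec, gains: np.ndarray | None = None) -> np.ndarray:
    """Map from exogenous input channels to populations, shape (n_pop, n_in)."""
    n_in = len(model.inputs)
    M = np.zeros((model.n_populations, n_in))
    for j, (label, target) in enumerate(model.inputs.items()):
        M[model.population_index(target), j] = 1.0 if gains is None else gains[j]
    return M
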