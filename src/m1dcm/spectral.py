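"""Linearised spectral forward model over the 5-45 Hz band.

The observed auto-spectral density is predicted by linearising the network
around its fixed point: the Jacobian of the state equations (with a
first-order correction for interlaminar conduction delays) yields
input-to-output transfer functions H(f); the predicted spectrum is the sum
over layer inputs of |H(f)|^2 times the input's white+pink spectral
density, plus additive channel noise.

Time is in ms inside the state space, so angular frequency in the resolvent
is 2*pi*f/1000 for f in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BandError, DelayError, DesignError, StabilityError
from .model_space import CONDITIONS, ConditionModulationDesign, ModelSpec
from .dynamics import NeuralState, sigmoid_firing_derivative
from .params import FullParams, ObservationParams, SynapticParams, effective_connectivity

__all__ = [
    "DelayedJacobian",
    "SpectralPrediction",
    "system_jacobian",
    "transfer_functions",
    "predict_psd",
    "condition_sweep",
    "stacked_delay_matrix",
]

BAND = (5.0, 45.0)


@dataclass
class DelayedJacobian:
    """Jacobian of the stacked (xv, xI) system with its delay correction.

    ``Q = (I + D o J)^{-1} J`` is the first-order Taylor treatment of
    per-connection conduction delays (D holds the delay of each coupling
    entry in ms); with all delays zero Q equals J exactly.
    """

    J: np.ndarray
    D: np.ndarray
    Q: np.ndarray

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.Q)

    @property
    def is_stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))


def stacked_delay_matrix(model: ModelSpec, params: SynapticParams) -> np.ndarray:
    """Delay (ms) of each entry of the stacked Jacobian: inter-population
    couplings enter the xI rows at the source's xv column."""
    n = model.n_populations
    D = np.zeros((2 * n, 2 * n))
    inter = model.inter_connection_indices
    for d, idx in zip(params.delays, inter):
        c = model.connections[idx]
        s = model.population_index(c.source)
        t = model.population_index(c.target)
        D[n + t, s] = d
    return D


def system_jacobian(
    model: ModelSpec,
    params: SynapticParams,
    point: NeuralState | None = None,
    beta: np.ndarray | None = None,
) -> DelayedJacobian:
    """Analytic Jacobian of the state equations at a fixed point (the origin
    by default), with the first-order delay correction applied."""
    params.validate_for(model)
    n = model.n_populations
    xv = np.zeros(n) if point is None else point.xv
    G = effective_connectivity(model, params, beta)
    sprime = sigmoid_firing_derivative(xv, params.sigmoid_slope)

    J = np.zeros((2 * n, 2 * n))
    J[:n, n:] = np.eye(n)
    J[n:, :n] = params.kappa[:, None] * G * sprime[None, :] - np.diag(params.kappa ** 2)
    J[n:, n:] = -2.0 * np.diag(params.kappa)

    D = stacked_delay_matrix(model, params)
    if np.any(D):
        A = np.eye(2 * n) + D * J
        if abs(np.linalg.det(A)) < 1e-300:
            raise DelayError("first-order delay correction is singular")
        Q = np.linalg.solve(A, J)
    else:
        Q = J.copy()
    return DelayedJacobian(J=J, D=D, Q=Q)


def _input_rows(model: ModelSpec, params: SynapticParams) -> np.ndarray:
    """B matrix mapping layer inputs into the corresponding xI rows,
    scaled by the target population's kappa; shape (2n, n_inputs)."""
    n = model.n_populations
    B = np.zeros((2 * n, len(model.inputs)))
    for j, target in enumerate(model.inputs.values()):
        p = model.population_index(target)
        B[n + p, j] = params.kappa[p]
    return B


def _observation_row(model: ModelSpec, obs: ObservationParams) -> np.ndarray:
    n = model.n_populations
    L = np.zeros(2 * n)
    L[:n] = obs.gain * obs.contributions
    return L


def _resolvent_response(Q, rows, B, freqs):
    """rows @ (i*omega*I - Q)^{-1} @ B for each frequency; omega in rad/ms."""
    two_n = Q.shape[0]
    omega = 2.0 * np.pi * np.asarray(freqs, dtype=float) / 1000.0
    A = 1j * omega[:, None, None] * np.eye(two_n)[None] - Q[None]
    X = np.linalg.solve(A, np.broadcast_to(B, (omega.size,) + B.shape))
    return rows @ X  # (n_freq, n_rows?, n_inputs) via matmul broadcasting


def transfer_functions(
    jac: DelayedJacobian,
    model: ModelSpec,
    params: SynapticParams,
    obs: ObservationParams,
    freqs: np.ndarray,
) -> np.ndarray:
    """Complex response H(f) of the observed channel to each exogenous
    input, shape (n_freqs, n_inputs)."""
    ev = jac.eigenvalues
    if np.any(ev.real >= 0):
        bad = ev[ev.real >= 0]
        raise StabilityError(
            f"linearised system is unstable; offending eigenvalues: {bad}"
        )
    L = _observation_row(model, obs)
    B = _input_rows(model, params)
    H = _resolvent_response(jac.Q, L[None, :], B, freqs)
    return H[:, 0, :]


@dataclass
class SpectralPrediction:
    """Predicted (or measured) auto-spectral density on a frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray
    condition: str = "rest"
    population_psd: np.ndarray | None = None  # (n_pop, n_freq) diagnostic

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape:
            raise BandError("freqs and psd must share a shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise BandError("frequency grid must be strictly increasing")


def _check_band(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() < BAND[0] - 1e-9 or freqs.max() > BAND[1] + 1e-9:
        raise BandError(
            f"frequencies must lie within the modelled band {BAND[0]}-{BAND[1]} Hz"
        )
    return freqs


def predict_psd(
    model: ModelSpec,
    params: FullParams,
    condition: str = "rest",
    freqs: np.ndarray | None = None,
    with_population_psd: bool = False,
    with_channel_noise: bool = True,
) -> SpectralPrediction:
    """Predicted auto-spectral density of the virtual electrode for one
    condition.  Condition modulators scale the modulated connections and
    input gains by exp(beta) before linearisation; rest carries no
    modulation by definition."""
    from .config import default_frequency_grid

    freqs = default_frequency_grid() if freqs is None else freqs
    freqs = _check_band(freqs)
    beta = params.beta_for(model, condition)

    jac = system_jacobian(model, params.synaptic, beta=beta.connections)
    H = transfer_functions(jac, model, params.synaptic, params.observation, freqs)

    input_psd = params.noise.input_psd(freqs)  # (n_in, n_freq)
    input_psd = input_psd * np.exp(2.0 * beta.inputs)[:, None]
    psd = np.einsum("fl,lf->f", np.abs(H) ** 2, input_psd)
    if with_channel_noise:
        obs = params.observation
        psd = psd + obs.channel_noise_white + obs.channel_noise_pink / freqs

    population_psd = None
    if with_population_psd:
        n = model.n_populations
        rows = np.zeros((n, 2 * n))
        rows[:, :n] = np.eye(n)
        Hp = _resolvent_response(jac.Q, rows, _input_rows(model, params.synaptic),
                                 freqs)
        population_psd = np.einsum("fpl,lf->pf", np.abs(Hp) ** 2, input_psd)

    return SpectralPrediction(freqs=freqs, psd=psd, condition=condition,
                              population_psd=population_psd)


def predict_psd_unchecked(
    model: ModelSpec,
    params: FullParams,
    freqs: np.ndarray,
    condition: str = "rest",
    with_channel_noise: bool = True,
) -> np.ndarray:
    """Predicted auto-spectral density on an arbitrary positive frequency
    grid (no band restriction) — used for validation against time-domain
    simulation, where window smoothing needs the spectrum slightly outside
    the fitted band."""
    freqs = np.asarray(freqs, dtype=float)
    beta = params.beta_for(model, condition)
    jac = system_jacobian(model, params.synaptic, beta=beta.connections)
    H = transfer_functions(jac, model, params.synaptic, params.observation, freqs)
    input_psd = params.noise.input_psd(freqs) * np.exp(2.0 * beta.inputs)[:, None]
    psd = np.einsum("fl,lf->f", np.abs(H) ** 2, input_psd)
    if with_channel_noise:
        obs = params.observation
        psd = psd + obs.channel_noise_white + obs.channel_noise_pink / freqs
    return psd


def expected_welch_psd(
    model: ModelSpec,
    params: FullParams,
    grid: np.ndarray,
    fs: float,
    nperseg: int,
    condition: str = "rest",
    with_channel_noise: bool = False,
    kernel_halfwidth_hz: float = 2.0,
    fine_step_hz: float = 0.05,
) -> np.ndarray:
    """Expected value of a Hann-window Welch estimate of the predicted
    spectrum: the prediction convolved with the window's spectral leakage
    kernel.  This is the unbiased reference when validating the linearised
    prediction against periodograms of simulated series."""
    import scipy.signal

    grid = np.asarray(grid, dtype=float)
    offsets = np.arange(-kernel_halfwidth_hz, kernel_halfwidth_hz + 1e-12,
                        fine_step_hz)
    w = scipy.signal.get_window("hann", nperseg)
    n = np.arange(nperseg)
    phase = np.exp(-2j * np.pi * np.outer(offsets, n) / fs)
    kernel = np.abs(phase @ w) ** 2
    kernel /= np.trapezoid(kernel, offsets)

    fine = (grid[:, None] - offsets[None, :]).ravel()
    fine = np.clip(fine, fine_step_hz / 10.0, None)
    psd_fine = predict_psd_unchecked(
        model, params, np.unique(fine), condition=condition,
        with_channel_noise=with_channel_noise,
    )
    lookup = dict(zip(np.unique(fine), psd_fine))
    S = np.array([lookup[f] for f in fine]).reshape(grid.size, offsets.size)
    return np.trapezoid(S * kernel[None, :], offsets, axis=1)


def condition_sweep(
    model: ModelSpec,
    params: FullParams,
    design: ConditionModulationDesign,
    freqs: np.ndarray | None = None,
    **kwargs,
) -> dict[str, SpectralPrediction]:
    """One spectral prediction per condition of the design, on a shared
    frequency grid."""
    for cond in design.conditions:
        if cond not in CONDITIONS:
            raise DesignError(f"unknown condition label {cond!r}")
    for cond in params.condition_betas:
        if cond not in design.conditions:
            raise DesignError(f"betas supplied for unknown condition {cond!r}")
    from .config import default_frequency_grid

    freqs = default_frequency_grid() if freqs is None else freqs
    return {
        cond: predict_psd(model, params, condition=cond, freqs=freqs, **kwargs)
        for cond in design.conditions
    }
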