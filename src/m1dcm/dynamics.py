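"""Neural-mass state equations, noise inputs and time-domain simulation.

Each population obeys a pair of first-order equations implementing an
alpha-kernel synaptic convolution of its presynaptic input U:

    dxv/dt = xI
    dxI/dt = kappa * U - 2 * kappa * xI - kappa**2 * xv
    U      = sum over incoming connections of (signed strength) * S(xv_source)
             + exogenous input E

with S a zero-centred sigmoid of slope 2/3 mapping voltage to normalised
firing rate.  Time is in milliseconds throughout; frequencies quoted in Hz.

The exogenous input E to each layer is a seeded mixture of white and pink
(1/f) noise, synthesised in the frequency domain so its expected one-sided
spectral density is exactly the declared ``white + pink / f**exponent``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
from scipy.special import expit

from .errors import (
    FixedPointError,
    InstabilityError,
    NumericalError,
    ParameterError,
    ShapeError,
)
from .model_space import ModelSpec
from .params import NoiseSpec, SynapticParams, effective_connectivity, input_matrix

__all__ = [
    "NeuralState",
    "sigmoid_firing",
    "sigmoid_firing_derivative",
    "ode_rhs",
    "generate_endogenous_noise",
    "simulate_time_series",
    "simulate_schedule",
    "SimulationResult",
    "fixed_point",
]


@dataclass
class NeuralState:
    """Mean membrane potentials (xv, mV) and currents (xI, mV/ms)."""

    xv: np.ndarray
    xI: np.ndarray

    def __post_init__(self):
        self.xv = np.atleast_1d(np.asarray(self.xv, dtype=float))
        self.xI = np.atleast_1d(np.asarray(self.xI, dtype=float))
        if self.xv.shape != self.xI.shape:
            raise ShapeError("xv and xI must have the same shape")

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.xv, self.xI])

    @classmethod
    def from_stacked(cls, x: np.ndarray) -> "NeuralState":
        n = x.shape[0] // 2
        return cls(x[:n], x[n:])


def sigmoid_firing(v, slope: float = 2.0 / 3.0):
    """Zero-centred logistic voltage-to-rate transform,
    S(v) = 1 / (1 + exp(-slope * v)) - 1/2, bounded in (-1/2, 1/2)."""
    if slope <= 0:
        raise ParameterError("sigmoid slope must be positive")
    return expit(slope * np.asarray(v, dtype=float)) - 0.5


def sigmoid_firing_derivative(v, slope: float = 2.0 / 3.0):
    """dS/dv; equals slope/4 at v = 0."""
    if slope <= 0:
        raise ParameterError("sigmoid slope must be positive")
    s = expit(slope * np.asarray(v, dtype=float))
    return slope * s * (1.0 - s)


def _rhs_raw(x: np.ndarray, G: np.ndarray, kappa: np.ndarray, slope: float,
             E: np.ndarray) -> np.ndarray:
    """Stacked right-hand side; x may be (2n,) or (2n, batch)."""
    n = G.shape[0]
    xv, xI = x[:n], x[n:]
    if E.ndim < xv.ndim:
        E = E.reshape(E.shape + (1,) * (xv.ndim - E.ndim))
    kap = kappa.reshape((n,) + (1,) * (xv.ndim - 1))
    u = G @ (expit(slope * xv) - 0.5) + E
    dxv = xI
    dxI = kap * u - 2.0 * kap * xI - kap ** 2 * xv
    return np.concatenate([dxv, dxI], axis=0)


def ode_rhs(
    state: NeuralState,
    params: SynapticParams,
    model: ModelSpec,
    exogenous: np.ndarray | None = None,
    beta: np.ndarray | None = None,
) -> NeuralState:
    """Time derivative of the network state under per-population input
    ``exogenous`` (already mapped to populations)."""
    params.validate_for(model)
    n = model.n_populations
    if state.xv.shape[0] != n:
        raise ShapeError("state dimension does not match the model")
    if not (np.all(np.isfinite(state.xv)) and np.all(np.isfinite(state.xI))):
        raise NumericalError("state contains non-finite entries")
    E = np.zeros(n) if exogenous is None else np.asarray(exogenous, dtype=float)
    if E.shape[0] != n:
        raise ShapeError("exogenous input dimension does not match the model")
    G = effective_connectivity(model, params, beta)
    dx = _rhs_raw(state.stacked(), G, params.kappa, params.sigmoid_slope, E)
    return NeuralState.from_stacked(dx)


# ---------------------------------------------------------------------------
# Endogenous noise
# ---------------------------------------------------------------------------

def generate_endogenous_noise(
    n_samples: int,
    dt: float,
    spec: NoiseSpec,
    rng: np.random.Generator | None = None,
    n_realisations: int | None = None,
) -> np.ndarray:
    """Seeded per-layer input series with expected one-sided spectral
    density ``gain**2 * (white + pink / f**exponent)`` (units: power/Hz,
    with f in Hz and ``dt`` the sample step in ms).

    Returns shape (n_inputs, n_samples), or (n_realisations, n_inputs,
    n_samples) when ``n_realisations`` is given.  Streams are independent
    across layers and realisations.
    """
    if n_samples <= 1:
        raise ParameterError("n_samples must exceed 1")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    rng = np.random.default_rng(spec.seed) if rng is None else rng

    fs = 1000.0 / dt  # Hz
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    psd[1:] = spec.white_amplitude + spec.pink_amplitude / freqs[1:] ** spec.pink_exponent
    if spec.cutoff_hz is not None:
        psd[freqs > spec.cutoff_hz] = 0.0
    # Scale so the periodogram of the synthesised series has mean `psd`.
    amplitude = np.sqrt(psd * fs * n_samples / 2.0)

    reps = 1 if n_realisations is None else int(n_realisations)
    n_in = len(spec.input_gains)
    z = rng.standard_normal((reps, n_in, freqs.size, 2))
    spectrum = amplitude * (z[..., 0] + 1j * z[..., 1]) / np.sqrt(2.0)
    spectrum[..., 0] = 0.0  # zero-mean input
    series = np.fft.irfft(spectrum, n=n_samples, axis=-1)
    series *= spec.input_gains[None, :, None]
    return series[0] if n_realisations is None else series


# ---------------------------------------------------------------------------
# Fixed points
# ---------------------------------------------------------------------------

def fixed_point(
    model: ModelSpec,
    params: SynapticParams,
    mean_input: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> NeuralState:
    """Equilibrium of the noise-free system under a constant per-population
    input.  At equilibrium xI = 0 and kappa * U = kappa**2 * xv, so only the
    voltage equation G S(xv) + E = kappa * xv is solved (from the origin).
    With zero mean input the origin itself is the equilibrium."""
    params.validate_for(model)
    n = model.n_populations
    E = np.zeros(n) if mean_input is None else np.asarray(mean_input, dtype=float)
    G = effective_connectivity(model, params, beta)
    slope = params.sigmoid_slope

    if not np.any(E):
        return NeuralState(np.zeros(n), np.zeros(n))

    def residual(xv):
        return G @ (expit(slope * xv) - 0.5) + E - params.kappa * xv

    sol = scipy.optimize.root(residual, np.zeros(n), tol=tol,
                              options={"maxfev": max_iter * n})
    xv = sol.x
    # Newton polish to the tight residual contract
    for _ in range(50):
        res = residual(xv)
        if np.max(np.abs(res)) < 1e-12:
            break
        s = expit(slope * xv)
        Jac = G * (slope * s * (1.0 - s))[None, :] - np.diag(params.kappa)
        try:
            xv = xv - np.linalg.solve(Jac, res)
        except np.linalg.LinAlgError:
            break
    if np.max(np.abs(residual(xv))) > 1e-10:
        raise FixedPointError(f"fixed-point search did not converge: {sol.message}")
    return NeuralState(xv, np.zeros(n))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Voltage traces plus the exogenous noise that drove them."""

    times: np.ndarray            # seconds
    voltages: np.ndarray         # (..., n_pop, n_samples)
    noise: np.ndarray            # (..., n_inputs, 2*n_samples+1) at dt/2
    dt_ms: float
    seed: int | None


def _rk4_segment(
    x0: np.ndarray,
    G: np.ndarray,
    kappa: np.ndarray,
    slope: float,
    E_half: np.ndarray,
    dt: float,
    bound: float,
    out: np.ndarray,
    param_desc: str,
) -> np.ndarray:
    """Integrate n_steps = out.shape[-1] - 1 steps of RK4 with the forcing
    sampled at half-step resolution (E_half has 2*n_steps+1 samples)."""
    n = G.shape[0]
    x = x0.copy()
    out[..., 0] = x[:n]
    n_steps = out.shape[-1] - 1
    for i in range(n_steps):
        e0, e1, e2 = E_half[:, 2 * i], E_half[:, 2 * i + 1], E_half[:, 2 * i + 2]
        k1 = _rhs_raw(x, G, kappa, slope, e0)
        k2 = _rhs_raw(x + 0.5 * dt * k1, G, kappa, slope, e1)
        k3 = _rhs_raw(x + 0.5 * dt * k2, G, kappa, slope, e1)
        k4 = _rhs_raw(x + dt * k3, G, kappa, slope, e2)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.max(np.abs(x[:n])) > bound:
            raise InstabilityError(
                f"simulation diverged (|xv| > {bound:g}) at step {i}; {param_desc}"
            )
        out[..., i + 1] = x[:n]
    return x


def simulate_time_series(
    model: ModelSpec,
    params: SynapticParams,
    noise: NoiseSpec,
    duration: float,
    dt: float = 1.0,
    n_realisations: int | None = None,
    beta: np.ndarray | None = None,
    x0: NeuralState | None = None,
    rng: np.random.Generator | None = None,
    bound: float = 1e6,
    layer_forcing: np.ndarray | None = None,
) -> SimulationResult:
    """Fixed-step (RK4) integration of the stochastic network.

    Parameters
    ----------
    duration : float
        Length of the simulation in seconds.
    dt : float
        Integration step in ms.  Noise is synthesised at dt/2 so the RK4
        stages see properly interpolated forcing.
    n_realisations : int, optional
        Simulate this many independent realisations in one vectorised run.
    layer_forcing : array, optional
        Pre-generated per-layer forcing sampled at dt/2 (2*n_steps + 1
        samples); overrides the internal noise synthesis, e.g. to compare
        integrations of the same physical noise at different steps.

    Returns voltage traces of shape (n_pop, n_samples) — or with a leading
    realisation axis — sampled every ``dt``.
    """
    if duration <= 0 or dt <= 0:
        raise ParameterError("duration and dt must be positive")
    params.validate_for(model)
    n = model.n_populations
    n_steps = int(round(duration * 1000.0 / dt))
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    if layer_forcing is not None:
        layer_noise = np.asarray(layer_forcing, dtype=float)
        if layer_noise.shape[-1] != 2 * n_steps + 1:
            raise ShapeError(
                f"layer_forcing must provide {2 * n_steps + 1} half-step samples"
            )
    else:
        layer_noise = generate_endogenous_noise(
            2 * n_steps + 1, dt / 2.0, spec=noise, rng=rng,
            n_realisations=n_realisations,
        )
    M = input_matrix(model)  # gains already applied inside the generator
    G = effective_connectivity(model, params, beta)
    desc = (
        f"model={model.name}, kappa={np.round(params.kappa, 4).tolist()}, "
        f"max|G|={np.max(np.abs(G)):.3g}"
    )

    reps = 1 if n_realisations is None else int(n_realisations)
    ln = layer_noise.reshape(reps, len(model.inputs), -1)
    E_half = np.einsum("pl,rlt->ptr", M, ln)  # (n_pop, 2*n_steps+1, reps)

    if x0 is None:
        x = np.zeros((2 * n, reps))
    else:
        x = np.repeat(x0.stacked()[:, None], reps, axis=1)

    out = np.empty((n, reps, n_steps + 1))
    _rk4_segment(x, G, params.kappa, params.sigmoid_slope, E_half, dt, bound,
                 out, desc)

    times = np.arange(n_steps + 1) * (dt / 1000.0)
    voltages = out[:, 0, :] if n_realisations is None else out.transpose(1, 0, 2)
    return SimulationResult(
        times=times, voltages=voltages, noise=layer_noise, dt_ms=dt,
        seed=noise.seed,
    )


def simulate_schedule(
    model: ModelSpec,
    params: SynapticParams,
    noise: NoiseSpec,
    segments: "list[tuple[float, np.ndarray | None] | tuple[float, np.ndarray | None, np.ndarray | None]]",
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
    x0: NeuralState | None = None,
    bound: float = 1e6,
) -> SimulationResult:
    """Piecewise-stationary simulation: each segment is (duration_s, beta)
    or (duration_s, beta, input_log_gain), with ``beta`` the log-scale
    connectivity modulation and ``input_log_gain`` the per-layer log
    scaling of the exogenous input active during that segment (None for
    rest).  State carries over across boundaries and one continuous noise
    stream drives the whole run."""
    params.validate_for(model)
    n = model.n_populations
    segments = [(s if len(s) == 3 else (*s, None)) for s in segments]
    steps = [int(round(d * 1000.0 / dt)) for d, _, _ in segments]
    if any(s <= 0 for s in steps):
        raise ParameterError("each segment must span at least one step")
    total = sum(steps)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    layer_noise = generate_endogenous_noise(2 * total + 1, dt / 2.0, spec=noise,
                                            rng=rng)
    M = input_matrix(model)

    x = np.zeros((2 * n, 1)) if x0 is None else x0.stacked()[:, None]
    out = np.empty((n, 1, total + 1))
    offset = 0
    for (duration_s, beta, input_log), n_steps in zip(segments, steps):
        G = effective_connectivity(model, params, beta)
        desc = f"model={model.name}, segment at step {offset}"
        seg_out = out[..., offset:offset + n_steps + 1]
        seg_noise = layer_noise[:, 2 * offset:2 * (offset + n_steps) + 1]
        if input_log is not None:
            seg_noise = seg_noise * np.exp(np.asarray(input_log, float))[:, None]
        E_half = np.einsum("pl,lt->pt", M, seg_noise)[:, :, None]
        x = _rk4_segment(
            x, G, params.kappa, params.sigmoid_slope,
            E_half, dt, bound, seg_out, desc,
        )
        offset += n_steps

    times = np.arange(total + 1) * (dt / 1000.0)
    return SimulationResult(times=times, voltages=out[:, 0, :],
                            noise=layer_noise, dt_ms=dt, seed=noise.seed)
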