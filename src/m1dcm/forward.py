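"""Packed-parameter spectral forward operator used by the inversion.

The fitted parameter vector concatenates, in a fixed order: intrinsic
log-scalings (gamma, one per connection), condition modulators (beta, one
per modulated connection and non-rest condition, plus input modulators),
log deviations of rate constants and delays, log observation
contributions, log gain and log noise amplitudes.  Packing and unpacking
are exact inverses.

``SpectralForwardOperator`` maps a batch of parameter vectors to predicted
log-spectra over the conditions of the design.  Internally the transfer
function is evaluated by eigendecomposition of the delay-corrected system
matrix, H(f) = sum_m (L v_m)(w_m^T B) / (i*omega - lambda_m), which is
much cheaper than a per-frequency solve and yields stability information
(max Re lambda) for free.  Unstable parameter vectors produce NaN rows,
which the optimiser treats as rejected proposals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import default_frequency_grid, default_params, load_default_config
from .errors import ShapeError
from .model_space import ConditionModulationDesign, ModelSpec, default_design
from .params import ConditionBeta, FullParams

__all__ = ["ParamLayout", "build_layout", "SpectralForwardOperator"]


@dataclass(frozen=True)
class ParamLayout:
    """Ordered blocks of the packed parameter vector."""

    blocks: tuple[tuple[str, int], ...]

    @property
    def size(self) -> int:
        return sum(n for _, n in self.blocks)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.blocks)

    def slice_of(self, name: str) -> slice:
        start = 0
        for block, n in self.blocks:
            if block == name:
                return slice(start, start + n)
            start += n
        raise KeyError(f"unknown parameter block {name!r}")

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape[-1] != self.size:
            raise ShapeError(
                f"parameter vector has length {theta.shape[-1]}, expected {self.size}"
            )
        return {name: theta[..., self.slice_of(name)] for name, _ in self.blocks}

    def pack(self, values: dict[str, np.ndarray]) -> np.ndarray:
        parts = []
        for name, n in self.blocks:
            v = np.atleast_1d(np.asarray(values.get(name, np.zeros(n)), float))
            if v.shape[-1] != n:
                raise ShapeError(f"block {name!r} expects length {n}")
            parts.append(v)
        return np.concatenate(parts, axis=-1)

    def labels(self) -> list[str]:
        """One human-readable label per packed element."""
        out = []
        for name, n in self.blocks:
            out.extend([name] if n == 1 else [f"{name}[{i}]" for i in range(n)])
        return out


def build_layout(model: ModelSpec, design: ConditionModulationDesign) -> ParamLayout:
    blocks: list[tuple[str, int]] = [("gamma", model.n_connections)]
    for cond in design.non_rest_conditions:
        blocks.append((f"beta_{cond}", len(design.modulated_connections)))
    for cond in design.non_rest_conditions:
        blocks.append((f"input_beta_{cond}", len(design.modulated_inputs)))
    blocks += [
        ("log_kappa", model.n_populations),
        ("log_delay", len(model.inter_connection_indices)),
    ]
    blocks += [
        ("log_obs", _n_contributing(model)),
        ("log_gain", 1),
        ("log_input_white", 1),
        ("log_input_pink", 1),
        ("log_channel_white", 1),
        ("log_channel_pink", 1),
    ]
    return ParamLayout(tuple(blocks))


def _n_contributing(model: ModelSpec) -> int:
    params = default_params(model)
    return int(np.sum(params.observation.contributions > 0))


_VARIANCE_OF_BLOCK = {
    "gamma": "gamma",
    "log_kappa": "kappa",
    "log_delay": "delay",
    "log_obs": "obs_contrib",
    "log_gain": "gain",
    "log_input_white": "noise",
    "log_input_pink": "noise",
    "log_channel_white": "noise",
    "log_channel_pink": "noise",
}


def prior_variance_of_block(name: str, variances: dict) -> float:
    if name.startswith("beta_") or name.startswith("input_beta_"):
        return float(variances["beta"])
    return float(variances[_VARIANCE_OF_BLOCK[name]])


class SpectralForwardOperator:
    """Batched map from packed parameters to per-condition log-spectra.

    Parameters at the layout's origin (all zeros) reproduce the prior-mean
    prediction exactly; every packed element is a log-scale deviation from
    the configured baseline.
    """

    def __init__(
        self,
        model: ModelSpec,
        design: ConditionModulationDesign | None = None,
        freqs: np.ndarray | None = None,
        config: dict | None = None,
        base: FullParams | None = None,
    ):
        self.model = model
        self.design = default_design(model) if design is None else design
        self.config = load_default_config() if config is None else config
        self.freqs = (
            default_frequency_grid(self.config) if freqs is None else
            np.asarray(freqs, dtype=float)
        )
        self.base = default_params(model, self.config) if base is None else base
        self.layout = build_layout(model, self.design)

        n = model.n_populations
        self.n_pop = n
        conns = model.connections
        self._src = np.array([model.population_index(c.source) for c in conns])
        self._tgt = np.array([model.population_index(c.target) for c in conns])
        self._sign = np.array([c.sign_value for c in conns], dtype=float)
        inter = model.inter_connection_indices
        self._inter = np.array(inter, dtype=int)
        self._mod_conn = np.array(self.design.modulated_connections, dtype=int)
        input_labels = list(model.inputs)
        self._mod_inputs = np.array(
            [input_labels.index(l) for l in self.design.modulated_inputs], dtype=int
        )
        self._input_pop = np.array(
            [model.population_index(p) for p in model.inputs.values()]
        )
        self._obs_idx = np.flatnonzero(self.base.observation.contributions > 0)
        self._omega = 2.0 * np.pi * self.freqs / 1000.0  # rad/ms

    # ------------------------------------------------------------------
    @property
    def n_out(self) -> int:
        return len(self.design.conditions) * self.freqs.size

    def full_params(self, theta: np.ndarray) -> FullParams:
        """Interpret a packed vector as a FullParams (single vector only)."""
        v = self.layout.unpack(np.asarray(theta, dtype=float))
        base = self.base
        import copy

        p = copy.deepcopy(base)
        p.synaptic.gamma = base.synaptic.gamma + v["gamma"]
        p.synaptic.kappa = base.synaptic.kappa * np.exp(v["log_kappa"])
        p.synaptic.delays = base.synaptic.delays * np.exp(v["log_delay"])
        contrib = base.observation.contributions.copy()
        contrib[self._obs_idx] *= np.exp(v["log_obs"])
        p.observation.contributions = contrib
        p.observation.gain = base.observation.gain * float(np.exp(v["log_gain"][0]))
        p.observation.channel_noise_white = (
            base.observation.channel_noise_white * float(np.exp(v["log_channel_white"][0]))
        )
        p.observation.channel_noise_pink = (
            base.observation.channel_noise_pink * float(np.exp(v["log_channel_pink"][0]))
        )
        p.noise.white_amplitude = base.noise.white_amplitude * float(np.exp(v["log_input_white"][0]))
        p.noise.pink_amplitude = base.noise.pink_amplitude * float(np.exp(v["log_input_pink"][0]))
        for cond in self.design.non_rest_conditions:
            cb = np.zeros(self.model.n_connections)
            cb[self._mod_conn] = v[f"beta_{cond}"]
            ib = np.zeros(len(self.model.inputs))
            ib[self._mod_inputs] = v[f"input_beta_{cond}"]
            p.condition_betas[cond] = ConditionBeta(cb, ib)
        return p

    # ------------------------------------------------------------------
    def psd(self, theta: np.ndarray) -> np.ndarray:
        """Linear-power prediction, shape (..., n_conditions, n_freqs);
        NaN where the linearised system is unstable."""
        theta = np.asarray(theta, dtype=float)
        lead = theta.shape[:-1]
        th = theta.reshape(-1, theta.shape[-1])
        out = self._psd_flat(th)
        return out.reshape(lead + out.shape[1:])

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        """Log-power prediction flattened over conditions, shape (..., n_out)."""
        psd = self.psd(theta)
        lead = psd.shape[:-2]
        with np.errstate(invalid="ignore", divide="ignore"):
            logp = np.log(psd)
        return logp.reshape(lead + (self.n_out,))

    # ------------------------------------------------------------------
    def _psd_flat(self, th: np.ndarray) -> np.ndarray:
        B = th.shape[0]
        n = self.n_pop
        v = self.layout.unpack(th)
        base = self.base
        slope = base.synaptic.sigmoid_slope
        sprime0 = slope / 4.0  # sigmoid derivative at the resting fixed point

        kappa = base.synaptic.kappa[None, :] * np.exp(v["log_kappa"])  # (B, n)
        delays = base.synaptic.delays[None, :] * np.exp(v["log_delay"])
        contrib = np.broadcast_to(
            base.observation.contributions, (B, n)
        ).copy()
        contrib[:, self._obs_idx] *= np.exp(v["log_obs"])
        gain = base.observation.gain * np.exp(v["log_gain"][:, 0])  # (B,)
        white = base.noise.white_amplitude * np.exp(v["log_input_white"][:, 0])
        pink = base.noise.pink_amplitude * np.exp(v["log_input_pink"][:, 0])
        ch_w = base.observation.channel_noise_white * np.exp(
            v["log_channel_white"][:, 0]
        )
        ch_p = base.observation.channel_noise_pink * np.exp(
            v["log_channel_pink"][:, 0]
        )

        freqs = self.freqs
        n_cond = len(self.design.conditions)
        out = np.empty((B, n_cond, freqs.size))

        # frequency-shape of the input noise, shared across conditions
        noise_shape = (
            white[:, None] + pink[:, None] / freqs[None, :] ** base.noise.pink_exponent
        )  # (B, F)
        channel = ch_w[:, None] + ch_p[:, None] / freqs[None, :]

        eye2n = np.eye(2 * n)
        for ci, cond in enumerate(self.design.conditions):
            conn_log = v["gamma"].copy()
            input_log = np.zeros((B, len(self.model.inputs)))
            if cond != "rest":
                conn_log[:, self._mod_conn] += v[f"beta_{cond}"]
                input_log[:, self._mod_inputs] += v[f"input_beta_{cond}"]
            strength = self._sign * base.synaptic.base_strength * np.exp(conn_log)

            G = np.zeros((B, n, n))
            G[:, self._tgt, self._src] = strength
            J = np.zeros((B, 2 * n, 2 * n))
            J[:, :n, n:] = np.eye(n)
            J[:, n:, :n] = kappa[:, :, None] * G * sprime0
            idx = np.arange(n)
            J[:, n + idx, idx] -= kappa ** 2
            J[:, n + idx, n + idx] = -2.0 * kappa

            D = np.zeros((B, 2 * n, 2 * n))
            D[:, n + self._tgt[self._inter], self._src[self._inter]] = delays
            Q = np.linalg.solve(eye2n[None] + D * J, J)

            lam, V = np.linalg.eig(Q)  # (B, 2n), (B, 2n, 2n)
            unstable = lam.real.max(axis=-1) >= 0

            Bmat = np.zeros((B, 2 * n, len(self.model.inputs)))
            Bmat[:, n + self._input_pop, np.arange(len(self.model.inputs))] = (
                kappa[:, self._input_pop]
            )
            L = np.zeros((B, 2 * n))
            L[:, :n] = gain[:, None] * contrib

            with np.errstate(all="ignore"):
                W = np.einsum(
                    "bm,bml->bml", np.einsum("bs,bsm->bm", L, V),
                    np.linalg.solve(V, Bmat.astype(complex)),
                )
                resolvent = 1.0 / (
                    1j * self._omega[None, :, None] - lam[:, None, :]
                )  # (B, F, 2n)
                H = np.einsum("bml,bfm->bfl", W, resolvent)

                gains2 = (
                    base.noise.input_gains[None, :] ** 2 * np.exp(2.0 * input_log)
                )  # (B, n_in)
                psd = np.einsum("bfl,bl->bf", np.abs(H) ** 2, gains2) * noise_shape
            psd = psd + channel
            psd[unstable] = np.nan
            psd[~np.isfinite(psd).all(axis=1)] = np.nan
            out[:, ci, :] = psd
        return out
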