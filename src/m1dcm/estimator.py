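"""Scikit-learn style estimator for spectral DCM of a single source.

``SpectralDCM`` fits the laminar neural-mass model to per-condition
auto-spectra by variational Laplace and exposes the posterior, the free
energy (approximate log model evidence) and posterior-predictive spectra.
Module-level functions (``variational_laplace_fit``, ``free_energy``,
``posterior_predictive``) are thin wrappers over the estimator for
script-style use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import default_frequency_grid, load_config, prior_variances
from .errors import GridMismatchError, ShapeError
from .forward import SpectralForwardOperator, build_layout, prior_variance_of_block
from .inversion import (
    InversionTrace,
    PosteriorDensity,
    PriorDensity,
    fd_jacobian,
    gaussian_free_energy,
    variational_laplace,
)
from .model_space import ConditionModulationDesign, ModelSpec, default_design
from .model_space import build_reduced_cmc, enumerate_m1_models, winning_m1_model
from .spectral import SpectralPrediction

__all__ = [
    "SpectralDCM",
    "resolve_model",
    "build_priors",
    "variational_laplace_fit",
    "posterior_predictive",
    "free_energy",
]

_NAMED_MODELS = {
    "winning_m1": winning_m1_model,
    "m1_core": lambda: enumerate_m1_models()[0],
    "reduced_cmc": build_reduced_cmc,
}


def resolve_model(model: "ModelSpec | str") -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    if model in _NAMED_MODELS:
        return _NAMED_MODELS[model]()
    for spec in enumerate_m1_models():
        if spec.name == model:
            return spec
    raise KeyError(f"unknown model {model!r}")


def build_priors(
    model: ModelSpec,
    design: ConditionModulationDesign | None = None,
    config: dict | None = None,
) -> PriorDensity:
    """Zero-mean Gaussian prior over the packed log-scale parameters, with
    per-block variances from the configuration (1/16 on connectivity
    log-scalings and condition modulators, 1/64 on rate-constant and delay
    deviations, 1/8 on gain and noise logs)."""
    design = default_design(model) if design is None else design
    layout = build_layout(model, design)
    variances = prior_variances(config)
    diag = np.concatenate(
        [np.full(n, prior_variance_of_block(name, variances))
         for name, n in layout.blocks]
    )
    return PriorDensity(mean=np.zeros(layout.size), cov=np.diag(diag))


class SpectralDCM(BaseEstimator):
    """Dynamic causal model of single-source cross-spectral density.

    Parameters
    ----------
    model : ModelSpec or str, default="winning_m1"
        Microcircuit architecture to invert (a ModelSpec, or one of
        "winning_m1", "m1_core", "reduced_cmc", or an enumerated M1 name).
    design : ConditionModulationDesign, optional
        Condition-modulation design; defaults to all connections and all
        inputs modulated in the non-rest conditions.
    freqs : array, optional
        Frequency grid (Hz); defaults to 5-45 Hz at 0.5 Hz.
    config : dict, optional
        Configuration overrides merged over the packaged defaults.
    noise_precision : float, optional
        Fixed precision of the Gaussian error on log-power; estimated from
        the data when None.
    max_iter, tol, fd_step, lm_lambda0 :
        Optimiser controls (free-energy ascent; ``tol`` in nats).

    Attributes
    ----------
    posterior_ : PosteriorDensity
        Gaussian posterior over the packed log-scale parameters.
    free_energy_ : float
        Final free energy (approximate log model evidence, nats).
    trace_ : InversionTrace
        Accepted-step free energies and convergence status.
    forward_ : SpectralForwardOperator
        The packed forward operator (layout, baselines, grid).
    """

    def __init__(
        self,
        model="winning_m1",
        design=None,
        freqs=None,
        config=None,
        noise_precision=None,
        max_iter=128,
        tol=1e-2,
        fd_step=1e-4,
        lm_lambda0=1e-3,
    ):
        self.model = model
        self.design = design
        self.freqs = freqs
        self.config = config
        self.noise_precision = noise_precision
        self.max_iter = max_iter
        self.tol = tol
        self.fd_step = fd_step
        self.lm_lambda0 = lm_lambda0

    # ------------------------------------------------------------------
    def _build(self):
        model = resolve_model(self.model)
        design = default_design(model) if self.design is None else self.design
        config = load_config(self.config)
        freqs = (
            default_frequency_grid(config) if self.freqs is None
            else np.asarray(self.freqs, dtype=float)
        )
        forward = SpectralForwardOperator(model, design, freqs=freqs, config=config)
        prior = build_priors(model, design, config)
        return model, design, forward, prior

    def _validate_data(self, X, forward):
        if isinstance(X, dict):
            X = np.vstack([X[c] for c in forward.design.conditions])
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        n_cond = len(forward.design.conditions)
        if X.shape != (n_cond, forward.freqs.size):
            raise ShapeError(
                f"expected spectra of shape ({n_cond}, {forward.freqs.size}), "
                f"got {X.shape}"
            )
        if not np.isfinite(X).all() or np.any(X <= 0):
            raise ShapeError("spectra must be finite and strictly positive")
        return X

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit the model to per-condition power spectra.

        Parameters
        ----------
        X : array of shape (n_conditions, n_freqs), or mapping
            condition -> spectrum.  Strictly positive linear power on the
            estimator's frequency grid (log-power is fitted internally).
        y : ignored (scikit-learn API compatibility).
        """
        model, design, forward, prior = self._build()
        X = self._validate_data(X, forward)
        data_log = np.log(X).ravel()

        posterior, trace = variational_laplace(
            forward,
            data_log,
            prior,
            noise_precision=self.noise_precision,
            max_iter=self.max_iter,
            tol=self.tol,
            fd_step=self.fd_step,
            lm_lambda0=self.lm_lambda0,
        )
        self.model_ = model
        self.design_ = design
        self.forward_ = forward
        self.prior_ = prior
        self.freqs_ = forward.freqs
        self.data_ = X
        self.posterior_ = posterior
        self.trace_ = trace
        self.free_energy_ = trace.final_free_energy
        self.n_iter_ = trace.n_iterations
        self.converged_ = trace.converged
        self.tau_ = trace.tau
        return self

    # ------------------------------------------------------------------
    def predict(self, X=None):
        """Posterior-predictive spectra at the posterior mean, shape
        (n_conditions, n_freqs), linear power."""
        self._check_fitted()
        return self.forward_.psd(self.posterior_.mean)

    def predict_prediction_objects(self) -> dict[str, SpectralPrediction]:
        self._check_fitted()
        psd = self.predict()
        return {
            cond: SpectralPrediction(self.freqs_, psd[i], condition=cond)
            for i, cond in enumerate(self.design_.conditions)
        }

    def residuals(self):
        """Log-power residuals (data minus posterior prediction)."""
        self._check_fitted()
        return np.log(self.data_) - np.log(self.predict())

    def score(self, X=None, y=None):
        """R^2 of the posterior-mean prediction on log-power."""
        self._check_fitted()
        data = (
            np.log(self.data_) if X is None
            else np.log(self._validate_data(X, self.forward_))
        )
        pred = np.log(self.predict())
        ss_res = np.sum((data - pred) ** 2)
        ss_tot = np.sum((data - data.mean()) ** 2)
        return 1.0 - ss_res / ss_tot

    def free_energy(self, q: PosteriorDensity | None = None) -> float:
        """Free energy of an arbitrary Gaussian q (the fitted posterior by
        default) for the fitted data, at the fitted error precision."""
        self._check_fitted()
        q = self.posterior_ if q is None else q
        g = self.forward_(q.mean[None, :])[0]
        J = fd_jacobian(self.forward_, q.mean, step=self.fd_step, f0=g)
        r = np.log(self.data_).ravel() - g
        return gaussian_free_energy(r, J, q.mean, q.cov, self.prior_, self.tau_)

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise AttributeError("this SpectralDCM instance is not fitted yet")


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def variational_laplace_fit(
    model,
    design,
    data,
    priors: PriorDensity | None = None,
    **options,
) -> tuple[PosteriorDensity, InversionTrace]:
    """Fit ``model`` to per-condition spectra; returns (posterior, trace).

    ``data`` is an array (n_conditions, n_freqs) or mapping condition ->
    spectrum on the default grid.  ``priors`` overrides the configured
    prior density."""
    est = SpectralDCM(model=model, design=design, **options)
    if priors is not None:
        model_r = resolve_model(model)
        est.fit_with_priors = priors  # stash for introspection
        m, d, forward, _ = est._build()
        X = est._validate_data(data, forward)
        posterior, trace = variational_laplace(
            forward, np.log(X).ravel(), priors,
            noise_precision=est.noise_precision, max_iter=est.max_iter,
            tol=est.tol, fd_step=est.fd_step, lm_lambda0=est.lm_lambda0,
        )
        return posterior, trace
    est.fit(data)
    return est.posterior_, est.trace_


def posterior_predictive(model, design, posterior: PosteriorDensity,
                         freqs=None, data=None):
    """Forward prediction at the posterior mean; attaches log-residuals
    when data are supplied.  Returns (predictions, residuals)."""
    model = resolve_model(model)
    forward = SpectralForwardOperator(model, design, freqs=freqs)
    psd = forward.psd(posterior.mean)
    preds = {
        cond: SpectralPrediction(forward.freqs, psd[i], condition=cond)
        for i, cond in enumerate(forward.design.conditions)
    }
    residuals = None
    if data is not None:
        data = np.asarray(data, dtype=float)
        if data.shape != psd.shape:
            raise GridMismatchError("data and prediction shapes differ")
        residuals = np.log(data) - np.log(psd)
    return preds, residuals


def free_energy(data, model, q: PosteriorDensity, priors: PriorDensity,
                design=None, noise_precision: float = 1.0, freqs=None) -> float:
    """Free energy of Gaussian q for per-condition spectra ``data`` under
    ``model`` with the given priors and error precision (nats)."""
    model = resolve_model(model)
    forward = SpectralForwardOperator(model, design, freqs=freqs)
    if isinstance(data, dict):
        data = np.vstack([data[c] for c in forward.design.conditions])
    data = np.asarray(data, dtype=float)
    y = np.log(data).ravel()
    g = forward(q.mean[None, :])[0]
    J = fd_jacobian(forward, q.mean, f0=g)
    return gaussian_free_energy(y - g, J, q.mean, q.cov, priors, noise_precision)
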