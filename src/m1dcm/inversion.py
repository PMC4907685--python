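"""Variational-Laplace inversion: Gaussian posteriors and free energy.

The scheme fits a (generally nonlinear) forward model g(theta) to data y
under Gaussian observation error with precision tau, and a Gaussian prior
over theta.  The posterior is approximated by a Gaussian q = N(m, S) whose
covariance takes the Laplace form S = (tau * J'J + P0)^{-1} at the current
mean (J the Jacobian of g, P0 the prior precision).  The variational free
energy

    F = n/2 log(tau/2pi) - tau/2 (||y - g(m)||^2 + tr(J'J S)) - KL(q || prior)

bounds the log model evidence; it is ascended by damped Gauss-Newton steps
on m (Levenberg-Marquardt regularisation, steps accepted only if F does
not decrease) with closed-form coordinate updates of tau when the error
precision is estimated rather than fixed.  On a linear-Gaussian problem
the scheme is exact: the fixed point is the conjugate posterior and F
equals the log evidence there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import ParameterError, StabilityError

__all__ = [
    "PriorDensity",
    "PosteriorDensity",
    "InversionTrace",
    "gaussian_free_energy",
    "fd_jacobian",
    "variational_laplace",
]


@dataclass
class PriorDensity:
    """Gaussian density over the packed parameter vector."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ParameterError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ParameterError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) < -1e-10):
            raise ParameterError("covariance must be positive semidefinite")

    @property
    def size(self) -> int:
        return self.mean.size

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


class PosteriorDensity(PriorDensity):
    """Gaussian posterior (same structure as the prior)."""


@dataclass
class InversionTrace:
    """Free-energy history of accepted steps and convergence status."""

    free_energy_per_iteration: list[float] = field(default_factory=list)
    converged: bool = False
    n_iterations: int = 0
    n_rejected: int = 0
    tau: float = np.nan

    @property
    def final_free_energy(self) -> float:
        return self.free_energy_per_iteration[-1]


def _kl_gaussians(m, S, m0, S0_inv, logdet_S0) -> float:
    d = m - m0
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        return np.inf
    return 0.5 * (
        np.sum(S0_inv * S) + d @ S0_inv @ d - m.size + logdet_S0 - logdet_S
    )


def gaussian_free_energy(
    residual: np.ndarray,
    jacobian: np.ndarray,
    q_mean: np.ndarray,
    q_cov: np.ndarray,
    prior: PriorDensity,
    tau: float,
) -> float:
    """Variational free energy of q = N(q_mean, q_cov) for the linearised
    likelihood with error precision ``tau``.  When q equals the prior the
    KL term vanishes and F reduces to the expected log-likelihood."""
    n = residual.size
    M = jacobian.T @ jacobian
    expected_sse = residual @ residual + np.sum(M * q_cov)
    P0 = np.linalg.inv(prior.cov)
    _, logdet_S0 = np.linalg.slogdet(prior.cov)
    kl = _kl_gaussians(q_mean, q_cov, prior.mean, P0, logdet_S0)
    return (
        -0.5 * n * np.log(2.0 * np.pi) + 0.5 * n * np.log(tau)
        - 0.5 * tau * expected_sse - kl
    )


def fd_jacobian(
    forward,
    theta: np.ndarray,
    step: float = 1e-4,
    f0: np.ndarray | None = None,
) -> np.ndarray:
    """Central finite-difference Jacobian, shape (n_out, n_params).

    The forward map is called once on a (2p, p) batch of perturbed
    vectors.  Columns where a perturbed evaluation is non-finite (e.g. an
    unstable proposal) fall back to one-sided differences, or zero if both
    sides fail."""
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    probes = np.repeat(theta[None, :], 2 * p, axis=0)
    idx = np.arange(p)
    probes[2 * idx, idx] += step
    probes[2 * idx + 1, idx] -= step
    out = np.asarray(forward(probes))
    fp, fm = out[2 * idx], out[2 * idx + 1]
    J = (fp - fm).T / (2.0 * step)

    bad = ~np.isfinite(J).all(axis=0)
    if np.any(bad):
        if f0 is None:
            f0 = np.asarray(forward(theta[None, :]))[0]
        for j in np.flatnonzero(bad):
            if np.isfinite(fp[j]).all():
                J[:, j] = (fp[j] - f0) / step
            elif np.isfinite(fm[j]).all():
                J[:, j] = (f0 - fm[j]) / step
            else:
                J[:, j] = 0.0
    return J


def _tau_and_cov(M, P0, sse_mean, n, tau_fixed, tau_bounds=(1e-8, 1e8)):
    """Coordinate-ascent fixed point of (tau, S) given J'J and the squared
    residual at the mean.  Returns (tau, S, expected_sse)."""
    tau = tau_fixed if tau_fixed is not None else n / max(sse_mean, 1e-12)
    S = None
    for _ in range(32):
        H = tau * M + P0
        S = np.linalg.inv(H)
        S = 0.5 * (S + S.T)
        expected_sse = sse_mean + np.sum(M * S)
        if tau_fixed is not None:
            return tau, S, expected_sse
        tau_new = float(np.clip(n / expected_sse, *tau_bounds))
        if abs(np.log(tau_new / tau)) < 1e-10:
            tau = tau_new
            break
        tau = tau_new
    H = tau * M + P0
    S = np.linalg.inv(H)
    S = 0.5 * (S + S.T)
    return tau, S, sse_mean + np.sum(M * S)


def variational_laplace(
    forward,
    y: np.ndarray,
    prior: PriorDensity,
    noise_precision: float | None = None,
    max_iter: int = 128,
    tol: float = 1e-2,
    fd_step: float = 1e-4,
    lm_lambda0: float = 1e-3,
    max_rejections: int = 8,
) -> tuple[PosteriorDensity, InversionTrace]:
    """Fit ``forward`` to ``y`` by free-energy ascent.

    ``forward`` must accept a (batch, p) array and return (batch, n_out);
    non-finite outputs mark inadmissible (unstable) parameter vectors.
    Accepted-step free energies are non-decreasing by construction; a step
    that would lower F is rejected and the Levenberg-Marquardt damping
    increased.  Returns the Gaussian posterior and the trace.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    m = prior.mean.copy()
    P0 = np.linalg.inv(prior.cov)
    _, logdet_S0 = np.linalg.slogdet(prior.cov)

    def forward1(theta):
        return np.asarray(forward(theta[None, :]))[0]

    g = forward1(m)
    if not np.isfinite(g).all():
        raise StabilityError(
            "forward model is inadmissible (unstable) at the prior mean"
        )

    def point_quantities(m_cur, g_cur):
        J = fd_jacobian(forward, m_cur, step=fd_step, f0=g_cur)
        r = y - g_cur
        M = J.T @ J
        tau, S, expected_sse = _tau_and_cov(M, P0, r @ r, n, noise_precision)
        kl = _kl_gaussians(m_cur, S, prior.mean, P0, logdet_S0)
        F = (
            -0.5 * n * np.log(2.0 * np.pi) + 0.5 * n * np.log(tau)
            - 0.5 * tau * expected_sse - kl
        )
        return J, r, M, tau, S, F

    J, r, M, tau, S, F = point_quantities(m, g)
    trace = InversionTrace(free_energy_per_iteration=[float(F)], tau=tau)
    lam = lm_lambda0

    for iteration in range(max_iter):
        accepted = False
        for _ in range(max_rejections):
            Hgn = tau * M + P0
            H_damp = Hgn + lam * np.diag(np.diag(Hgn))
            grad = tau * (J.T @ r) - P0 @ (m - prior.mean)
            try:
                delta = scipy.linalg.solve(H_damp, grad, assume_a="pos")
            except np.linalg.LinAlgError:
                lam = min(lam * 8.0, 1e8)
                trace.n_rejected += 1
                continue
            m_new = m + delta
            g_new = forward1(m_new)
            if not np.isfinite(g_new).all():
                lam = min(lam * 8.0, 1e8)
                trace.n_rejected += 1
                continue
            J_new, r_new, M_new, tau_new, S_new, F_new = point_quantities(
                m_new, g_new
            )
            if F_new >= F - 1e-9:
                accepted = True
                break
            lam = min(lam * 8.0, 1e8)
            trace.n_rejected += 1

        if not accepted:
            break
        improvement = F_new - F
        m, g, J, r, M, tau, S, F = m_new, g_new, J_new, r_new, M_new, tau_new, S_new, F_new
        trace.free_energy_per_iteration.append(float(F))
        trace.n_iterations = iteration + 1
        lam = max(lam * 0.3, 1e-8)
        if improvement < tol:
            trace.converged = True
            break

    trace.tau = float(tau)
    posterior = PosteriorDensity(mean=m, cov=S)
    return posterior, trace
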