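"""Free-energy model comparison and group-level parameter statistics.

Model comparison is fixed-effects: per-subject free energies are summed
per model (all subjects assumed to share one architecture), differences in
summed free energy are log Bayes factors, and posterior model
probabilities follow from a softmax under a uniform model prior.  The
conventional evidence categories are weak (BF < 3), positive (3 <= BF <
20), strong (20 <= BF < 150) and very strong (BF >= 150); a free-energy
difference of 3 nats corresponds to a Bayes factor of about 20:1.

Group statistics are classical: per-parameter one-sample t-tests across
subjects with Benjamini-Hochberg false-discovery-rate correction, plus
trend flags for uncorrected 0.05 < p < 0.10.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import IncompleteGridError, ParameterError

__all__ = [
    "bayes_factor",
    "evidence_category",
    "compare_models",
    "group_ttest",
    "bh_fdr",
]

#: Bayes-factor thresholds of the conventional evidence scale.
EVIDENCE_THRESHOLDS = {"positive": 3.0, "strong": 20.0, "very strong": 150.0}


def bayes_factor(delta_F: float) -> float:
    """Bayes factor implied by a free-energy (log evidence) difference:
    exp(delta_F).  A difference of 3 nats is about 20:1."""
    return float(np.exp(delta_F))


def evidence_category(bf: float) -> str:
    """Conventional label of a Bayes factor: weak / positive / strong /
    very strong (thresholds 3, 20, 150)."""
    if bf >= EVIDENCE_THRESHOLDS["very strong"]:
        return "very strong"
    if bf >= EVIDENCE_THRESHOLDS["strong"]:
        return "strong"
    if bf >= EVIDENCE_THRESHOLDS["positive"]:
        return "positive"
    return "weak"


def compare_models(free_energies, model_names=None, subject_ids=None) -> pd.DataFrame:
    """Fixed-effects comparison of a subjects-by-models free-energy grid.

    Parameters
    ----------
    free_energies : DataFrame (subjects x models) or 2-D array
        Per-subject free energy of each model; no missing cells allowed.

    Returns
    -------
    DataFrame indexed by model with columns ``total_F``, ``relative_logev``
    (vs the best model, 0 for the best), ``bayes_factor_vs_best`` (evidence
    for the best model over this one), ``posterior_prob`` (softmax, uniform
    model prior) and ``evidence_category`` of the best-vs-this comparison.
    """
    if isinstance(free_energies, pd.DataFrame):
        df = free_energies
    else:
        F = np.asarray(free_energies, dtype=float)
        if F.ndim == 1:
            F = F[None, :]
        df = pd.DataFrame(
            F,
            columns=model_names
            or [f"model_{i + 1}" for i in range(F.shape[1])],
            index=subject_ids or range(F.shape[0]),
        )
    if df.isna().any().any():
        missing = [(str(i), str(c)) for i, c in zip(*np.where(df.isna().values))]
        raise IncompleteGridError(
            f"free-energy grid has missing cells (subject, model): {missing}"
        )
    total = df.sum(axis=0)
    rel = total - total.max()
    with np.errstate(over="ignore"):
        bf_best = np.exp(-rel)  # evidence for the best model over each model
    stable = rel - rel.max()
    post = np.exp(stable) / np.exp(stable).sum()
    out = pd.DataFrame(
        {
            "total_F": total,
            "relative_logev": rel,
            "bayes_factor_vs_best": bf_best,
            "posterior_prob": post,
            "evidence_category": [evidence_category(b) for b in bf_best],
        }
    )
    return out.sort_values("relative_logev", ascending=False)


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level ``q``: sort the
    p-values, find the largest rank i with p(i) <= i*q/m, reject all
    smaller ranks."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ParameterError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def group_ttest(
    estimates,
    parameter_names=None,
    q: float = 0.05,
    trend_band: tuple[float, float] = (0.05, 0.10),
) -> pd.DataFrame:
    """Per-parameter two-tailed one-sample t-tests across subjects.

    ``estimates`` is (n_subjects, n_parameters); requires >= 3 subjects.
    Zero-variance columns get p = 0 if their mean is nonzero else 1 (a
    documented convention, with a warning).  Significance flags follow
    BH-FDR at level ``q``; trends are uncorrected ``trend_band`` p-values.
    """
    E = np.asarray(
        estimates.values if isinstance(estimates, pd.DataFrame) else estimates,
        dtype=float,
    )
    if E.ndim == 1:
        E = E[:, None]
    if E.shape[0] < 3:
        raise ParameterError("group t-tests require at least 3 subjects")
    if not np.isfinite(E).all():
        raise ParameterError("estimates must be finite")
    if parameter_names is None:
        parameter_names = (
            list(estimates.columns) if isinstance(estimates, pd.DataFrame)
            else [f"param_{j}" for j in range(E.shape[1])]
        )

    mean = E.mean(axis=0)
    sd = E.std(axis=0, ddof=1)
    n = E.shape[0]
    t = np.empty(E.shape[1])
    p = np.empty(E.shape[1])
    zero_var = sd == 0
    if np.any(zero_var):
        warnings.warn(
            "zero-variance parameter column(s); p set to 0 (mean != 0) or 1",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 1)
    t[zero_var & (mean != 0)] = np.inf * np.sign(mean[zero_var & (mean != 0)])
    p[zero_var] = np.where(mean[zero_var] != 0, 0.0, 1.0)

    significant = bh_fdr(p, q=q)
    trend = (~significant) & (p > trend_band[0]) & (p < trend_band[1])
    return pd.DataFrame(
        {
            "mean": mean,
            "t": t,
            "p": p,
            "significant": significant,
            "trend": trend,
        },
        index=parameter_names,
    )
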