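r"""Dysregulated-gene ("outlier") calls from betweenness differences.

For each gene the |B_normal - B_tumor| values across the cohort are
approximately distributed as a normal truncated at zero (the difference is
an absolute value).  We fit the location/scale (mu, sigma) of that
truncated normal by maximum likelihood and flag gene i as an outlier in
patient p when its difference strictly exceeds mu + t * sigma.  Genes
observed in too few patients, or with zero variance, are unfittable and
never flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("betweennet")

DEFAULT_T = 0.5
DEFAULT_MIN_OBS = 5

#: optimizer tolerance for the truncated-normal MLE
_FIT_TOL = 1e-8


@dataclass(frozen=True)
class GeneFit:
    """Fitted truncated-normal parameters for one gene."""

    mu: float
    sigma: float
    n_obs: int


@dataclass
class OutlierCalls:
    """Per-patient outlier gene sets plus the per-gene fits behind them."""

    outliers: dict[str, frozenset[str]] = field(default_factory=dict)
    fits: dict[str, GeneFit] = field(default_factory=dict)
    t: float = DEFAULT_T

    def outlier_genes(self, patient: str) -> frozenset[str]:
        return self.outliers.get(patient, frozenset())

    @property
    def total_occurrences(self) -> int:
        return sum(len(s) for s in self.outliers.values())


def fit_truncated_normal(
    values, min_obs: int = DEFAULT_MIN_OBS
) -> tuple[float, float] | None:
    """MLE of (mu, sigma) for a normal truncated to [0, inf).

    The likelihood uses the zero-truncated density
    ``phi((x - mu)/sigma) / (sigma * Phi(mu/sigma))``; optimization starts
    at the sample mean and standard deviation and is bounded, so the fit is
    deterministic.  Returns None (the "unfittable" sentinel) for fewer than
    ``min_obs`` values or zero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < min_obs:
        return None
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("values must be finite and >= 0")
    m0 = float(x.mean())
    s0 = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if s0 == 0.0:
        return None

    def nll(params: np.ndarray) -> float:
        mu, sigma = params
        z = (x - mu) / sigma
        # log normalizer: P(X > 0) = Phi(mu / sigma)
        return float(
            x.size * np.log(sigma)
            + 0.5 * np.sum(z * z)
            + 0.5 * x.size * np.log(2 * np.pi)
            + x.size * stats.norm.logsf(-mu / sigma)
        )

    scale = max(abs(m0), s0)
    res = optimize.minimize(
        nll,
        x0=np.array([m0, s0]),
        method="L-BFGS-B",
        bounds=[(-1e3 * scale, 1e3 * scale), (1e-8 * scale, 1e3 * scale)],
        options={"ftol": _FIT_TOL, "gtol": _FIT_TOL},
    )
    mu, sigma = float(res.x[0]), float(res.x[1])
    if not (np.isfinite(mu) and np.isfinite(sigma) and sigma > 0):
        return None
    return mu, sigma


def call_outliers(
    table: pd.DataFrame,
    t: float = DEFAULT_T,
    min_obs: int = DEFAULT_MIN_OBS,
    scope: str = "per-gene",
) -> OutlierCalls:
    """Flag per-patient outliers from a betweenness-difference table.

    Parameters
    ----------
    table:
        DataFrame with columns ``patient, gene, b_diff`` (rows with NaN
        b_diff -- gene absent from one of the patient's networks -- are
        ignored; such a gene can never be an outlier in that patient).
    t:
        Threshold in fitted standard deviations above the fitted mean
        (strict inequality).
    min_obs:
        Minimum number of patients with a defined difference for a gene to
        be fittable.
    scope:
        ``"per-gene"`` fits one truncated normal per gene across patients
        (default); ``"global"`` fits a single pooled distribution and
        applies the same threshold to every gene.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if scope not in ("per-gene", "global"):
        raise ValueError(f"scope must be 'per-gene' or 'global', got {scope!r}")
    calls = OutlierCalls(t=t)
    defined = table.dropna(subset=["b_diff"]) if len(table) else table
    if len(defined) == 0:
        logger.warning("call_outliers: empty betweenness table, no calls")
        return calls
    calls.outliers = {p: set() for p in defined["patient"].unique()}

    if scope == "global":
        fit = fit_truncated_normal(defined["b_diff"].to_numpy(), min_obs=min_obs)
        if fit is None:
            logger.warning("call_outliers: pooled distribution unfittable")
        else:
            mu, sigma = fit
            cutoff = mu + t * sigma
            pooled = GeneFit(mu=mu, sigma=sigma, n_obs=len(defined))
            for gene, sub in defined.groupby("gene", sort=True):
                calls.fits[gene] = pooled
                for patient, value in zip(sub["patient"], sub["b_diff"]):
                    if value > cutoff:
                        calls.outliers[patient].add(gene)
    else:
        for gene, sub in defined.groupby("gene", sort=True):
            fit = fit_truncated_normal(sub["b_diff"].to_numpy(), min_obs=min_obs)
            if fit is None:
                continue
            mu, sigma = fit
            calls.fits[gene] = GeneFit(mu=mu, sigma=sigma, n_obs=len(sub))
            cutoff = mu + t * sigma
            for patient, value in zip(sub["patient"], sub["b_diff"]):
                if value > cutoff:
                    calls.outliers[patient].add(gene)

    calls.outliers = {p: frozenset(s) for p, s in calls.outliers.items()}
    return calls
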