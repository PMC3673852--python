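"""Empirical Bayes variance moderation and multiple testing.

Gene variances are modeled with a scaled inverse chi-square prior
sigma_g^2 ~ s0^2 * d0 / chi2_{d0}.  The hyperparameters are estimated by
moment matching on the log residual variances; the posterior variance

    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)

shrinks each gene toward the prior, and the moderated t statistic
t~ = beta / (s~ sqrt(v_j)) follows an exact t distribution on d0 + d
degrees of freedom under the null, which is what gives the method its exact
small-sample theory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .linear_model import LinearFitSet

__all__ = [
    "VariancePrior",
    "EBayesResult",
    "fit_variance_prior",
    "squeeze_var",
    "moderated_t",
    "bh_adjust",
    "storey_pi0",
    "top_table",
]

logger = logging.getLogger(__name__)

#: estimated prior df above this are reported as infinite
D0_INF_CUTOFF = 1e6


@dataclass
class VariancePrior:
    """Scaled inverse chi-square prior for gene variances; d0 may be inf."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("prior degrees of freedom must be positive")
        if not (self.s0_2 > 0):
            raise ValueError("prior variance must be positive")


@dataclass
class EBayesResult:
    """Moderated statistics for every gene and contrast."""

    s_tilde_2: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_total: float
    q: np.ndarray
    prior: VariancePrior
    coef_names: list
    beta: np.ndarray
    probes: list | None = None
    pi0: float | None = field(default=None)


def _trigamma(x: float) -> float:
    return float(polygamma(1, x))


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is positive, strictly decreasing and convex, so Newton on the
    reciprocal scale converges monotonically from the asymptotic start
    x ~ 1/y + 1/2.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        # Newton step: f(x) = trigamma(x) - y, f'(x) = psi''(x) < 0
        deriv = float(polygamma(2, x))
        step = (tri - y) / deriv
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * (1.0 + abs(x)):
            return x_new
        x = x_new
    return x


def fit_variance_prior(sigma2: np.ndarray, d: float) -> VariancePrior:
    """Moment-match (d0, s0^2) from the gene residual variances.

    Works on e_g = log s_g^2 - psi(d/2) + log(d/2), whose mean is
    log s0^2 + psi(d0/2) - log(d0/2) and whose excess variance over the
    sampling term trigamma(d/2) is trigamma(d0/2).  The trigamma equation is
    solved by Newton root-finding; zero or negative excess dispersion yields
    d0 = infinity (all genes share one variance).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if d <= 0:
        raise ValueError("residual df must be positive")
    ok = sigma2 > 0
    if not ok.all():
        n_bad = int((~ok).sum())
        if not ok.any():
            raise ValueError("all gene variances are zero")
        logger.warning("excluding %d zero variances from prior estimation", n_bad)
        sigma2 = sigma2[ok]
    G = len(sigma2)
    if G < 10:
        raise ValueError("need at least 10 genes to estimate the variance prior")
    e = np.log(sigma2) - digamma(d / 2.0) + math.log(d / 2.0)
    excess = float(np.var(e, ddof=0) * G / (G - 1)) - _trigamma(d / 2.0)
    if excess <= 0:
        d0 = math.inf
        s0_2 = math.exp(float(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        if d0 > D0_INF_CUTOFF:
            d0 = math.inf
            s0_2 = math.exp(float(np.mean(e)))
        else:
            s0_2 = math.exp(
                float(np.mean(e)) + digamma(d0 / 2.0) - math.log(d0 / 2.0)
            )
    return VariancePrior(d0=d0, s0_2=s0_2)


def squeeze_var(sigma2: np.ndarray, d: float, prior: VariancePrior) -> np.ndarray:
    """Posterior variances (d0 s0^2 + d s_g^2) / (d0 + d), with d0=inf -> s0^2."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if math.isinf(prior.d0):
        return np.full_like(sigma2, prior.s0_2)
    return (prior.d0 * prior.s0_2 + d * sigma2) / (prior.d0 + d)


def moderated_t(fit: LinearFitSet, prior: VariancePrior | None = None) -> EBayesResult:
    """Moderated t statistics, p-values and BH-adjusted q-values for a fit.

    If ``prior`` is omitted it is estimated from the fit's own variances.
    With infinite prior df the statistics are referred to the normal
    distribution (the t limit).
    """
    if prior is None:
        prior = fit_variance_prior(fit.sigma**2, fit.df_residual)
    s_tilde_2 = squeeze_var(fit.sigma**2, fit.df_residual, prior)
    v = fit.stdev_unscaled
    if np.any(v <= 0):
        raise RuntimeError("non-positive unscaled standard deviation")
    t = fit.beta / (np.sqrt(s_tilde_2)[:, None] * v[None, :])
    df_total = prior.d0 + fit.df_residual
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = np.column_stack([bh_adjust(p[:, j]) for j in range(p.shape[1])])
    return EBayesResult(
        s_tilde_2=s_tilde_2,
        t=t,
        p=p,
        df_total=df_total,
        q=q,
        prior=prior,
        coef_names=list(fit.coef_names),
        beta=fit.beta,
        probes=fit.probes,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone and capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adj, 1.0)
    return q


def storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Fixed-lambda estimate of the proportion of true nulls.

    pi0-hat = #{p > lambda} / (m (1 - lambda)), clamped to (0, 1].  Null
    p-values are uniform so the tail count above lambda, inflated by
    1/(1-lambda), estimates the null fraction.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    pi0 = np.sum(p > lam) / (m * (1.0 - lam))
    if pi0 <= 0.0:
        logger.warning("no p-values above lambda=%.2f; pi0 clamped to 1/m", lam)
        pi0 = 1.0 / m
    return float(min(pi0, 1.0))


def top_table(
    result: EBayesResult,
    coef: str | int = 0,
    n: int | None = None,
    sort_by: str = "p",
) -> pd.DataFrame:
    """Ranked per-gene table for one contrast.

    Columns: probe, logFC, t, p, q; sorted by ``sort_by`` (``p`` ascending by
    default, ``t`` by absolute value descending, ``logFC`` by absolute value
    descending); ties broken by probe identifier.
    """
    if isinstance(coef, str):
        if coef not in result.coef_names:
            raise KeyError(f"unknown coefficient {coef!r}; have {result.coef_names}")
        j = result.coef_names.index(coef)
    else:
        j = int(coef)
        if not 0 <= j < len(result.coef_names):
            raise KeyError(f"coefficient index {j} out of range")
    G = result.p.shape[0]
    probes = result.probes if result.probes is not None else [str(i) for i in range(G)]
    df = pd.DataFrame(
        {
            "probe": probes,
            "logFC": result.beta[:, j],
            "t": result.t[:, j],
            "p": result.p[:, j],
            "q": result.q[:, j],
        }
    )
    if sort_by == "p":
        df = df.sort_values(["p", "probe"], kind="stable")
    elif sort_by in ("t", "logFC"):
        df = df.reindex(
            df.assign(_key=-df[sort_by].abs())
            .sort_values(["_key", "probe"], kind="stable")
            .index
        )
    else:
        raise ValueError(f"unknown sort key {sort_by!r}")
    if n is not None:
        df = df.head(n)
    return df.reset_index(drop=True)
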