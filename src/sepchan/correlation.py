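"""Pooling per-gene variance ratios into a common intra-spot correlation.

Because var(M) = 2*sigma^2*(1-rho) and var(A) = sigma^2*(1+rho)/2, the
ratio 4*sigma2_A/sigma2_M equals (1+rho)/(1-rho) and so
tau_g = 0.5*log(4*sigma2_A/sigma2_M) = atanh(rho_g).  The per-gene REML
estimates give noisy tau_g-hat values whose bias is a known function of the
fractional degrees of freedom; after bias correction a trimmed mean across
genes yields a highly precise estimate of the common correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma
from scipy.stats import trim_mean

__all__ = [
    "CorrelationEstimate",
    "tau_gene",
    "tau_bias",
    "estimate_common_correlation",
    "pooled_tau",
]

logger = logging.getLogger(__name__)

#: downstream rescaling divides by sqrt(2(1-rho)) and sqrt((1+rho)/2), so the
#: pooled estimate is clamped away from +-1 to keep both factors finite
RHO_CLAMP = 0.99


@dataclass
class CorrelationEstimate:
    """Pooled intra-spot correlation with the per-gene statistics behind it."""

    rho: float
    tau: float
    tau_g: np.ndarray = field(repr=False)
    trim: float
    genes_used: int

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (-1, 1)")


def tau_gene(fit) -> float:
    """Fisher-z scale variance-ratio statistic 0.5*log(4*s2_A/s2_M) for one gene."""
    if not fit.usable:
        raise ValueError("tau_gene is undefined for an unusable fit")
    return 0.5 * math.log(4.0 * fit.sigma2_A / fit.sigma2_M)


def tau_bias(d_M: float, d_A: float) -> float:
    """Finite-df bias of tau_gene, from the chi-square log-moments.

    With sigma2_s-hat ~ sigma2_s * chi2_{d_s}/d_s, E log sigma2_s-hat exceeds
    log sigma2_s by psi(d_s/2) - log(d_s/2), so

        bias = 0.5 * [(psi(d_A/2) - log(d_A/2)) - (psi(d_M/2) - log(d_M/2))]

    and tau_gene - bias is approximately unbiased for atanh(rho).  Vanishes
    when d_M = d_A.
    """
    if d_M <= 0 or d_A <= 0:
        raise ValueError("degrees of freedom must be positive")
    g = lambda d: digamma(d / 2.0) - math.log(d / 2.0)
    return 0.5 * (g(d_A) - g(d_M))


def _usable_taus(fits) -> np.ndarray:
    vals = [
        tau_gene(f) - tau_bias(f.d_M, f.d_A) for f in fits if f.usable
    ]
    return np.asarray(vals, dtype=float)


def estimate_common_correlation(fits, trim: float = 0.15) -> CorrelationEstimate:
    """Trimmed mean of bias-corrected per-gene tau statistics.

    Parameters
    ----------
    fits : sequence of GeneHetFit
        Per-gene REML results; unusable fits are skipped.
    trim : float
        Fraction of genes removed from each tail of the sorted corrected
        taus before averaging (default 0.15).
    """
    taus = _usable_taus(fits)
    if len(taus) < 10:
        raise ValueError(
            f"only {len(taus)} usable gene fits; need at least 10 to pool"
        )
    tau = float(trim_mean(taus, trim))
    rho = math.tanh(tau)
    if abs(rho) > RHO_CLAMP:
        logger.warning("pooled rho %.4f clamped to +-%.2f", rho, RHO_CLAMP)
        rho = math.copysign(RHO_CLAMP, rho)
        tau = math.atanh(rho)
    return CorrelationEstimate(
        rho=rho, tau=tau, tau_g=taus, trim=trim, genes_used=len(taus)
    )


def pooled_tau(fits) -> float:
    """Non-robust pooled estimator 0.5*log(4*sum(s2_A)/sum(s2_M)).

    The theoretically efficient estimator under gene-wise independence,
    exposed for diagnostics; it is sensitive to extreme-variance genes, which
    is why the trimmed mean is the default.  No bias correction is applied.
    """
    usable = [f for f in fits if f.usable]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable fits")
    sA = sum(f.sigma2_A for f in usable)
    sM = sum(f.sigma2_M for f in usable)
    return 0.5 * math.log(4.0 * sA / sM)
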