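"""Closed-form design-efficiency calculators.

All results follow from the stratum variances var(M) = 2*sigma^2*(1-rho)
and var(A) = sigma^2*(1+rho)/2.  For a common reference design the A-values
add a fraction (1-rho)/(1+rho) of the M-value Fisher information to a
treatment contrast; log-ratio analysis of a common reference design beats a
single-channel experiment iff rho > 1/2; and in an unconnected design the
cross-island contrast is estimable only from the separate-channel analysis,
with relative efficiency 1-rho versus a within-island contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DesignEfficiencyReport",
    "ma_variances",
    "info_gain_A_vs_M",
    "common_reference_eval",
    "unconnected_eval",
    "paired_eval",
]


@dataclass
class DesignEfficiencyReport:
    """Variances and efficiency ratios for one design scenario."""

    design: str
    n: int
    sigma2: float
    rho: float
    variances: dict = field(default_factory=dict)
    ratios: dict = field(default_factory=dict)
    break_even_rho: float | None = None

    def as_dict(self) -> dict:
        d = {
            "design": self.design,
            "n": self.n,
            "sigma2": self.sigma2,
            "rho": self.rho,
            "variances": dict(self.variances),
            "ratios": dict(self.ratios),
        }
        if self.break_even_rho is not None:
            d["break_even_rho"] = self.break_even_rho
        return d


def _check(sigma2: float, rho: float) -> None:
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")


def ma_variances(sigma2: float, rho: float):
    """(var(M), var(A)) = (2*sigma2*(1-rho), sigma2*(1+rho)/2)."""
    _check(sigma2, rho)
    return 2.0 * sigma2 * (1.0 - rho), sigma2 * (1.0 + rho) / 2.0


def info_gain_A_vs_M(rho: float) -> float:
    """Extra Fisher information from A-values relative to M-values, (1-rho)/(1+rho).

    This is the fractional gain of the separate-channel over the log-ratio
    analysis for a common reference treatment contrast: 1 at rho = 0 (the
    information doubles) and 0 as rho -> 1 (the log-ratios are fully
    efficient).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    return (1.0 - rho) / (1.0 + rho)


def common_reference_eval(n: int, sigma2: float, rho: float) -> DesignEfficiencyReport:
    """Variances for the two-treatment common reference design with n arrays.

    n/2 arrays hybridize treatment B against the reference, n/2 treatment C.
    The B-C contrast has var(gamma_M) = 8*sigma2*(1-rho)/n from M-values and
    var(gamma_A) = 8*sigma2*(1+rho)/n from A-values; a one-channel design of
    the same size would give 4*sigma2/n, so the log-ratio analysis wins iff
    rho > 1/2.  The combined (separate-channel) variance is the
    inverse-information sum.
    """
    if n <= 0 or n % 2:
        raise ValueError("n must be a positive even number of arrays")
    _check(sigma2, rho)
    var_M = 8.0 * sigma2 * (1.0 - rho) / n
    var_A = 8.0 * sigma2 * (1.0 + rho) / n
    var_one_channel = 4.0 * sigma2 / n
    var_combined = 1.0 / (1.0 / var_M + 1.0 / var_A)
    return DesignEfficiencyReport(
        design="common_reference",
        n=n,
        sigma2=sigma2,
        rho=rho,
        variances={
            "gamma_M": var_M,
            "gamma_A": var_A,
            "one_channel": var_one_channel,
            "combined": var_combined,
        },
        ratios={
            "info_gain_A_vs_M": info_gain_A_vs_M(rho),
            "log_ratio_vs_one_channel": var_one_channel / var_M,
        },
        break_even_rho=0.5,
    )


def unconnected_eval(n: int, sigma2: float, rho: float) -> DesignEfficiencyReport:
    """Variances for the two-island design (B/C on n/2 arrays, D/E on n/2).

    The within-island contrast gamma = beta_B - beta_C has variance
    4*sigma2*(1-rho)/n; the cross-island contrast delta = beta_B - beta_D is
    estimable only through the A-values and has variance 4*sigma2/n, so its
    relative efficiency versus the direct contrast is 1-rho.
    """
    if n <= 0 or n % 2:
        raise ValueError("n must be a positive even number of arrays")
    _check(sigma2, rho)
    var_within = 4.0 * sigma2 * (1.0 - rho) / n
    var_cross = 4.0 * sigma2 / n
    return DesignEfficiencyReport(
        design="unconnected",
        n=n,
        sigma2=sigma2,
        rho=rho,
        variances={"gamma_within_island": var_within, "delta_cross_island": var_cross},
        ratios={"relative_efficiency_delta_vs_gamma": 1.0 - rho},
    )


def paired_eval(n: int, sigma2: float, rho: float) -> DesignEfficiencyReport:
    """Paired two-treatment design: the A-values carry no contrast information.

    Both analyses estimate the treatment contrast as the mean M-value with
    variance 2*sigma2*(1-rho)/n; the information gain from A is exactly 0.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    _check(sigma2, rho)
    var_M = 2.0 * sigma2 * (1.0 - rho) / n
    return DesignEfficiencyReport(
        design="paired",
        n=n,
        sigma2=sigma2,
        rho=rho,
        variances={"gamma_M": var_M, "combined": var_M},
        ratios={"info_gain_A_vs_M": 0.0},
    )


def atanh_identity_residual(sigma2: float, rho: float) -> float:
    """|0.5*log(4 var(A)/var(M)) - atanh(rho)|; identically 0 in exact arithmetic."""
    var_M, var_A = ma_variances(sigma2, rho)
    return abs(0.5 * math.log(4.0 * var_A / var_M) - math.atanh(rho))
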