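"""Gene-wise linear modeling on the rescaled M/A scale.

Once a common intra-spot correlation rho is fixed, dividing the M rows of
data and design by sqrt(2(1-rho)) and the A rows by sqrt((1+rho)/2) makes
every observation share the gene variance sigma_g^2.  Ordinary least squares
on the rescaled system is then exactly generalized least squares on the
original correlated channel observations, which is what lets the separate
channel analysis reuse the standard empirical Bayes machinery.

The classic log-ratio analysis is the M-only special case and is provided
for comparison; contrasts that cross unconnected islands of a design are
not estimable from M-values alone and raise an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_design import ChannelDesign, ContrastMatrix, DesignError, TargetsTable, build_channel_design
from .ma import MAData, TransformedDesign

__all__ = [
    "LinearFitSet",
    "rescale_ma",
    "fit_gene_lm",
    "contrast_fit",
    "fit_log_ratio",
]


class EstimabilityError(ValueError):
    """A contrast is not estimable from the available information."""


@dataclass
class LinearFitSet:
    """Per-gene least squares results shared across all probes of one design.

    Attributes
    ----------
    beta : ndarray (G, p)
        Coefficient (or contrast) estimates per gene.
    sigma : ndarray (G,)
        Residual standard deviations s_g.
    df_residual : float
        Residual degrees of freedom (common to all genes).
    cov_unscaled : ndarray (p, p)
        (X'X)^-1 of the fitted design; multiply by s_g^2 for covariances.
    stdev_unscaled : ndarray (p,)
        sqrt of the diagonal of cov_unscaled (the 1/sqrt of the effective
        sample size v_j per coefficient).
    """

    beta: np.ndarray
    sigma: np.ndarray
    df_residual: float
    cov_unscaled: np.ndarray
    stdev_unscaled: np.ndarray
    coef_names: list
    method: str = "separate_channel"
    probes: list | None = None
    rowspace: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.df_residual <= 0:
            raise DesignError("no residual degrees of freedom")
        if np.any(self.sigma < 0):
            raise ValueError("negative residual standard deviation")


def rescale_ma(ma: MAData, Z: TransformedDesign, rho: float):
    """Divide M and A rows of data and design by their sd factors.

    M rows are divided by sqrt(2(1-rho)), A rows by sqrt((1+rho)/2); the
    result is a homoscedastic regression with per-observation variance
    sigma_g^2.

    Returns
    -------
    z_star : ndarray (G, 2n)
    Z_star : TransformedDesign
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    n = Z.n_arrays
    sd_M = np.sqrt(2.0 * (1.0 - rho))
    sd_A = np.sqrt((1.0 + rho) / 2.0)
    row_sd = np.concatenate([np.full(n, sd_M), np.full(n, sd_A)])
    z_star = ma.z() / row_sd
    Z_star = TransformedDesign(
        Z=Z.Z / row_sd[:, None], coef_names=list(Z.coef_names), n_arrays=n
    )
    return z_star, Z_star


def fit_gene_lm(z_star: np.ndarray, Z_star: TransformedDesign, probes=None) -> LinearFitSet:
    """Ordinary least squares per gene on the rescaled system.

    beta_g = (Z*'Z*)^-1 Z*' z*_g and s_g^2 = RSS_g / (2n - p).
    """
    z_star = np.atleast_2d(np.asarray(z_star, dtype=float))
    X = Z_star.Z
    ny, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise DesignError("rescaled design is rank deficient")
    if ny <= p:
        raise DesignError("need more observations than coefficients")
    XtX = X.T @ X
    cov_unscaled = np.linalg.inv(XtX)
    beta = z_star @ X @ cov_unscaled  # (G, p)
    resid = z_star - beta @ X.T
    df = ny - p
    sigma = np.sqrt(np.sum(resid**2, axis=1) / df)
    return LinearFitSet(
        beta=beta,
        sigma=sigma,
        df_residual=df,
        cov_unscaled=cov_unscaled,
        stdev_unscaled=np.sqrt(np.diag(cov_unscaled)),
        coef_names=list(Z_star.coef_names),
        method="separate_channel",
        probes=probes,
    )


def contrast_fit(fit: LinearFitSet, contrasts: ContrastMatrix) -> LinearFitSet:
    """Re-express a fit in terms of contrasts: beta C and C'VC."""
    C = contrasts.C
    if C.shape[0] != fit.beta.shape[1]:
        raise ValueError(
            f"contrast matrix has {C.shape[0]} rows but fit has "
            f"{fit.beta.shape[1]} coefficients"
        )
    if fit.rowspace is not None:
        # log-ratio fits on disconnected designs: a contrast is estimable
        # only if it lies in the row space of the difference design
        proj = fit.rowspace @ C
        bad = [
            contrasts.names[j]
            for j in range(C.shape[1])
            if not np.allclose(proj[:, j], C[:, j], atol=1e-8)
        ]
        if bad:
            raise EstimabilityError(
                f"contrasts not estimable from log-ratios (unconnected design): {bad}"
            )
    return LinearFitSet(
        beta=fit.beta @ C,
        sigma=fit.sigma,
        df_residual=fit.df_residual,
        cov_unscaled=C.T @ fit.cov_unscaled @ C,
        stdev_unscaled=np.sqrt(np.diag(C.T @ fit.cov_unscaled @ C)),
        coef_names=list(contrasts.names),
        method=fit.method,
        probes=fit.probes,
        rowspace=fit.rowspace,
    )


def fit_log_ratio(ma: MAData, targets: TargetsTable, design: ChannelDesign | None = None) -> LinearFitSet:
    """Classic M-value analysis: per-gene OLS of M on the difference design.

    The difference design has one row per array, equal to the red channel
    row minus the green channel row of the channel design.  Its rank is
    deficient by one per connected island (only within-island comparisons
    are identifiable), so coefficients are computed by minimum-norm least
    squares and downstream contrasts are checked for estimability.
    """
    if design is None:
        design = build_channel_design(targets)
    n = design.n_arrays
    D = design.X[n:] - design.X[:n]
    rank = np.linalg.matrix_rank(D)
    if n <= rank:
        raise DesignError("log-ratio fit needs more arrays than the design rank")
    Dpinv = np.linalg.pinv(D)
    beta = ma.M @ Dpinv.T
    resid = ma.M - beta @ D.T
    df = n - rank
    sigma = np.sqrt(np.sum(resid**2, axis=1) / df)
    cov_unscaled = Dpinv @ Dpinv.T  # pseudo-inverse of D'D
    # projector onto the row space of D, for contrast estimability checks
    rowspace = Dpinv @ D
    return LinearFitSet(
        beta=beta,
        sigma=sigma,
        df_residual=df,
        cov_unscaled=cov_unscaled,
        stdev_unscaled=np.sqrt(np.diag(cov_unscaled)),
        coef_names=list(design.coef_names),
        method="log_ratio",
        probes=list(ma.probes),
        rowspace=rowspace,
    )
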