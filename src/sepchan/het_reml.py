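"""Per-gene REML for the two-stratum heteroscedastic M/A regression.

The stacked observation vector z_g = (M_g, A_g) follows E(z_g) = Z beta_g
with independent errors whose variance is sigma2_M on the first n rows and
sigma2_A on the last n.  For two variance strata the REML score equations
reduce to a fixed point: weighted least squares at the current variances,
then sigma2_s <- RSS_s / sum_{i in s}(1 - h_i) with h the leverages of the
weighted fit.  The leverage sums are the fractional effective degrees of
freedom d_M, d_A that calibrate the approximate chi-square distributions of
the variance estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ma import MAData, TransformedDesign

__all__ = ["GeneHetFit", "reml_two_strata", "fit_all_genes"]

#: default convergence tolerance on the relative change of both variances
DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 40
#: variances are clamped at this multiple of the gene's mean squared scale
VAR_FLOOR_FRAC = 1e-10
#: a stratum whose residual df falls at or below this is saturated by design
DF_FLOOR = 1e-3


@dataclass
class GeneHetFit:
    """REML result for one gene.

    ``usable`` is True when both strata carry positive effective degrees of
    freedom and neither variance hit the floor; only usable fits enter the
    correlation pooling.
    """

    sigma2_M: float
    sigma2_A: float
    d_M: float
    d_A: float
    n_iter: int
    converged: bool
    usable: bool


def _reml_batch(
    zmat: np.ndarray,
    Z: np.ndarray,
    n: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
):
    """Vectorized two-stratum REML over the rows of ``zmat`` (G x 2n).

    Returns arrays (sigma2_M, sigma2_A, d_M, d_A, n_iter, converged, usable).
    The design ``Z`` (2n x p) is shared by all genes, so the per-gene normal
    equations are rank-p combinations of two precomputed Gram matrices.
    """
    zmat = np.atleast_2d(np.asarray(zmat, dtype=float))
    G, ny = zmat.shape
    p = Z.shape[1]
    if ny != Z.shape[0] or ny != 2 * n:
        raise ValueError("z length must equal the 2n design rows")
    if ny <= p:
        raise ValueError("need more observations than coefficients (2n > rank Z)")

    ZM, ZA = Z[:n], Z[n:]
    GM = ZM.T @ ZM
    GA = ZA.T @ ZA

    # OLS start: both variances at the pooled residual mean square
    beta0, *_ = np.linalg.lstsq(Z, zmat.T, rcond=None)
    resid0 = zmat - beta0.T @ Z.T
    scale = np.mean(zmat**2, axis=1)
    floor = VAR_FLOOR_FRAC * np.maximum(scale, 1e-300)
    s2 = np.sum(resid0**2, axis=1) / (ny - p)
    s2 = np.maximum(s2, floor)
    s2M = s2.copy()
    s2A = s2.copy()

    dM = np.full(G, np.nan)
    dA = np.full(G, np.nan)
    converged = np.zeros(G, dtype=bool)
    n_iter = np.zeros(G, dtype=int)
    floored = s2 <= floor

    for it in range(1, max_iter + 1):
        wM = 1.0 / s2M
        wA = 1.0 / s2A
        # per-gene normal equations: (wM*GM + wA*GA) beta = wM ZM'zM + wA ZA'zA
        Amat = wM[:, None, None] * GM + wA[:, None, None] * GA
        bvec = wM[:, None] * (zmat[:, :n] @ ZM) + wA[:, None] * (zmat[:, n:] @ ZA)
        try:
            Ainv = np.linalg.inv(Amat)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(Amat)
        beta = np.einsum("gpq,gq->gp", Ainv, bvec)
        resid = zmat - beta @ Z.T
        # leverages of the weighted projection: h_i = w_i x_i' (X'WX)^-1 x_i
        quad = np.einsum("ip,gpq,iq->gi", Z, Ainv, Z)
        w_rows = np.concatenate(
            [np.repeat(wM[:, None], n, axis=1), np.repeat(wA[:, None], n, axis=1)],
            axis=1,
        )
        h = w_rows * quad
        dM_it = np.sum(1.0 - h[:, :n], axis=1)
        dA_it = np.sum(1.0 - h[:, n:], axis=1)
        rssM = np.sum(resid[:, :n] ** 2, axis=1)
        rssA = np.sum(resid[:, n:] ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s2M_new = np.where(dM_it > DF_FLOOR, rssM / np.maximum(dM_it, DF_FLOOR), s2M)
            s2A_new = np.where(dA_it > DF_FLOOR, rssA / np.maximum(dA_it, DF_FLOOR), s2A)
        hit_floor = (s2M_new < floor) | (s2A_new < floor)
        floored |= hit_floor
        s2M_new = np.maximum(s2M_new, floor)
        s2A_new = np.maximum(s2A_new, floor)
        rel = np.maximum(
            np.abs(s2M_new - s2M) / s2M, np.abs(s2A_new - s2A) / s2A
        )
        newly = (~converged) & (rel < tol)
        n_iter[~converged] = it
        converged |= newly
        s2M, s2A = s2M_new, s2A_new
        dM, dA = dM_it, dA_it
        if converged.all():
            break

    saturated = (dM <= DF_FLOOR) | (dA <= DF_FLOOR)
    usable = converged & ~floored & ~saturated
    return s2M, s2A, dM, dA, n_iter, converged, usable


def reml_two_strata(
    z_g: np.ndarray,
    Z: TransformedDesign,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> GeneHetFit:
    """Fit the two-stratum REML model for a single gene.

    Parameters
    ----------
    z_g : ndarray, shape (2n,)
        Stacked M then A values for the gene.
    Z : TransformedDesign
        Shared M/A-scale design (full column rank).
    """
    s2M, s2A, dM, dA, it, conv, usable = _reml_batch(
        np.asarray(z_g, dtype=float)[None, :], Z.Z, Z.n_arrays, tol, max_iter
    )
    return GeneHetFit(
        sigma2_M=float(s2M[0]),
        sigma2_A=float(s2A[0]),
        d_M=float(dM[0]),
        d_A=float(dA[0]),
        n_iter=int(it[0]),
        converged=bool(conv[0]),
        usable=bool(usable[0]),
    )


def fit_all_genes(
    ma: MAData,
    Z: TransformedDesign,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    logger=None,
) -> list:
    """Run the two-stratum REML for every probe; failures are flagged, not fatal."""
    s2M, s2A, dM, dA, it, conv, usable = _reml_batch(
        ma.z(), Z.Z, Z.n_arrays, tol, max_iter
    )
    fits = [
        GeneHetFit(
            sigma2_M=float(s2M[g]),
            sigma2_A=float(s2A[g]),
            d_M=float(dM[g]),
            d_A=float(dA[g]),
            n_iter=int(it[g]),
            converged=bool(conv[g]),
            usable=bool(usable[g]),
        )
        for g in range(len(s2M))
    ]
    if logger is not None:
        logger.info(
            "REML: %d genes, %d converged, %d usable",
            len(fits),
            int(conv.sum()),
            int(usable.sum()),
        )
    return fits
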