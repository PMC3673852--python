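"""M/A reparameterization and normalization.

For each spot the within-spot log-ratio M = red - green and the spot mean
A = (red + green)/2 are independent contrasts of the two correlated channel
intensities: var(M) = 2*sigma^2*(1-rho), var(A) = sigma^2*(1+rho)/2, and
corr(M, A) = 0.  Stacking (M_g, A_g) turns the correlated homoscedastic
channel model into an independent two-stratum heteroscedastic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_design import ChannelDesign, DesignError, TwoChannelMatrix

__all__ = [
    "MAData",
    "TransformedDesign",
    "to_ma",
    "from_ma",
    "transform_design",
    "normalize_m_loess",
    "normalize_a_quantile",
]


@dataclass
class MAData:
    """G x n matrices of M-values and A-values with identifiers."""

    probes: list
    arrays: list
    M: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.M.shape != self.A.shape:
            raise ValueError("M and A must have the same shape")

    @property
    def n_probes(self) -> int:
        return self.M.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.M.shape[1]

    def z(self) -> np.ndarray:
        """Per-gene stacked observation vectors, shape (G, 2n): M block then A block."""
        return np.hstack([self.M, self.A])


@dataclass
class TransformedDesign:
    """The 2n x p design on the (M, A) scale: Z = (C_M C_A)^T X.

    Rows 1..n form the M block, rows n+1..2n the A block.
    """

    Z: np.ndarray
    coef_names: list
    n_arrays: int

    @property
    def M_block(self) -> np.ndarray:
        return self.Z[: self.n_arrays]

    @property
    def A_block(self) -> np.ndarray:
        return self.Z[self.n_arrays :]


def to_ma(y: TwoChannelMatrix) -> MAData:
    """M = red - green, A = (red + green)/2, elementwise."""
    return MAData(
        probes=list(y.probes),
        arrays=list(y.arrays),
        M=y.red - y.green,
        A=(y.red + y.green) / 2.0,
    )


def from_ma(ma: MAData) -> TwoChannelMatrix:
    """Exact inverse of :func:`to_ma`: green = A - M/2, red = A + M/2."""
    return TwoChannelMatrix(
        probes=list(ma.probes),
        arrays=list(ma.arrays),
        green=ma.A - ma.M / 2.0,
        red=ma.A + ma.M / 2.0,
    )


def transform_design(design: ChannelDesign) -> TransformedDesign:
    """Apply the M/A contrasts to a channel design.

    With the green-then-red row convention, C_M^T = (-1, 1) (x) I_n and
    C_A^T = (1/2, 1/2) (x) I_n act blockwise: the M row for array i is
    (red row i) - (green row i) and the A row is their average.
    """
    n = design.n_arrays
    if design.X.shape[0] != 2 * n:
        raise DesignError("channel design must have 2n rows")
    Xg = design.X[:n]
    Xr = design.X[n:]
    Z = np.vstack([Xr - Xg, (Xr + Xg) / 2.0])
    return TransformedDesign(Z=Z, coef_names=list(design.coef_names), n_arrays=n)


def normalize_m_loess(
    ma: MAData, span: float = 0.3, iterations: int = 4
) -> MAData:
    """Within-array loess normalization of the M-values.

    For each array the M-values are replaced by their residuals from a robust
    local linear regression of M on A (span ``span``, ``iterations``
    robustifying reweights).  This removes intensity-dependent dye bias; the
    A-values are left untouched, so the normalized M-values agree with the
    classic log-ratio pipeline.
    """
    G, n = ma.M.shape
    if G < 10:
        raise ValueError(f"loess normalization needs >= 10 spots per array, got {G}")
    M = ma.M.copy()
    for i in range(n):
        fitted = lowess(
            ma.M[:, i],
            ma.A[:, i],
            frac=span,
            it=iterations,
            xvals=ma.A[:, i],
        )
        M[:, i] = ma.M[:, i] - fitted
    return MAData(probes=list(ma.probes), arrays=list(ma.arrays), M=M, A=ma.A.copy())


def normalize_a_quantile(ma: MAData) -> MAData:
    """Between-array quantile normalization of the A-values.

    Each array's sorted A-values are replaced by the mean of the sorted
    values across arrays; ties within an array receive the mean of the means
    at their tied sorted positions.  M-values are unchanged.
    """
    A = ma.A
    G, n = A.shape
    sort_idx = np.argsort(A, axis=0, kind="stable")
    mean_sorted = np.take_along_axis(A, sort_idx, axis=0).mean(axis=1)
    Anew = np.empty_like(A)
    for i in range(n):
        col = A[:, i]
        order = sort_idx[:, i]
        out = np.empty(G)
        out[order] = mean_sorted
        # average the target values over tied input positions
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < G:
            sums = np.bincount(inv, weights=out)
            counts = np.bincount(inv)
            out = (sums / counts)[inv]
        Anew[:, i] = out
    return MAData(probes=list(ma.probes), arrays=list(ma.arrays), M=ma.M.copy(), A=Anew)
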