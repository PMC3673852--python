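"""Independent oracle implementations used only by the tests.

These deliberately avoid the code paths they check: the REML criterion is
maximized by brute-force grid refinement, the special functions are computed
by recurrence plus asymptotic series, and BH adjustment follows the step-up
definition in O(m^2).
"""

from __future__ import annotations

import math

import numpy as np


def reml_loglik(s2M: float, s2A: float, z: np.ndarray, Z: np.ndarray, n: int) -> float:
    """Residual log-likelihood of the two-stratum heteroscedastic model."""
    w = np.concatenate([np.full(n, 1.0 / s2M), np.full(n, 1.0 / s2A)])
    ZtWZ = Z.T @ (w[:, None] * Z)
    beta = np.linalg.solve(ZtWZ, Z.T @ (w * z))
    e = z - Z @ beta
    return (
        -0.5 * (n * math.log(s2M) + n * math.log(s2A))
        - 0.5 * math.log(np.linalg.det(ZtWZ))
        - 0.5 * float(e @ (w * e))
    )


def grid_reml(z: np.ndarray, Z: np.ndarray, n: int, passes: int = 3) -> tuple:
    """Maximize the REML criterion over (log s2M, log s2A) by grid refinement.

    Starts from a wide grid centred on the pooled OLS residual mean square
    and zooms in; final resolution ~5e-4 on the log scale.
    """
    beta0, *_ = np.linalg.lstsq(Z, z, rcond=None)
    s2 = float(np.sum((z - Z @ beta0) ** 2) / (len(z) - Z.shape[1]))
    cM = cA = math.log(s2)
    half = 4.0
    best = None
    for _ in range(passes):
        gM = np.linspace(cM - half, cM + half, 41)
        gA = np.linspace(cA - half, cA + half, 41)
        best = (-np.inf, cM, cA)
        for lm in gM:
            for la in gA:
                ll = reml_loglik(math.exp(lm), math.exp(la), z, Z, n)
                if ll > best[0]:
                    best = (ll, lm, la)
        _, cM, cA = best
        step = gM[1] - gM[0]
        half = 2.0 * step
    return math.exp(cM), math.exp(cA)


def digamma_series(x: float) -> float:
    """Digamma by upward recurrence and the asymptotic series."""
    acc = 0.0
    while x < 10.0:
        acc -= 1.0 / x
        x += 1.0
    x2 = 1.0 / (x * x)
    return acc + (
        math.log(x)
        - 0.5 / x
        - x2 * (1.0 / 12.0 - x2 * (1.0 / 120.0 - x2 * (1.0 / 252.0 - x2 / 240.0)))
    )


def trigamma_series(x: float) -> float:
    """Trigamma by upward recurrence and the asymptotic series."""
    acc = 0.0
    while x < 10.0:
        acc += 1.0 / (x * x)
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    return acc + inv * (
        1.0
        + inv
        * (
            0.5
            + inv
            * (1.0 / 6.0 - inv2 * (1.0 / 30.0 - inv2 * (1.0 / 42.0 - inv2 / 30.0)))
        )
    )


def bh_stepup_bruteforce(p: np.ndarray) -> np.ndarray:
    """O(m^2) literal step-up definition of BH adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        # adjusted p_i = min over all j with p_j >= p_i of m*p_j/rank(p_j)
        vals = []
        for j in range(m):
            if p[j] >= p[i]:
                rank = int(np.sum(p <= p[j]))
                vals.append(m * p[j] / rank)
        q[i] = min(1.0, min(vals))
    return q


def gls_channels(ych: np.ndarray, X: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Generalized least squares on the 2n channel observations.

    The correlation matrix has unit diagonal and rho linking the green and
    red observation of each spot (rows i and n+i).
    """
    C = np.eye(2 * n)
    for i in range(n):
        C[i, n + i] = C[n + i, i] = rho
    Ci = np.linalg.inv(C)
    return np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ ych)
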