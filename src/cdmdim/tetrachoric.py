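"""Maximum-likelihood tetrachoric correlations for dichotomous items.

The tetrachoric correlation of two 0/1 items is the correlation of the
latent bivariate normal assumed to underlie them.  With the thresholds fixed
at the inverse-normal transforms of the observed margins, the ML estimate of
rho is the value at which the model joint probability of the (1,1) cell
equals the observed proportion; that equation is solved by Brent's method on
an in-house bivariate-normal CDF (Gauss-Legendre quadrature of the
correlation-derivative identity), which keeps the J x J matrix cheap enough
for repeated use inside factor-analytic pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = ["bvn_cdf", "tetrachoric_2x2", "tetrachoric_matrix", "TetrachoricMatrix", "smooth_correlation"]

# Gauss-Legendre nodes/weights on [0, 1], fixed order 48: accurate to ~1e-12
# for |rho| <= 0.999 in the integral below.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)
_GL_NODES = 0.5 * (_GL_NODES + 1.0)
_GL_WEIGHTS = 0.5 * _GL_WEIGHTS


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses Phi2(h,k,rho) = Phi(h)Phi(k) + integral_0^rho phi2(h,k,r) dr with
    fixed Gauss-Legendre quadrature; phi2 is the bivariate normal density.
    """
    if abs(rho) >= 1.0:
        if rho >= 1.0:
            return float(norm.cdf(min(h, k)))
        return float(max(0.0, norm.cdf(h) + norm.cdf(k) - 1.0))
    r = rho * _GL_NODES
    omr2 = 1.0 - r * r
    dens = np.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * omr2)) / (
        2.0 * np.pi * np.sqrt(omr2)
    )
    return float(norm.cdf(h) * norm.cdf(k) + rho * np.dot(_GL_WEIGHTS, dens))


def tetrachoric_2x2(table: np.ndarray, correction: float = 0.5) -> float:
    """ML tetrachoric correlation of a 2x2 contingency table.

    ``table[a, b]`` counts observations with item1 = a, item2 = b.  Zero
    cells receive a continuity correction before estimation.  Thresholds are
    fixed at the inverse-normal margins; rho solves Phi2(h, k, rho) = p11.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if t[0].sum() == 0 or t[1].sum() == 0 or t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
        raise ValueError("an item has zero variance")
    if (t == 0).any():
        t = t + correction
    n = t.sum()
    p11 = t[1, 1] / n
    p1_ = t[1].sum() / n  # P(item1 = 1)
    p_1 = t[:, 1].sum() / n  # P(item2 = 1)
    if p1_ in (0.0, 1.0) or p_1 in (0.0, 1.0):
        raise ValueError("an item has zero variance")
    # thresholds: latent value above tau codes a 1
    h = float(norm.ppf(1.0 - p1_))
    k = float(norm.ppf(1.0 - p_1))
    # p11 = P(X > h, Y > k) = 1 - Phi(h) - Phi(k) + Phi2(h, k, rho)
    def f(rho: float) -> float:
        return 1.0 - norm.cdf(h) - norm.cdf(k) + bvn_cdf(h, k, rho) - p11

    lo, hi = -0.9999, 0.9999
    flo, fhi = f(lo), f(hi)
    if flo >= 0.0:
        return -1.0 + 1e-4
    if fhi <= 0.0:
        return 1.0 - 1e-4
    return float(brentq(f, lo, hi, xtol=1e-10))


def smooth_correlation(R: np.ndarray, min_eig: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clip a symmetric matrix to PSD and rescale to unit diagonal.

    Returns the (possibly) smoothed matrix and a flag saying whether
    smoothing was applied.
    """
    R = np.asarray(R, dtype=float)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= min_eig:
        return R, False
    vals = np.maximum(vals, min_eig)
    S = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S, True


@dataclass
class TetrachoricMatrix:
    """J x J symmetric matrix of pairwise tetrachoric correlations."""

    values: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _bvn_upper_batch(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(X > h, Y > k) for arrays of thresholds/correlations (broadcast)."""
    r = rho[:, None] * _GL_NODES[None, :]
    omr2 = 1.0 - r * r
    hh = h[:, None]
    kk = k[:, None]
    dens = np.exp(-(hh * hh - 2.0 * r * hh * kk + kk * kk) / (2.0 * omr2)) / (
        2.0 * np.pi * np.sqrt(omr2)
    )
    phi2 = norm.cdf(h) * norm.cdf(k) + rho * (dens @ _GL_WEIGHTS)
    return 1.0 - norm.cdf(h) - norm.cdf(k) + phi2


def tetrachoric_matrix(responses: np.ndarray, smooth: bool = True) -> TetrachoricMatrix:
    """Pairwise two-by-two ML tetrachoric correlation matrix of 0/1 items.

    All pairs are solved simultaneously by a vectorized bisection on the
    cell-probability equation (the function is strictly increasing in rho),
    which matches the scalar :func:`tetrachoric_2x2` estimate to ~1e-9.
    Non-positive-definite results are eigenvalue-smoothed (flagged on the
    returned object) so downstream factor extraction stays well posed.
    Raises for items with a single observed category, naming the item.
    """
    X = np.asarray(responses)
    N, J = X.shape
    means = X.mean(axis=0)
    degenerate = np.flatnonzero((means == 0.0) | (means == 1.0))
    if degenerate.size:
        raise ValueError(f"items {degenerate.tolist()} have zero variance")
    ones = X.astype(np.int64)
    n11_m = (ones.T @ ones).astype(float)
    colsum = ones.sum(axis=0).astype(float)
    iu = np.triu_indices(J, k=1)
    a11 = n11_m[iu]
    a10 = colsum[iu[0]] - a11
    a01 = colsum[iu[1]] - a11
    a00 = N - a11 - a10 - a01
    cells = np.stack([a00, a01, a10, a11], axis=1)
    zero = (cells == 0).any(axis=1)
    cells[zero] += 0.5  # continuity correction for empty cells
    tot = cells.sum(axis=1)
    p11 = cells[:, 3] / tot
    p1_ = (cells[:, 2] + cells[:, 3]) / tot
    p_1 = (cells[:, 1] + cells[:, 3]) / tot
    h = norm.ppf(1.0 - p1_)
    k = norm.ppf(1.0 - p_1)
    lo = np.full(p11.shape, -0.9999)
    hi = np.full(p11.shape, 0.9999)
    # monotone in rho: 60 bisection steps pin rho to ~1e-17 of the bracket
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _bvn_upper_batch(h, k, mid) < p11
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    rho = 0.5 * (lo + hi)
    R = np.eye(J)
    R[iu] = rho
    R[iu[1], iu[0]] = rho
    if smooth:
        R, did = smooth_correlation(R)
        return TetrachoricMatrix(R, smoothed=did)
    return TetrachoricMatrix(R, smoothed=False)
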