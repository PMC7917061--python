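"""Exploratory factor analysis engine: principal-axis extraction and
oblimin (quartimin) oblique rotation by gradient projection.

This is the shared engine behind discrete-factor-loading Q-matrix
estimation and the very-simple-structure index.  Extraction iterates
communalities on the reduced correlation matrix with clamping against
Heywood cases; rotation is the standard gradient-projection algorithm for
oblique rotations with the quartimin criterion (the oblimin family at
gamma = 0), run from several starts with the best criterion kept.
"""

from __future__ import annotations

import numpy as np

__all__ = ["principal_axis", "oblimin_rotate", "efa", "sample_eigenvalues"]


def sample_eigenvalues(R: np.ndarray) -> np.ndarray:
    """Eigenvalues of a correlation matrix in non-increasing order."""
    vals = np.linalg.eigvalsh(np.asarray(R, dtype=float))
    return vals[::-1]


def principal_axis(
    R: np.ndarray,
    n_factors: int,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Principal-axis factor loadings (unrotated) from a correlation matrix.

    Communalities start at the squared multiple correlations and are
    iterated; they are clamped to [0, 0.998] so Heywood cases cannot
    destabilise the extraction.
    """
    R = np.asarray(R, dtype=float)
    J = R.shape[0]
    if not 1 <= n_factors <= J:
        raise ValueError("factor count must be between 1 and the item count")
    try:
        inv_diag = np.diag(np.linalg.inv(R))
        h2 = np.clip(1.0 - 1.0 / inv_diag, 0.0, 0.998)
    except np.linalg.LinAlgError:
        h2 = np.full(J, 0.5)
    loadings = np.zeros((J, n_factors))
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[idx], 0.0, None)
        loadings = vecs[:, idx] * np.sqrt(lam)
        h2_new = np.clip((loadings**2).sum(axis=1), 0.0, 0.998)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    # sign convention: each factor's largest loading is positive
    for k in range(n_factors):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] = -loadings[:, k]
    return loadings


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion value and gradient with respect to the pattern."""
    L2 = L**2
    K = L.shape[1]
    Nmat = np.ones((K, K)) - np.eye(K)
    X = L2 @ Nmat
    f = float((L2 * X).sum()) / 4.0
    G = L * X
    return f, G


def _gpa_oblique(
    A: np.ndarray,
    T0: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gradient-projection oblique rotation (Bernaards-Jennrich scheme)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            v = 1.0 / np.sqrt((X**2).sum(axis=0))
            Tt = X * v
            try:
                Tti = np.linalg.inv(Tt)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            Lt = A @ Tti.T
            ft, Gqt = _quartimin(Lt)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, L, f, Gq = Tt, Lt, ft, Gqt
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    return L, Phi, f


def oblimin_rotate(
    loadings: np.ndarray,
    n_starts: int = 10,
    seed: int = 1234,
) -> tuple[np.ndarray, np.ndarray]:
    """Quartimin-rotated pattern matrix and factor correlation matrix.

    Runs gradient projection from the identity plus ``n_starts - 1`` random
    oblique starts and keeps the solution with the lowest criterion.
    """
    A = np.asarray(loadings, dtype=float)
    K = A.shape[1]
    if K == 1:
        return A.copy(), np.ones((1, 1))
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    starts = [np.eye(K)]
    for _ in range(max(0, n_starts - 1)):
        M = rng.standard_normal((K, K))
        M /= np.sqrt((M**2).sum(axis=0))
        starts.append(M)
    for T0 in starts:
        try:
            L, Phi, f = _gpa_oblique(A, T0)
        except np.linalg.LinAlgError:
            continue
        if best is None or f < best[2]:
            best = (L, Phi, f)
    if best is None:
        raise RuntimeError("oblique rotation failed from every start")
    L, Phi, _ = best
    # orient factors so the dominant loading of each is positive
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(K)])
    signs[signs == 0] = 1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


def efa(R: np.ndarray, n_factors: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis extraction followed by oblimin rotation.

    Returns the rotated pattern matrix (J x K) and the factor correlation
    matrix (K x K).
    """
    A = principal_axis(R, n_factors)
    return oblimin_rotate(A)
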