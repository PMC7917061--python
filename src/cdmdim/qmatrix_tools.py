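"""Empirical Q-matrix estimation, validation and recovery scoring.

Three tools live here:

* **DFL estimation** — factor-analyse the tetrachoric correlation matrix
  with K factors, oblimin-rotate, and dichotomise each row of absolute
  loadings at its own mean (an entry becomes 1 when the loading is at least
  the row mean).
* **Hull/PVAF validation** — for each item, score candidate q-vectors by the
  proportion of latent-class success-probability variance they account for
  (PVAF), trace the upper convex hull of (parameter count, PVAF) points and
  keep the elbow: the simplest q-vector that still discriminates.
* **QRR** — the Q-matrix recovery rate: proportion of correctly specified
  q-entries after optimal column alignment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import FitResult, QMatrix, fit_em
from .factors import efa
from .tetrachoric import TetrachoricMatrix, tetrachoric_matrix

logger = logging.getLogger(__name__)

PVAF_FALLBACK_CUTOFF = 0.95  # used only when the hull has no interior vertex

__all__ = ["dfl_estimate", "pvaf", "hull_validate", "qrr", "item_pvaf_table"]


def dfl_estimate(
    responses: np.ndarray | None,
    K: int,
    corr: TetrachoricMatrix | None = None,
) -> QMatrix:
    """Discrete-factor-loading Q-matrix estimate with K attributes.

    A precomputed tetrachoric matrix may be passed to amortise the expensive
    step across repeated calls (e.g. over a range of K).  Rows are
    dichotomised at their own mean absolute loading; the row maximum is
    always at or above the mean, so no all-zero rows can occur.
    """
    if corr is None:
        if responses is None:
            raise ValueError("need responses or a precomputed correlation matrix")
        corr = tetrachoric_matrix(responses)
    R = corr.values
    J = R.shape[0]
    if not 1 <= K <= J:
        raise ValueError("K must lie between 1 and the item count")
    loadings, _ = efa(R, K)
    absl = np.abs(loadings)
    cut = absl.mean(axis=1, keepdims=True)
    entries = (absl >= cut).astype(np.int8)
    # guard (cannot trigger for finite loadings, kept for degenerate ties)
    empty = entries.sum(axis=1) == 0
    if empty.any():
        entries[empty, np.argmax(absl[empty], axis=1)] = 1
    return QMatrix(entries)


def _class_success_probs(fit: FitResult, responses: np.ndarray) -> np.ndarray:
    """(J, L) nonparametric item success probabilities per latent class.

    Posterior-expected correct counts over posterior-expected class counts;
    classes with negligible posterior mass inherit the overall item mean.
    """
    X = np.asarray(responses, dtype=float)
    post = fit.posterior
    Nl = post.sum(axis=0)  # (L,)
    Rl = post.T @ X  # (L, J)
    means = X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = Rl / Nl[:, None]
    starved = Nl < 1e-8
    if starved.any():
        P[starved] = means
    return np.clip(P.T, 0.0, 1.0)


def _collapse_variance(P_l: np.ndarray, w: np.ndarray, mask: int) -> float:
    """Weighted between-group variance of class success probabilities after
    collapsing latent classes onto the attribute subset ``mask``."""
    L = len(w)
    glab = np.arange(L) & mask
    Wg = np.bincount(glab, weights=w, minlength=L)
    Sg = np.bincount(glab, weights=w * P_l, minlength=L)
    keep = Wg > 0
    pbar = Sg.sum()
    return float((Sg[keep] ** 2 / Wg[keep]).sum() - pbar**2)


def pvaf(
    fit: FitResult,
    responses: np.ndarray,
    item: int,
    candidate: np.ndarray,
) -> float:
    """Proportion of variance accounted for by a candidate q-vector.

    Ratio of the class-weight-weighted variance of item success
    probabilities collapsed onto the candidate attributes to the variance
    under the full K-attribute vector.  Returns 0 (with a warning) when the
    item does not discriminate at all under the full vector.
    """
    candidate = np.asarray(candidate, dtype=int)
    K = fit.class_space.K
    if candidate.shape != (K,) or not np.isin(candidate, (0, 1)).all():
        raise ValueError("candidate q-vector must be binary of length K")
    P_l = _class_success_probs(fit, responses)[item]
    w = fit.class_space.weights
    full_mask = (1 << K) - 1
    denom = _collapse_variance(P_l, w, full_mask)
    if denom <= 1e-12:
        logger.warning("item %d does not discriminate; PVAF set to 0", item)
        return 0.0
    mask = int((candidate * (1 << np.arange(K))).sum())
    return float(np.clip(_collapse_variance(P_l, w, mask) / denom, 0.0, 1.0))


def item_pvaf_table(
    fit: FitResult, responses: np.ndarray, item: int
) -> list[dict]:
    """Best candidate per complexity level for one item.

    Returns, for k = 0..K, the attribute subset with the highest PVAF among
    those of size k, with its parameter count ``2**k``.  The k = 0 row is the
    non-discriminating baseline (PVAF 0, one parameter).
    """
    K = fit.class_space.K
    P_l = _class_success_probs(fit, responses)[item]
    w = fit.class_space.weights
    full_mask = (1 << K) - 1
    denom = _collapse_variance(P_l, w, full_mask)
    rows = [{"k": 0, "mask": 0, "n_params": 1, "pvaf": 0.0}]
    for k in range(1, K + 1):
        best_mask, best_val = None, -1.0
        for attrs in itertools.combinations(range(K), k):
            mask = 0
            for a in attrs:
                mask |= 1 << a
            val = (
                _collapse_variance(P_l, w, mask) / denom if denom > 1e-12 else 0.0
            )
            if val > best_val:
                best_mask, best_val = mask, val
        rows.append(
            {"k": k, "mask": int(best_mask), "n_params": 2**k, "pvaf": float(np.clip(best_val, 0.0, 1.0))}
        )
    return rows


def _hull_select(rows: list[dict]) -> int:
    """Elbow of the (parameter count, PVAF) series: returns the chosen mask.

    Keeps the upper convex hull, then picks the interior vertex with the
    largest ratio of incoming to outgoing slope.  With no interior vertex
    the simplest complexity reaching the PVAF fallback cutoff wins.
    """
    pts = [(r["n_params"], r["pvaf"], r["mask"]) for r in rows]
    hull = list(pts)
    changed = True
    while changed and len(hull) > 2:
        changed = False
        for t in range(1, len(hull) - 1):
            x0, y0, _ = hull[t - 1]
            x1, y1, _ = hull[t]
            x2, y2, _ = hull[t + 1]
            chord = y0 + (y2 - y0) * (x1 - x0) / (x2 - x0)
            if y1 <= chord + 1e-12:
                del hull[t]
                changed = True
                break
    if len(hull) > 2:
        best_t, best_ratio = None, -np.inf
        for t in range(1, len(hull) - 1):
            x0, y0, _ = hull[t - 1]
            x1, y1, m = hull[t]
            x2, y2, _ = hull[t + 1]
            s_in = (y1 - y0) / (x1 - x0)
            s_out = (y2 - y1) / (x2 - x1)
            ratio = s_in / s_out if s_out > 1e-12 else np.inf
            if ratio > best_ratio:
                best_t, best_ratio = t, ratio
        return hull[best_t][2]
    adequate = [r for r in rows[1:] if r["pvaf"] >= PVAF_FALLBACK_CUTOFF]
    return adequate[0]["mask"] if adequate else rows[-1]["mask"]


def hull_validate(
    responses: np.ndarray,
    Q0: QMatrix,
    model: str = "GDINA",
    fit: FitResult | None = None,
    seed: int = 0,
) -> QMatrix:
    """Hull/PVAF validation of a provisional Q-matrix.

    A single model fit under ``Q0`` supplies posterior class weights and
    nonparametric per-class item success probabilities; each item's q-vector
    is then re-selected at the elbow of its PVAF-versus-complexity hull.
    The result never contains an all-zero row.
    """
    if fit is None:
        fit = fit_em(responses, Q0, model=model, seed=seed)
    K = Q0.K
    entries = np.zeros((Q0.J, K), dtype=np.int8)
    for j in range(Q0.J):
        rows = item_pvaf_table(fit, responses, j)
        mask = _hull_select(rows)
        if mask == 0:  # never leave an item without attributes
            mask = rows[1]["mask"]
        entries[j] = [(mask >> k) & 1 for k in range(K)]
    return QMatrix(entries)


def qrr(Q_est: QMatrix, Q_true: QMatrix) -> tuple[float, np.ndarray]:
    """Q-matrix recovery rate after optimal column alignment.

    The maximum over column permutations of ``Q_est`` of the mean q-entry
    agreement with ``Q_true``; the maximising permutation is returned too
    (``perm[k]`` is the estimated column matched to true column k).  Solved
    exactly as a linear assignment on the pairwise agreement-count matrix.
    """
    A, B = Q_est.entries, Q_true.entries
    if A.shape != B.shape:
        raise ValueError("Q-matrices must have identical shape")
    J, K = A.shape
    agree = np.zeros((K, K))
    for ke in range(K):
        for kt in range(K):
            agree[ke, kt] = (A[:, ke] == B[:, kt]).sum()
    row, col = linear_sum_assignment(-agree)
    perm = np.empty(K, dtype=int)
    perm[col] = row
    return float(agree[row, col].sum() / (J * K)), perm
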