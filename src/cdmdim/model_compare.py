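"""Model-comparison dimensionality assessment and combination rules.

The MC procedure treats the attribute count as a model-selection problem:
for each candidate K the Q-matrix is estimated from the data (DFL), refined
(Hull/PVAF), a CDM is fitted under it, and the candidates are compared with
AIC, BIC, or the count of items showing significant pairwise
Fisher-transformed correlation residuals (Bonferroni-corrected per item).
Generating Q-matrices can be injected per K to measure the upper-limit
performance the procedure would reach with a perfectly recovered Q-matrix.

``combine_rules`` implements the agreement guidelines for reconciling
several methods' suggestions in applied work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import FitResult, QMatrix, fit_em, information_criteria, prob_table
from .dim_methods import DimSuggestion
from .qmatrix_tools import dfl_estimate, hull_validate
from .tetrachoric import tetrachoric_matrix

logger = logging.getLogger(__name__)

__all__ = ["ResidualStats", "MCCandidate", "residual_stats", "mc_select", "combine_rules", "DecisionRecord"]


@dataclass
class ResidualStats:
    """Absolute-fit residual z-scores and item flags.

    ``z_prop`` holds per-item proportion-correct residuals; ``z_fisher`` and
    ``z_logodds`` are symmetric J x J matrices of pairwise residual z-scores
    (Fisher-transformed correlations and log-odds ratios).  ``item_flags``
    marks items with at least one significant Fisher pair residual after a
    per-item Bonferroni correction; only these drive MC selection.
    """

    z_prop: np.ndarray
    z_fisher: np.ndarray
    z_logodds: np.ndarray
    item_flags: np.ndarray
    min_p_fisher: float
    alpha: float

    @property
    def n_flagged_items(self) -> int:
        return int(self.item_flags.sum())


@dataclass
class MCCandidate:
    """One row of the MC comparison table."""

    K: int
    Q_est: QMatrix | None
    Q_val: QMatrix
    fit: FitResult
    aic: float
    bic: float
    n_flagged_items: int
    min_p_fisher: float


def _model_pair_moments(fit: FitResult, Q: QMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied item means and E[X_j X_j'] from class weights."""
    P = prob_table(Q, fit.item_params, fit.class_space.profiles)  # (J, L)
    w = fit.class_space.weights
    p = P @ w
    Ejj = (P * w) @ P.T
    return p, Ejj


def residual_stats(
    fit: FitResult,
    responses: np.ndarray,
    Q: QMatrix,
    alpha: float = 0.05,
) -> ResidualStats:
    """Observed-versus-predicted residual z-scores under a fitted CDM.

    Predicted moments come from the estimated class weights and item
    probability tables.  Pairwise correlations are compared on the Fisher-z
    scale with standard error ``1/sqrt(N-3)``; log-odds ratios use observed
    cell counts with a 0.5 continuity correction.  An item is flagged when
    any of its J-1 Fisher pair residuals is significant at
    ``alpha / (J - 1)`` (two-sided).
    """
    X = np.asarray(responses, dtype=float)
    N, J = X.shape
    p_pred, E_pred = _model_pair_moments(fit, Q)
    p_obs = X.mean(axis=0)

    # item proportion-correct residuals
    se_p = np.sqrt(np.clip(p_pred * (1 - p_pred), 1e-12, None) / N)
    z_prop = (p_obs - p_pred) / se_p

    # pairwise Pearson correlations, observed and model-implied
    def corr_from(p: np.ndarray, E: np.ndarray) -> np.ndarray:
        cov = E - np.outer(p, p)
        sd = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        return np.clip(cov / np.outer(sd, sd), -0.999999, 0.999999)

    E_obs = (X.T @ X) / N
    r_obs = corr_from(p_obs, E_obs)
    r_pred = corr_from(p_pred, E_pred)
    z_fisher = (np.arctanh(r_obs) - np.arctanh(r_pred)) * np.sqrt(N - 3)
    np.fill_diagonal(z_fisher, 0.0)

    # pairwise log-odds ratios (continuity-corrected observed cells)
    n11 = X.T @ X
    n10 = X.T @ (1 - X)
    n01 = (1 - X).T @ X
    n00 = (1 - X).T @ (1 - X)
    degenerate = (n11 == 0) | (n10 == 0) | (n01 == 0) | (n00 == 0)
    if degenerate.any():
        logger.info("log-odds residuals: %d pairs continuity-corrected", int(degenerate.sum() // 2))
    c = 0.5
    l_obs = np.log(((n11 + c) * (n00 + c)) / ((n10 + c) * (n01 + c)))
    p11 = np.clip(E_pred, 1e-10, None)
    p10 = np.clip(p_pred[:, None] - E_pred, 1e-10, None)
    p01 = np.clip(p_pred[None, :] - E_pred, 1e-10, None)
    p00 = np.clip(1 - p_pred[:, None] - p_pred[None, :] + E_pred, 1e-10, None)
    l_pred = np.log((p11 * p00) / (p10 * p01))
    se_l = np.sqrt(1 / (n11 + c) + 1 / (n10 + c) + 1 / (n01 + c) + 1 / (n00 + c))
    z_logodds = (l_obs - l_pred) / se_l
    np.fill_diagonal(z_logodds, 0.0)

    iu = np.triu_indices(J, k=1)
    pvals = 2 * norm.sf(np.abs(z_fisher))
    np.fill_diagonal(pvals, 1.0)
    cutoff = alpha / (J - 1)  # Bonferroni at the item level
    item_flags = (pvals < cutoff).any(axis=1)
    return ResidualStats(
        z_prop=z_prop,
        z_fisher=z_fisher,
        z_logodds=z_logodds,
        item_flags=item_flags,
        min_p_fisher=float(pvals[iu].min()),
        alpha=alpha,
    )


def _select_khat(table: pd.DataFrame, index: str) -> int:
    """Selection rules: argmin AIC/BIC (ties to smaller K); for the residual
    criterion, the smallest K attaining the minimum flagged-item count."""
    if index in ("aic", "bic"):
        col = table[index]
        return int(table.loc[col.idxmin(), "K"])  # idxmin takes the first (smallest K)
    if index == "r":
        best = table["n_flagged_items"].min()
        return int(table.loc[table["n_flagged_items"] == best, "K"].min())
    raise ValueError("index must be 'aic', 'bic' or 'r'")


def mc_select(
    responses: np.ndarray,
    model: str = "GDINA",
    index: str = "aic",
    kmax: int = 9,
    Q_override: dict[int, QMatrix] | None = None,
    Q_extra: dict[int, QMatrix] | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[DimSuggestion, pd.DataFrame, list[MCCandidate]]:
    """Model-comparison estimate of the attribute count.

    For each K in 1..kmax: DFL Q-matrix estimation (one shared tetrachoric
    matrix), Hull/PVAF validation, a model fit, and AIC/BIC/residual flags.
    ``Q_override`` maps K to a fixed Q-matrix that bypasses DFL+Hull for
    that candidate; ``Q_extra`` maps K to fixed Q-matrices fitted *in
    addition to* the empirical candidates (the generating-Q upper-limit
    variants add the true-Q model as an extra competitor; its rows carry
    ``override=True`` in the table).  Candidates whose fit fails are
    excluded with a log record.
    """
    X = np.asarray(responses)
    N = X.shape[0]
    Q_override = Q_override or {}
    Q_extra = Q_extra or {}
    tet = tetrachoric_matrix(X)
    candidates: list[MCCandidate] = []
    is_override: list[bool] = []
    plan: list[tuple[int, QMatrix | None]] = [(K, None) for K in range(1, kmax + 1)]
    plan += [(K, Q) for K, Q in sorted(Q_extra.items())]
    for K, Q_fixed in plan:
        try:
            if Q_fixed is not None or K in Q_override:
                Q_est = None
                Q_val = Q_fixed if Q_fixed is not None else Q_override[K]
                fit = fit_em(X, Q_val, model=model, seed=seed)
            else:
                Q_est = dfl_estimate(None, K, corr=tet)
                fit0 = fit_em(X, Q_est, model=model, seed=seed)
                Q_val = hull_validate(X, Q_est, model=model, fit=fit0)
                if np.array_equal(Q_val.entries, Q_est.entries):
                    fit = fit0
                else:
                    # warm-start from the first fit: unchanged items keep
                    # their parameters, weights carry over
                    init_probs = [
                        fit0.item_params.probs[j]
                        if np.array_equal(Q_val.entries[j], Q_est.entries[j])
                        else None
                        for j in range(Q_val.J)
                    ]
                    fit = fit_em(
                        X,
                        Q_val,
                        model=model,
                        seed=seed,
                        init_probs=init_probs,
                        init_weights=fit0.class_space.weights,
                    )
            aic, bic = information_criteria(fit, N)
            rs = residual_stats(fit, X, Q_val, alpha=alpha)
        except (np.linalg.LinAlgError, ValueError, RuntimeError) as exc:
            logger.warning("MC candidate K=%d failed: %s", K, exc)
            continue
        is_override.append(Q_fixed is not None)
        candidates.append(
            MCCandidate(
                K=K,
                Q_est=Q_est,
                Q_val=Q_val,
                fit=fit,
                aic=aic,
                bic=bic,
                n_flagged_items=rs.n_flagged_items,
                min_p_fisher=rs.min_p_fisher,
            )
        )
    if not candidates:
        raise RuntimeError("every MC candidate failed to fit")
    table = pd.DataFrame(
        {
            "K": [c.K for c in candidates],
            "minus2ll": [-2 * c.fit.loglik for c in candidates],
            "n_params": [c.fit.n_params for c in candidates],
            "aic": [c.aic for c in candidates],
            "bic": [c.bic for c in candidates],
            "n_flagged_items": [c.n_flagged_items for c in candidates],
            "min_p_fisher": [c.min_p_fisher for c in candidates],
            "override": is_override,
        }
    )
    khat = _select_khat(table, index)
    suggestion = DimSuggestion(
        method=f"MC_{index.upper() if index != 'r' else 'r'}",
        khat=khat,
        curve={"table": table},
    )
    return suggestion, table, candidates


@dataclass
class DecisionRecord:
    """Outcome of the combination-rule guidelines."""

    step: str  # 'a', 'b', 'c' or 'd'
    decided: int | None
    explore: list[int] = field(default_factory=list)
    suggestions: dict[str, int] = field(default_factory=dict)


def combine_rules(suggestions: dict[str, int]) -> DecisionRecord:
    """Agreement guidelines over several methods' suggested counts.

    (a) all methods agree: retain that count; (b) some (but not all) pair
    agrees on a unique value: retain it; (c) no agreement but some methods
    are within one attribute of each other: explore those counts; (d) strong
    disagreement: explore every suggested count.
    """
    if len(suggestions) < 2:
        raise ValueError("need suggestions from at least two methods")
    ks = list(suggestions.values())
    values, counts = np.unique(ks, return_counts=True)
    if len(values) == 1:
        return DecisionRecord("a", int(values[0]), [int(values[0])], dict(suggestions))
    top = counts.max()
    if top >= 2:
        modes = values[counts == top]
        if len(modes) == 1:
            return DecisionRecord("b", int(modes[0]), [int(modes[0])], dict(suggestions))
        return DecisionRecord("b", None, [int(m) for m in modes], dict(suggestions))
    close = set()
    svals = sorted(values)
    for i in range(len(svals) - 1):
        if svals[i + 1] - svals[i] <= 1:
            close.update((int(svals[i]), int(svals[i + 1])))
    if close:
        return DecisionRecord("c", None, sorted(close), dict(suggestions))
    return DecisionRecord("d", None, sorted(int(v) for v in values), dict(suggestions))
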