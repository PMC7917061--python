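"""Core cognitive-diagnosis machinery: DINA and G-DINA models.

Cognitive diagnosis models (CDMs) are restricted latent class models for
dichotomous response data.  Respondents are characterised by a binary
*attribute profile* ``alpha`` of length ``K``; the J x K binary *Q-matrix*
declares which attributes each item measures.  This module provides the
latent class space, item response probabilities under the DINA (conjunctive,
guess/slip) and G-DINA (saturated, delta-parameterised) models, the marginal
likelihood, and a monotone EM estimator for both models.

Canonical profile order
-----------------------
The ``2**K`` attribute profiles are ordered by binary counting with
attribute 1 as the fastest-varying bit: profile ``l`` has
``alpha_k = (l >> k) & 1``.  All class-indexed quantities (weights,
posteriors, probability tables) follow this order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-4  # estimation clamp for success probabilities
MAX_K = 15

__all__ = [
    "QMatrix",
    "LatentClassSpace",
    "ItemParams",
    "FitResult",
    "enumerate_profiles",
    "dina_prob",
    "gdina_prob",
    "probs_to_deltas",
    "deltas_to_probs",
    "prob_table",
    "marginal_loglik",
    "fit_em",
    "information_criteria",
    "validate_responses",
]


class InvalidParameterError(ValueError):
    """A parameter set violates its domain (e.g. probability outside [0,1])."""


@dataclass(frozen=True)
class QMatrix:
    """J x K binary item-attribute incidence matrix.

    Every entry is 0/1 and every item measures at least one attribute.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=np.int8)
        if arr.ndim != 2:
            raise ValueError("Q-matrix must be two-dimensional")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("Q-matrix entries must be 0 or 1")
        if (arr.sum(axis=1) == 0).any():
            bad = np.flatnonzero(arr.sum(axis=1) == 0)
            raise ValueError(f"items {bad.tolist()} measure no attribute")
        if arr.shape[0] < arr.shape[1]:
            raise ValueError("need at least as many items as attributes")
        object.__setattr__(self, "entries", arr)

    @property
    def J(self) -> int:
        return self.entries.shape[0]

    @property
    def K(self) -> int:
        return self.entries.shape[1]


@dataclass
class LatentClassSpace:
    """All ``2**K`` attribute profiles plus a probability weight per profile."""

    profiles: np.ndarray  # (L, K) binary, canonical order
    weights: np.ndarray  # (L,) nonnegative, sums to 1

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=np.int8)
        self.weights = np.asarray(self.weights, dtype=float)
        L, K = self.profiles.shape
        if L != 2**K:
            raise ValueError("profile count must be 2**K")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def K(self) -> int:
        return self.profiles.shape[1]

    @property
    def L(self) -> int:
        return self.profiles.shape[0]


@dataclass
class ItemParams:
    """Per-item success probabilities over reduced latent groups.

    ``model`` is ``"DINA"`` or ``"GDINA"``.  For DINA, ``probs[j]`` has two
    entries ``[g_j, 1 - s_j]`` indexed by the conjunction indicator eta.  For
    G-DINA, ``probs[j]`` has ``2**Kstar_j`` entries indexed by the reduced
    attribute mask (bit k* = mastery of the k*-th required attribute, in
    Q-matrix column order).
    """

    model: str
    probs: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model not in ("DINA", "GDINA"):
            raise ValueError("model must be 'DINA' or 'GDINA'")
        self.probs = [np.asarray(p, dtype=float) for p in self.probs]
        for j, p in enumerate(self.probs):
            if (p < 0).any() or (p > 1).any():
                raise InvalidParameterError(
                    f"item {j}: success probabilities outside [0, 1]"
                )

    @property
    def J(self) -> int:
        return len(self.probs)

    def n_item_params(self) -> int:
        return sum(len(p) for p in self.probs)


@dataclass
class FitResult:
    """Outcome of an EM fit: parameters, weights, likelihood, posteriors."""

    item_params: ItemParams
    class_space: LatentClassSpace
    loglik: float
    n_params: int
    posterior: np.ndarray  # (N, L)
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "model": self.item_params.model,
            "item_probs": [p.tolist() for p in self.item_params.probs],
            "class_weights": self.class_space.weights.tolist(),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }


def validate_responses(responses: np.ndarray) -> np.ndarray:
    """Check an N x J dichotomous response matrix and return it as int8."""
    X = np.asarray(responses)
    if X.ndim != 2:
        raise ValueError("response matrix must be two-dimensional")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("responses must be 0/1 with no missing values")
    return X.astype(np.int8)


def enumerate_profiles(K: int) -> LatentClassSpace:
    """All ``2**K`` binary attribute profiles in canonical order, uniform weights."""
    if not 1 <= K <= MAX_K:
        raise ValueError(f"K must be between 1 and {MAX_K}, got {K}")
    L = 2**K
    idx = np.arange(L)
    profiles = ((idx[:, None] >> np.arange(K)[None, :]) & 1).astype(np.int8)
    return LatentClassSpace(profiles, np.full(L, 1.0 / L))


def dina_prob(g: float, s: float, eta: int) -> float:
    """DINA success probability ``g**(1-eta) * (1-s)**eta``.

    ``eta`` is 1 when all required attributes are mastered, else 0.
    """
    if not (0 <= g <= 1 and 0 <= s <= 1):
        raise InvalidParameterError("g and s must lie in [0, 1]")
    if eta not in (0, 1):
        raise ValueError("eta must be 0 or 1")
    return (1.0 - s) if eta else g


def _subset_masks(mask: int) -> list[int]:
    """All submasks of ``mask`` (including 0 and mask itself)."""
    subs = [0]
    bit_positions = [b for b in range(mask.bit_length()) if mask >> b & 1]
    for r in range(1, len(bit_positions) + 1):
        for combo in itertools.combinations(bit_positions, r):
            m = 0
            for b in combo:
                m |= 1 << b
            subs.append(m)
    return subs


def gdina_prob(deltas: np.ndarray, reduced_profile: np.ndarray) -> float:
    """G-DINA success probability for one reduced attribute profile.

    ``deltas`` is indexed by attribute-subset bitmask (``deltas[0]`` is the
    intercept, ``deltas[1 << k]`` the main effect of required attribute k,
    higher masks the interactions).  The probability is the intercept plus the
    main effects of the mastered attributes plus all interactions among them.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    kstar = n.bit_length() - 1
    if n != 2**kstar:
        raise InvalidParameterError("delta vector length must be a power of two")
    profile = np.asarray(reduced_profile, dtype=int)
    if profile.shape != (kstar,):
        raise ValueError("reduced profile length must match the delta set")
    mask = int((profile * (1 << np.arange(kstar))).sum())
    p = float(sum(deltas[sub] for sub in _subset_masks(mask)))
    if not -1e-12 <= p <= 1 + 1e-12:
        raise InvalidParameterError(f"delta set yields probability {p:.4f} outside [0,1]")
    return min(max(p, 0.0), 1.0)


def probs_to_deltas(probs: np.ndarray) -> np.ndarray:
    """Difference-contrast (Moebius) transform of a reduced probability table.

    ``probs`` is indexed by reduced-profile bitmask; returns deltas on the
    same indexing.  Exact inverse of :func:`deltas_to_probs`.
    """
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    kstar = n.bit_length() - 1
    if n != 2**kstar:
        raise ValueError("probability table length must be a power of two")
    deltas = probs.copy()
    # in-place subset-sum Moebius inversion, one bit at a time
    for b in range(kstar):
        bit = 1 << b
        for m in range(n):
            if m & bit:
                deltas[m] -= deltas[m ^ bit]
    return deltas


def deltas_to_probs(deltas: np.ndarray) -> np.ndarray:
    """Zeta (subset-sum) transform: probability table from delta coefficients."""
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    kstar = n.bit_length() - 1
    if n != 2**kstar:
        raise ValueError("delta vector length must be a power of two")
    probs = deltas.copy()
    for b in range(kstar):
        bit = 1 << b
        for m in range(n):
            if m & bit:
                probs[m] += probs[m ^ bit]
    if (probs < -1e-12).any() or (probs > 1 + 1e-12).any():
        raise InvalidParameterError("delta set yields probabilities outside [0,1]")
    return np.clip(probs, 0.0, 1.0)


def item_group_labels(q_row: np.ndarray, profiles: np.ndarray, model: str) -> np.ndarray:
    """Reduced-group label of every latent class for one item.

    DINA: the conjunction indicator eta (0/1).  G-DINA: the reduced-profile
    bitmask over the item's required attributes (Q-matrix column order).
    """
    req = np.flatnonzero(q_row)
    sub = profiles[:, req]
    if model == "DINA":
        return sub.all(axis=1).astype(np.intp)
    return (sub * (1 << np.arange(len(req)))).sum(axis=1).astype(np.intp)


def prob_table(Q: QMatrix, params: ItemParams, profiles: np.ndarray) -> np.ndarray:
    """(J, L) success-probability table: item x latent class."""
    J = Q.J
    L = profiles.shape[0]
    P = np.empty((J, L))
    for j in range(J):
        glab = item_group_labels(Q.entries[j], profiles, params.model)
        P[j] = params.probs[j][glab]
    return P


def _class_loglik(X: np.ndarray, P: np.ndarray) -> np.ndarray:
    """(N, L) log-likelihood of each response vector under each class.

    Boundary probabilities (exactly 0 or 1) combined with a contradicting
    response yield -inf for that class, without crashing.
    """
    Xf = X.astype(float)
    with np.errstate(divide="ignore"):
        logP = np.log(P)
        log1mP = np.log1p(-P)
    boundary = ~np.isfinite(logP) | ~np.isfinite(log1mP)
    if boundary.any():
        ll = Xf @ np.where(np.isfinite(logP), logP, 0.0) + (1.0 - Xf) @ np.where(
            np.isfinite(log1mP), log1mP, 0.0
        )
        contradictions = Xf @ (P == 0.0) + (1.0 - Xf) @ (P == 1.0)
        ll[contradictions > 0] = -np.inf
        return ll
    return Xf @ logP + (1.0 - Xf) @ log1mP


def marginal_loglik(
    responses: np.ndarray,
    Q: QMatrix,
    params: ItemParams,
    weights: np.ndarray,
) -> float:
    """Marginal log-likelihood of a response matrix under a CDM.

    ``sum_i log sum_l w_l prod_j P_j(alpha_l)^x (1-P_j(alpha_l))^(1-x)``,
    computed with log-sum-exp stability.  Returns ``-inf`` when some
    respondent contradicts a degenerate (0/1) probability in every class.
    """
    from scipy.special import logsumexp

    X = validate_responses(responses)
    weights = np.asarray(weights, dtype=float)
    space = enumerate_profiles(Q.K)
    P = prob_table(Q, params, space.profiles)
    ll = _class_loglik(X, P)
    with np.errstate(divide="ignore"):
        logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
    return float(logsumexp(ll + logw, axis=1).sum())


def _init_item_probs(
    X: np.ndarray, Q: QMatrix, model: str, rng: np.random.Generator
) -> list[np.ndarray]:
    # jitter around the observed item means, tilted so that groups with more
    # mastered attributes start with higher success (orients the latent scale)
    means = X.mean(axis=0)
    probs = []
    for j in range(Q.J):
        kstar = int(Q.entries[j].sum())
        if model == "DINA":
            n_mastered = np.array([0.0, 1.0])
            denom = 1.0
        else:
            masks = np.arange(2**kstar)
            n_mastered = np.array([bin(m).count("1") for m in masks], dtype=float)
            denom = max(kstar, 1)
        tilt = 0.3 * (n_mastered / denom - 0.5)
        jitter = rng.uniform(-0.05, 0.05, size=len(n_mastered))
        probs.append(np.clip(means[j] + tilt + jitter, PROB_FLOOR, 1 - PROB_FLOOR))
    return probs


def fit_em(
    responses: np.ndarray,
    Q: QMatrix,
    model: str = "GDINA",
    max_iter: int = 1000,
    tol: float = 1e-4,
    ll_tol: float = 1e-4,
    seed: int | np.random.Generator | None = 0,
    group_floor: float = 1e-2,
    init_probs: list[np.ndarray] | None = None,
    init_weights: np.ndarray | None = None,
) -> FitResult:
    """Fit a DINA or G-DINA model by EM with unstructured class weights.

    Item parameters are expected-count weighted success proportions per
    reduced latent group; class weights are the posterior means.  Convergence
    is declared when the largest absolute parameter change falls below
    ``tol`` or the log-likelihood improves by less than ``ll_tol`` (the
    latter matters for overparameterised fits, where EM wanders along flat
    directions with no material likelihood gain).  Reduced groups with
    expected count below ``group_floor`` keep their previous
    (boundary-smoothed) value, with a logged warning.

    ``init_probs`` / ``init_weights`` warm-start the algorithm (e.g. from a
    previous fit under a closely related Q-matrix); entries of ``init_probs``
    may be None to fall back to the default start for that item.
    """
    X = validate_responses(responses)
    N, J = X.shape
    if N < 2:
        raise ValueError("need at least two respondents")
    if J != Q.J:
        raise ValueError("response matrix and Q-matrix disagree on item count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    space = enumerate_profiles(Q.K)
    L = space.L
    glabs = [item_group_labels(Q.entries[j], space.profiles, model) for j in range(J)]
    n_groups = [int(g.max()) + 1 for g in glabs]

    probs = _init_item_probs(X, Q, model, rng)
    if init_probs is not None:
        for j, p in enumerate(init_probs):
            if p is not None and len(p) == len(probs[j]):
                probs[j] = np.clip(np.asarray(p, dtype=float), PROB_FLOOR, 1 - PROB_FLOOR)
    weights = np.full(L, 1.0 / L)
    if init_weights is not None and len(init_weights) == L:
        weights = np.maximum(np.asarray(init_weights, dtype=float), 1e-12)
        weights = weights / weights.sum()
    Xf = X.astype(float)

    from scipy.special import logsumexp

    loglik_path = []
    converged = False
    posterior = np.full((N, L), 1.0 / L)
    n_iter = 0
    starved_groups = 0
    for n_iter in range(1, max_iter + 1):
        # E-step; for binary x, x log p + (1-x) log(1-p) = x logit(p) + log(1-p)
        P = np.empty((J, L))
        for j in range(J):
            P[j] = probs[j][glabs[j]]
        logP = np.log(P)
        log1mP = np.log1p(-P)
        joint = Xf @ (logP - log1mP) + (log1mP.sum(axis=0) + np.log(weights))
        # manual log-sum-exp: the shifted exponentials double as the posterior
        m = joint.max(axis=1)
        shifted = np.exp(joint - m[:, None])
        denom = shifted.sum(axis=1)
        loglik_path.append(float((m + np.log(denom)).sum()))
        posterior = shifted / denom[:, None]

        # M-step
        new_weights = posterior.mean(axis=0)
        new_weights = np.maximum(new_weights, 1e-12)
        new_weights /= new_weights.sum()

        Nl = posterior.sum(axis=0)  # (L,)
        Rl = posterior.T @ Xf  # (L, J)
        delta = float(np.max(np.abs(new_weights - weights)))
        new_probs = []
        for j in range(J):
            I_g = np.bincount(glabs[j], weights=Nl, minlength=n_groups[j])
            R_g = np.bincount(glabs[j], weights=Rl[:, j], minlength=n_groups[j])
            p_new = probs[j].copy()
            ok = I_g >= group_floor
            if not ok.all():
                starved_groups += 1
            p_new[ok] = np.clip(R_g[ok] / I_g[ok], PROB_FLOOR, 1 - PROB_FLOOR)
            delta = max(delta, float(np.max(np.abs(p_new - probs[j]))))
            new_probs.append(p_new)

        probs = new_probs
        weights = new_weights
        ll_gain = (
            loglik_path[-1] - loglik_path[-2] if len(loglik_path) >= 2 else np.inf
        )
        if delta < tol or abs(ll_gain) < ll_tol:
            converged = True
            break

    if starved_groups:
        logger.warning(
            "EM: %d item-group updates skipped for near-empty expected counts",
            starved_groups,
        )
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)

    params = ItemParams(model=model, probs=probs)
    final_space = LatentClassSpace(space.profiles, weights)
    loglik = marginal_loglik(X, Q, params, weights)
    n_params = params.n_item_params() + (L - 1)
    return FitResult(
        item_params=params,
        class_space=final_space,
        loglik=loglik,
        n_params=n_params,
        posterior=posterior,
        n_iter=n_iter,
        converged=converged,
        loglik_path=np.asarray(loglik_path),
    )


def information_criteria(fit: FitResult, N: int) -> tuple[float, float]:
    """(AIC, BIC) from a fit: ``-2 loglik + 2 np`` and ``-2 loglik + np ln N``."""
    m2ll = -2.0 * fit.loglik
    aic = m2ll + 2.0 * fit.n_params
    bic = m2ll + fit.n_params * np.log(N)
    return float(aic), float(bic)
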