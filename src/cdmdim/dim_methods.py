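"""Classical dimensionality-assessment statistics for dichotomous data.

Each method returns a :class:`DimSuggestion` carrying the suggested
dimension count and the diagnostic curve it was read from:

* parallel analysis (Pearson or tetrachoric correlations; mean or 95th
  percentile reference criterion; column-permutation reference samples),
* Velicer's minimum average partial (MAP),
* very simple structure (VSS, complexity 1 or 2),
* DETECT (rest-score conditional covariances maximised over Ward
  partitions),
* the empirical Kaiser criterion (Marchenko-Pastur-derived references).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .factors import efa, sample_eigenvalues
from .tetrachoric import TetrachoricMatrix, smooth_correlation, tetrachoric_matrix

DEFAULT_MAX_K = 9

__all__ = [
    "DimSuggestion",
    "parallel_analysis",
    "map_velicer",
    "vss",
    "detect",
    "ekc",
    "conditional_covariances",
    "detect_index",
    "assess_dimensionality",
]


@dataclass
class DimSuggestion:
    """A method's recommended dimension count plus its diagnostic curve."""

    method: str
    khat: int
    curve: dict = field(default_factory=dict)


def _pearson_corr(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        raise ValueError(f"items {degenerate.tolist()} have zero variance")
    return np.corrcoef(X, rowvar=False)


def leading_count(sample: np.ndarray, reference: np.ndarray) -> int:
    """Length of the leading run where sample eigenvalues beat references."""
    k = 0
    for s, r in zip(sample, reference):
        if s > r:
            k += 1
        else:
            break
    return k


def parallel_analysis(
    responses: np.ndarray,
    corr_type: str = "pearson",
    criterion: str = "mean",
    n_perm: int = 100,
    rng: np.random.Generator | int | None = None,
    max_redraws: int = 5,
) -> DimSuggestion:
    """Horn's parallel analysis with column-permutation reference samples.

    Sample eigenvalues are the principal-components eigenvalues of the
    chosen correlation matrix.  Each reference sample permutes every item's
    responses independently (preserving the univariate margins while
    destroying dependence); the reference eigenvalue at each position is the
    mean or the 95th percentile across permutations.  The suggestion is the
    number of leading sample eigenvalues exceeding their reference.
    """
    if corr_type not in ("pearson", "tetrachoric"):
        raise ValueError("corr_type must be 'pearson' or 'tetrachoric'")
    if criterion not in ("mean", "p95"):
        raise ValueError("criterion must be 'mean' or 'p95'")
    if n_perm < 1:
        raise ValueError("need at least one permutation sample")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = np.asarray(responses)

    def corr_of(M: np.ndarray) -> np.ndarray:
        if corr_type == "pearson":
            return _pearson_corr(M)
        return tetrachoric_matrix(M).values

    sample = sample_eigenvalues(corr_of(X))
    refs = np.empty((n_perm, X.shape[1]))
    for b in range(n_perm):
        for _ in range(max_redraws):
            perm = rng.permuted(X, axis=0)
            try:
                refs[b] = sample_eigenvalues(corr_of(perm))
                break
            except ValueError:  # degenerate permuted copy; redraw
                continue
        else:
            raise RuntimeError("could not build a reference sample")
    reference = refs.mean(axis=0) if criterion == "mean" else np.percentile(refs, 95, axis=0)
    khat = leading_count(sample, reference)
    tag = {"pearson": "r", "tetrachoric": "p"}[corr_type] + {"mean": "m", "p95": "95"}[criterion]
    return DimSuggestion(
        method=f"PA_{tag}",
        khat=khat,
        curve={"sample": sample, "reference": reference},
    )


def map_velicer(
    corr: TetrachoricMatrix | np.ndarray,
    max_K: int = DEFAULT_MAX_K,
) -> DimSuggestion:
    """Velicer's minimum average partial on a correlation matrix.

    For m = 0..max_K the first m principal components are partialled out of
    the correlation matrix and the mean squared off-diagonal partial
    correlation (the MAP index) is recorded; the suggestion is the m with
    the smallest index.  A singular residual truncates the curve there.
    """
    R = corr.values if isinstance(corr, TetrachoricMatrix) else np.asarray(corr, float)
    R, _ = smooth_correlation(R)
    J = R.shape[0]
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    off = ~np.eye(J, dtype=bool)
    curve = []
    for m in range(min(max_K, J - 1) + 1):
        if m == 0:
            partial = R
        else:
            Lm = vecs[:, :m] * np.sqrt(np.clip(vals[:m], 0.0, None))
            C = R - Lm @ Lm.T
            d = np.diag(C)
            if (d <= 1e-10).any():
                break  # singular residual: truncate the curve
            partial = C / np.sqrt(np.outer(d, d))
        curve.append(float((partial[off] ** 2).mean()))
    curve_arr = np.asarray(curve)
    khat = int(np.argmin(curve_arr))
    return DimSuggestion(method="MAP", khat=khat, curve={"map": curve_arr})


def vss_index(R: np.ndarray, loadings: np.ndarray, Phi: np.ndarray, v: int) -> float:
    """Very-simple-structure index of one rotated solution.

    Keeps each row's v largest absolute loadings, reconstructs the
    correlation matrix, and compares mean squared off-diagonal residual to
    observed: ``1 - MS_residual / MS_observed``.
    """
    L = np.asarray(loadings, dtype=float)
    J, K = L.shape
    S = np.zeros_like(L)
    for j in range(J):
        keep = np.argsort(-np.abs(L[j]))[: min(v, K)]
        S[j, keep] = L[j, keep]
    resid = R - S @ Phi @ S.T
    off = ~np.eye(J, dtype=bool)
    ms_resid = float((resid[off] ** 2).mean())
    ms_obs = float((R[off] ** 2).mean())
    if ms_obs == 0.0:
        return 0.0
    return 1.0 - ms_resid / ms_obs


def vss(
    responses: np.ndarray | None,
    v: int = 1,
    max_K: int = DEFAULT_MAX_K,
    corr: TetrachoricMatrix | np.ndarray | None = None,
) -> DimSuggestion:
    """Very simple structure on tetrachoric correlations.

    For each candidate K >= v a K-factor oblimin solution is simplified to v
    loadings per row and scored; the suggestion is the K with the highest
    index.  Extraction failures skip that K.
    """
    if corr is None:
        if responses is None:
            raise ValueError("need responses or a correlation matrix")
        corr = tetrachoric_matrix(responses)
    R = corr.values if isinstance(corr, TetrachoricMatrix) else np.asarray(corr, float)
    J = R.shape[0]
    curve: dict[int, float] = {}
    for K in range(v, min(max_K, J - 1) + 1):
        try:
            loadings, Phi = efa(R, K)
            curve[K] = vss_index(R, loadings, Phi, v)
        except (np.linalg.LinAlgError, RuntimeError):
            continue
    if not curve:
        raise RuntimeError("factor extraction failed for every candidate K")
    khat = max(curve, key=curve.get)
    return DimSuggestion(method=f"VSS{v}", khat=int(khat), curve={"vss": curve})


def conditional_covariances(
    responses: np.ndarray, conditioning: str = "total"
) -> np.ndarray:
    """Conditional covariance of every item pair given the raw score.

    ``conditioning='total'`` stratifies on the raw total score (all items,
    the literal reading and what the standard implementation does: its small
    negative bias is part of the method's documented overestimation
    behaviour); ``'rest'`` stratifies on the total minus the pair, which
    removes that bias.  Within each score stratum with at least two
    observations the sample covariance is taken; strata are pooled with
    frequency weights.
    """
    X = np.asarray(responses, dtype=np.int64)
    N, J = X.shape
    if J < 2:
        raise ValueError("need at least two items")
    if conditioning not in ("total", "rest"):
        raise ValueError("conditioning must be 'total' or 'rest'")
    T = X.sum(axis=1)
    C = np.zeros((J, J))
    nbins = J + 1
    if conditioning == "total":
        n_tot = np.bincount(T, minlength=nbins)
        s_tot = np.stack(
            [np.bincount(T, weights=X[:, j], minlength=nbins) for j in range(J)]
        )
    for j in range(J):
        xj = X[:, j]
        Tj = T - xj
        for jp in range(j + 1, J):
            xk = X[:, jp]
            if conditioning == "total":
                r = T
                n, sj, sk = n_tot, s_tot[j], s_tot[jp]
            else:
                r = Tj - xk
                n = np.bincount(r, minlength=nbins)
                sj = np.bincount(r, weights=xj, minlength=nbins)
                sk = np.bincount(r, weights=xk, minlength=nbins)
            sjk = np.bincount(r, weights=(xj & xk), minlength=nbins)
            m = n >= 2
            if not m.any():
                continue
            nm = n[m]
            cov = sjk[m] / nm - (sj[m] / nm) * (sk[m] / nm)
            C[j, jp] = C[jp, j] = float(np.average(cov, weights=nm))
    return C


def detect_index(C: np.ndarray, clusters: np.ndarray, center: bool = False) -> float:
    """DETECT index of one partition.

    Mean over item pairs of ``(-1)**c * C_jj'`` where c is 0 for
    within-cluster pairs and 1 for between-cluster pairs; ``center=True``
    subtracts the average conditional covariance from every pair first (the
    centred estimator variant of the index).
    """
    J = C.shape[0]
    iu = np.triu_indices(J, k=1)
    vals = C[iu]
    cbar = vals.mean() if center else 0.0
    same = (clusters[iu[0]] == clusters[iu[1]]).astype(float)
    sign = np.where(same == 1.0, 1.0, -1.0)
    return float((sign * (vals - cbar)).mean())


def detect(
    responses: np.ndarray,
    max_K: int = DEFAULT_MAX_K,
    conditioning: str = "total",
    center: bool = False,
) -> DimSuggestion:
    """DETECT: conditional-covariance index maximised over Ward partitions.

    Items are Ward-clustered on the conditional-covariance dissimilarity;
    the index is evaluated on the nested partitions with 1..max_K clusters
    and the argmax is the suggested dimensionality.  The defaults (total
    raw-score conditioning, uncentred index) match the behaviour of the
    standard exploratory implementation, including its overestimation
    tendency on multidimensional diagnostic data.
    """
    C = conditional_covariances(responses, conditioning=conditioning)
    J = C.shape[0]
    dissim = C.max() - C
    np.fill_diagonal(dissim, 0.0)
    dissim = np.maximum(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="ward")
    curve = {}
    partitions = {}
    for k in range(1, min(max_K, J) + 1):
        clusters = fcluster(Z, t=k, criterion="maxclust")
        curve[k] = detect_index(C, clusters, center=center)
        partitions[k] = clusters
    khat = max(curve, key=curve.get)
    return DimSuggestion(
        method="DETECT",
        khat=int(khat),
        curve={"detect": curve, "clusters": partitions[khat]},
    )


def ekc(
    corr: TetrachoricMatrix | np.ndarray,
    N: int,
    max_K: int | None = None,
) -> DimSuggestion:
    """Empirical Kaiser criterion.

    Reference eigenvalues follow the Marchenko-Pastur null edge
    ``(1 + sqrt(J/N))**2`` scaled by the variance left after the preceding
    sample eigenvalues, and are coerced to at least 1.  The suggestion is
    the leading run of sample eigenvalues above their references.
    """
    R = corr.values if isinstance(corr, TetrachoricMatrix) else np.asarray(corr, float)
    J = R.shape[0]
    if N <= J:
        import warnings

        warnings.warn("EKC references are asymptotic; N <= J is outside their remit")
    sample = sample_eigenvalues(R)
    edge = (1.0 + np.sqrt(J / N)) ** 2
    refs = np.empty(J)
    cum = 0.0
    for k in range(J):
        refs[k] = max(1.0, (J - cum) / (J - k) * edge)
        cum += sample[k]
    khat = leading_count(sample, refs)
    if max_K is not None:
        khat = min(khat, max_K)
    return DimSuggestion(method="EKC", khat=khat, curve={"sample": sample, "reference": refs})


def assess_dimensionality(
    responses: np.ndarray,
    methods: tuple[str, ...] = ("PA_rm",),
    rng: np.random.Generator | int | None = None,
    model: str = "GDINA",
    max_K: int = DEFAULT_MAX_K,
) -> dict[str, DimSuggestion]:
    """Apply a subset of methods to one response matrix.

    Method ids: PA_rm, PA_r95, PA_pm, PA_p95, MAP, VSS1, VSS2, DETECT, EKC,
    MC_AIC, MC_BIC, MC_r.  Tetrachoric-based methods share one correlation
    matrix; MC variants fit CDMs under ``model``.
    """
    from .model_compare import mc_select

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = np.asarray(responses)
    out: dict[str, DimSuggestion] = {}
    tet: TetrachoricMatrix | None = None

    def tet_corr() -> TetrachoricMatrix:
        nonlocal tet
        if tet is None:
            tet = tetrachoric_matrix(X)
        return tet

    for mid in methods:
        if mid.startswith("PA_"):
            tag = mid[3:]
            corr_type = "pearson" if tag[0] == "r" else "tetrachoric"
            criterion = "mean" if tag[1:] == "m" else "p95"
            out[mid] = parallel_analysis(X, corr_type, criterion, rng=rng)
        elif mid == "MAP":
            out[mid] = map_velicer(tet_corr(), max_K=max_K)
        elif mid in ("VSS1", "VSS2"):
            out[mid] = vss(None, v=int(mid[-1]), max_K=max_K, corr=tet_corr())
        elif mid == "DETECT":
            out[mid] = detect(X, max_K=max_K)
        elif mid == "EKC":
            out[mid] = ekc(tet_corr(), N=X.shape[0])
        elif mid in ("MC_AIC", "MC_BIC", "MC_r"):
            index = mid.split("_")[1].lower()
            out[mid] = mc_select(X, model=model, index=index, kmax=max_K)[0]
        else:
            raise ValueError(f"unknown method id: {mid}")
    return out
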