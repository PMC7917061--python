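"""Synthetic CDM data generation under a fully crossed factorial design.

The generator emulates a Monte-Carlo study design for cognitive diagnosis
data: examinee attribute profiles come from a thresholded equicorrelated
multivariate normal, Q-matrices are random under identifiability constraints,
item parameters are drawn from item-quality uniform bands with a
monotonicity constraint, and responses are Bernoulli under the DINA or
G-DINA model.

Design factors (fully crossed, 972 conditions):

======================  =====================
number of attributes K  4, 5, 6
item quality IQ         0.40, 0.60, 0.80
sample size N           500, 1000, 2000
items per attribute JK  4, 8
attribute correlation   0, 0.30, 0.60
attribute thresholds    0, 0.50, 1
generating model M      DINA, G-DINA
======================  =====================
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ItemParams, QMatrix, validate_responses

__all__ = [
    "FACTOR_LEVELS",
    "SimCondition",
    "GeneratedDataset",
    "design_conditions",
    "gen_qmatrix",
    "gen_attribute_profiles",
    "gen_item_params",
    "gen_responses",
    "generate_dataset",
    "check_qmatrix_constraints",
    "save_dataset",
    "load_dataset",
]

FACTOR_LEVELS: dict[str, tuple] = {
    "K": (4, 5, 6),
    "IQ": (0.40, 0.60, 0.80),
    "N": (500, 1000, 2000),
    "JK": (4, 8),
    "AC": (0.0, 0.30, 0.60),
    "AT": (0.0, 0.50, 1.0),
    "M": ("DINA", "GDINA"),
}

# item-quality bands: IQ -> (P(0) low, P(0) high, P(1) low, P(1) high)
IQ_BANDS: dict[float, tuple[float, float, float, float]] = {
    0.80: (0.00, 0.20, 0.80, 1.00),
    0.60: (0.10, 0.30, 0.70, 0.90),
    0.40: (0.20, 0.40, 0.60, 0.80),
}

DELTA_SUM_MIN = 0.15  # per-attribute sum of delta terms must exceed this


class QMatrixGenerationError(RuntimeError):
    """Constraint satisfaction failed within the retry budget."""


@dataclass(frozen=True)
class SimCondition:
    """One cell of the factorial design."""

    K: int
    IQ: float
    N: int
    JK: int
    AC: float
    AT: float
    M: str

    def __post_init__(self) -> None:
        if self.M not in ("DINA", "GDINA"):
            raise ValueError("M must be 'DINA' or 'GDINA'")

    @property
    def J(self) -> int:
        return self.JK * self.K

    def label(self) -> str:
        return (
            f"K{self.K}_IQ{self.IQ:.2f}_N{self.N}_JK{self.JK}"
            f"_AC{self.AC:.2f}_AT{self.AT:.2f}_{self.M}"
        )


@dataclass
class GeneratedDataset:
    """A simulated dataset bundle: truth plus observed responses."""

    condition: SimCondition
    Q_true: QMatrix
    params_true: ItemParams
    profiles_true: np.ndarray  # (N, K) binary
    responses: np.ndarray  # (N, J) binary
    seed: int | None = None


def design_conditions(levels: dict[str, tuple] | None = None) -> list[SimCondition]:
    """Fully crossed design; the default levels give 972 conditions."""
    lv = dict(FACTOR_LEVELS)
    if levels:
        lv.update(levels)
    order = ("K", "IQ", "N", "JK", "AC", "AT", "M")
    return [
        SimCondition(**dict(zip(order, combo)))
        for combo in itertools.product(*(lv[f] for f in order))
    ]


def _complexity_counts(J: int, K: int) -> tuple[int, int, int]:
    """Items measuring 1, 2 and 3 attributes: proportions 0.50/0.40/0.10 of J.

    Largest-remainder rounding, with the one-attribute count never below 2K
    (room for the two embedded identity blocks).
    """
    props = np.array([0.50, 0.40, 0.10])
    raw = J * props
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for idx in np.argsort(-remainder)[: J - counts.sum()]:
        counts[idx] += 1
    if counts[0] < 2 * K:
        deficit = 2 * K - counts[0]
        counts[0] = 2 * K
        for idx in (1, 2):
            take = min(deficit, counts[idx] - 0)
            counts[idx] -= take
            deficit -= take
            if deficit == 0:
                break
    if counts.sum() != J:
        raise ValueError(f"cannot allocate complexity counts for J={J}, K={K}")
    return tuple(int(c) for c in counts)


def check_qmatrix_constraints(Q: QMatrix, max_col_corr: float = 0.50) -> dict:
    """Independent checker for the four generator constraints.

    Returns a dict of booleans: two identity blocks embedded, every attribute
    measured by an extra item beyond them, all pairwise column correlations
    below the cutoff, and complexity proportions matching the rounding rule.
    """
    arr = Q.entries
    J, K = arr.shape
    row_sums = arr.sum(axis=1)
    single = arr[row_sums == 1]
    unit_counts = np.array([(single == np.eye(K, dtype=np.int8)[k]).all(1).sum() for k in range(K)])
    two_identity = bool((unit_counts >= 2).all())
    # beyond the two identity blocks, each attribute appears in >= 1 more row
    extra = arr.sum(axis=0) - np.minimum(unit_counts, 2)
    extra_measurement = bool((extra >= 1).all())
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr.T)
    off = corr[~np.eye(K, dtype=bool)]
    col_corr_ok = bool(np.nanmax(np.abs(off)) < max_col_corr)
    counts = _complexity_counts(J, K)
    complexity_ok = tuple(int((row_sums == m).sum()) for m in (1, 2, 3)) == counts
    return {
        "two_identity_blocks": two_identity,
        "extra_measurement": extra_measurement,
        "column_correlation": col_corr_ok,
        "complexity_proportions": complexity_ok,
        "all": two_identity and extra_measurement and col_corr_ok and complexity_ok,
    }


def attribute_thresholds(K: int, AT: float) -> np.ndarray:
    """Equidistant attribute mastery thresholds from -AT to AT (length K)."""
    if AT < 0:
        raise ValueError("attribute threshold spread must be nonnegative")
    return np.zeros(1) if K == 1 else np.linspace(-AT, AT, K)


def gen_qmatrix(
    K: int,
    JK: int,
    rng: np.random.Generator,
    max_tries: int = 5000,
) -> QMatrix:
    """Random Q-matrix with J = JK*K rows satisfying the generator constraints.

    (a) at least two embedded K x K identity blocks; (b) each attribute
    measured by at least one further item; (c) all pairwise column Pearson
    correlations below 0.50; (d) one/two/three-attribute item proportions
    0.50/0.40/0.10 of J (rounded).  Rows are shuffled, so the identity blocks
    sit at random positions.
    """
    J = JK * K
    if K < 3:
        raise ValueError("complexity proportions need at least three attributes")
    n1, n2, n3 = _complexity_counts(J, K)
    if n1 < 2 * K:
        raise ValueError("design too small to embed two identity blocks")
    for _ in range(max_tries):
        rows = []
        rows.extend(np.eye(K, dtype=np.int8))
        rows.extend(np.eye(K, dtype=np.int8))
        for _ in range(n1 - 2 * K):
            r = np.zeros(K, dtype=np.int8)
            r[rng.integers(K)] = 1
            rows.append(r)
        for _ in range(n2):
            r = np.zeros(K, dtype=np.int8)
            r[rng.choice(K, size=2, replace=False)] = 1
            rows.append(r)
        for _ in range(n3):
            r = np.zeros(K, dtype=np.int8)
            r[rng.choice(K, size=3, replace=False)] = 1
            rows.append(r)
        arr = np.array(rows, dtype=np.int8)
        # constraint (b): each attribute in >= 1 row beyond the identity blocks
        if (arr[2 * K :].sum(axis=0) < 1).any():
            continue
        corr = np.corrcoef(arr.T)
        if np.abs(corr[~np.eye(K, dtype=bool)]).max() >= 0.50:
            continue
        arr = arr[rng.permutation(J)]
        return QMatrix(arr)
    raise QMatrixGenerationError(
        f"no admissible Q-matrix for K={K}, JK={JK} in {max_tries} tries"
    )


def gen_attribute_profiles(
    N: int,
    K: int,
    AC: float,
    AT: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """N x K binary profiles from a thresholded equicorrelated MVN.

    Latent draws come from MVN(0, Sigma) with unit variances and all
    off-diagonal correlations AC; attribute k is mastered iff the draw
    exceeds threshold k, the thresholds forming an equidistant sequence from
    -AT to AT (so roughly half the attributes are easier, half harder).
    """
    if not 0.0 <= AC < 1.0:
        raise ValueError("attribute correlation must lie in [0, 1)")
    if AT < 0:
        raise ValueError("attribute threshold spread must be nonnegative")
    # equicorrelated MVN via a shared standard-normal factor
    g = rng.standard_normal((N, 1))
    e = rng.standard_normal((N, K))
    z = np.sqrt(AC) * g + np.sqrt(1.0 - AC) * e
    return (z > attribute_thresholds(K, AT)).astype(np.int8)


def _gdina_item_probs(
    kstar: int,
    p0: float,
    p1: float,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Reduced probability table for a multi-attribute G-DINA item.

    Intermediate group probabilities are uniform between P(0) and P(1),
    redrawn until (i) the mean success is non-decreasing in the number of
    mastered attributes and (ii) the sum of the delta terms involving each
    attribute — which telescopes to P(1) minus the all-but-that-attribute
    probability — exceeds 0.15.
    """
    n = 2**kstar
    masks = np.arange(n)
    popcount = np.array([bin(m).count("1") for m in masks])
    full = n - 1
    inter = (popcount > 0) & (popcount < kstar)
    n_inter = int(inter.sum())
    batch = 256
    tries = 0
    while tries < max_tries:
        draws = rng.uniform(p0, p1, size=(batch, n_inter))
        tries += batch
        for row in draws:
            probs = np.empty(n)
            probs[0] = p0
            probs[full] = p1
            probs[inter] = row
            means = [probs[popcount == m].mean() for m in range(kstar + 1)]
            if np.any(np.diff(means) < 0):
                continue
            # per-attribute delta sum: P(1) - P(all but attribute k)
            if any(p1 - probs[full ^ (1 << k)] <= DELTA_SUM_MIN for k in range(kstar)):
                continue
            return probs
    return np.array([])  # signal failure; caller redraws P(0), P(1)


def gen_item_params(
    Q: QMatrix,
    IQ: float,
    model: str,
    rng: np.random.Generator,
    max_outer: int = 200,
) -> ItemParams:
    """Item parameters from the IQ uniform bands.

    ``P(0)`` and ``P(1)`` are uniform in the band for the item-quality level;
    DINA items get ``g = P(0)``, ``s = 1 - P(1)``.  Multi-attribute G-DINA
    items get intermediate group probabilities by rejection sampling under
    monotonicity and the per-attribute delta-sum floor.
    """
    if IQ not in IQ_BANDS:
        raise ValueError(f"item quality must be one of {sorted(IQ_BANDS)}")
    lo0, hi0, lo1, hi1 = IQ_BANDS[IQ]
    probs: list[np.ndarray] = []
    for j in range(Q.J):
        kstar = int(Q.entries[j].sum())
        for attempt in range(max_outer):
            p0 = rng.uniform(lo0, hi0)
            p1 = rng.uniform(lo1, hi1)
            if model == "DINA" or kstar == 1:
                probs.append(np.array([p0, p1]))
                break
            table = _gdina_item_probs(kstar, p0, p1, rng)
            if table.size:
                probs.append(table)
                break
        else:
            raise RuntimeError(
                f"item {j}: could not satisfy G-DINA constraints after {max_outer} redraws"
            )
    return ItemParams(model=model, probs=probs)


def gen_responses(
    profiles: np.ndarray,
    Q: QMatrix,
    params: ItemParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Bernoulli responses with person-item success probabilities
    given by the DINA or G-DINA model."""
    profiles = np.asarray(profiles)
    N = profiles.shape[0]
    P = np.empty((N, Q.J))
    for j in range(Q.J):
        req = np.flatnonzero(Q.entries[j])
        sub = profiles[:, req]
        if params.model == "DINA":
            lab = sub.all(axis=1).astype(np.intp)
        else:
            lab = (sub * (1 << np.arange(len(req)))).sum(axis=1).astype(np.intp)
        P[:, j] = params.probs[j][lab]
    return (rng.random((N, Q.J)) < P).astype(np.int8)


def generate_dataset(
    condition: SimCondition,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> GeneratedDataset:
    """Generate one complete dataset for a design condition.

    The same seed always reproduces the same bundle bit-for-bit.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
        seed_val = None
    else:
        rng = np.random.default_rng(seed)
        seed_val = seed if isinstance(seed, int) else None
    Q = gen_qmatrix(condition.K, condition.JK, rng)
    params = gen_item_params(Q, condition.IQ, condition.M, rng)
    profiles = gen_attribute_profiles(
        condition.N, condition.K, condition.AC, condition.AT, rng
    )
    responses = gen_responses(profiles, Q, params, rng)
    return GeneratedDataset(
        condition=condition,
        Q_true=Q,
        params_true=params,
        profiles_true=profiles,
        responses=responses,
        seed=seed_val,
    )


def save_dataset(ds: GeneratedDataset, path: str | Path) -> None:
    """Write a dataset bundle as a directory of CSVs plus JSON metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    J, K = ds.Q_true.J, ds.Q_true.K
    pd.DataFrame(
        ds.responses, columns=[f"item{j+1}" for j in range(J)]
    ).to_csv(path / "responses.csv", index=False)
    pd.DataFrame(
        ds.Q_true.entries, columns=[f"attr{k+1}" for k in range(K)]
    ).to_csv(path / "qmatrix.csv", index=False)
    pd.DataFrame(
        ds.profiles_true, columns=[f"attr{k+1}" for k in range(K)]
    ).to_csv(path / "profiles.csv", index=False)
    meta = {
        "condition": vars(ds.condition) | {"J": ds.condition.J},
        "model": ds.params_true.model,
        "item_probs": [p.tolist() for p in ds.params_true.probs],
        "seed": ds.seed,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def load_dataset(path: str | Path) -> GeneratedDataset:
    """Load a dataset bundle written by :func:`save_dataset`."""
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    cond_fields = {k: meta["condition"][k] for k in ("K", "IQ", "N", "JK", "AC", "AT", "M")}
    condition = SimCondition(**cond_fields)
    responses = validate_responses(
        pd.read_csv(path / "responses.csv").to_numpy()
    )
    Q = QMatrix(pd.read_csv(path / "qmatrix.csv").to_numpy())
    profiles = pd.read_csv(path / "profiles.csv").to_numpy().astype(np.int8)
    params = ItemParams(
        model=meta["model"], probs=[np.asarray(p) for p in meta["item_probs"]]
    )
    return GeneratedDataset(
        condition=condition,
        Q_true=Q,
        params_true=params,
        profiles_true=profiles,
        responses=responses,
        seed=meta.get("seed"),
    )
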