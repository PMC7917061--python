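"""Monte-Carlo study harness: run conditions, score suggestions, summarise.

The harness generates datasets over a (possibly subsetted) factorial
design, applies a chosen set of dimensionality methods to each, and logs a
tidy suggestion table keyed by condition factors, replicate and method.
Metrics follow the usual simulation-study conventions:

* ``HR``   — hit rate, proportion of replicates with the suggested count
  equal to the generating count;
* ``CHR``  — close hit rate, suggestion within one attribute;
* ``ME``   — mean error (bias) of the suggestion;
* ``RMSE`` — root mean squared error;
* ``AR`` / ``AHR`` — agreement rate between methods and the hit rate
  conditional on agreement;
* ``QRR``  — Q-matrix recovery rate for the estimation/validation stages.

Per-dataset RNG streams are spawned from the master seed so results are
identical regardless of worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dim_methods import assess_dimensionality
from .qmatrix_tools import dfl_estimate, hull_validate, qrr
from .core import fit_em
from .simulate import SimCondition, design_conditions, generate_dataset
from .tetrachoric import tetrachoric_matrix

logger = logging.getLogger(__name__)

FACTOR_COLUMNS = ("K", "IQ", "N", "JK", "AC", "AT", "M")

__all__ = [
    "StudyConfig",
    "hit_metrics",
    "agreement_metrics",
    "partial_eta_squared",
    "EffectSummary",
    "run_study",
    "summarize_overall",
    "summarize_by_factor",
    "agreement_table",
    "qmatrix_recovery_study",
    "stratified_subset",
]


def hit_metrics(khat: list[int] | np.ndarray, K: int | np.ndarray) -> dict[str, float]:
    """HR, CHR, ME and RMSE of a vector of suggested counts.

    ``K`` may be a scalar (one condition) or a matching vector (pooled
    across conditions).
    """
    khat = np.asarray(khat, dtype=float)
    if khat.size == 0:
        raise ValueError("need at least one suggestion")
    K = np.broadcast_to(np.asarray(K, dtype=float), khat.shape)
    err = khat - K
    return {
        "HR": float((err == 0).mean()),
        "CHR": float((np.abs(err) <= 1).mean()),
        "ME": float(err.mean()),
        "RMSE": float(np.sqrt((err**2).mean())),
    }


def agreement_metrics(
    k1: list[int] | np.ndarray,
    k2: list[int] | np.ndarray,
    K: int | np.ndarray,
) -> dict[str, float]:
    """Agreement rate and agreement hit rate of two methods.

    ``AHR`` is the hit rate among replicates where both methods agree; when
    they never agree it is returned as NaN (missing).
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if k1.shape != k2.shape:
        raise ValueError("suggestion vectors must have equal length")
    K = np.broadcast_to(np.asarray(K, dtype=float), k1.shape)
    agree = k1 == k2
    ar = float(agree.mean())
    ahr = float((k1[agree] == K[agree]).mean()) if agree.any() else float("nan")
    return {"AR": ar, "AHR": ahr}


@dataclass
class EffectSummary:
    """Partial eta-squared of one factor (or interaction) on an outcome."""

    factor: str
    ss_effect: float
    ss_error: float
    eta_p2: float
    medium: bool  # > 0.060
    large: bool  # > 0.140


def partial_eta_squared(
    table: pd.DataFrame,
    factor: str | tuple[str, str],
    outcome: str,
    covariates: tuple[str, ...] = (),
) -> EffectSummary:
    """Fixed-effects ANOVA partial eta-squared for a factor or a two-way
    interaction: ``SS_effect / (SS_effect + SS_error)``.

    ``covariates`` adds further categorical main effects to the model;
    passing a 2-tuple as ``factor`` tests the interaction on top of both
    main effects.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.copy()
    interaction = isinstance(factor, tuple)
    names = list(factor) if interaction else [factor]
    for name in names + list(covariates):
        if df[name].nunique() < 2:
            raise ValueError(f"factor '{name}' has a single level")
        df[name] = df[name].astype("category")
    if interaction:
        term = f"C({names[0]}):C({names[1]})"
        rhs = [f"C({names[0]})", f"C({names[1]})", term]
    else:
        term = f"C({names[0]})"
        rhs = [term]
    rhs += [f"C({c})" for c in covariates]
    total_ss = float(((df[outcome] - df[outcome].mean()) ** 2).sum())
    if total_ss < 1e-12:  # constant outcome: no effect by definition
        return EffectSummary(
            factor=":".join(names), ss_effect=0.0, ss_error=0.0,
            eta_p2=0.0, medium=False, large=False,
        )
    model = smf.ols(f"{outcome} ~ {' + '.join(rhs)}", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    ss_effect = float(anova.loc[term, "sum_sq"])
    ss_error = float(anova.loc["Residual", "sum_sq"])
    denom = ss_effect + ss_error
    eta = ss_effect / denom if denom > 1e-12 * total_ss else 0.0
    label = ":".join(names)
    return EffectSummary(
        factor=label,
        ss_effect=ss_effect,
        ss_error=ss_error,
        eta_p2=float(eta),
        medium=eta > 0.060,
        large=eta > 0.140,
    )


@dataclass
class StudyConfig:
    """What to simulate and which methods to score.

    ``conditions`` defaults to the full 972-condition crossing; the
    replicate count is deliberately small by default so a desk run stays
    cheap — raise it for precision.
    """

    conditions: list[SimCondition] = field(default_factory=design_conditions)
    replicates: int = 3
    methods: tuple[str, ...] = ("PA_rm",)
    seed: int = 0
    max_K: int = 9
    n_jobs: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(open(path))
        levels = raw.get("factor_levels")
        conditions = design_conditions(levels) if levels is not None else design_conditions()
        return cls(
            conditions=conditions,
            replicates=int(raw.get("replicates", 3)),
            methods=tuple(raw.get("methods", ("PA_rm",))),
            seed=int(raw.get("seed", 0)),
            max_K=int(raw.get("max_K", 9)),
            n_jobs=int(raw.get("n_jobs", 1)),
        )


def _dataset_rngs(seed: int, n_cond: int, reps: int) -> list[list[np.random.SeedSequence]]:
    root = np.random.SeedSequence(seed)
    flat = root.spawn(n_cond * reps)
    return [flat[c * reps : (c + 1) * reps] for c in range(n_cond)]


def _score_one(
    condition: SimCondition,
    rep: int,
    seed_seq: np.random.SeedSequence,
    methods: tuple[str, ...],
    max_K: int,
) -> list[dict]:
    rng = np.random.default_rng(seed_seq)
    ds = generate_dataset(condition, rng)
    rows = []
    base = {f: getattr(condition, f) for f in FACTOR_COLUMNS}
    base["replicate"] = rep
    for mid in methods:
        row = dict(base)
        row["method"] = mid
        try:
            if mid.endswith("_G") and mid.startswith("MC_"):
                from .model_compare import mc_select

                index = mid.split("_")[1].lower()
                sugg, _, _ = mc_select(
                    ds.responses,
                    model=condition.M,
                    index=index,
                    kmax=max_K,
                    Q_extra={condition.K: ds.Q_true},
                )
                row["khat"] = sugg.khat
            else:
                sugg = assess_dimensionality(
                    ds.responses,
                    methods=(mid,),
                    rng=rng,
                    model=condition.M,
                    max_K=max_K,
                )[mid]
                row["khat"] = sugg.khat
            row["failed"] = False
        except Exception as exc:  # failures recorded, not fatal
            logger.warning(
                "%s failed on %s rep %d: %s", mid, condition.label(), rep, exc
            )
            row["khat"] = np.nan
            row["failed"] = True
        rows.append(row)
    return rows


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the study and return the tidy per-dataset suggestion log.

    Columns: the seven design factors, replicate, method, khat, failed.
    Deterministic under the master seed; datasets are independent work
    units, so the result does not depend on the worker count.
    """
    seqs = _dataset_rngs(config.seed, len(config.conditions), config.replicates)
    tasks = [
        (cond, rep, seqs[c][rep])
        for c, cond in enumerate(config.conditions)
        for rep in range(config.replicates)
    ]
    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=config.n_jobs)(
            delayed(_score_one)(cond, rep, sq, config.methods, config.max_K)
            for cond, rep, sq in tasks
        )
    else:
        chunks = [
            _score_one(cond, rep, sq, config.methods, config.max_K)
            for cond, rep, sq in tasks
        ]
    rows = [row for chunk in chunks for row in chunk]
    return pd.DataFrame(rows)


def _valid(log: pd.DataFrame) -> pd.DataFrame:
    return log[~log["failed"] & log["khat"].notna()]


def summarize_overall(log: pd.DataFrame) -> pd.DataFrame:
    """Per-method overall HR/CHR/ME/RMSE (failures excluded, counts shown)."""
    out = []
    for mid, grp in _valid(log).groupby("method"):
        m = hit_metrics(grp["khat"].to_numpy(), grp["K"].to_numpy())
        n_fail = int(log[(log["method"] == mid) & log["failed"]].shape[0])
        out.append({"method": mid, **m, "R": len(grp), "failures": n_fail})
    return pd.DataFrame(out).set_index("method")


def summarize_by_factor(log: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Per-method HR/CHR/ME/RMSE split by one design factor's levels."""
    out = []
    for (mid, level), grp in _valid(log).groupby(["method", factor]):
        m = hit_metrics(grp["khat"].to_numpy(), grp["K"].to_numpy())
        out.append({"method": mid, factor: level, **m, "R": len(grp)})
    return pd.DataFrame(out).set_index(["method", factor])


def agreement_table(log: pd.DataFrame, methods: tuple[str, ...]) -> pd.DataFrame:
    """Pairwise AR / AHR over datasets where both methods produced answers."""
    wide = _valid(log).pivot_table(
        index=[*FACTOR_COLUMNS, "replicate"], columns="method", values="khat"
    )
    out = []
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            if m1 not in wide.columns or m2 not in wide.columns:
                continue
            sub = wide[[m1, m2]].dropna()
            K = sub.index.get_level_values("K").to_numpy(dtype=float)
            am = agreement_metrics(sub[m1].to_numpy(), sub[m2].to_numpy(), K)
            out.append({"method1": m1, "method2": m2, **am, "R": len(sub)})
    return pd.DataFrame(out)


def stratified_subset(
    conditions: list[SimCondition],
    fraction: float,
    seed: int = 0,
) -> list[SimCondition]:
    """Deterministic stratified subset of a condition list.

    Conditions are taken at a regular stride after a seeded shuffle, which
    balances all factors to within one condition per level.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(conditions))
    step = max(1, round(1 / fraction))
    return [conditions[i] for i in sorted(order[::step])]


def qmatrix_recovery_study(
    conditions: list[SimCondition],
    replicates: int = 1,
    seed: int = 0,
    hull: bool = True,
) -> pd.DataFrame:
    """Q-matrix recovery rates of DFL (and optionally DFL + Hull) at the
    generating K, one row per dataset."""
    seqs = _dataset_rngs(seed, len(conditions), replicates)
    rows = []
    for c, cond in enumerate(conditions):
        for rep in range(replicates):
            rng = np.random.default_rng(seqs[c][rep])
            ds = generate_dataset(cond, rng)
            row = {f: getattr(cond, f) for f in FACTOR_COLUMNS}
            row["replicate"] = rep
            try:
                tet = tetrachoric_matrix(ds.responses)
                Q_est = dfl_estimate(None, cond.K, corr=tet)
                row["qrr_dfl"], _ = qrr(Q_est, ds.Q_true)
                if hull:
                    fit0 = fit_em(ds.responses, Q_est, model=cond.M)
                    Q_val = hull_validate(ds.responses, Q_est, model=cond.M, fit=fit0)
                    row["qrr_hull"], _ = qrr(Q_val, ds.Q_true)
                row["failed"] = False
            except Exception as exc:
                logger.warning("QRR failed on %s rep %d: %s", cond.label(), rep, exc)
                row["failed"] = True
            rows.append(row)
    return pd.DataFrame(rows)
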