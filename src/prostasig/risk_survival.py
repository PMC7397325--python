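"""Composite risk stratification and survival analysis.

Implements the four high-risk biomarker rules used to intersect prognostic
calls on a cohort —

* DESNT: a sample is a DESNT cancer when its DESNT admixture proportion
  (gamma) is strictly larger than every other latent signature's gamma;
* NMF1: membership of the poor-prognosis consensus-NMF subgroup (supplied
  as a boolean flag by the subgrouping classifier);
* Prolaris-style cell-cycle score: the mean within-sample z-scored
  expression of the cell-cycle gene set, with the top quartile flagged
  high-risk;
* HES6-signature classifier calls (supplied as a boolean flag) —

and quantifies outcome differences between flag combinations with
Kaplan–Meier curves, log-rank tests, the time at which a stratum reaches
25% cumulative events, and Cox proportional-hazards models with Gleason
score as a covariate.  Time is measured in months to biochemical
recurrence throughout.  Kaplan–Meier, log-rank and Cox fits are delegated
to lifelines (Efron tie handling for Cox).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .errors import ConfigError, DegenerateSampleError, MissingGeneError, SurvivalError
from .expression_io import GeneSet
from .signature_overlap import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "StratificationResult",
    "prolaris_score",
    "prolaris_flag",
    "assign_desnt",
    "combine_flags",
    "km_fit",
    "time_to_event_quantile",
    "logrank_test",
    "cox_ph",
    "stratify_interaction",
]

FLAG_COLUMNS = ("desnt", "nmf1", "prolaris", "hes6")


def prolaris_score(matrix: pd.DataFrame, ccp_genes: GeneSet) -> pd.Series:
    """Mean within-sample z-scored expression of the cell-cycle genes.

    For each sample t, score(t) = mean over present cell-cycle genes of
    (x_gt - mean_t) / sd_t, where mean_t and sd_t run over all genes of the
    sample (n-1 divisor).
    """
    if matrix.shape[0] < 2:
        raise DegenerateSampleError("need at least two genes to z-score a sample")
    present = sorted(ccp_genes.restrict(matrix.index))
    if not present:
        raise MissingGeneError(
            f"no gene of set {ccp_genes.name!r} is present in the matrix"
        )
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    degenerate = sd.index[sd.to_numpy() == 0.0]
    if len(degenerate):
        raise DegenerateSampleError(
            f"sample(s) with zero expression variance: {', '.join(map(str, degenerate[:5]))}"
        )
    z = matrix.loc[present].sub(mean, axis=1).div(sd, axis=1)
    return z.mean(axis=0).rename("prolaris_score")


def prolaris_flag(scores: pd.Series, quantile: float = 0.75) -> pd.Series:
    """Flag the top (1 - quantile) fraction of samples, exactly ceil((1-q)N).

    Boundary ties are resolved by score (descending) then sample ID
    (ascending), so the flagged count is always exact; any tie-break is
    logged.
    """
    if len(scores) < 4:
        raise ConfigError("quartile flagging requires at least 4 samples")
    if not 0.0 < quantile < 1.0:
        raise ConfigError("quantile must lie strictly between 0 and 1")
    n_flag = math.ceil((1.0 - quantile) * len(scores))
    # deterministic: sort by (-score, sample id)
    order = scores.to_frame("s").assign(sid=scores.index.astype(str)) \
        .sort_values(["s", "sid"], ascending=[False, True])
    cutoff_ids = order.index[:n_flag]
    if n_flag < len(scores) and order["s"].iloc[n_flag - 1] == order["s"].iloc[n_flag]:
        logger.info("prolaris_flag: tie at the quartile boundary broken by sample ID order")
    flags = pd.Series(False, index=scores.index, name="prolaris")
    flags.loc[cutoff_ids] = True
    return flags


def assign_desnt(gamma: pd.DataFrame, desnt_column: str = "DESNT") -> pd.Series:
    """DESNT call per sample: the DESNT gamma strictly exceeds all others.

    Ties (including uniform rows) are not DESNT.
    """
    if desnt_column not in gamma.columns:
        raise ConfigError(f"gamma table has no {desnt_column!r} column")
    others = gamma.drop(columns=[desnt_column])
    flag = gamma[desnt_column] > others.max(axis=1)
    return flag.rename("desnt")


def combine_flags(flags: pd.DataFrame, clinical: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tally all 16 combinations of the four high-risk flags.

    Returns one row per combination with the sample count ``n`` and, when a
    clinical table is supplied, the number of recurrence events ``events``
    in that cell.  Cell counts sum to the cohort size by construction.
    """
    missing = [c for c in FLAG_COLUMNS if c not in flags.columns]
    if missing:
        raise ConfigError(f"flags table lacks column(s): {missing}")
    if flags[list(FLAG_COLUMNS)].isna().any().any():
        raise ConfigError("flags must be defined for every sample")
    rows = []
    for combo in itertools.product([False, True], repeat=4):
        mask = np.ones(len(flags), dtype=bool)
        for col, val in zip(FLAG_COLUMNS, combo):
            mask &= flags[col].to_numpy(dtype=bool) == val
        row = dict(zip(FLAG_COLUMNS, combo))
        row["n"] = int(mask.sum())
        if clinical is not None:
            ids = flags.index[mask]
            row["events"] = int(clinical.loc[ids, "event"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SurvivalCurve:
    """Kaplan–Meier product-limit estimate for one group."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""
    timeline: np.ndarray = field(default_factory=lambda: np.array([]))
    survival_at_timeline: np.ndarray = field(default_factory=lambda: np.array([]))


def km_fit(times, events, label: str = "") -> SurvivalCurve:
    """Kaplan–Meier estimate; censored samples leave the risk set after t."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise SurvivalError("cannot fit a survival curve to an empty group")
    if times.shape != events.shape:
        raise SurvivalError("times and events must have equal length")
    if (times < 0).any():
        raise SurvivalError("times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or "KM")
    table = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    has_event = table["observed"] > 0
    event_times = table.index[has_event].to_numpy(dtype=float)
    return SurvivalCurve(
        event_times=event_times,
        survival=surv.loc[table.index[has_event]].to_numpy(dtype=float),
        at_risk=table.loc[has_event, "at_risk"].to_numpy(dtype=int),
        label=label,
        timeline=surv.index.to_numpy(dtype=float),
        survival_at_timeline=surv.to_numpy(dtype=float),
    )


def time_to_event_quantile(curve: SurvivalCurve, q: float = 0.25) -> float:
    """Smallest event time at which survival has dropped to <= 1 - q.

    Returns NaN when the curve never reaches 1 - q (the quantile is
    undefined within follow-up).
    """
    if not 0.0 <= q < 1.0:
        raise ConfigError("q must lie in [0, 1)")
    target = 1.0 - q
    below = curve.survival <= target + 1e-12
    if not below.any():
        return float("nan")
    return float(curve.event_times[np.argmax(below)])


def logrank_test(groups) -> tuple[float, float]:
    """Log-rank chi-square test across >= 2 groups of (times, events)."""
    groups = list(groups)
    if len(groups) < 2 or any(len(np.asarray(t)) == 0 for t, _ in groups):
        raise SurvivalError("log-rank requires at least two non-empty groups")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=int) for _, e in groups])
    if events.sum() == 0:
        raise SurvivalError("log-rank test undefined: no events in any group")
    labels = np.concatenate([np.full(len(np.asarray(t)), i) for i, (t, _) in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def cox_ph(clinical: pd.DataFrame, covariates: pd.DataFrame,
           max_iter: int = 100) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CIs).

    ``clinical`` needs ``time`` and ``event`` columns; ``covariates`` is a
    samples x covariates table sharing the clinical index.  Returns one row
    per covariate: log_hr, hr, ci_lower, ci_upper, se, p.
    """
    cov = covariates.loc[clinical.index]
    if cov.isna().any().any():
        raise ConfigError("covariates contain missing values")
    for col in cov.columns:
        if cov[col].nunique() < 2:
            raise SurvivalError(f"covariate {col!r} is constant")
    if clinical["event"].sum() < 1:
        raise SurvivalError("Cox model requires at least one event")
    df = pd.concat([clinical[["time", "event"]], cov.astype(float)], axis=1)
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event",
                   fit_options={"max_steps": max_iter})
    except ConvergenceError as exc:
        raise SurvivalError(f"Cox partial-likelihood fit did not converge: {exc}") from exc
    summary = fitter.summary
    out = pd.DataFrame({
        "log_hr": summary["coef"],
        "hr": summary["exp(coef)"],
        "ci_lower": np.exp(summary["coef lower 95%"]),
        "ci_upper": np.exp(summary["coef upper 95%"]),
        "se": summary["se(coef)"],
        "p": summary["p"],
    })
    out.index.name = "covariate"
    return out


STRATA = ("neither", "desnt_only", "hes6_only", "both")


@dataclass
class StratificationResult:
    """Composite stratification of a cohort by DESNT and SIG-HES6 calls."""

    strata: pd.Series
    strata_summary: pd.DataFrame
    pairwise_tests: pd.DataFrame
    risk_count_summary: pd.DataFrame
    cox_risk_count: pd.DataFrame | None
    intersections: pd.DataFrame


def _group_summary(groups: dict[str, pd.DataFrame], q: float = 0.25) -> pd.DataFrame:
    rows = []
    for name, sub in groups.items():
        if len(sub) == 0:
            rows.append({"stratum": name, "n": 0, "events": 0, "time_to_25pct_events": float("nan")})
            continue
        curve = km_fit(sub["time"], sub["event"], label=str(name))
        rows.append({
            "stratum": name,
            "n": int(len(sub)),
            "events": int(sub["event"].sum()),
            "time_to_25pct_events": time_to_event_quantile(curve, q=q),
        })
    return pd.DataFrame(rows).set_index("stratum")


def stratify_interaction(flags: pd.DataFrame, clinical: pd.DataFrame,
                         hes6_components: tuple[str, ...] = ("nmf1", "prolaris", "hes6"),
                         ) -> StratificationResult:
    """Cross DESNT with the SIG-HES6 family and compare outcomes.

    Samples fall into four strata: flagged by neither family, by DESNT
    only, by at least one SIG-HES6 component only, or by both.  Pairwise
    log-rank tests between non-empty strata are BH-adjusted; each stratum
    reports its time to 25% events.  A separate breakdown groups samples by
    their total number of positive flags (0-4) and fits a Cox model of that
    count with Gleason score as a covariate (when Gleason is available and
    non-constant).
    """
    missing = [c for c in ("desnt", *hes6_components) if c not in flags.columns]
    if missing:
        raise ConfigError(f"flags table lacks column(s): {missing}")
    flags = flags.loc[clinical.index]
    desnt = flags["desnt"].astype(bool)
    hes6_any = flags[list(hes6_components)].astype(bool).any(axis=1)
    strata = pd.Series(
        np.select(
            [~desnt & ~hes6_any, desnt & ~hes6_any, ~desnt & hes6_any, desnt & hes6_any],
            STRATA,
            default=STRATA[0],
        ),
        index=flags.index,
        name="stratum",
    )
    groups = {name: clinical.loc[strata.index[strata == name]] for name in STRATA}
    summary = _group_summary(groups)

    nonempty = [name for name in STRATA if len(groups[name]) > 0]
    tests = []
    if len(nonempty) < 2:
        logger.info("stratify_interaction: fewer than two non-empty strata; "
                    "pairwise comparisons skipped")
    else:
        for a, b in itertools.combinations(nonempty, 2):
            ga, gb = groups[a], groups[b]
            try:
                stat, p = logrank_test([
                    (ga["time"].to_numpy(), ga["event"].to_numpy()),
                    (gb["time"].to_numpy(), gb["event"].to_numpy()),
                ])
            except SurvivalError:
                stat, p = float("nan"), float("nan")
            tests.append({"a": a, "b": b, "statistic": stat, "p": p})
    pairwise = pd.DataFrame(tests, columns=["a", "b", "statistic", "p"])
    if len(pairwise):
        ok = pairwise["p"].notna()
        pairwise["adj_p"] = np.nan
        if ok.any():
            pairwise.loc[ok, "adj_p"] = bh_adjust(pairwise.loc[ok, "p"])
    else:
        pairwise["adj_p"] = pd.Series(dtype=float)

    n_flags = flags[list(FLAG_COLUMNS)].astype(bool).sum(axis=1)
    count_groups = {str(k): clinical.loc[n_flags.index[n_flags == k]] for k in range(5)}
    risk_count_summary = _group_summary(count_groups)
    risk_count_summary.index.name = "n_positive_flags"

    cox_result = None
    cov = pd.DataFrame({"n_positive_flags": n_flags})
    if "gleason" in clinical.columns and clinical["gleason"].notna().all() \
            and clinical["gleason"].nunique() > 1:
        cov["gleason"] = clinical["gleason"]
    try:
        cox_result = cox_ph(clinical, cov)
    except SurvivalError as exc:
        logger.info("risk-count Cox model skipped: %s", exc)

    intersections = combine_flags(flags[list(FLAG_COLUMNS)], clinical)
    return StratificationResult(
        strata=strata,
        strata_summary=summary,
        pairwise_tests=pairwise,
        risk_count_summary=risk_count_summary,
        cox_risk_count=cox_result,
        intersections=intersections,
    )
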