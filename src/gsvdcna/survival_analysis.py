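"""Survival comparison of patient groups: Kaplan-Meier, log-rank, Cox PH.

Thin, validated layer over lifelines.  Kaplan-Meier curves and medians per
group with the two-sided (unweighted) log-rank test; Cox proportional
hazards with Efron tie handling, Wald 95% confidence intervals, and
Harrell's concordance index, in uni- or bivariate mode.  Medians are the
first time the survival curve drops to 0.5 or below; an unreached median is
reported as NaN and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .errors import DataMismatchError, NumericalError

__all__ = [
    "SurvivalComparison",
    "CoxResult",
    "km_compare",
    "cox_fit",
    "dichotomize",
]


@dataclass
class SurvivalComparison:
    """Per-group KM curves, medians, and the log-rank comparison."""

    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]
    median_difference: float
    logrank_statistic: float
    logrank_p: float
    group_sizes: dict[str, int]
    median_unreached: list[str] = field(default_factory=list)


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs and Harrell concordance."""

    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    concordance: float
    n_events: int
    warnings: list[str] = field(default_factory=list)


def _validate_records(df: pd.DataFrame, time_col: str, event_col: str) -> pd.DataFrame:
    for col in (time_col, event_col):
        if col not in df.columns:
            raise DataMismatchError(f"records lack the column {col!r}")
    sub = df.dropna(subset=[time_col, event_col]).copy()
    if (sub[time_col] < 0).any():
        raise DataMismatchError("survival times must be nonnegative")
    if not set(sub[event_col].unique()) <= {0, 1}:
        raise DataMismatchError("event flags must be 0 (censored) or 1 (death)")
    return sub


def km_compare(
    records: pd.DataFrame,
    group_field: str,
    time_col: str = "survival_months",
    event_col: str = "event",
) -> SurvivalComparison:
    """Kaplan-Meier estimates per group plus a two-sided log-rank test.

    The median difference (for two groups) is the median of the
    second sorted group label minus the first; with an unreached median it
    is NaN and the group is listed in ``median_unreached``.
    """
    df = _validate_records(records, time_col, event_col)
    if group_field not in df.columns:
        raise DataMismatchError(f"records lack the grouping column {group_field!r}")
    groups = sorted(df[group_field].dropna().unique(), key=str)
    if len(groups) < 2:
        raise DataMismatchError(
            f"need at least two nonempty groups in {group_field!r}, got {groups}"
        )
    if df[event_col].sum() == 0:
        raise DataMismatchError("all records are censored; no events to compare")

    curves, medians, sizes, unreached = {}, {}, {}, []
    for g in groups:
        sub = df[df[group_field] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        curves[str(g)] = kmf.survival_function_
        med = kmf.median_survival_time_
        if np.isinf(med):
            medians[str(g)] = float("nan")
            unreached.append(str(g))
        else:
            medians[str(g)] = float(med)
        sizes[str(g)] = len(sub)

    if len(groups) == 2:
        a, b = groups
        res = logrank_test(
            df.loc[df[group_field] == a, time_col],
            df.loc[df[group_field] == b, time_col],
            df.loc[df[group_field] == a, event_col],
            df.loc[df[group_field] == b, event_col],
        )
        diff = medians[str(b)] - medians[str(a)]
    else:
        res = multivariate_logrank_test(df[time_col], df[group_field], df[event_col])
        diff = float("nan")
    if unreached:
        warnings.warn(f"median never reached for group(s) {unreached}; difference flagged NaN")
    return SurvivalComparison(
        curves=curves,
        medians=medians,
        median_difference=float(diff),
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        group_sizes=sizes,
        median_unreached=unreached,
    )


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str] | str,
    time_col: str = "survival_months",
    event_col: str = "event",
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) for one or two covariates.

    Returns per-covariate hazard ratios with Wald 95% CIs and Harrell's
    concordance index.  Non-convergence (e.g. monotone likelihood under
    complete separation) raises :class:`NumericalError` naming the
    covariates.
    """
    if isinstance(covariates, str):
        covariates = [covariates]
    if not 1 <= len(covariates) <= 2:
        raise DataMismatchError("cox_fit supports one or two covariates")
    df = _validate_records(records, time_col, event_col)
    cols = [time_col, event_col] + list(covariates)
    df = df.dropna(subset=cols)[cols].copy()
    for cov in covariates:
        vals = df[cov]
        if not np.issubdtype(vals.dtype, np.number):
            df[cov] = pd.factorize(vals)[0].astype(float)
        if df[cov].nunique() < 2:
            raise DataMismatchError(f"covariate {cov!r} is constant")
    if df[event_col].sum() == 0:
        raise DataMismatchError("all records are censored; the partial likelihood is empty")

    cph = CoxPHFitter()
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col=time_col, event_col=event_col)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            raise NumericalError(
                f"Cox model failed to converge for covariates {covariates}: {exc}"
            ) from exc
    for w in caught:
        msg = str(w.message)
        if "convergence" in msg.lower() or "separation" in msg.lower():
            notes.append(msg.splitlines()[0])

    ci = np.exp(cph.confidence_intervals_)
    return CoxResult(
        hazard_ratios={c: float(np.exp(cph.params_[c])) for c in covariates},
        ci_lower={c: float(ci.loc[c].iloc[0]) for c in covariates},
        ci_upper={c: float(ci.loc[c].iloc[1]) for c in covariates},
        p_values={c: float(cph.summary.loc[c, "p"]) for c in covariates},
        concordance=float(cph.concordance_index_),
        n_events=int(df[event_col].sum()),
        warnings=notes,
    )


def dichotomize(
    records: pd.DataFrame, column: str, cutpoint: float | None = None
) -> pd.Series:
    """Binary indicator: value >= cutpoint (cohort median by default).

    Used for the age comparison analyses; grade is conventionally
    dichotomized as IV vs II-III upstream of this helper.
    """
    vals = pd.to_numeric(records[column], errors="coerce")
    if cutpoint is None:
        cutpoint = float(vals.median())
    return (vals >= cutpoint).astype(int)
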