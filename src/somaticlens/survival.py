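"""Survival stratification: Kaplan-Meier, log-rank, screening, Cox PH.

Endpoints follow the clinical convention: overall survival (OS) is time
from initial treatment to death or last follow-up; disease-free
survival (DFS) is time from initial treatment to first recurrence.
Univariate screening keeps every candidate whose Kaplan-Meier log-rank
p-value is <= 0.2 (boundary inclusive); the retained covariates enter a
multivariate Cox proportional-hazards model with Efron tie handling and
Wald 95% confidence intervals. Estimation is delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "CoxResult",
    "CoxFitError",
    "km_estimate",
    "logrank_test",
    "screen_covariates",
    "cox_fit",
]


class CoxFitError(RuntimeError):
    """Raised when a Cox fit is degenerate (no events, constant or
    completely separating covariate) rather than silently estimated."""


@dataclass(frozen=True)
class CoxResult:
    """Per-covariate hazard ratio with Wald 95% CI."""

    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI does not bracket the hazard ratio")


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if len(t) == 0:
        raise ValueError("no survival records")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    return t


def km_estimate(
    records: pd.DataFrame,
    time_col: str = "dfs_months",
    event_col: str = "dfs_event",
) -> pd.DataFrame:
    """Product-limit survival curve honoring right-censoring.

    Returns a step function as a DataFrame with ``time`` and
    ``survival`` columns; the curve starts at S(0) = 1.
    """
    t = _check_times(records[time_col])
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=records[event_col].astype(bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.values, "survival": sf.iloc[:, 0].values})


def logrank_test(
    records: pd.DataFrame,
    group_col: str,
    time_col: str = "dfs_months",
    event_col: str = "dfs_event",
) -> tuple[float, float]:
    """k-group log-rank chi-square (k-1 df) and its p-value."""
    t = _check_times(records[time_col])
    groups = records[group_col]
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs >= 2 nonempty groups")
    res = multivariate_logrank_test(
        t, groups, records[event_col].astype(bool)
    )
    return float(res.test_statistic), float(res.p_value)


def _is_stratifiable(series: pd.Series, max_levels: int = 6) -> bool:
    if series.dtype == bool or series.dtype == object:
        return series.nunique() <= max_levels
    uniques = series.nunique()
    if np.issubdtype(series.dtype, np.integer):
        return uniques <= max_levels
    return uniques <= max_levels  # floats allowed only with few levels


def screen_covariates(
    records: pd.DataFrame,
    candidates: Sequence[str],
    time_col: str = "dfs_months",
    event_col: str = "dfs_event",
    alpha: float = 0.2,
) -> list[str]:
    """Keep candidates whose KM log-rank p is <= alpha (order preserved).

    Candidates must be binary/categorical; a continuous covariate must
    be dichotomized by the caller first (an explicit cutpoint is
    required, none is guessed here).
    """
    selected = []
    for cand in candidates:
        series = records[cand]
        if not _is_stratifiable(series):
            raise ValueError(
                f"covariate {cand!r} looks continuous; dichotomize it "
                "explicitly before screening"
            )
        _, p = logrank_test(records, cand, time_col=time_col, event_col=event_col)
        if p <= alpha:
            selected.append(cand)
    return selected


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "dfs_months",
    event_col: str = "dfs_event",
) -> dict[str, CoxResult]:
    """Multivariate Cox PH fit (Efron ties), Wald 95% CIs.

    Degenerate inputs — no observed events, a covariate constant across
    samples, or monotone likelihood from complete separation — raise
    :class:`CoxFitError` instead of returning a silent estimate.
    """
    _check_times(records[time_col])
    n_events = int(records[event_col].sum())
    if n_events == 0:
        raise CoxFitError("no observed events; hazard ratios undefined")
    for cov in covariates:
        if records[cov].nunique() <= 1:
            raise CoxFitError(f"covariate {cov!r} is constant; no information")
    df = records[[time_col, event_col, *covariates]].copy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            cph.fit(df, duration_col=time_col, event_col=event_col)
    except (ConvergenceError, ConvergenceWarning) as exc:
        # monotone likelihood / complete separation surfaces here
        raise CoxFitError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    results = {}
    for cov in covariates:
        row = summary.loc[cov]
        results[cov] = CoxResult(
            covariate=cov,
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
            n=len(df),
            n_events=n_events,
        )
    return results
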