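"""Relapse-free survival machinery.

RFS is the time from operation to recurrence; patients without recurrence
are censored at last follow-up.  The module wraps Kaplan-Meier estimation,
the two-group log-rank test and Cox proportional-hazards fits (lifelines,
Efron tie handling), and implements Harrell's concordance index for
comparing prognostic risk scores head-to-head on one cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "CoxResult",
    "ConcordanceResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "concordance_index",
    "compare_signatures",
]


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratio with Wald 95% confidence interval for one covariate."""

    variable: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class ConcordanceResult:
    name: str
    c_index: float
    n_usable_pairs: int


def _check_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in outcomes.columns:
            raise ValueError(f"outcomes table must contain a {col!r} column")
    if (outcomes["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not outcomes["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    return outcomes


def km_estimate(outcomes: pd.DataFrame, groups: Sequence) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves, one per group label.

    Returns a mapping group -> DataFrame with columns ``time`` and
    ``survival`` (step function values; survival starts at 1 and is
    non-increasing).
    """
    outcomes = _check_outcomes(outcomes)
    if len(outcomes) == 0:
        raise ValueError("no samples to estimate survival from")
    groups = pd.Series(list(groups), index=outcomes.index)
    curves: dict[str, pd.DataFrame] = {}
    for label, idx in groups.groupby(groups).groups.items():
        sub = outcomes.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return curves


def logrank_test(outcomes: pd.DataFrame, groups: Sequence) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and its p-value."""
    outcomes = _check_outcomes(outcomes)
    groups = pd.Series(list(groups), index=outcomes.index)
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {len(labels)}")
    a = outcomes.loc[groups == labels[0]]
    b = outcomes.loc[groups == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def _fit_one(df: pd.DataFrame, variables: list[str]) -> list[CoxResult]:
    cph = CoxPHFitter()  # lifelines defaults: Efron handling of tied event times
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df[variables + ["time", "event"]], duration_col="time", event_col="event")
        except Exception as exc:  # convergence failure, singular design, separation
            raise RuntimeError(f"Cox fit failed for variables {variables}: {exc}") from exc
    out = []
    for var in variables:
        row = cph.summary.loc[var]
        out.append(
            CoxResult(
                variable=var,
                hazard_ratio=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
            )
        )
    return out


def cox_fit(
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
    mode: str = "univariate",
    *,
    entry_p: float = 0.05,
    multivariate_variables: Sequence[str] | None = None,
) -> list[CoxResult]:
    """Cox proportional-hazards fits of RFS on clinical covariates.

    ``mode="univariate"`` fits each covariate alone.  ``mode="multivariate"``
    enters the variables whose univariate Wald p-value is below ``entry_p``
    (the conventional stepwise entry rule), unless an explicit
    ``multivariate_variables`` list overrides the rule.  Covariates must be
    numeric (binary indicators or continuous) with no missing values.
    """
    outcomes = _check_outcomes(outcomes)
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values: {bad}")
    df = covariates.join(outcomes[["time", "event"]], how="inner")
    if len(df) != len(covariates):
        raise ValueError("covariates and outcomes must cover the same samples")

    if mode == "univariate":
        results: list[CoxResult] = []
        for var in covariates.columns:
            results.extend(_fit_one(df, [var]))
        return results
    if mode != "multivariate":
        raise ValueError("mode must be 'univariate' or 'multivariate'")

    if multivariate_variables is None:
        uni = cox_fit(covariates, outcomes, "univariate")
        multivariate_variables = [r.variable for r in uni if r.p_value < entry_p]
        if not multivariate_variables:
            raise ValueError(f"no covariate reaches univariate p < {entry_p}")
    return _fit_one(df, list(multivariate_variables))


def concordance_index(risk: Sequence[float], outcomes: pd.DataFrame, name: str = "risk") -> ConcordanceResult:
    """Harrell's concordance index of a risk score for censored survival.

    A pair of samples is usable when the one with the shorter observed time
    had an event; pairs with equal observed times are unusable.  Among
    usable pairs, a pair is concordant when the shorter-surviving sample
    carries the higher risk; ties in risk count one half.  c = 0.5 means an
    uninformative score.
    """
    outcomes = _check_outcomes(outcomes)
    risk = np.asarray(risk, dtype=float)
    if risk.shape[0] != len(outcomes):
        raise ValueError("risk and outcomes must have equal length")
    if not np.isfinite(risk).all():
        raise ValueError("risk scores must be finite")
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy(dtype=int)

    # pair (i, j) usable iff time_i < time_j and event_i == 1
    shorter = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    concordant = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    n_usable = int(shorter.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs (all times tied or no events)")
    score = (shorter & concordant).sum() + 0.5 * (shorter & tied).sum()
    return ConcordanceResult(name=name, c_index=float(score / n_usable), n_usable_pairs=n_usable)


def compare_signatures(risk_table: pd.DataFrame, outcomes: pd.DataFrame) -> list[ConcordanceResult]:
    """Concordance index for several named risk scores on one sample set.

    Each column of ``risk_table`` is a prognostic score (e.g. the TP53
    signature next to externally computed OncotypeDX / Mammaprint / PAM50
    risk scores); all columns are evaluated on the identical samples so the
    c-indices are directly comparable.
    """
    if risk_table.isna().any().any():
        bad = risk_table.columns[risk_table.isna().any()].tolist()
        raise ValueError(f"risk columns contain missing values: {bad}")
    common = risk_table.index.intersection(outcomes.index)
    if len(common) == 0:
        raise ValueError("risk table and outcomes share no samples")
    sub = outcomes.loc[common]
    return [
        concordance_index(risk_table.loc[common, col].to_numpy(), sub, name=str(col))
        for col in risk_table.columns
    ]
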