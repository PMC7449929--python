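"""The GLUT-ratio biomarker and its response and survival analyses.

The GLUT-ratio — GLUT3 (SLC2A3) expression relative to GLUT1 (SLC2A1) — is a
surrogate for the balance between immune-cell and cancer-cell glucose uptake
in a tumor sample.  This module computes the ratio per sample (either as the
plain ratio of log-normalized values or as a z-score difference for cohorts
distributed as z-scores), compares it between immunotherapy response groups
(Mann-Whitney for two groups, Kruskal-Wallis for three), relates its
on-treatment change to the baseline value (waterfall analysis), and tests its
association with progression-free survival (mean-split Kaplan-Meier/log-rank
and univariate Cox regression).

A response cohort is a long-format DataFrame with columns ``patient_id``,
``timepoint`` ("pre"/"on"), ``glut1``, ``glut3``, ``response`` (one of "PD",
"SD", "PR_CR"), ``pfs_time`` and ``event``; each (patient, timepoint) pair is
unique.  Responders are PR_CR patients; PD and SD are nonresponders.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    GlutmeError,
    ParameterError,
    SurvivalModelError,
)
from .stratification import CorrelationResult, pearson

logger = logging.getLogger(__name__)

RESPONSE_CLASSES = ("PD", "SD", "PR_CR")
RESPONDER = "PR_CR"
TIMEPOINTS = ("pre", "on")
COHORT_COLUMNS = ("patient_id", "timepoint", "glut1", "glut3", "response", "pfs_time", "event")

DEFAULT_PSEUDOCOUNT = 1e-6


def validate_response_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the response-cohort schema and invariants; returns the frame."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ParameterError(f"response cohort is missing columns: {missing}")
    if cohort.duplicated(subset=["patient_id", "timepoint"]).any():
        raise ParameterError("duplicate (patient_id, timepoint) rows")
    if not cohort["timepoint"].isin(TIMEPOINTS).all():
        raise ParameterError(f"timepoint must be one of {TIMEPOINTS}")
    if not cohort["response"].isin(RESPONSE_CLASSES).all():
        raise ParameterError(f"response must be one of {RESPONSE_CLASSES}")
    if (cohort["pfs_time"] < 0).any():
        raise ParameterError("pfs_time must be nonnegative")
    return cohort


def glut_ratio(
    cohort: pd.DataFrame,
    mode: str = "ratio",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-sample GLUT-ratio.

    Parameters
    ----------
    cohort
        Long-format response cohort (see module docstring).
    mode
        ``"ratio"`` computes ``(glut3 + pseudocount) / (glut1 + pseudocount)``
        on the expression scale the cohort carries (log-normalized by
        convention).  ``"zdiff"`` computes ``z(glut3) - z(glut1)`` with
        z-scores taken across the samples of the same timepoint — the variant
        used for cohorts distributed only as z-scores.
    pseudocount
        Small positive stabilizer for the ratio mode.

    Returns
    -------
    pandas.DataFrame
        Columns ``patient_id``, ``timepoint``, ``glut_ratio``.
    """
    validate_response_cohort(cohort)
    out = cohort[["patient_id", "timepoint"]].copy()
    if mode == "ratio":
        denom = cohort["glut1"] + pseudocount
        if (denom <= 0).any():
            raise ParameterError("glut1 + pseudocount must be positive in ratio mode")
        out["glut_ratio"] = (cohort["glut3"] + pseudocount) / denom
    elif mode == "zdiff":
        ratio = pd.Series(index=cohort.index, dtype=float)
        for tp, grp in cohort.groupby("timepoint"):
            z1 = stats.zscore(grp["glut1"], ddof=0)
            z3 = stats.zscore(grp["glut3"], ddof=0)
            ratio.loc[grp.index] = z3 - z1
        out["glut_ratio"] = ratio
    else:
        raise ParameterError(f"unknown GLUT-ratio mode {mode!r}")
    return out


def percent_change(pre: float, on: float) -> float:
    """Percent change of the ratio from baseline: ``100 * (on - pre) / pre``."""
    if pre == 0:
        raise DegenerateInputError("baseline ratio is zero; percent change undefined")
    return 100.0 * (on - pre) / pre


@dataclass
class GroupComparison:
    """Rank-test comparison of the ratio across response groups."""

    statistic: float
    p: float
    method: str
    group_sizes: dict[str, int]


_EXACT_MAX_N = 12


def compare_groups(values, groups) -> GroupComparison:
    """Compare the GLUT-ratio between response groups.

    Two groups are compared with the Mann-Whitney U test (exact two-sided p
    when the combined sample is small and tie-free, normal approximation with
    tie correction otherwise); three or more groups with the Kruskal-Wallis H
    test and its chi-square p-value.
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(list(groups))
    if len(values) != len(groups):
        raise ParameterError("values and groups must have equal length")
    level_values = {g: values[(groups == g).to_numpy()] for g in groups.unique()}
    sizes = {g: len(v) for g, v in level_values.items()}
    if any(n < 2 for n in sizes.values()) or len(sizes) < 2:
        raise ParameterError(f"each of >=2 groups needs >=2 observations, got {sizes}")
    if len(sizes) == 2:
        (a, b) = level_values.values()
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) + len(b) <= _EXACT_MAX_N and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupComparison(float(res.statistic), float(res.pvalue), f"mann-whitney-{method}", sizes)
    res = stats.kruskal(*level_values.values())
    return GroupComparison(float(res.statistic), float(res.pvalue), "kruskal-wallis", sizes)


@dataclass
class SurvivalSplit:
    """Mean-split Kaplan-Meier curves and the log-rank test between them."""

    threshold: float
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival
    logrank_statistic: float
    logrank_p: float
    group_sizes: dict[str, int]
    median_survival: dict[str, float]


def km_logrank(ratios, times, events) -> SurvivalSplit:
    """Kaplan-Meier survival split at the cohort-mean GLUT-ratio.

    Patients are divided at the mean (not median) ratio into high
    (ratio > mean) and low groups; product-limit curves are estimated per
    group and compared with the log-rank test.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    ratios = np.asarray(ratios, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not len(ratios) == len(times) == len(events):
        raise ParameterError("ratios, times and events must have equal length")
    if events.sum() == 0:
        raise SurvivalModelError("all observations censored; survival comparison undefined")
    threshold = float(ratios.mean())
    high = ratios > threshold
    sizes = {"high": int(high.sum()), "low": int((~high).sum())}
    if min(sizes.values()) < 2:
        raise ParameterError(f"mean split leaves a group with <2 patients: {sizes}")
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for name, sel in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=name)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[name] = sf
        medians[name] = float(kmf.median_survival_time_)
    lr = logrank_test(times[high], times[~high], events[high], events[~high])
    return SurvivalSplit(
        threshold=threshold,
        curves=curves,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        group_sizes=sizes,
        median_survival=medians,
    )


@dataclass
class CoxResult:
    """Univariate proportional-hazards fit for the GLUT-ratio."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    n: int
    n_events: int


def cox_assoc(ratios, times, events) -> CoxResult:
    """Univariate Cox proportional-hazards association of the ratio with PFS.

    Fits the partial likelihood (Breslow tie handling) with the ratio as the
    single covariate and reports the hazard ratio per unit of the covariate
    with its Wald 95% CI and p-value.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = pd.DataFrame(
        {
            "ratio": np.asarray(ratios, dtype=float),
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=bool),
        }
    )
    if len(df) < 10:
        raise ParameterError("Cox association requires at least 10 patients")
    if df["event"].sum() < 3:
        raise ParameterError("Cox association requires at least 3 events")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # lifelines' CoxPHFitter resolves tied event times with Breslow's method
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise SurvivalModelError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary.loc["ratio"]
    if not np.isfinite([s["coef"], s["se(coef)"]]).all() or abs(s["coef"]) > 50:
        raise SurvivalModelError("monotone likelihood: coefficient estimate diverged")
    return CoxResult(
        hazard_ratio=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p=float(s["p"]),
        coef=float(s["coef"]),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def waterfall_table(
    cohort: pd.DataFrame,
    ratios: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, CorrelationResult]]:
    """Per-patient baseline ratio, on-treatment %change and response class.

    Joins the pre- and on-treatment ratios of every patient sampled at both
    timepoints, computes the percent change from baseline, and correlates the
    baseline ratio with the %change overall and within each response class
    (the waterfall analysis: the on-treatment rise of the GLUT-ratio is
    expected in tumors that start low, except in progressive disease).

    Returns
    -------
    (table, correlations)
        ``table`` has one row per paired patient, sorted by descending
        %change for waterfall plotting; ``correlations`` maps "overall" and
        each response class to a :class:`CorrelationResult`.  Subgroups too
        small or degenerate to correlate are skipped with a warning.
    """
    validate_response_cohort(cohort)
    wide = ratios.pivot(index="patient_id", columns="timepoint", values="glut_ratio")
    if "pre" not in wide.columns or "on" not in wide.columns:
        raise ParameterError("cohort has no paired pre/on patients")
    wide = wide.dropna(subset=["pre", "on"])
    if len(wide) == 0:
        raise ParameterError("cohort has no paired pre/on patients")
    resp = cohort.drop_duplicates("patient_id").set_index("patient_id")["response"]
    table = pd.DataFrame(
        {
            "baseline_ratio": wide["pre"],
            "on_ratio": wide["on"],
            "pct_change": [percent_change(p, o) for p, o in zip(wide["pre"], wide["on"])],
            "response": resp.reindex(wide.index),
        }
    ).sort_values("pct_change", ascending=False)

    correlations: dict[str, CorrelationResult] = {}
    subsets = {"overall": table, **{cls: table[table["response"] == cls] for cls in RESPONSE_CLASSES}}
    for name, sub in subsets.items():
        try:
            correlations[name] = pearson(sub["baseline_ratio"], sub["pct_change"])
        except GlutmeError as exc:
            warnings.warn(f"waterfall correlation skipped for {name}: {exc}", stacklevel=2)
    return table, correlations
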