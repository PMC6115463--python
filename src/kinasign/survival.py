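"""Kaplan–Meier, log-rank and Cox proportional-hazards analysis.

Per-kinase prognostic value is assessed two ways: univariately with the
Kaplan–Meier estimator and log-rank test, and multivariately with a Cox
model adjusting each kinase (or K-high) indicator for tumor stage (T),
nodal status (N), grade (G) and age, with Bonferroni correction across the
kinase tests.  Fitting is delegated to lifelines (Efron handling of tied
event times, damped Newton maximisation of the partial likelihood).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as LLConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .errors import ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

ADJUSTMENT_COVARIATES = ("T", "N", "G", "age")


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None  # None = "not reached"
    label: str = ""

    @property
    def median_label(self) -> str:
        return "not reached" if self.median is None else f"{self.median:g}"


@dataclass
class CoxFit:
    """Cox partial-likelihood fit: one row per covariate.

    ``summary`` columns: ``beta``, ``hr`` (= exp(beta)), ``se``,
    ``p`` (Wald); ``p_adjusted`` is filled by the caller when several
    kinase models are corrected together.
    """

    summary: pd.DataFrame
    n: int
    n_events: int
    log_likelihood: float
    converged: bool = True
    warnings: list = field(default_factory=list)


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times <= 0).any():
        raise ValidationError("survival times must be > 0")
    if not np.isin(events, [0, 1]).all():
        raise ValidationError("events must be 0/1")
    return times, events.astype(int)


def km_fit(times, events, groups=None) -> dict:
    """Kaplan–Meier curves, one per group (single key "" if ungrouped).

    The median is the smallest observed time with S(t) <= 0.5, or None
    ("not reached") when the curve never drops that far.
    """
    times, events = _check_surv(times, events)
    if groups is None:
        groups = np.repeat("", len(times))
    groups = np.asarray(groups)
    out = {}
    for label in pd.unique(groups):
        sel = groups == label
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(label))
        sf = kmf.survival_function_.iloc[:, 0]
        ts = sf.index.to_numpy(float)
        surv = sf.to_numpy(float)
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(float)
        below = np.flatnonzero(surv <= 0.5)
        median = float(ts[below[0]]) if below.size else None
        out[label] = KMCurve(times=ts, survival=surv, at_risk=at_risk,
                             median=median, label=str(label))
    return out


def logrank(times, events, groups) -> tuple:
    """Log-rank test across >= 2 groups; returns (chi-square, p)."""
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValidationError("log-rank needs at least two groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(times, events, covariates: pd.DataFrame) -> CoxFit:
    """Cox proportional-hazards fit of all supplied covariates.

    Covariates typically comprise one kinase (or K-high) indicator plus
    the T / N / G / age adjusters, entered as numeric scores.  Constant
    covariates are rejected; having fewer events than covariates is
    flagged unstable.  Non-convergence (e.g. monotone likelihood under
    perfect separation) raises :class:`ConvergenceError`.
    """
    times, events = _check_surv(times, events)
    covariates = covariates.astype(float)
    constant = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if constant:
        raise ValidationError(f"constant covariates: {constant}")
    warnings = []
    if events.sum() < covariates.shape[1]:
        msg = (f"only {int(events.sum())} events for {covariates.shape[1]} "
               "covariates; estimates unstable")
        logger.warning(msg)
        warnings.append(msg)
    frame = covariates.copy()
    frame["_time"] = times
    frame["_event"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="_time", event_col="_event",
                fit_options={"precision": 1e-9, "max_steps": 500})
    except LLConvergenceError as exc:
        raise ConvergenceError(
            f"Cox partial likelihood did not converge: {exc}"
        ) from exc
    summary = pd.DataFrame({
        "beta": cph.params_,
        "hr": np.exp(cph.params_),
        "se": cph.standard_errors_,
        "p": cph.summary["p"],
    })
    return CoxFit(summary=summary, n=len(times), n_events=int(events.sum()),
                  log_likelihood=float(cph.log_likelihood_),
                  converged=True, warnings=warnings)


def bonferroni(p_list) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p)."""
    p = np.asarray(p_list, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def kinase_survival_report(cohort: pd.DataFrame, indicators: pd.DataFrame,
                           adjusters=ADJUSTMENT_COVARIATES) -> pd.DataFrame:
    """Univariate log-rank + adjusted Cox HR for each kinase indicator.

    ``indicators`` is a patient × variable 0/1 frame (per-kinase status,
    K-high, K-test variables).  Each variable gets its own Cox model with
    the shared adjusters; Wald p-values of the kinase terms are Bonferroni
    corrected across variables.
    """
    rows = []
    for name in indicators.columns:
        ind = indicators[name]
        chi2, p_lr = logrank(cohort["time"], cohort["event"], ind)
        covs = pd.concat([ind, cohort[list(adjusters)]], axis=1)
        fit = cox_fit(cohort["time"], cohort["event"], covs)
        rows.append({
            "variable": name,
            "logrank_chi2": chi2,
            "logrank_p": p_lr,
            "cox_hr": fit.summary.loc[name, "hr"],
            "cox_beta": fit.summary.loc[name, "beta"],
            "cox_se": fit.summary.loc[name, "se"],
            "cox_p": fit.summary.loc[name, "p"],
        })
    report = pd.DataFrame(rows).set_index("variable")
    report["cox_p_bonferroni"] = bonferroni(report["cox_p"].to_numpy())
    return report
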