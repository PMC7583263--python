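"""Survival analysis: Kaplan-Meier, log-rank, time-dependent ROC, Cox.

The time-dependent ROC follows the cumulative-case / dynamic-control
definition with Kaplan-Meier censoring adjustment (the Heagerty-Lumley-Pepe
estimator, "KM" method): at horizon *t* a case is a subject with an event at
or before *t* and a control is a subject still event-free beyond *t*.
Optimal dichotomizing cutoffs maximize the Youden index.  KM curves,
log-rank tests and Cox partial-likelihood fits are delegated to lifelines;
covariates that violate proportional hazards (Schoenfeld-residual test) are
refit with a covariate x log(time) interaction as a time-dependent term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "TdROCCurve",
    "CutoffResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "td_roc",
    "optimal_cutoff",
    "cox_fit",
]


def _check_times(time: np.ndarray) -> None:
    if not np.isfinite(time).all():
        raise ValueError("survival times must be finite")
    if (time < 0).any():
        raise ValueError("survival times must be non-negative")


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    event_times: np.ndarray      # distinct event times, increasing
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray          # risk-set size at each event time
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function lookup of S(t); S(0) = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate; events precede censorings at tied times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one sample")
    _check_times(time)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    ev_times = np.unique(time[event == 1])
    surv = np.array([float(kmf.predict(t)) for t in ev_times])
    at_risk = np.array([(time >= t).sum() for t in ev_times])
    return KMCurve(event_times=ev_times, survival=surv, at_risk=at_risk, n=time.size)


def logrank_test(*groups) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, two-sided p).

    Each group is a ``(time, event)`` pair.  Requires at least two groups
    and at least one event overall.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {i} has zero observations")
        _check_times(t)
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    ev = np.concatenate(events)
    if ev.sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), ev
    )
    return float(res.test_statistic), float(res.p_value)


def _km_surv_at(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """Fast product-limit S(horizon) used inside the ROC estimator."""
    if time.size == 0:
        return 1.0
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    mask = (t <= horizon) & (e == 1)
    if not mask.any():
        return 1.0
    ev_times, counts = np.unique(t[mask], return_counts=True)
    at_risk = time.size - np.searchsorted(t, ev_times, side="left")
    return float(np.prod(1.0 - counts / at_risk))


@dataclass
class TdROCCurve:
    """Time-dependent ROC at one horizon."""

    horizon: float
    thresholds: np.ndarray       # sorted unique score values, ascending
    sensitivity: np.ndarray      # per threshold, cases = events <= horizon
    specificity: np.ndarray
    auc: float
    n_cases_observed: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def td_roc(scores, time, event, horizon: float) -> TdROCCurve:
    """Cumulative/dynamic time-dependent ROC with KM censoring adjustment.

    For threshold *c*, with S the all-sample KM survival and S_c the KM
    survival among subjects scoring above *c*,

        sens(c) = (1 - S_c(t)) * P(score > c) / (1 - S(t))
        spec(c) = 1 - S_c(t) * P(score > c) / S(t)

    Curves are monotonized (running maximum as the threshold falls) before
    the trapezoidal AUC is taken, so sensitivity and 1-specificity are
    non-increasing along ascending thresholds.  With no censoring this
    reduces exactly to the empirical ROC, and the AUC to the Mann-Whitney
    statistic.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (scores.size == time.size == event.size):
        raise ValueError("scores and samples must be aligned")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    _check_times(time)
    n_cases = int(((time <= horizon) & (event == 1)).sum())
    if n_cases == 0:
        raise ValueError("no events at or before the horizon")

    thresholds = np.unique(scores)
    if thresholds.size == 1:
        warnings.warn("constant scores: AUC defined as 0.5", stacklevel=2)
        return TdROCCurve(horizon=horizon, thresholds=thresholds,
                          sensitivity=np.array([0.5]), specificity=np.array([0.5]),
                          auc=0.5, n_cases_observed=n_cases)

    s_all = _km_surv_at(time, event, horizon)
    if s_all >= 1.0:
        raise ValueError("no events at or before the horizon")
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, c in enumerate(thresholds):
        above = scores > c
        p_above = above.mean()
        s_c = _km_surv_at(time[above], event[above], horizon)
        sens[i] = (1.0 - s_c) * p_above / (1.0 - s_all)
        spec[i] = 1.0 - s_c * p_above / s_all
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    # KM-adjusted estimates need not be monotone under heavy censoring;
    # enforce the ROC shape along descending thresholds.
    sens = np.maximum.accumulate(sens[::-1])[::-1]
    spec = np.maximum.accumulate(spec)

    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return TdROCCurve(horizon=horizon, thresholds=thresholds,
                      sensitivity=sens, specificity=spec, auc=auc,
                      n_cases_observed=n_cases)


@dataclass
class CutoffResult:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def optimal_cutoff(curve: TdROCCurve) -> CutoffResult:
    """Cutoff maximizing Youden J = sens + spec - 1.

    Ties are broken toward the smallest cutoff, which maximizes the size of
    the dichotomized High group (scores strictly above the cutoff).
    """
    if curve.thresholds.size == 0:
        raise ValueError("empty threshold set")
    j = curve.sensitivity + curve.specificity - 1.0
    best = int(np.argmax(np.isclose(j, j.max(), atol=1e-12)))
    return CutoffResult(
        cutoff=float(curve.thresholds[best]),
        youden_j=float(j[best]),
        sensitivity=float(curve.sensitivity[best]),
        specificity=float(curve.specificity[best]),
    )


@dataclass
class CoxFit:
    """Cox model summary: one row per term with HR, 95% CI and p."""

    summary: pd.DataFrame        # index = term; columns hr, ci_low, ci_high, p
    n: int
    n_events: int
    time_dependent_terms: list[str] = field(default_factory=list)
    separation_flag: bool = False

    def hazard_ratio(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])


def _tidy_summary(fitted) -> pd.DataFrame:
    s = fitted.summary
    return pd.DataFrame({
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })


def _split_at_event_times(df: pd.DataFrame, time_col: str,
                          event_col: str) -> pd.DataFrame:
    """Counting-process (start, stop] episodes split at distinct event times.

    The risk-set composition at every event time is preserved exactly, so a
    time-fixed model refit on the long format reproduces the short-format
    partial likelihood; time interactions are then added on ``stop``.
    """
    cut_times = np.unique(df.loc[df[event_col] == 1, time_col].to_numpy())
    rows = []
    for sid, rec in enumerate(df.to_dict("records")):
        t = rec[time_col]
        e = rec[event_col]
        stops = cut_times[cut_times < t].tolist() + [t]
        starts = [0.0] + stops[:-1]
        base = {c: v for c, v in rec.items() if c not in (time_col, event_col)}
        for k, (a, b) in enumerate(zip(starts, stops)):
            rows.append({**base, "id": sid, "start": a, "stop": b,
                         event_col: int(e) if k == len(stops) - 1 else 0})
    return pd.DataFrame(rows)


def cox_fit(covariates: pd.DataFrame, time, event,
            check_ph: bool = True, ph_alpha: float = 0.05) -> CoxFit:
    """Cox proportional-hazards fit (Efron tie handling via lifelines).

    When *check_ph* is true, covariates failing the Schoenfeld-residual test
    (p < *ph_alpha*, log-time transform) are re-entered with an additional
    ``x * log(t)`` interaction, i.e. as time-dependent covariates, and the
    model is refit in episodic (start-stop) form.

    Raises
    ------
    ValueError
        If there are fewer events than covariates + 1 (advising a penalized
        or reduced model instead).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_times(time)
    if covariates.shape[1] < 1:
        raise ValueError("need at least one covariate")
    n_events = int(event.sum())
    if n_events < covariates.shape[1] + 1:
        raise ValueError(
            f"only {n_events} events for {covariates.shape[1]} covariates; "
            "use a penalized (Firth-type) or reduced model"
        )
    df = covariates.reset_index(drop=True).copy()
    df["_time"] = np.maximum(time, 1e-9)
    df["_event"] = event

    cph = CoxPHFitter()
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError:
        separation = True
        logger.warning("Cox fit did not converge (possible separation); "
                       "refitting with a small ridge penalty")
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")

    violating: list[str] = []
    if check_ph and not separation:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ph = proportional_hazard_test(cph, df, time_transform="log")
            pvals = ph.summary["p"]
            violating = sorted({t[0] if isinstance(t, tuple) else t
                                for t, p in pvals.items() if p < ph_alpha})
        except Exception:  # degenerate residuals on tiny fixtures
            violating = []

    if not violating:
        summary = _tidy_summary(cph)
        if separation:
            summary.loc[:, ["ci_low", "ci_high"]] = [0.0, np.inf]
        return CoxFit(summary=summary, n=len(df), n_events=n_events,
                      separation_flag=separation)

    # Episodic refit with x*log(t) interactions for the violating terms.
    long = _split_at_event_times(df, "_time", "_event")
    td_terms = []
    for term in violating:
        name = f"{term}:log(t)"
        long[name] = long[term] * np.log(np.maximum(long["stop"], 1e-9))
        td_terms.append(name)
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(long, id_col="id", start_col="start", stop_col="stop",
                event_col="_event")
    return CoxFit(summary=_tidy_summary(ctv), n=len(df), n_events=n_events,
                  time_dependent_terms=td_terms, separation_flag=separation)
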