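"""Kaplan-Meier estimation, log-rank testing and Cox proportional hazards.

The inferential engine for the single-marker and combined-marker survival
analyses: product-limit curves with 5-year overall survival, multi-group
log-rank tests, univariate/multivariate Cox fits (Efron tie handling), and
backward-conditional covariate elimination by likelihood-ratio testing.

Estimation is delegated to lifelines; this module fixes the conventions
(event definition, CI level, elimination rule) and exposes plain containers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import ConvergenceWarning
from scipy import stats

__all__ = [
    "EVENT_DEFINITIONS",
    "events_from_cause",
    "KMCurve",
    "km_curve",
    "survival_at",
    "five_year_os",
    "LogrankResult",
    "logrank_test",
    "CoxFit",
    "CoxError",
    "cox_fit",
    "null_partial_log_likelihood",
    "BackwardStep",
    "BackwardResult",
    "cox_backward_conditional",
]

#: Recognised event definitions.  ``cancer_specific`` treats cancer death as
#: the event and both non-cancer death and alive-at-last-follow-up as
#: censored; ``all_death`` counts any death.
EVENT_DEFINITIONS = ("cancer_specific", "all_death")


def events_from_cause(cause: pd.Series, definition: str = "cancer_specific") -> pd.Series:
    """Map a vital-status/cause column to a boolean event indicator."""
    if definition not in EVENT_DEFINITIONS:
        raise ValueError(f"unknown event definition {definition!r}")
    causes = set(cause.dropna().unique())
    known = {"cancer_death", "noncancer_death", "censored", "alive"}
    unknown = causes - known
    if unknown:
        raise ValueError(f"unknown vital status values: {sorted(unknown)}")
    if definition == "cancer_specific":
        return cause.eq("cancer_death")
    return cause.isin(["cancer_death", "noncancer_death"])


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times.

    The curve is right-continuous and constant between event times; before
    the first event the survival probability is 1.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.event_times) == len(self.survival_prob) == len(self.at_risk)):
            raise ValueError("KM curve arrays must have equal length")
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival_prob) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier curve; ties resolved events-before-censorings."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.size == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    observed = table["observed"].to_numpy()
    mask = observed > 0
    times = table.index.to_numpy(dtype=float)[mask]
    sf = kmf.survival_function_["KM_estimate"]
    surv = np.array([float(sf.loc[tt]) for tt in times])
    at_risk = table["at_risk"].to_numpy()[mask]
    return KMCurve(event_times=times, survival_prob=surv, at_risk=at_risk)


def survival_at(curve: KMCurve, t: float) -> float:
    """Step-function evaluation S(t) of a KM curve (right-continuous)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival_prob[idx])


def five_year_os(curve: KMCurve) -> float:
    """5-year overall survival: 100 x S(60 months)."""
    return 100.0 * survival_at(curve, 60.0)


# ---------------------------------------------------------------------------
# Log-rank


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    p: float


def logrank_test(time, event, group) -> LogrankResult:
    """Multi-group log-rank test across pooled event times."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    g = np.asarray(group)
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if not e.any():
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(t, g, e)
    df = int(labels.size - 1)
    chi2 = float(res.test_statistic)
    return LogrankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# Cox proportional hazards


class CoxError(RuntimeError):
    """Cox partial-likelihood maximisation failed."""


@dataclass(frozen=True)
class CoxFit:
    """One fitted proportional-hazards model.

    ``summary`` has one row per covariate with columns ``coef``, ``se``,
    ``hr``, ``ci_lower``, ``ci_upper`` (95%, Wald, on the HR scale) and
    ``wald_p``.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    warnings: tuple[str, ...] = field(default=())

    @property
    def hr(self) -> pd.Series:
        return self.summary["hr"]

    @property
    def coefficients(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def wald_p(self) -> pd.Series:
        return self.summary["wald_p"]

    @property
    def covariates(self) -> list[str]:
        return list(self.summary.index)


def cox_fit(covariates, time, event) -> CoxFit:
    """Maximise the Cox partial likelihood (Efron ties) and summarise.

    ``covariates`` is a DataFrame (or Series) of numeric per-patient values;
    constant covariates are rejected.  Monotone-likelihood / separation
    warnings from the optimiser are captured on the returned fit rather than
    raised.
    """
    X = covariates.to_frame() if isinstance(covariates, pd.Series) else covariates.copy()
    if X.shape[1] == 0:
        raise ValueError("at least one covariate required")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    for col in X.columns:
        if X[col].nunique(dropna=True) < 2:
            raise ValueError(f"covariate {col!r} is constant")
    n_events = int(e.sum())
    if n_events < X.shape[1] + 1:
        raise ValueError(
            f"{n_events} events cannot support {X.shape[1]} covariates"
        )
    df = X.reset_index(drop=True).astype(float)
    df["_time"] = t
    df["_event"] = e.astype(int)
    cph = CoxPHFitter()
    caught: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always", ConvergenceWarning)
            cph.fit(df, duration_col="_time", event_col="_event")
        caught = [str(w.message) for w in wlist if issubclass(w.category, ConvergenceWarning)]
    except ConvergenceError as err:
        raise CoxError(f"Cox model did not converge: {err}") from err
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "wald_p": s["p"],
        }
    )
    out.index.name = "covariate"
    return CoxFit(
        summary=out,
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(df)),
        n_events=n_events,
        warnings=tuple(caught),
    )


def null_partial_log_likelihood(time, event) -> float:
    """Efron partial log-likelihood of the covariate-free model (beta = 0)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    ll = 0.0
    for tj in np.unique(t[e]):
        nj = int((t >= tj).sum())
        dj = int((e & (t == tj)).sum())
        ll -= sum(math.log(nj - l) for l in range(dj))
    return ll


# ---------------------------------------------------------------------------
# Backward-conditional elimination


@dataclass(frozen=True)
class BackwardStep:
    step: int
    removed: str
    p_removal: float
    remaining: tuple[str, ...]


@dataclass(frozen=True)
class BackwardResult:
    final: CoxFit | None  #: None when every candidate was eliminated
    trace: tuple[BackwardStep, ...]
    retained: tuple[str, ...]


def cox_backward_conditional(
    covariates: pd.DataFrame,
    time,
    event,
    *,
    removal_alpha: float = 0.10,
) -> BackwardResult:
    """Step-wise backward elimination from the full Cox model.

    At each step every remaining covariate is tested by the likelihood-ratio
    test between the current model and the model refit without it; the
    covariate with the largest removal p is dropped if that p >= the stay
    threshold ``removal_alpha`` (default 0.10).  Elimination stops when all
    remaining covariates have removal p below the threshold, or when the
    model is empty.
    """
    remaining = list(covariates.columns)
    if not remaining:
        raise ValueError("no candidate covariates")
    current = cox_fit(covariates[remaining], time, event)  # full model must converge
    null_ll = null_partial_log_likelihood(time, event)
    trace: list[BackwardStep] = []
    step = 0
    while remaining:
        removal_p: dict[str, float] = {}
        for cov in remaining:
            reduced = [c for c in remaining if c != cov]
            ll_reduced = (
                cox_fit(covariates[reduced], time, event).log_likelihood
                if reduced
                else null_ll
            )
            lr = max(0.0, 2.0 * (current.log_likelihood - ll_reduced))
            removal_p[cov] = float(stats.chi2.sf(lr, 1))
        worst = max(removal_p, key=lambda c: (removal_p[c], c))
        if removal_p[worst] < removal_alpha:
            break
        step += 1
        remaining.remove(worst)
        trace.append(
            BackwardStep(
                step=step,
                removed=worst,
                p_removal=removal_p[worst],
                remaining=tuple(remaining),
            )
        )
        current = (
            cox_fit(covariates[remaining], time, event) if remaining else None
        )
        if current is None:
            break
    return BackwardResult(final=current, trace=tuple(trace), retained=tuple(remaining))
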