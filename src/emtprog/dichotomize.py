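"""Survival-driven dichotomization of continuous marker scores.

Each marker/compartment score is split into LOW/HIGH at the cutpoint that
maximises the absolute standardized two-group log-rank statistic over all
admissible observed thresholds (maximally selected log-rank statistics, the
method behind the common biomarker cut-off packages).  LOW means
score <= cutoff; a minimum group-size fraction per arm keeps the scan away
from degenerate extreme splits.

The returned maximal statistic is selection-biased: no correction for having
scanned many candidate thresholds is applied, and downstream p-values for the
dichotomized marker inherit that optimism.  Run reports flag this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CutpointError",
    "CutpointResult",
    "logrank_uv",
    "logrank_z",
    "find_optimal_cutpoint",
    "apply_cutpoint",
]


class CutpointError(ValueError):
    """No admissible cutpoint exists for the given scores/constraints."""


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    max_std_statistic: float
    n_low: int
    n_high: int
    candidates_evaluated: int


def logrank_uv(time, event, in_group) -> tuple[float, float]:
    """Two-group log-rank score U and its hypergeometric variance V.

    U sums, over distinct event times, the observed minus expected events in
    the flagged group; V is the usual conditional (hypergeometric) variance.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    g = np.asarray(in_group, dtype=bool)
    if t.shape != e.shape or t.shape != g.shape:
        raise ValueError("time, event and group must have equal length")
    u = 0.0
    v = 0.0
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        nj = int(at_risk.sum())
        n1j = int((at_risk & g).sum())
        dying = e & (t == tj)
        dj = int(dying.sum())
        d1j = int((dying & g).sum())
        frac = n1j / nj
        u += d1j - dj * frac
        if nj > 1:
            v += dj * frac * (1.0 - frac) * (nj - dj) / (nj - 1)
    return u, v


def logrank_z(time, event, in_group) -> float:
    """Standardized log-rank statistic U/sqrt(V); 0 when V degenerates."""
    u, v = logrank_uv(time, event, in_group)
    if v <= 0:
        return 0.0
    return u / math.sqrt(v)


def find_optimal_cutpoint(
    scores,
    time,
    event,
    *,
    min_prop: float = 0.10,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint.

    Evaluates every distinct observed score value c for which both arms of
    the split LOW = {score <= c} retain at least ``ceil(min_prop * n)``
    patients, computes the standardized two-group log-rank statistic for the
    split, and returns the c with the largest absolute statistic.  Ties in
    the statistic break toward the smallest cutoff; tied scores are never
    split across arms (the threshold is an observed value).

    Only ranks of the scores matter: any strictly monotone transform leaves
    the selected split unchanged.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if not (s.shape == t.shape == e.shape):
        raise ValueError("scores, time and event must have equal length")
    n = s.size
    if n < 10:
        raise CutpointError(f"need >= 10 patients for cutpoint search, got {n}")
    if not e.any():
        raise CutpointError("no events; log-rank cutpoint undefined")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise CutpointError("all scores identical; no cutpoint exists")

    min_arm = math.ceil(min_prop * n)
    best: tuple[float, float] | None = None  # (|z|, cutoff)
    evaluated = 0
    for c in uniq[:-1]:  # the maximum can never be a threshold
        n_low = int((s <= c).sum())
        if n_low < min_arm or (n - n_low) < min_arm:
            continue
        evaluated += 1
        z = abs(logrank_z(t, e, s > c))
        if best is None or z > best[0]:
            best = (z, float(c))
    if best is None:
        raise CutpointError(
            f"no candidate threshold leaves >= {min_arm} patients per arm"
        )
    z_max, cutoff = best
    n_low = int((s <= cutoff).sum())
    return CutpointResult(
        cutoff=cutoff,
        max_std_statistic=z_max,
        n_low=n_low,
        n_high=n - n_low,
        candidates_evaluated=evaluated,
    )


def apply_cutpoint(score: float, cutoff: float) -> str:
    """LOW/HIGH call for a score at a given cutoff (HIGH iff score > cutoff)."""
    return "HIGH" if score > cutoff else "LOW"
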