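"""Immunohistochemistry scoring.

Tumour-cell staining is quantified with the weighted histoscore: the examiner
records, per marker and cellular compartment, the percentage of tumour cells
with no / weak / moderate / strong staining, and the score is

    H = 0·pct_none + 1·pct_weak + 2·pct_moderate + 3·pct_strong,

giving a value between 0 and 300.  Stromal periostin uses a different scheme:
the percentage of positive stromal cells is binned into a grade P in 0–3
(0–25, 26–50, 51–75, 76–100 %) and multiplied by an intensity grade I in 0–3,
giving a P×I score in 0–9.

Scorer agreement between two raters is summarised with the intraclass
correlation coefficient ICC(2,1): two-way random effects, single rater,
absolute agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScoringError",
    "IntensityProfile",
    "Histoscore",
    "PeriostinQuantification",
    "PeriostinScore",
    "compute_histoscore",
    "grade_periostin_percentage",
    "compute_periostin_score",
    "interrater_icc",
    "score_rows",
]

_SUM_TOL = 1e-9


class ScoringError(ValueError):
    """Raised when a staining quantification violates its invariants."""


@dataclass(frozen=True)
class IntensityProfile:
    """Distribution of tumour-cell staining intensity in one compartment.

    The four percentages must each lie in [0, 100] and sum to 100 (fractional
    entries allowed, tolerance 1e-9).  ``label`` is carried only to make
    validation errors traceable to an input row.
    """

    pct_none: float
    pct_weak: float
    pct_moderate: float
    pct_strong: float
    label: str | None = None

    def __post_init__(self) -> None:
        fracs = (self.pct_none, self.pct_weak, self.pct_moderate, self.pct_strong)
        where = f" ({self.label})" if self.label else ""
        for name, v in zip(("none", "weak", "moderate", "strong"), fracs):
            if not np.isfinite(v) or v < 0 or v > 100:
                raise ScoringError(
                    f"pct_{name}={v!r} outside [0, 100]{where}"
                )
        total = float(sum(fracs))
        if abs(total - 100.0) > _SUM_TOL:
            raise ScoringError(
                f"intensity fractions sum to {total!r}, expected 100{where}"
            )


@dataclass(frozen=True)
class Histoscore:
    value: float
    marker: str | None = None
    compartment: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or not 0.0 <= self.value <= 300.0:
            raise ScoringError(f"histoscore {self.value!r} outside [0, 300]")


@dataclass(frozen=True)
class PeriostinQuantification:
    """Raw stromal periostin read-out: % positive stroma and intensity 0-3."""

    pct_positive_stroma: float
    intensity_grade: int
    label: str | None = None

    def __post_init__(self) -> None:
        where = f" ({self.label})" if self.label else ""
        p = self.pct_positive_stroma
        if not np.isfinite(p) or p < 0 or p > 100:
            raise ScoringError(f"pct_positive_stroma={p!r} outside [0, 100]{where}")
        if self.intensity_grade not in (0, 1, 2, 3):
            raise ScoringError(
                f"intensity_grade={self.intensity_grade!r} not in {{0,1,2,3}}{where}"
            )


@dataclass(frozen=True)
class PeriostinScore:
    p_grade: int
    i_grade: int
    value: int

    def __post_init__(self) -> None:
        if self.value != self.p_grade * self.i_grade:
            raise ScoringError("periostin score must equal p_grade * i_grade")


def compute_histoscore(
    profile: IntensityProfile,
    marker: str | None = None,
    compartment: str | None = None,
) -> Histoscore:
    """Weighted histoscore of an intensity profile (0-300)."""
    value = (
        0.0 * profile.pct_none
        + 1.0 * profile.pct_weak
        + 2.0 * profile.pct_moderate
        + 3.0 * profile.pct_strong
    )
    return Histoscore(value=float(value), marker=marker, compartment=compartment)


def grade_periostin_percentage(pct: float) -> int:
    """Bin % positive stromal cells into the P grade 0-3.

    Integer percentages reproduce the printed bins 0-25 / 26-50 / 51-75 /
    76-100; fractional inputs fall into the half-open generalisation
    [0,25], (25,50], (50,75], (75,100].
    """
    if not np.isfinite(pct) or pct < 0 or pct > 100:
        raise ScoringError(f"percentage {pct!r} outside [0, 100]")
    if pct <= 25:
        return 0
    if pct <= 50:
        return 1
    if pct <= 75:
        return 2
    return 3


def compute_periostin_score(q: PeriostinQuantification) -> PeriostinScore:
    """P×I periostin score (0-9) from the raw stromal quantification."""
    p = grade_periostin_percentage(q.pct_positive_stroma)
    return PeriostinScore(p_grade=p, i_grade=q.intensity_grade, value=p * q.intensity_grade)


def interrater_icc(
    scores_a,
    scores_b,
    *,
    absolute_agreement: bool = True,
) -> float:
    """Intraclass correlation between two raters' scores.

    Default is ICC(2,1): two-way random effects, single rater, absolute
    agreement — systematic shifts between raters count against agreement.
    ``absolute_agreement=False`` gives the consistency variant ICC(3,1).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ScoringError("paired score lists must be 1-d and equal length")
    n = a.size
    if n < 3:
        raise ScoringError("need at least 3 paired scores for an ICC")
    x = np.column_stack([a, b])
    k = 2
    grand = x.mean()
    if np.allclose(x, grand):
        raise ScoringError("scores are constant; ICC undefined (zero variance)")
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((subj_means - grand) ** 2).sum()
    ss_cols = n * ((rater_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if absolute_agreement:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    if denom <= 0:
        raise ScoringError("degenerate variance decomposition; ICC undefined")
    return float((msr - mse) / denom)


_PROFILE_COLS = ["pct_none", "pct_weak", "pct_moderate", "pct_strong"]


def score_rows(quantifications: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``score`` column to a long-format staining table.

    Each row is one patient × marker × compartment.  Three input modes are
    recognised per row:

    * a precomputed ``histoscore`` in [0, 300];
    * the four intensity percentages (weighted histoscore is computed);
    * ``pct_positive_stroma`` + ``intensity_grade`` (periostin P×I score).

    Validation failures report the offending row index and patient.
    """
    df = quantifications.copy()
    scores = np.full(len(df), np.nan)
    for pos, (idx, row) in enumerate(df.iterrows()):
        label = f"row {idx}, patient {row.get('patient_id', '?')}, " \
                f"{row.get('marker', '?')}/{row.get('compartment', '?')}"
        if "histoscore" in df.columns and pd.notna(row["histoscore"]):
            h = Histoscore(float(row["histoscore"]))
            scores[pos] = h.value
        elif "pct_positive_stroma" in df.columns and pd.notna(row["pct_positive_stroma"]):
            q = PeriostinQuantification(
                float(row["pct_positive_stroma"]),
                int(row["intensity_grade"]),
                label=label,
            )
            scores[pos] = compute_periostin_score(q).value
        elif all(c in df.columns for c in _PROFILE_COLS) and pd.notna(row["pct_none"]):
            profile = IntensityProfile(
                float(row["pct_none"]),
                float(row["pct_weak"]),
                float(row["pct_moderate"]),
                float(row["pct_strong"]),
                label=label,
            )
            scores[pos] = compute_histoscore(profile).value
        else:
            raise ScoringError(f"no usable quantification columns in {label}")
    df["score"] = scores
    return df
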