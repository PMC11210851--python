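"""Combined-marker prognostic classifiers.

Two rule-based models combine stromal periostin status (Ps) with tumour
Fascin/Snail statuses into prognostic groups:

* **FcFsPs** — stromal Fascin (Fs), cytoplasmic Fascin (Fc) and Ps map to
  four groups.  The model is deliberately asymmetric: stromal Fascin is
  protective, so high Fs pulls patterns toward the good group while the
  worst pattern is low Fs with both Fc and Ps high.
* **FcSnPs** — cytoplasmic Fascin (Fc), nuclear Snail (Sn) and Ps map to
  three groups purely by how many of the three markers are HIGH
  (0-1 good, 2 intermediate, 3 poor).

Patients missing any required stain are excluded from that model's labelling
(with counts reported), mirroring the varying per-analysis cohort sizes of
marker panels scored on overlapping tissue subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import CoxFit, KMCurve, cox_fit, km_curve

__all__ = [
    "FCFSPS_LABELS",
    "FCSNPS_LABELS",
    "CombinedLabel",
    "classify_fcfsps",
    "classify_fcsnps",
    "combine_pairwise",
    "label_cohort",
    "ModelSurvivalReport",
    "model_survival_report",
]

FCFSPS_LABELS = ("good", "intermediate1", "intermediate2", "poor")
FCSNPS_LABELS = ("good", "intermediate", "poor")

_STATUSES = ("LOW", "HIGH")

#: Exhaustive FcFsPs truth table, keyed by (fs, fc, ps).
_FCFSPS_TABLE: dict[tuple[str, str, str], str] = {
    ("LOW", "LOW", "LOW"): "good",
    ("HIGH", "LOW", "LOW"): "good",
    ("HIGH", "HIGH", "LOW"): "good",
    ("HIGH", "LOW", "HIGH"): "good",
    ("LOW", "LOW", "HIGH"): "intermediate1",
    ("LOW", "HIGH", "LOW"): "intermediate1",
    ("HIGH", "HIGH", "HIGH"): "intermediate2",
    ("LOW", "HIGH", "HIGH"): "poor",
}


@dataclass(frozen=True)
class CombinedLabel:
    model: str  # "FcFsPs" | "FcSnPs"
    label: str

    def __post_init__(self) -> None:
        allowed = {"FcFsPs": FCFSPS_LABELS, "FcSnPs": FCSNPS_LABELS}.get(self.model)
        if allowed is None:
            raise ValueError(f"unknown model {self.model!r}")
        if self.label not in allowed:
            raise ValueError(f"label {self.label!r} not valid for {self.model}")


def _check_status(name: str, value: str) -> None:
    if value not in _STATUSES:
        raise ValueError(f"{name} status must be LOW or HIGH, got {value!r}")


def classify_fcfsps(fs: str, fc: str, ps: str) -> CombinedLabel:
    """FcFsPs group for one patient (arguments ordered fs, fc, ps)."""
    for name, v in (("fs", fs), ("fc", fc), ("ps", ps)):
        _check_status(name, v)
    return CombinedLabel("FcFsPs", _FCFSPS_TABLE[(fs, fc, ps)])


def classify_fcsnps(fc: str, sn: str, ps: str) -> CombinedLabel:
    """FcSnPs group: good/intermediate/poor by the count of HIGH statuses."""
    for name, v in (("fc", fc), ("sn", sn), ("ps", ps)):
        _check_status(name, v)
    n_high = sum(v == "HIGH" for v in (fc, sn, ps))
    label = "good" if n_high <= 1 else ("intermediate" if n_high == 2 else "poor")
    return CombinedLabel("FcSnPs", label)


def combine_pairwise(marker_status: str, ps_status: str) -> str:
    """Joint stratum of one tumour-marker status with periostin status."""
    _check_status("marker", marker_status)
    _check_status("ps", ps_status)
    return f"{marker_status}/{ps_status}"


def label_cohort(statuses: pd.DataFrame, model: str) -> tuple[pd.Series, int]:
    """Label every patient in a wide status table; count exclusions.

    ``statuses`` must carry the model's required shorthand columns (FcFsPs:
    Fs, Fc, Ps; FcSnPs: Fc, Sn, Ps) with values LOW/HIGH or NaN.  Patients
    with any required status missing get NaN and are counted as excluded.
    """
    required = {"FcFsPs": ["Fs", "Fc", "Ps"], "FcSnPs": ["Fc", "Sn", "Ps"]}[model]
    missing_cols = [c for c in required if c not in statuses.columns]
    if missing_cols:
        raise ValueError(f"status table lacks columns {missing_cols} for {model}")
    sub = statuses[required]
    complete = sub.notna().all(axis=1)
    labels = pd.Series(np.nan, index=statuses.index, dtype=object, name=model)
    classify = classify_fcfsps if model == "FcFsPs" else classify_fcsnps
    for idx in statuses.index[complete]:
        labels.loc[idx] = classify(*sub.loc[idx, required]).label
    return labels, int((~complete).sum())


# ---------------------------------------------------------------------------
# Survival report for a labelled cohort


@dataclass(frozen=True)
class ModelSurvivalReport:
    model: str
    reference: str
    counts: pd.Series
    events: pd.Series
    cox: pd.DataFrame | None  #: HR/CI/p per non-reference group; None if no contrasts
    non_estimable: tuple[str, ...]
    km: dict[str, KMCurve]
    fit: CoxFit | None


def model_survival_report(
    labels: pd.Series,
    time,
    event,
    *,
    model: str,
    reference: str = "good",
) -> ModelSurvivalReport:
    """Per-group Cox contrasts vs the good-prognosis reference, plus KM curves.

    Groups are dummy-coded against ``reference``.  A non-reference group with
    zero events cannot support a finite hazard ratio; it is reported as
    non-estimable and omitted from the fit rather than silently dropped from
    the report.
    """
    order = list(FCFSPS_LABELS if model == "FcFsPs" else FCSNPS_LABELS)
    t = pd.Series(np.asarray(time, dtype=float), index=labels.index)
    e = pd.Series(np.asarray(event, dtype=bool), index=labels.index)
    keep = labels.notna()
    lab, t, e = labels[keep].astype(str), t[keep], e[keep]
    present = [g for g in order if (lab == g).any()]
    if reference not in present:
        raise ValueError(f"reference group {reference!r} is empty")
    counts = pd.Series({g: int((lab == g).sum()) for g in present})
    events = pd.Series({g: int(e[lab == g].sum()) for g in present})
    km = {g: km_curve(t[lab == g], e[lab == g]) for g in present}

    contrasts = [g for g in present if g != reference]
    non_estimable = tuple(g for g in contrasts if events[g] == 0)
    fitted = [g for g in contrasts if g not in non_estimable]
    fit = None
    rows = []
    if fitted:
        in_model = lab.isin([reference] + fitted)
        dummies = pd.DataFrame(
            {g: (lab[in_model] == g).astype(float) for g in fitted}
        )
        fit = cox_fit(dummies, t[in_model], e[in_model])
        for g in fitted:
            row = fit.summary.loc[g]
            rows.append(
                {
                    "group": g,
                    "hr": row["hr"],
                    "ci_lower": row["ci_lower"],
                    "ci_upper": row["ci_upper"],
                    "wald_p": row["wald_p"],
                    "estimable": True,
                }
            )
    for g in non_estimable:
        rows.append(
            {"group": g, "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan,
             "wald_p": np.nan, "estimable": False}
        )
    cox = pd.DataFrame(rows).set_index("group") if rows else None
    if cox is not None:
        cox = cox.reindex([g for g in order if g in cox.index])
    return ModelSurvivalReport(
        model=model,
        reference=reference,
        counts=counts,
        events=events,
        cox=cox,
        non_estimable=non_estimable,
        km=km,
        fit=fit,
    )
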