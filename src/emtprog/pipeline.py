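"""End-to-end orchestration: scoring -> dichotomization -> survival -> combined
models -> associations, with table-shaped CSV reports.

Reports follow the print conventions of the source tables: percentages are
half-up rounded to one decimal against each variable's own non-missing
denominator; hazard ratios, confidence limits and p-values to three
decimals.  Every run writes a JSON log recording the settings used, patients
excluded per analysis, the association method chosen per test, and the
standing caveats (cutpoint-selection bias; no multiplicity correction).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import combined as comb
from .dichotomize import CutpointError, find_optimal_cutpoint
from .scoring import score_rows
from .simulate import SHORTHAND
from .survival import (
    CoxError,
    cox_backward_conditional,
    cox_fit,
    events_from_cause,
    five_year_os,
    km_curve,
    logrank_test,
)

__all__ = [
    "round_half_up",
    "percentage",
    "CohortSummary",
    "summarize_cohort",
    "RunConfig",
    "run_full_pipeline",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (print convention; banker's rounding is not)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int, decimals: int = 1) -> float:
    """Exact count percentage, half-up rounded: 110/202 -> 54.5."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    pct = Decimal(count * 100) / Decimal(denominator)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Cohort summary (demographics table)


@dataclass(frozen=True)
class CohortSummary:
    table: pd.DataFrame  #: variable, level, n, denominator, pct
    median_age: float | None
    age_range: tuple[float, float] | None
    median_follow_up: float | None
    follow_up_range: tuple[float, float] | None


_SUMMARY_SKIP = {"patient_id", "vital_status"}


def summarize_cohort(patients: pd.DataFrame, variables=None) -> CohortSummary:
    """Per-variable counts and percentages over non-missing denominators.

    Each categorical variable uses its own non-missing n as the percentage
    denominator, so variables assayed on overlapping subsets report honest
    percentages (denominators are carried in the output for auditability).
    """
    if patients.empty:
        raise ValueError("empty cohort")
    if variables is None:
        variables = [
            c for c in patients.columns
            if c not in _SUMMARY_SKIP and patients[c].dtype == object
        ]
    rows = []
    for var in variables:
        col = patients[var].dropna()
        denom = int(len(col))
        if denom == 0:
            continue
        counts = col.value_counts()
        # preserve first-appearance order of levels rather than count order
        levels = [lv for lv in pd.unique(col) if lv in counts.index]
        for lv in levels:
            n = int(counts[lv])
            rows.append(
                {
                    "variable": var,
                    "level": lv,
                    "n": n,
                    "denominator": denom,
                    "pct": percentage(n, denom),
                }
            )
    age = patients["age"].dropna() if "age" in patients.columns else pd.Series(dtype=float)
    fu = (
        patients["time_months"].dropna()
        if "time_months" in patients.columns
        else pd.Series(dtype=float)
    )
    return CohortSummary(
        table=pd.DataFrame(rows),
        median_age=float(age.median()) if len(age) else None,
        age_range=(float(age.min()), float(age.max())) if len(age) else None,
        median_follow_up=float(fu.median()) if len(fu) else None,
        follow_up_range=(float(fu.min()), float(fu.max())) if len(fu) else None,
    )


# ---------------------------------------------------------------------------
# Full pipeline


#: Ordinal codings for the multivariate Cox covariates (single linear code
#: per covariate, matching a one-HR-per-covariate presentation).
COVARIATE_CODES: dict[str, dict[str, int]] = {
    "age_group": {"<65": 0, ">=65": 1},
    "sex": {"Male": 0, "Female": 1},
    "location": {"Colon": 0, "Rectum": 1},
    "t_stage": {"1": 0, "2": 1, "3": 2, "4": 3},
    "n_stage": {"0": 0, "1": 1, "2": 2},
    "m_stage": {"0": 0, "1": 1},
    "stage": {"I": 0, "II": 1, "III": 2, "IV": 3},
    "differentiation": {"Well": 0, "Moderately": 1, "Poorly": 2},
    "local_metastasis": {"Absence": 0, "Presence": 1},
    "lymphovascular_invasion": {"Absence": 0, "Presence": 1},
    "perineural_invasion": {"Absence": 0, "Presence": 1},
}

_MODEL_CODES = {
    "FcFsPs": {"good": 0, "intermediate1": 1, "intermediate2": 2, "poor": 3},
    "FcSnPs": {"good": 0, "intermediate": 1, "poor": 2},
}

#: Marker/periostin pairings examined as joint strata.
_PAIRWISE_MARKERS = ("Em", "Bm", "Fc", "Fs", "Sc", "Sn", "Ss")


@dataclass(frozen=True)
class RunConfig:
    patients_csv: str | Path
    scores_csv: str | Path
    out_dir: str | Path
    event_definition: str = "cancer_specific"
    min_prop: float = 0.10
    removal_alpha: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_prop <= 0.5:
            raise ValueError("min_prop must be in (0, 0.5]")
        for p in (self.patients_csv, self.scores_csv):
            if not Path(p).exists():
                raise FileNotFoundError(p)


_PATIENT_REQUIRED = ("patient_id", "time_months", "vital_status")
_SCORE_REQUIRED = ("patient_id", "marker", "compartment")


def _validate(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    for col in required:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{name}: missing {col} in rows {list(bad[:5])}")


def _fmt(x: float | None, nd: int = 3) -> float | None:
    return None if x is None or not np.isfinite(x) else round_half_up(float(x), nd)


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns output paths.

    Deterministic given inputs and settings.  On failure any partially
    written outputs are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
        return path

    try:
        return _run(config, out, emit, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, out: Path, emit, written: list[Path]) -> dict:
    patients = pd.read_csv(
        config.patients_csv, dtype={c: object for c in COVARIATE_CODES}
    )
    scores_in = pd.read_csv(config.scores_csv)
    _validate(patients, _PATIENT_REQUIRED, "patients table")
    _validate(scores_in, _SCORE_REQUIRED, "scores table")
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"]
        raise ValueError(f"duplicate patient ids: {list(dup[:5])}")
    if (patients["time_months"].astype(float) <= 0).any():
        bad = patients.index[patients["time_months"].astype(float) <= 0]
        raise ValueError(f"non-positive follow-up in rows {list(bad[:5])}")

    patients = patients.set_index("patient_id", drop=False)
    event = events_from_cause(patients["vital_status"], config.event_definition)
    time = patients["time_months"].astype(float)
    log: dict = {
        "settings": {
            "event_definition": config.event_definition,
            "min_prop": config.min_prop,
            "removal_alpha": config.removal_alpha,
            "icc_definition": "ICC(2,1) two-way random, single rater, absolute agreement",
            "ties": "efron",
            "seed": config.seed,
        },
        "caveats": [
            "cutpoints are maximally selected; downstream single-marker "
            "p-values are selection-biased (no correction applied)",
            "association p-values are uncorrected for multiplicity",
        ],
        "n_patients": int(len(patients)),
        "n_events": int(event.sum()),
        "exclusions": {},
        "association_methods": {},
    }

    # ---- demographics summary -------------------------------------------
    summary = summarize_cohort(patients.drop(columns=["patient_id"]))
    emit("demographics_summary.csv", summary.table)

    # ---- scoring + dichotomization ---------------------------------------
    scored = score_rows(scores_in)
    cut_rows, status_rows = [], []
    statuses_wide = pd.DataFrame(index=patients.index)
    for (marker, compartment), grp in scored.groupby(["marker", "compartment"], sort=True):
        grp = grp[grp["patient_id"].isin(patients.index)]
        pid = grp["patient_id"].to_numpy()
        s = grp["score"].to_numpy(dtype=float)
        t = time.loc[pid].to_numpy()
        e = event.loc[pid].to_numpy()
        short = SHORTHAND.get((marker, compartment), f"{marker}:{compartment}")
        try:
            cut = find_optimal_cutpoint(s, t, e, min_prop=config.min_prop)
        except CutpointError as err:
            log.setdefault("cutpoint_failures", {})[short] = str(err)
            continue
        cut_rows.append(
            {
                "marker": marker,
                "compartment": compartment,
                "shorthand": short,
                "cutoff": cut.cutoff,
                "max_std_statistic": cut.max_std_statistic,
                "n_low": cut.n_low,
                "n_high": cut.n_high,
                "candidates_evaluated": cut.candidates_evaluated,
            }
        )
        call = np.where(s > cut.cutoff, "HIGH", "LOW")
        statuses_wide.loc[pid, short] = call
        for p, st in zip(pid, call):
            status_rows.append(
                {
                    "patient_id": p,
                    "marker": marker,
                    "compartment": compartment,
                    "shorthand": short,
                    "status": st,
                    "cutoff_used": cut.cutoff,
                }
            )
        log["exclusions"][short] = int(len(patients) - len(grp))
    cutoffs = pd.DataFrame(cut_rows)
    emit("cutoffs.csv", cutoffs)
    emit("marker_status.csv", pd.DataFrame(status_rows))

    # ---- single-marker survival battery ---------------------------------
    t2_rows, km_rows = [], []
    for row in cut_rows:
        short = row["shorthand"]
        st = statuses_wide[short].dropna()
        t = time.loc[st.index]
        e = event.loc[st.index]
        denom = int(len(st))
        fit = None
        try:
            fit = cox_fit((st == "HIGH").astype(float).rename(short), t, e)
        except (CoxError, ValueError) as err:
            log.setdefault("cox_failures", {})[short] = str(err)
        for arm in ("LOW", "HIGH"):
            mask = st == arm
            curve = km_curve(t[mask], e[mask]) if mask.any() else None
            entry = {
                "marker": row["marker"],
                "compartment": row["compartment"],
                "shorthand": short,
                "arm": arm.lower(),
                "n": int(mask.sum()),
                "pct": percentage(int(mask.sum()), denom),
                "events": int(e[mask].sum()),
                "five_year_os": _fmt(five_year_os(curve), 0) if curve else None,
            }
            if arm == "HIGH" and fit is not None:
                s = fit.summary.iloc[0]
                entry.update(
                    hr=_fmt(s["hr"]), ci_lower=_fmt(s["ci_lower"]),
                    ci_upper=_fmt(s["ci_upper"]), p=_fmt(s["wald_p"]),
                )
            t2_rows.append(entry)
            if curve:
                for tt, sp, ar in zip(curve.event_times, curve.survival_prob, curve.at_risk):
                    km_rows.append(
                        {"analysis": short, "group": arm.lower(), "time": tt,
                         "survival": sp, "at_risk": int(ar)}
                    )
    emit("single_marker_survival.csv", pd.DataFrame(t2_rows))

    # ---- combined models --------------------------------------------------
    label_rows, combined_rows, t3_rows = [], [], []
    model_labels: dict[str, pd.Series] = {}
    for model in ("FcFsPs", "FcSnPs"):
        needed = {"FcFsPs": ["Fs", "Fc", "Ps"], "FcSnPs": ["Fc", "Sn", "Ps"]}[model]
        if not all(c in statuses_wide.columns for c in needed):
            log.setdefault("model_failures", {})[model] = "missing marker statuses"
            continue
        labels, excluded = comb.label_cohort(statuses_wide, model)
        log["exclusions"][model] = excluded
        model_labels[model] = labels
        for pid, lab in labels.dropna().items():
            label_rows.append({"patient_id": pid, "model": model, "label": lab})
        report = comb.model_survival_report(
            labels, time, event, model=model
        )
        for g in report.counts.index:
            entry = {
                "model": model, "group": g,
                "n": int(report.counts[g]), "events": int(report.events[g]),
                "reference": g == report.reference,
            }
            if report.cox is not None and g in report.cox.index:
                r = report.cox.loc[g]
                entry.update(
                    hr=_fmt(r["hr"]), ci_lower=_fmt(r["ci_lower"]),
                    ci_upper=_fmt(r["ci_upper"]), p=_fmt(r["wald_p"]),
                    estimable=bool(r["estimable"]),
                )
            combined_rows.append(entry)
        for g, curve in report.km.items():
            for tt, sp, ar in zip(curve.event_times, curve.survival_prob, curve.at_risk):
                km_rows.append(
                    {"analysis": model, "group": g, "time": tt,
                     "survival": sp, "at_risk": int(ar)}
                )
    emit("labels.csv", pd.DataFrame(label_rows))
    emit("combined_model_survival.csv", pd.DataFrame(combined_rows))

    # ---- multivariate Cox per combined model -----------------------------
    for model, labels in model_labels.items():
        X = pd.DataFrame(index=patients.index)
        for cov, codes in COVARIATE_CODES.items():
            if cov in patients.columns:
                X[cov] = patients[cov].map(codes)
        X[model] = labels.map(_MODEL_CODES[model])
        X = X.dropna()
        t = time.loc[X.index]
        e = event.loc[X.index]
        log["exclusions"][f"multivariate_{model}"] = int(len(patients) - len(X))
        usable = [c for c in X.columns if X[c].nunique() > 1]
        X = X[usable]
        # per-covariate univariate fits
        for cov in X.columns:
            try:
                f = cox_fit(X[[cov]].astype(float), t, e)
                s = f.summary.iloc[0]
                t3_rows.append(
                    {"model": model, "covariate": cov, "analysis": "univariate",
                     "hr": _fmt(s["hr"]), "ci_lower": _fmt(s["ci_lower"]),
                     "ci_upper": _fmt(s["ci_upper"]), "p": _fmt(s["wald_p"])}
                )
            except (CoxError, ValueError) as err:
                log.setdefault("cox_failures", {})[f"{model}:uni:{cov}"] = str(err)
        # forced entry: one model with every covariate
        try:
            forced = cox_fit(X.astype(float), t, e)
            for cov in forced.covariates:
                s = forced.summary.loc[cov]
                t3_rows.append(
                    {"model": model, "covariate": cov, "analysis": "forced_entry",
                     "hr": _fmt(s["hr"]), "ci_lower": _fmt(s["ci_lower"]),
                     "ci_upper": _fmt(s["ci_upper"]), "p": _fmt(s["wald_p"])}
                )
        except (CoxError, ValueError) as err:
            log.setdefault("cox_failures", {})[f"{model}:forced"] = str(err)
        # backward conditional
        try:
            back = cox_backward_conditional(
                X.astype(float), t, e, removal_alpha=config.removal_alpha
            )
            log.setdefault("backward_trace", {})[model] = [
                dataclasses.asdict(s) for s in back.trace
            ]
            if back.final is not None:
                for cov in back.final.covariates:
                    s = back.final.summary.loc[cov]
                    t3_rows.append(
                        {"model": model, "covariate": cov, "analysis": "backward",
                         "hr": _fmt(s["hr"]), "ci_lower": _fmt(s["ci_lower"]),
                         "ci_upper": _fmt(s["ci_upper"]), "p": _fmt(s["wald_p"])}
                    )
        except (CoxError, ValueError) as err:
            log.setdefault("cox_failures", {})[f"{model}:backward"] = str(err)
    emit("multivariate_cox.csv", pd.DataFrame(t3_rows))

    # ---- pairwise marker x periostin strata ------------------------------
    pair_rows = []
    if "Ps" in statuses_wide.columns:
        for short in _PAIRWISE_MARKERS:
            if short not in statuses_wide.columns:
                continue
            both = statuses_wide[[short, "Ps"]].dropna()
            strata = pd.Series(
                [comb.combine_pairwise(a, b) for a, b in both.itertuples(index=False)],
                index=both.index,
            )
            t = time.loc[both.index]
            e = event.loc[both.index]
            try:
                lr = logrank_test(t, e, strata)
            except ValueError:
                lr = None
            for stratum in sorted(strata.unique()):
                mask = strata == stratum
                pair_rows.append(
                    {
                        "marker": short, "stratum": f"{short}:{stratum.split('/')[0]}"
                        f"/Ps:{stratum.split('/')[1]}",
                        "n": int(mask.sum()), "events": int(e[mask].sum()),
                        "logrank_chi2": _fmt(lr.chi2) if lr else None,
                        "logrank_df": lr.df if lr else None,
                        "logrank_p": _fmt(lr.p) if lr else None,
                    }
                )
    emit("pairwise_pn_strata.csv", pd.DataFrame(pair_rows))

    # ---- association battery --------------------------------
    a_rows = []
    clin_vars = [c for c in COVARIATE_CODES if c in patients.columns]
    group_vars: dict[str, pd.Series] = {
        model: labels for model, labels in model_labels.items()
    }
    for short in statuses_wide.columns:
        group_vars[short] = statuses_wide[short]
    for gname, gvar in group_vars.items():
        for cv in clin_vars:
            try:
                table = assoc.crosstab(gvar.rename(gname), patients[cv])
                res = assoc.independence_test(table)
            except ValueError as err:
                log.setdefault("association_failures", {})[f"{gname}~{cv}"] = str(err)
                continue
            log["association_methods"][f"{gname}~{cv}"] = res.method
            a_rows.append(
                {
                    "group_variable": gname, "clinical_variable": cv,
                    "rows": table.counts.shape[0], "cols": table.counts.shape[1],
                    "n": table.n, "method": res.method,
                    "statistic": _fmt(res.statistic) if res.statistic is not None else None,
                    "df": res.df, "p": _fmt(res.p),
                }
            )
    emit("associations.csv", pd.DataFrame(a_rows))
    emit("km_curves.csv", pd.DataFrame(km_rows))

    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str))
    written.append(log_path)
    return {"out_dir": str(out), "files": [str(p) for p in written], "log": log}
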