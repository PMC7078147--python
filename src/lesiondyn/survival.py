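"""Linking lesion-dynamics heterogeneity to overall survival.

The per-patient heterogeneity metric is the median of the zero-shift
inter-class CC values over the patient's class pairs (liver-lung,
liver-node, ...).  Patients with lesions in a single class have no pair
and therefore no median CC; they are excluded from the CC-based survival
analyses.  The metric is used either continuously or dichotomized at a
conservative threshold (default 0.35: "low" = median CC <= threshold,
more heterogeneous; "high" = above).

Survival machinery (Kaplan-Meier product-limit curves with
Greenwood/log-log confidence bands, the log-rank test, Cox proportional
hazards with Efron tie handling) is delegated to lifelines; this module
owns the metric derivation, the analysis-set rules and the model
specifications: ECOG performance (binary), baseline tumor size TS0,
early tumor shrinkage TS_ratio = (TS0 - TS8)/TS0 at 8 weeks, KRAS status,
and median CC (continuous or binary), optionally with a KRAS x median-CC
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .crosscorr import CCRecord
from .trial_data import LesionSeries, PatientCovariates, total_ts

CC_THRESHOLD = 0.35

#: Cox terms mirroring the standard multivariate specification with the
#: heterogeneity metric entered continuously / as a binary group.
CONTINUOUS_CC_TERMS = ("ecog_not_active", "ts0", "ts_ratio8", "kras_mut", "median_cc")
BINARY_CC_TERMS = ("ecog_not_active", "ts0", "ts_ratio8", "kras_mut", "cc_low")
INTERACTION_TERMS = CONTINUOUS_CC_TERMS + ("kras_mut_x_median_cc",)


def median_cc(cc_records: Sequence[CCRecord]) -> dict[str, float]:
    """Per-patient median of defined zero-shift CC values.

    Patients with no defined inter-class pair are absent from the result
    (missing, not zero).  An even pair count takes the midpoint of the two
    central values (standard median).
    """
    by_patient: dict[str, list[float]] = {}
    for r in cc_records:
        if np.isfinite(r.cc_zero):
            by_patient.setdefault(r.patient_id, []).append(r.cc_zero)
    return {pid: float(np.median(v)) for pid, v in by_patient.items()}


def dichotomize(value: float | None, threshold: float = CC_THRESHOLD) -> str | None:
    """"low" if median CC <= threshold (equal-to rule), "high" above;
    missing in -> missing out."""
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return None
    return "low" if value <= threshold else "high"


def ets(ts0: float, ts8: float | None) -> float | None:
    """Early tumor shrinkage TS_ratio = (TS0 - TS8)/TS0.

    1 means complete disappearance by week 8, 0 no change, negative growth.
    ``ts0`` must be positive; a missing ``ts8`` yields a missing ratio.
    """
    if ts0 is None or not np.isfinite(ts0) or ts0 <= 0:
        raise ValueError(f"ts0 must be > 0, got {ts0!r}")
    if ts8 is None or not np.isfinite(ts8):
        return None
    return (ts0 - ts8) / ts0


def build_outcomes(covariates: Sequence[PatientCovariates],
                   interclass_records: Sequence[CCRecord],
                   series_by_patient: Mapping[str, Mapping[str, LesionSeries]],
                   threshold: float = CC_THRESHOLD,
                   ets_time: float = 8.0, ets_tolerance: float = 2.0,
                   ) -> pd.DataFrame:
    """Assemble the per-patient outcome table.

    One row per patient present in ``series_by_patient`` (the preprocessed
    analysis set): survival time/event, covariates, baseline total TS,
    early-shrinkage ratio at ``ets_time`` weeks (nearest visit within
    tolerance), median CC and its dichotomized group.  Missing values stay
    NaN; downstream model fits drop incomplete rows per their term list.
    """
    cov_by_pid = {c.patient_id: c for c in covariates}
    med = median_cc(interclass_records)
    ts0 = total_ts(series_by_patient, 0.0, ets_tolerance)
    ts8 = total_ts(series_by_patient, ets_time, ets_tolerance)

    rows = []
    for pid in sorted(series_by_patient):
        cov = cov_by_pid[pid]
        t0 = ts0.get(pid)
        ratio = None
        if t0 is not None and t0 > 0:
            ratio = ets(t0, ts8.get(pid))
        m = med.get(pid)
        rows.append({
            "patient_id": pid,
            "arm": cov.arm,
            "kras": cov.kras,
            "ecog": cov.ecog,
            "os_time": cov.os_time,
            "os_event": cov.os_event,
            "ts0": np.nan if t0 is None else t0,
            "ts_ratio8": np.nan if ratio is None else ratio,
            "median_cc": np.nan if m is None else m,
            "cc_group": dichotomize(m, threshold),
        })
    return pd.DataFrame(rows, columns=["patient_id", "arm", "kras", "ecog",
                                       "os_time", "os_event", "ts0",
                                       "ts_ratio8", "median_cc", "cc_group"])


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / Cox


@dataclass
class KMResult:
    """Product-limit estimate for one group."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    median: float            # inf when not reached
    median_ci: tuple[float, float]
    n: int
    n_events: int
    risk_table: pd.DataFrame | None = None


def km_estimate(outcomes: pd.DataFrame, group_field: str = "cc_group",
                risk_times: Sequence[float] | None = None,
                time_col: str = "os_time", event_col: str = "os_event",
                ) -> dict[str, KMResult]:
    """Kaplan-Meier curves per level of ``group_field``.

    The median is the earliest time at which S(t) <= 0.5 (infinity when the
    curve never reaches 0.5, i.e. median not reached); its CI inverts the
    log-log Greenwood confidence band of S(t).  ``risk_times`` adds a
    number-at-risk table (count and % of the group still at risk).
    """
    df = outcomes.dropna(subset=[group_field])
    out: dict[str, KMResult] = {}
    for level, sub in df.groupby(group_field, sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(level))
        median = float(kmf.median_survival_time_)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        risk = None
        if risk_times is not None:
            t = np.asarray(sub[time_col], dtype=float)
            risk = pd.DataFrame({
                "time": list(risk_times),
                "n_at_risk": [int((t >= rt).sum()) for rt in risk_times],
            })
            risk["pct_at_risk"] = 100.0 * risk["n_at_risk"] / len(sub)
        out[str(level)] = KMResult(
            label=str(level),
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            median=median,
            median_ci=(lo, hi),
            n=len(sub),
            n_events=int(sub[event_col].sum()),
            risk_table=risk,
        )
    return out


def logrank(outcomes: pd.DataFrame, group_field: str = "cc_group",
            time_col: str = "os_time", event_col: str = "os_event",
            ) -> tuple[float, int, float]:
    """Log-rank test across the levels of ``group_field``.

    Returns (chi-square statistic, degrees of freedom, p value).  The
    statistic compares observed vs expected events under the pooled
    risk-set null with hypergeometric variance terms.
    """
    df = outcomes.dropna(subset=[group_field])
    levels = df[group_field].unique()
    if len(levels) < 2:
        raise ValueError(f"need >= 2 non-empty groups, got {sorted(map(str, levels))}")
    res = multivariate_logrank_test(df[time_col], df[group_field], df[event_col])
    return float(res.test_statistic), len(levels) - 1, float(res.p_value)


def _design_matrix(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the model terms.

    kras_mut: 1 = mutated, 0 = wild type, NaN = missing;
    ecog_not_active: 1 = not fully active; cc_low: 1 = median CC <= threshold.
    """
    d = pd.DataFrame({
        "os_time": outcomes["os_time"].astype(float),
        "os_event": outcomes["os_event"].astype(int),
        "ts0": outcomes["ts0"].astype(float),
        "ts_ratio8": outcomes["ts_ratio8"].astype(float),
        "median_cc": outcomes["median_cc"].astype(float),
    })
    d["kras_mut"] = outcomes["kras"].map({"mut": 1.0, "wt": 0.0})
    d["ecog_not_active"] = outcomes["ecog"].map(
        {"not_fully_active": 1.0, "fully_active": 0.0})
    d["cc_low"] = outcomes["cc_group"].map({"low": 1.0, "high": 0.0})
    d["kras_mut_x_median_cc"] = d["kras_mut"] * d["median_cc"]
    return d


def cox_fit(outcomes: pd.DataFrame, terms: Sequence[str] = CONTINUOUS_CC_TERMS,
            time_col: str = "os_time", event_col: str = "os_event",
            ) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    ``terms`` name columns of the design matrix (see
    :data:`CONTINUOUS_CC_TERMS`, :data:`BINARY_CC_TERMS`,
    :data:`INTERACTION_TERMS`).  Rows with a missing value in any term are
    excluded, so with CC terms the analysis set shrinks to patients having
    a median CC.  Returns one row per term: coefficient, hazard ratio,
    Wald 95% CI and p value, plus the fitted n and event count.
    Non-convergence raises lifelines' convergence error.
    """
    d = _design_matrix(outcomes)
    cols = [time_col, event_col] + list(terms)
    d = d[cols].dropna()
    if d.empty:
        raise ValueError("no complete-case rows for the requested terms")
    cph = CoxPHFitter()
    cph.fit(d, duration_col=time_col, event_col=event_col)
    s = cph.summary
    out = pd.DataFrame({
        "term": s.index,
        "coef": s["coef"].to_numpy(),
        "hr": s["exp(coef)"].to_numpy(),
        "hr_ci_low": s["exp(coef) lower 95%"].to_numpy(),
        "hr_ci_high": s["exp(coef) upper 95%"].to_numpy(),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)
    out["n"] = len(d)
    out["n_events"] = int(d[event_col].sum())
    return out


def km_curves_frame(km: Mapping[str, KMResult]) -> pd.DataFrame:
    """Flatten KM curves to (group, time, survival) rows for CSV export."""
    rows = []
    for label in sorted(km):
        r = km[label]
        for t, s in zip(r.times, r.survival):
            rows.append({"group": label, "time": float(t), "survival": float(s)})
    return pd.DataFrame(rows, columns=["group", "time", "survival"])


def km_summary_frame(km: Mapping[str, KMResult]) -> pd.DataFrame:
    rows = []
    for label in sorted(km):
        r = km[label]
        rows.append({
            "group": label, "n": r.n, "n_events": r.n_events,
            "median": r.median, "median_ci_low": r.median_ci[0],
            "median_ci_high": r.median_ci[1],
        })
    return pd.DataFrame(rows, columns=["group", "n", "n_events", "median",
                                       "median_ci_low", "median_ci_high"])
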