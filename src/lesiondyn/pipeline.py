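"""End-to-end heterogeneity pipeline.

Chains the stages: preprocessing -> lesion classification (+ rare-class
merging) -> cTL construction -> inter-class (and optionally intra-class)
cross-correlation -> K-means clustering of the CC values -> per-patient
median CC -> survival linkage (Kaplan-Meier, log-rank, Cox).  All outputs
are plain tables written as CSV/JSON; a fixed seed makes two runs on the
same inputs byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify as cls_mod
from . import heterogeneity as het
from . import survival as surv
from .classify import ClassRuleset
from .crosscorr import CCRecord, cc_records_to_frame
from .trial_data import (LesionRecord, PatientCovariates, PreprocessReport,
                         build_series, preprocess)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Run-level settings of the heterogeneity pipeline."""

    ruleset: ClassRuleset | None = None
    min_patients: int = 30          # rare-class merge threshold
    max_lag: int = 12               # visit-index shifts searched per side
    k: int | None = 3               # cluster count; None -> elbow selection
    k_max: int = 6
    seed: int = 0
    n_restarts: int = 50
    cc_threshold: float = 0.35      # median-CC dichotomization
    similar_cut: float = 0.35       # cluster interpretation cutoffs
    different_cut: float = -0.35
    survival_arm: str | None = "cetuximab"   # None -> all patients
    ets_time: float = 8.0
    ets_tolerance: float = 2.0
    run_intra: bool = True
    run_survival: bool = True
    intra_classes: tuple[str, ...] | None = None  # None -> all merged classes
    risk_times: tuple[float, ...] = (0.0, 40.0, 80.0, 120.0, 160.0)


@dataclass
class PipelineResult:
    preprocess_report: PreprocessReport
    merge_report: cls_mod.MergeReport
    class_summary: pd.DataFrame
    interclass_records: list[CCRecord]
    cluster_zero: het.ClusterResult
    report_zero: pd.DataFrame
    lags_zero: pd.DataFrame
    cluster_max: het.ClusterResult
    report_max: pd.DataFrame
    lags_max: pd.DataFrame
    outcomes: pd.DataFrame | None = None
    km: dict | None = None
    logrank: tuple[float, int, float] | None = None
    cox_continuous: pd.DataFrame | None = None
    cox_binary: pd.DataFrame | None = None
    cox_interaction: pd.DataFrame | None = None
    intra_records: dict[str, list[CCRecord]] = field(default_factory=dict)
    intra_reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def run_pipeline(records: Sequence[LesionRecord],
                 covariates: Sequence[PatientCovariates],
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full lesion-heterogeneity analysis on one dataset."""
    config = config or PipelineConfig()
    kept, pre_report = preprocess(records, covariates)
    series = build_series(kept)
    classified = cls_mod.classify_all(series, config.ruleset)
    classified, merge_report = cls_mod.merge_rare_classes(classified,
                                                          config.min_patients)
    arm_pids = {c.patient_id for c in covariates if c.arm == "cetuximab"}
    summary = cls_mod.class_summary(
        classified, {"ALL": list(classified), "cetuximab": arm_pids})

    ctls = het.build_all_ctls(series, classified)
    inter = het.interclass_pairs(ctls, config.max_lag)

    cl0, kept0 = het.cluster_cc(inter, use_max_cc=False, k=config.k,
                                k_max=config.k_max, seed=config.seed,
                                n_restarts=config.n_restarts)
    rep0, lags0 = het.cluster_report(cl0, kept0, config.similar_cut,
                                     config.different_cut)
    clm, keptm = het.cluster_cc(inter, use_max_cc=True, k=config.k,
                                k_max=config.k_max, seed=config.seed,
                                n_restarts=config.n_restarts)
    repm, lagsm = het.cluster_report(clm, keptm, config.similar_cut,
                                     config.different_cut)

    result = PipelineResult(
        preprocess_report=pre_report,
        merge_report=merge_report,
        class_summary=summary,
        interclass_records=inter,
        cluster_zero=cl0, report_zero=rep0, lags_zero=lags0,
        cluster_max=clm, report_max=repm, lags_max=lagsm,
    )

    if config.run_intra:
        targets = config.intra_classes
        if targets is None:
            targets = tuple(sorted({c.class_name
                                    for p in classified.values()
                                    for c in p.values()}))
        for cname in targets:
            recs = het.intraclass_pairs(series, classified, cname, config.max_lag)
            result.intra_records[cname] = recs
            n_def = len(recs) - het.undefined_cc_count(recs)
            if config.k is not None and n_def >= max(config.k + 1, 4):
                clc, keptc = het.cluster_cc(recs, use_max_cc=False, k=config.k,
                                            seed=config.seed,
                                            n_restarts=config.n_restarts)
                repc, _ = het.cluster_report(clc, keptc, config.similar_cut,
                                             config.different_cut)
                result.intra_reports[cname] = repc
            else:
                result.notes.append(
                    f"intra-class {cname}: too few defined CCs to cluster")

    if config.run_survival:
        outcomes = surv.build_outcomes(covariates, inter, series,
                                       config.cc_threshold, config.ets_time,
                                       config.ets_tolerance)
        if config.survival_arm is not None:
            outcomes = outcomes[outcomes["arm"] == config.survival_arm]
        outcomes = outcomes.reset_index(drop=True)
        result.outcomes = outcomes
        groups = outcomes["cc_group"].dropna()
        if groups.nunique() >= 2:
            result.km = surv.km_estimate(outcomes, "cc_group",
                                         risk_times=config.risk_times)
            result.logrank = surv.logrank(outcomes, "cc_group")
            try:
                result.cox_continuous = surv.cox_fit(outcomes,
                                                     surv.CONTINUOUS_CC_TERMS)
                result.cox_binary = surv.cox_fit(outcomes, surv.BINARY_CC_TERMS)
                result.cox_interaction = surv.cox_fit(outcomes,
                                                      surv.INTERACTION_TERMS)
            except Exception as exc:   # noqa: BLE001 - surfaced as a note
                result.notes.append(f"Cox fit failed: {exc}")
        else:
            result.notes.append("survival skipped: fewer than two CC groups")
    return result


def write_outputs(result: PipelineResult, outdir) -> list[Path]:
    """Write every pipeline artifact as CSV/JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)

    result.preprocess_report.to_json(outdir / "preprocess_report.json")
    written.append(outdir / "preprocess_report.json")
    with open(outdir / "merge_report.json", "w") as fh:
        json.dump(result.merge_report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(outdir / "merge_report.json")

    summary = cls_mod.format_class_summary(result.class_summary)
    summary.index.name = "class"
    path = outdir / "class_summary.csv"
    summary.to_csv(path)
    written.append(path)

    _csv(cc_records_to_frame(result.interclass_records), "cc_interclass.csv")
    _csv(result.report_zero, "cluster_report_zero.csv")
    _csv(result.lags_zero, "cluster_lags_zero.csv")
    _csv(result.report_max, "cluster_report_max.csv")
    _csv(result.lags_max, "cluster_lags_max.csv")

    for cname, recs in result.intra_records.items():
        safe = cname.lower().replace(" ", "_")
        _csv(cc_records_to_frame(recs), f"cc_intraclass_{safe}.csv")
    for cname, rep in result.intra_reports.items():
        safe = cname.lower().replace(" ", "_")
        _csv(rep, f"cluster_report_intra_{safe}.csv")

    if result.outcomes is not None:
        _csv(result.outcomes, "outcomes.csv")
    if result.km is not None:
        _csv(surv.km_curves_frame(result.km), "km_curves.csv")
        _csv(surv.km_summary_frame(result.km), "km_summary.csv")
        risk = []
        for label in sorted(result.km):
            rt = result.km[label].risk_table
            if rt is not None:
                rt = rt.copy()
                rt.insert(0, "group", label)
                risk.append(rt)
        if risk:
            _csv(pd.concat(risk, ignore_index=True), "km_risk_table.csv")
    if result.logrank is not None:
        stat, dof, p = result.logrank
        with open(outdir / "logrank.json", "w") as fh:
            json.dump({"statistic": stat, "df": dof, "p": p}, fh, indent=2,
                      sort_keys=True)
            fh.write("\n")
        written.append(outdir / "logrank.json")
    for name, df in (("cox_continuous.csv", result.cox_continuous),
                     ("cox_binary.csv", result.cox_binary),
                     ("cox_interaction.csv", result.cox_interaction)):
        if df is not None:
            _csv(df, name)
    return written
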