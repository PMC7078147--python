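"""Long-format lesion measurement tables.

Reading, validation and preprocessing of per-visit tumor-size measurements
(one row per patient x lesion x assessment), plus assembly into per-lesion
time series and per-patient total tumor size (TS).

Sizes are in mm when the run-level metric is ``SLD`` (longest diameter,
RECIST-style) and in mm^2 when it is ``SOPD`` (product of perpendicular
diameters, modified-WHO-style).  The two metrics are never mixed within one
analysis run.  Time is measured in weeks from baseline (first assessment).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LESION_FIELDS = (
    "patient_id",
    "lesion_id",
    "organ_text",
    "lesion_type",
    "time",
    "size",
    "metric",
)
COVARIATE_FIELDS = (
    "patient_id",
    "arm",
    "kras",
    "ecog",
    "surgery_time",
    "os_time",
    "os_event",
)

LESION_TYPES = frozenset({"primary", "metastatic", "node"})
METRICS = frozenset({"SLD", "SOPD"})
ARMS = frozenset({"cetuximab", "control"})
KRAS_LEVELS = frozenset({"wt", "mut", "missing"})
ECOG_LEVELS = frozenset({"fully_active", "not_fully_active", "missing"})


class TableFormatError(ValueError):
    """Raised when a delimited table misses required columns."""


class RowValidationError(ValueError):
    """Raised when individual rows violate record invariants.

    ``rows`` holds the offending 0-based data-row indices (header excluded).
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class LesionRecord:
    """One measurement of one lesion at one assessment visit."""

    patient_id: str
    lesion_id: str
    organ_text: str
    lesion_type: str
    time: float
    size: float
    metric: str

    def validate(self) -> list[str]:
        problems = []
        if self.lesion_type not in LESION_TYPES:
            problems.append(f"lesion_type {self.lesion_type!r} not in {sorted(LESION_TYPES)}")
        if self.metric not in METRICS:
            problems.append(f"metric {self.metric!r} not in {sorted(METRICS)}")
        if not np.isfinite(self.time) or self.time < 0:
            problems.append(f"time {self.time!r} must be finite and >= 0")
        if not np.isfinite(self.size) or self.size < 0:
            problems.append(f"size {self.size!r} must be finite and >= 0")
        return problems


@dataclass
class LesionSeries:
    """Time-ordered size trajectory of one lesion or one class aggregate."""

    patient_id: str
    series_id: str
    times: np.ndarray
    sizes: np.ndarray
    organ_text: str = ""
    lesion_type: str = "metastatic"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.sizes.shape:
            raise ValueError("times and sizes must be 1-D and equal-length")
        if self.times.size < 1:
            raise ValueError("a series needs at least one visit")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PatientCovariates:
    """Per-patient treatment arm, biomarkers and survival outcome."""

    patient_id: str
    arm: str
    kras: str
    ecog: str
    os_time: float
    os_event: int
    surgery_time: float | None = None

    def validate(self) -> list[str]:
        problems = []
        if self.arm not in ARMS:
            problems.append(f"arm {self.arm!r} not in {sorted(ARMS)}")
        if self.kras not in KRAS_LEVELS:
            problems.append(f"kras {self.kras!r} not in {sorted(KRAS_LEVELS)}")
        if self.ecog not in ECOG_LEVELS:
            problems.append(f"ecog {self.ecog!r} not in {sorted(ECOG_LEVELS)}")
        if not np.isfinite(self.os_time) or self.os_time <= 0:
            problems.append(f"os_time {self.os_time!r} must be > 0")
        if self.os_event not in (0, 1):
            problems.append(f"os_event {self.os_event!r} must be 0 or 1")
        if self.surgery_time is not None and (
            not np.isfinite(self.surgery_time) or self.surgery_time < 0
        ):
            problems.append(f"surgery_time {self.surgery_time!r} must be >= 0 or empty")
        return problems


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_columns(df: pd.DataFrame, fields: Sequence[str],
                     column_map: Mapping[str, str] | None,
                     optional: Sequence[str] = ()) -> dict[str, str]:
    colmap = {f: f for f in fields}
    if column_map:
        colmap.update(column_map)
    missing = [colmap[f] for f in fields
               if colmap[f] not in df.columns and f not in optional]
    if missing:
        raise TableFormatError(f"missing required column(s): {missing}")
    return colmap


def read_lesion_table(path, column_map: Mapping[str, str] | None = None,
                      sep: str = ",") -> list[LesionRecord]:
    """Read and validate a long-format lesion table.

    Parameters
    ----------
    path : str or file-like
        Delimited text file with a header row.
    column_map : mapping, optional
        Maps canonical field names (``patient_id`` ... ``metric``) to the
        file's column names when they differ.
    sep : str
        Field delimiter (default comma; pass ``"\\t"`` for TSV).

    Raises
    ------
    TableFormatError
        A required column is absent.
    RowValidationError
        Rows violate record invariants; the message names the 0-based data
        rows (and duplicate keys, where applicable).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = _resolve_columns(df, LESION_FIELDS, column_map)

    time = pd.to_numeric(df[colmap["time"]], errors="coerce")
    size = pd.to_numeric(df[colmap["size"]], errors="coerce")
    bad_numeric = sorted(df.index[time.isna() | size.isna()].tolist())
    if bad_numeric:
        raise RowValidationError(
            f"non-numeric time/size in row(s) {bad_numeric}", bad_numeric)

    records = []
    problems: dict[int, list[str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rec = LesionRecord(
            patient_id=str(getattr(row, colmap["patient_id"])),
            lesion_id=str(getattr(row, colmap["lesion_id"])),
            organ_text=str(getattr(row, colmap["organ_text"])).strip(),
            lesion_type=str(getattr(row, colmap["lesion_type"])).strip().lower(),
            time=float(time.iloc[i]),
            size=float(size.iloc[i]),
            metric=str(getattr(row, colmap["metric"])).strip().upper(),
        )
        errs = rec.validate()
        if errs:
            problems[i] = errs
        records.append(rec)
    if problems:
        detail = "; ".join(f"row {i}: {', '.join(v)}" for i, v in sorted(problems.items()))
        raise RowValidationError(f"invalid rows: {detail}", sorted(problems))

    keys = [(r.patient_id, r.lesion_id, r.time) for r in records]
    seen: dict[tuple, int] = {}
    for i, k in enumerate(keys):
        if k in seen:
            raise RowValidationError(
                f"duplicate (patient_id, lesion_id, time) key {k} in rows "
                f"{seen[k]} and {i}", [seen[k], i])
        seen[k] = i

    metrics = {r.metric for r in records}
    if len(metrics) > 1:
        raise RowValidationError(
            f"mixed size metrics {sorted(metrics)}; one run must use a single metric")
    return records


def read_covariate_table(path, column_map: Mapping[str, str] | None = None,
                         sep: str = ",") -> list[PatientCovariates]:
    """Read and validate the per-patient covariate table.

    ``surgery_time`` may be blank (no surgery).  See
    :func:`read_lesion_table` for error semantics.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = _resolve_columns(df, COVARIATE_FIELDS, column_map,
                              optional=("surgery_time",))
    has_surgery = colmap["surgery_time"] in df.columns

    covs = []
    problems: dict[int, list[str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        surgery_raw = str(getattr(row, colmap["surgery_time"])).strip() if has_surgery else ""
        try:
            surgery = float(surgery_raw) if surgery_raw else None
        except ValueError:
            problems[i] = [f"non-numeric surgery_time {surgery_raw!r}"]
            continue
        try:
            os_time = float(str(getattr(row, colmap["os_time"])))
            os_event = int(float(str(getattr(row, colmap["os_event"]))))
        except ValueError:
            problems[i] = ["non-numeric os_time/os_event"]
            continue
        cov = PatientCovariates(
            patient_id=str(getattr(row, colmap["patient_id"])),
            arm=str(getattr(row, colmap["arm"])).strip().lower(),
            kras=str(getattr(row, colmap["kras"])).strip().lower(),
            ecog=str(getattr(row, colmap["ecog"])).strip().lower(),
            os_time=os_time,
            os_event=os_event,
            surgery_time=surgery,
        )
        errs = cov.validate()
        if errs:
            problems[i] = errs
        covs.append(cov)
    if problems:
        detail = "; ".join(f"row {i}: {', '.join(v)}" for i, v in sorted(problems.items()))
        raise RowValidationError(f"invalid rows: {detail}", sorted(problems))

    pids = [c.patient_id for c in covs]
    dupes = sorted({p for p in pids if pids.count(p) > 1})
    if dupes:
        raise RowValidationError(f"duplicate patient_id(s) {dupes}")
    return covs


def write_lesion_table(records: Iterable[LesionRecord], path, sep: str = ",") -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=LESION_FIELDS)
    df.to_csv(path, sep=sep, index=False)


def write_covariate_table(covariates: Iterable[PatientCovariates], path,
                          sep: str = ",") -> None:
    rows = []
    for c in covariates:
        d = dataclasses.asdict(c)
        d["surgery_time"] = "" if c.surgery_time is None else c.surgery_time
        rows.append(d)
    df = pd.DataFrame(rows, columns=COVARIATE_FIELDS)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PreprocessReport:
    """Per-rule exclusion counts produced by :func:`preprocess`."""

    n_input_records: int = 0
    n_input_patients: int = 0
    patients_baseline_only: list[str] = field(default_factory=list)
    n_records_post_surgery_removed: int = 0
    patients_with_surgery_truncation: list[str] = field(default_factory=list)
    patients_baseline_only_after_truncation: list[str] = field(default_factory=list)
    n_output_records: int = 0
    n_output_patients: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _baseline_only_patients(records: Sequence[LesionRecord]) -> set[str]:
    times: dict[str, set[float]] = {}
    for r in records:
        times.setdefault(r.patient_id, set()).add(r.time)
    return {pid for pid, ts in times.items() if len(ts) <= 1}


def preprocess(records: Sequence[LesionRecord],
               covariates: Sequence[PatientCovariates],
               ) -> tuple[list[LesionRecord], PreprocessReport]:
    """Apply the study exclusion rules to validated lesion records.

    Rule (a) removes patients whose assessments all fall on a single visit
    (baseline only: no dynamics to compare).  Rule (b) truncates, for
    patients with a recorded tumor-surgery time, every measurement strictly
    after surgery (the last pre-surgery assessment remains valid data).
    Rule (a) is re-applied afterwards, since truncation can leave a patient
    with a single remaining visit.

    Returns the surviving records and a :class:`PreprocessReport`.
    Raises ``ValueError`` if a patient present in ``records`` has no
    covariate row.
    """
    cov_by_pid = {c.patient_id: c for c in covariates}
    missing = sorted({r.patient_id for r in records} - set(cov_by_pid))
    if missing:
        raise ValueError(f"covariates missing for patient(s): {missing}")

    report = PreprocessReport(
        n_input_records=len(records),
        n_input_patients=len({r.patient_id for r in records}),
    )

    drop_a = _baseline_only_patients(records)
    report.patients_baseline_only = sorted(drop_a)
    kept = [r for r in records if r.patient_id not in drop_a]

    truncated_patients = set()
    kept2 = []
    for r in kept:
        st = cov_by_pid[r.patient_id].surgery_time
        if st is not None and r.time > st:
            report.n_records_post_surgery_removed += 1
            truncated_patients.add(r.patient_id)
        else:
            kept2.append(r)
    report.patients_with_surgery_truncation = sorted(truncated_patients)

    drop_a2 = _baseline_only_patients(kept2)
    report.patients_baseline_only_after_truncation = sorted(drop_a2)
    out = [r for r in kept2 if r.patient_id not in drop_a2]

    report.n_output_records = len(out)
    report.n_output_patients = len({r.patient_id for r in out})
    return out, report


def build_series(records: Sequence[LesionRecord],
                 ) -> dict[str, dict[str, LesionSeries]]:
    """Assemble preprocessed records into per-lesion time series.

    Returns ``{patient_id: {lesion_id: LesionSeries}}`` with visits sorted
    by time; the lesion's organ text and type are retained as metadata.
    """
    grouped: dict[str, dict[str, list[LesionRecord]]] = {}
    for r in records:
        grouped.setdefault(r.patient_id, {}).setdefault(r.lesion_id, []).append(r)

    out: dict[str, dict[str, LesionSeries]] = {}
    for pid, lesions in grouped.items():
        out[pid] = {}
        for lid, recs in lesions.items():
            recs = sorted(recs, key=lambda r: r.time)
            out[pid][lid] = LesionSeries(
                patient_id=pid,
                series_id=lid,
                times=np.array([r.time for r in recs]),
                sizes=np.array([r.size for r in recs]),
                organ_text=recs[0].organ_text,
                lesion_type=recs[0].lesion_type,
            )
    return out


def total_ts(series_by_patient: Mapping[str, Mapping[str, LesionSeries]],
             t_query: float, tolerance: float = 2.0) -> dict[str, float | None]:
    """Per-patient total tumor size at the visit nearest ``t_query``.

    For each patient, the assessment visit whose time is nearest to
    ``t_query`` (ties -> earlier visit) within ``tolerance`` weeks is
    selected, and the sizes of all lesions actually measured at that visit
    are summed.  Patients with no qualifying visit map to ``None`` --
    missingness is a value, not an error.
    """
    if t_query < 0 or tolerance < 0:
        raise ValueError("t_query and tolerance must be >= 0")
    out: dict[str, float | None] = {}
    for pid, lesions in series_by_patient.items():
        visit_times = sorted({float(t) for s in lesions.values() for t in s.times})
        candidates = [t for t in visit_times if abs(t - t_query) <= tolerance]
        if not candidates:
            out[pid] = None
            continue
        best = min(candidates, key=lambda t: (abs(t - t_query), t))
        total = 0.0
        for s in lesions.values():
            hit = np.isclose(s.times, best)
            if hit.any():
                total += float(s.sizes[hit][0])
        out[pid] = total
    return out


def flatten_series(series_by_patient: Mapping[str, Mapping[str, LesionSeries]],
                   metric: str = "SLD") -> list[LesionRecord]:
    """Inverse of :func:`build_series` (up to record order)."""
    recs = []
    for pid, lesions in series_by_patient.items():
        for lid, s in lesions.items():
            for t, v in zip(s.times, s.sizes):
                recs.append(LesionRecord(pid, lid, s.organ_text, s.lesion_type,
                                         float(t), float(v), metric))
    return recs
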