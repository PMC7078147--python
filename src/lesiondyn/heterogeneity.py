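"""Inter-class and intra-class heterogeneity analyses.

The inter-class analysis sums, within each patient, the sizes of all
lesions of one organ class into a class-related target lesion (cTL) and
cross-correlates the patient's cTL pairs (e.g. liver-lung) -- lesion
dynamics *between* tissues.  The intra-class analysis cross-correlates
individual lesion pairs within one class -- dynamics *within* a tissue.

The resulting CC values are grouped by 1-D K-means.  Cluster count is
either fixed (the conventional choice is k = 3) or chosen by the elbow
method on the SSE curve (maximum curvature of log SSE vs k).
Clusters are numbered 1..k by ascending centroid, so cluster 1 is the most
negative ("different dynamics") and cluster k the most positive ("similar
dynamics"); centroids below -0.35 are labeled "different", above +0.35
"similar", in between "undefined".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifiedLesion
from .crosscorr import CCRecord, cc_profile, DEFAULT_MAX_LAG
from .trial_data import LesionSeries

SIMILAR_CUT = 0.35
DIFFERENT_CUT = -0.35


# ---------------------------------------------------------------------------
# cTL construction and pair enumeration


def build_ctls(lesion_series: Mapping[str, LesionSeries],
               class_of: Mapping[str, str]) -> dict[str, LesionSeries]:
    """Sum one patient's lesions into per-class series (cTLs).

    The sum runs over complete-case visits only: a visit enters the cTL iff
    *all* lesions of the class were measured at it, so the summed series is
    never deflated by a partially missing visit.  Classes whose summed
    series retains fewer than two visits are dropped (no dynamics).
    """
    by_class: dict[str, list[LesionSeries]] = {}
    for lid, s in lesion_series.items():
        by_class.setdefault(class_of[lid], []).append(s)

    out: dict[str, LesionSeries] = {}
    for cls, members in by_class.items():
        times = members[0].times
        for s in members[1:]:
            times = np.intersect1d(times, s.times)
        if times.size < 2:
            continue
        total = np.zeros(times.size)
        for s in members:
            idx = np.searchsorted(s.times, times)
            total += s.sizes[idx]
        out[cls] = LesionSeries(
            patient_id=members[0].patient_id,
            series_id=cls,
            times=times,
            sizes=total,
        )
    return out


def build_all_ctls(series_by_patient: Mapping[str, Mapping[str, LesionSeries]],
                   classified: Mapping[str, Mapping[str, ClassifiedLesion]],
                   ) -> dict[str, dict[str, LesionSeries]]:
    return {
        pid: build_ctls(lesions,
                        {lid: classified[pid][lid].class_name for lid in lesions})
        for pid, lesions in series_by_patient.items()
    }


def interclass_pairs(ctls_by_patient: Mapping[str, Mapping[str, LesionSeries]],
                     max_lag: int = DEFAULT_MAX_LAG) -> list[CCRecord]:
    """One CC record per unordered cTL (class) pair, per patient.

    Patients with fewer than two eligible classes contribute nothing: the
    analysis includes only patients presenting lesions in more than one
    tissue.
    """
    records = []
    for pid in sorted(ctls_by_patient):
        ctls = ctls_by_patient[pid]
        classes = sorted(ctls)
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                records.append(cc_profile(ctls[classes[i]], ctls[classes[j]],
                                          max_lag, kind="inter"))
    return records


def intraclass_pairs(series_by_patient: Mapping[str, Mapping[str, LesionSeries]],
                     classified: Mapping[str, Mapping[str, ClassifiedLesion]],
                     class_name: str, max_lag: int = DEFAULT_MAX_LAG,
                     ) -> list[CCRecord]:
    """All unordered within-patient lesion pairs of one class.

    Only patients with more than one lesion in the class enter the
    analysis of that class.
    """
    records = []
    for pid in sorted(series_by_patient):
        lesions = series_by_patient[pid]
        members = sorted(lid for lid in lesions
                         if classified[pid][lid].class_name == class_name)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                records.append(cc_profile(lesions[members[i]], lesions[members[j]],
                                          max_lag, kind="intra"))
    return records


# ---------------------------------------------------------------------------
# 1-D K-means and elbow selection


@dataclass
class ClusterResult:
    """K-means output on a set of scalar CC values.

    ``centroids`` are sorted ascending and clusters renumbered accordingly,
    so label 0 ("cluster 1") is the lowest-centroid cluster.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    sse: float
    values: np.ndarray

    @property
    def n(self) -> int:
        return int(self.values.size)


def _dp_tables(v_sorted: np.ndarray, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D K-means dynamic program on sorted values.

    Optimal 1-D clusters are contiguous in sorted order, so the global
    optimum is found by partitioning: ``D[j, i]`` is the minimal SSE of the
    first ``i`` points split into ``j`` clusters, ``A[j, i]`` the argmin
    split point.  O(k n^2) with vectorized inner minimization.
    """
    n = v_sorted.size
    cs = np.concatenate(([0.0], np.cumsum(v_sorted)))
    cs2 = np.concatenate(([0.0], np.cumsum(v_sorted * v_sorted)))
    D = np.full((k_max + 1, n + 1), np.inf)
    A = np.zeros((k_max + 1, n + 1), dtype=np.int64)
    D[0, 0] = 0.0
    for j in range(1, k_max + 1):
        for i in range(j, n + 1):
            m = np.arange(j - 1, i)      # last point of the previous cluster
            length = i - m
            seg_sum = cs[i] - cs[m]
            seg_cost = np.maximum((cs2[i] - cs2[m]) - seg_sum * seg_sum / length,
                                  0.0)
            total = D[j - 1, m] + seg_cost
            t = int(np.argmin(total))    # ties -> earliest split
            D[j, i] = total[t]
            A[j, i] = m[t]
    return D, A


def _dp_labels(A: np.ndarray, k: int, n: int) -> np.ndarray:
    bounds = [n]
    for j in range(k, 0, -1):
        bounds.append(int(A[j, bounds[-1]]))
    bounds = bounds[::-1]                # 0 = b0 < b1 < ... < bk = n
    labels = np.empty(n, dtype=int)
    for c in range(k):
        labels[bounds[c]:bounds[c + 1]] = c
    return labels


def kmeans_1d(values: Sequence[float], k: int, seed: int = 0,
              n_restarts: int = 50) -> ClusterResult:
    """Globally optimal K-means on scalars (exact dynamic programming).

    In one dimension the optimal clusters are contiguous intervals of the
    sorted values, so the minimum-SSE assignment is computed exactly by
    dynamic programming over split points rather than by randomized
    Lloyd iterations; the result is deterministic and always at least as
    good as any restarted Lloyd run.  ``seed`` and ``n_restarts`` are
    accepted for interface stability and do not affect the (already
    deterministic) result.

    Raises ``ValueError`` when ``k`` exceeds the number of distinct values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    n_distinct = np.unique(v).size
    if k < 1 or k > n_distinct:
        raise ValueError(f"k={k} must be in 1..{n_distinct} (distinct values)")
    order = np.argsort(v, kind="stable")
    vs = v[order]
    D, A = _dp_tables(vs, k)
    sorted_labels = _dp_labels(A, k, vs.size)
    labels = np.empty(v.size, dtype=int)
    labels[order] = sorted_labels
    centroids = np.array([vs[sorted_labels == c].mean() for c in range(k)])
    return ClusterResult(
        k=k,
        centroids=centroids,
        labels=labels,
        sse=float(D[k, vs.size]),
        values=v,
    )


def sse_curve(values: Sequence[float], k_max: int, seed: int = 0,
              n_restarts: int = 50) -> np.ndarray:
    """Optimal SSE(k) for k = 1..k_max (single dynamic-programming pass)."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    if k_max > np.unique(v).size:
        raise ValueError("k_max exceeds the number of distinct values")
    D, _ = _dp_tables(v, k_max)
    return D[1:, v.size].copy()


def elbow_k_from_sse(sse: Sequence[float]) -> int:
    """Elbow of an SSE-vs-k curve: the k of maximum curvature of log SSE,
    i.e. maximizing log SSE(k-1) - 2 log SSE(k) + log SSE(k+1); ties ->
    smaller k.

    The log scale makes the bend detection scale-free: with well-separated
    groups the *relative* SSE drop collapses after the true k, whereas raw
    second differences are dominated by the huge absolute drop from k=1 to
    k=2 and would call an elbow at 2 regardless of structure.
    """
    s = np.asarray(sse, dtype=float)
    if s.size < 3:
        raise ValueError("need SSE for at least k = 1..3")
    if np.any(s < 0):
        raise ValueError("SSE values must be >= 0")
    s = np.maximum(s, 1e-300)
    ls = np.log(s)
    curvature = ls[:-2] - 2.0 * ls[1:-1] + ls[2:]
    return int(np.argmax(curvature)) + 2


def choose_k_elbow(values: Sequence[float], k_max: int = 6, seed: int = 0,
                   n_restarts: int = 50) -> int:
    """Select the cluster count by the elbow method.

    Computes SSE(k) for k = 1..k_max (shrinking k_max with a warning when
    there are fewer than k_max + 1 distinct values) and returns the k of
    maximum curvature.  SSE(k) is checked to be non-increasing (guaranteed
    by the exact optimizer).
    """
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    v = np.asarray(values, dtype=float).ravel()
    n_distinct = np.unique(v).size
    if n_distinct < k_max + 1:
        new_k_max = n_distinct - 1
        if new_k_max < 3:
            raise ValueError(
                f"only {n_distinct} distinct values; elbow needs at least 4")
        warnings.warn(f"k_max shrunk from {k_max} to {new_k_max} "
                      f"({n_distinct} distinct values)", stacklevel=2)
        k_max = new_k_max
    sse = sse_curve(v, k_max, seed, n_restarts)
    if np.any(np.diff(sse) > 1e-8 * max(1.0, float(sse[0]))):
        raise RuntimeError(f"SSE(k) not non-increasing: {sse}")
    return elbow_k_from_sse(sse)


# ---------------------------------------------------------------------------
# clustering of CC records and reporting


def cluster_cc(cc_records: Sequence[CCRecord], use_max_cc: bool = False,
               k: int | None = 3, k_max: int = 6, seed: int = 0,
               n_restarts: int = 50,
               ) -> tuple[ClusterResult, list[CCRecord]]:
    """Cluster the defined CC values of a set of pair records.

    ``use_max_cc`` selects the lag-maximized CC instead of the zero-shift
    CC.  Undefined (NaN) values are excluded and reported separately by
    :func:`cluster_report`.  ``k=None`` triggers elbow selection.
    Returns the cluster result and the records actually clustered, in the
    same order as ``result.values``.
    """
    picked = [(r, r.cc_max if use_max_cc else r.cc_zero) for r in cc_records]
    kept = [(r, v) for r, v in picked if np.isfinite(v)]
    if not kept:
        raise ValueError("no defined CC values to cluster")
    values = np.array([v for _, v in kept])
    if k is None:
        k = choose_k_elbow(values, k_max, seed, n_restarts)
    result = kmeans_1d(values, k, seed, n_restarts)
    return result, [r for r, _ in kept]


def interpretation_label(centroid: float, similar_cut: float = SIMILAR_CUT,
                         different_cut: float = DIFFERENT_CUT) -> str:
    if centroid < different_cut:
        return "different"
    if centroid > similar_cut:
        return "similar"
    return "undefined"


def cluster_report(result: ClusterResult, records: Sequence[CCRecord],
                   similar_cut: float = SIMILAR_CUT,
                   different_cut: float = DIFFERENT_CUT,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster summary table and best-lag histogram.

    The table has one row per cluster (numbered 1..k by ascending
    centroid): centroid, % of CC pairs, % of patients with >= 1 pair in the
    cluster, and the interpretation label.  Pair percentages sum to 100;
    patient percentages can exceed 100 summed over clusters because one
    patient may have pairs in several clusters.  The histogram is long
    format (cluster, lag, count) over the lags at which each pair's CC was
    maximized.
    """
    if len(records) != result.n:
        raise ValueError("records must align with the clustered values")
    n_pairs = result.n
    all_patients = {r.patient_id for r in records}
    rows = []
    hist_rows = []
    for c in range(result.k):
        member_idx = np.flatnonzero(result.labels == c)
        members = [records[i] for i in member_idx]
        patients = {r.patient_id for r in members}
        centroid = float(result.centroids[c])
        rows.append({
            "cluster": c + 1,
            "centroid": centroid,
            "n_pairs": len(members),
            "pct_pairs": 100.0 * len(members) / n_pairs,
            "n_patients": len(patients),
            "pct_patients": 100.0 * len(patients) / len(all_patients),
            "label": interpretation_label(centroid, similar_cut, different_cut),
        })
        lags, counts = np.unique([r.best_lag for r in members], return_counts=True)
        for lag, cnt in zip(lags, counts):
            hist_rows.append({"cluster": c + 1, "lag": int(lag), "count": int(cnt)})
    report = pd.DataFrame(rows, columns=["cluster", "centroid", "n_pairs",
                                         "pct_pairs", "n_patients",
                                         "pct_patients", "label"])
    hist = pd.DataFrame(hist_rows, columns=["cluster", "lag", "count"])
    return report, hist


def similar_share(report: pd.DataFrame, similar_cut: float = SIMILAR_CUT) -> float:
    """Total % of pairs with similar dynamics: the top cluster plus any
    other cluster whose centroid also exceeds the similarity cutoff."""
    mask = report["centroid"] > similar_cut
    return float(report.loc[mask, "pct_pairs"].sum())


def undefined_cc_count(cc_records: Sequence[CCRecord], use_max_cc: bool = False) -> int:
    """Number of pairs whose selected CC is undefined (flat segment or
    insufficient overlap); these are excluded from clustering."""
    vals = [r.cc_max if use_max_cc else r.cc_zero for r in cc_records]
    return int(sum(0 if np.isfinite(v) else 1 for v in vals))
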