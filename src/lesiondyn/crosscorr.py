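"""Cross-correlation of lesion-size time courses.

The similarity of two within-patient lesion trajectories is summarized by
the cross-correlation coefficient (CC): the Pearson product-moment
correlation of the two size vectors on their shared assessment grid,
evaluated at zero lag and at integer visit-index shifts of one series over
the other.  CC values lie in [-1, 1]: values near 1 indicate similar
dynamics, values near -1 opposite dynamics, values near 0 undefined
relationships.

Lags are counted in assessment *visits*, not calendar time: within a
patient the protocol synchronizes assessment dates, so a shift of one
visit is the natural unit of delay.  At each lag the correlation is
normalized by the mean and standard deviation of the overlapping window
only, which is what keeps every value inside [-1, 1].

A pair needs at least two shared visits to be computable; with exactly two
the CC is +/-1 by construction and no shift is possible.  A window with
zero variance (flat segment) has no defined correlation; such values are
returned as NaN and excluded downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trial_data import LesionSeries

DEFAULT_MAX_LAG = 12

_TIE_TOL = 1e-12


@dataclass
class CCRecord:
    """Cross-correlation result for one lesion (or class) pair.

    ``cc_zero``/``cc_max`` are NaN when undefined.  ``lag_profile`` maps
    each evaluated lag to its CC.  ``kind`` tags the analysis ("inter" for
    class-level pairs, "intra" for within-class lesion pairs).
    """

    patient_id: str
    id_a: str
    id_b: str
    cc_zero: float
    cc_max: float
    best_lag: int
    n_overlap_zero: int
    lag_profile: dict[int, float] = field(default_factory=dict)
    kind: str = ""
    note: str = ""

    @property
    def computable(self) -> bool:
        return self.n_overlap_zero >= 2


def align_series(a: LesionSeries, b: LesionSeries,
                 time_tolerance: float = 0.0,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Visits present in both series, in time order.

    Returns ``(times, sizes_a, sizes_b)``.  With the default tolerance 0,
    visits match on exact time equality; a positive tolerance greedily
    pairs each visit of ``a`` with the nearest unused visit of ``b`` within
    tolerance.  Fewer than two common visits makes the pair non-computable
    (the caller decides how to flag it).
    """
    ta, tb = a.times, b.times
    if time_tolerance <= 0:
        common, ia, ib = np.intersect1d(ta, tb, return_indices=True)
        return common, a.sizes[ia], b.sizes[ib]
    used = np.zeros(tb.size, dtype=bool)
    times, xa, xb = [], [], []
    for i, t in enumerate(ta):
        d = np.abs(tb - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= time_tolerance:
            used[j] = True
            times.append((t + tb[j]) / 2.0)
            xa.append(a.sizes[i])
            xb.append(b.sizes[j])
    return np.asarray(times), np.asarray(xa), np.asarray(xb)


def cc_at_lag(x: Sequence[float], y: Sequence[float], lag: int) -> float:
    """Pearson correlation of ``x[i]`` with ``y[i + lag]`` over the overlap.

    ``x`` and ``y`` must be equal-length aligned vectors (n >= 2) and
    ``|lag| <= n - 2`` so the overlap keeps at least two points.  Returns
    NaN when either overlapping segment has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 2:
        raise ValueError("insufficient overlap: need at least 2 points")
    if abs(lag) > n - 2:
        raise ValueError(f"|lag| must be <= {n - 2} for length-{n} vectors")
    if lag >= 0:
        xs, ys = x[: n - lag], y[lag:]
    else:
        xs, ys = x[-lag:], y[: n + lag]
    if xs.size == 2:
        # two points: correlation is the sign of the joint step, exactly
        dx, dy = xs[1] - xs[0], ys[1] - ys[0]
        if dx == 0.0 or dy == 0.0:
            return float("nan")
        return 1.0 if (dx > 0) == (dy > 0) else -1.0
    scale_x = float(np.max(np.abs(xs)))
    scale_y = float(np.max(np.abs(ys)))
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    sx = float(np.sqrt(np.sum(xs * xs)))
    sy = float(np.sqrt(np.sum(ys * ys)))
    # a segment is flat (undefined correlation) when its spread is zero up
    # to float round-off relative to the segment's magnitude
    if sx <= 1e-9 * scale_x or sy <= 1e-9 * scale_y or sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.sum(xs * ys) / (sx * sy))
    return min(1.0, max(-1.0, r))


def cc_profile(a: LesionSeries, b: LesionSeries, max_lag: int = DEFAULT_MAX_LAG,
               time_tolerance: float = 0.0, patient_id: str | None = None,
               kind: str = "") -> CCRecord:
    """Zero-lag and lag-maximized CC for one pair of series.

    Lags -L..L are evaluated with ``L = min(max_lag, n_overlap - 2)``, so a
    two-assessment pair admits only lag 0 (CC then is +/-1, or NaN if a
    segment is flat).  ``best_lag`` attains the maximum CC; ties are broken
    toward the smallest |lag|, then toward the negative lag.
    """
    pid = patient_id if patient_id is not None else a.patient_id
    times, xa, xb = align_series(a, b, time_tolerance)
    n = int(times.size)
    if n < 2:
        return CCRecord(pid, a.series_id, b.series_id,
                        float("nan"), float("nan"), 0, n,
                        kind=kind, note="insufficient overlap")
    L = min(max_lag, n - 2)
    profile = {lag: cc_at_lag(xa, xb, lag) for lag in range(-L, L + 1)}
    defined = {lag: v for lag, v in profile.items() if np.isfinite(v)}
    if not defined:
        return CCRecord(pid, a.series_id, b.series_id,
                        float("nan"), float("nan"), 0, n, profile,
                        kind=kind, note="zero variance")
    vmax = max(defined.values())
    candidates = [lag for lag, v in defined.items() if v >= vmax - _TIE_TOL]
    best = min(candidates, key=lambda lag: (abs(lag), lag > 0))
    return CCRecord(pid, a.series_id, b.series_id,
                    profile[0], defined[best], int(best), n, profile,
                    kind=kind)


def cc_records_to_frame(records: Iterable[CCRecord]) -> pd.DataFrame:
    """Flatten CC records to a table (one row per pair) for CSV export."""
    rows = [
        {
            "patient_id": r.patient_id,
            "id_a": r.id_a,
            "id_b": r.id_b,
            "cc_zero": r.cc_zero,
            "cc_max": r.cc_max,
            "best_lag": r.best_lag,
            "n_overlap": r.n_overlap_zero,
            "kind": r.kind,
            "note": r.note,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "id_a", "id_b", "cc_zero", "cc_max",
                       "best_lag", "n_overlap", "kind", "note"])


def pairwise_profiles(series: Sequence[LesionSeries], max_lag: int = DEFAULT_MAX_LAG,
                      time_tolerance: float = 0.0, kind: str = "") -> list[CCRecord]:
    """CC profiles for every unordered pair of the given series."""
    return [cc_profile(a, b, max_lag, time_tolerance, kind=kind)
            for a, b in itertools.combinations(series, 2)]
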