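"""End-to-end early-warning analysis of R-R interval cohorts.

The procedure: crop every pre-tachyarrhythmia (VT) and control (CR)
record to a common length from the end, so the arrhythmia onset sits at
the final sample; slide a fixed-length window (default 60 samples, stride
1) along each record; transform each window into its epsilon-regular
graph (default epsilon = 0.04 s) and record the mean graph degree; average
the per-window degree across subjects per group; subtract CR from VT
pairwise; and read the early warning off the difference curve as its
global minimum followed by the first local maximum.  The warning lead
time is the summed RR intervals from the warning window to the onset.

Window indexing is 1-based with window i starting at sample i, so
"window i" and "sample i" coincide — the warning window index is directly
a position in the record.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
import pandas as pd

from .core import TimeSeries, as_series
from .io_rr import CohortRecord, pair_records

__all__ = [
    "AnalysisConfig",
    "WindowedDegreeCurve",
    "EarlyWarning",
    "EarlyWarningReport",
    "crop_tail",
    "subsample_segment",
    "windowed_mean_degree",
    "group_average_curve",
    "difference_curve",
    "detect_early_warning",
    "lead_time_seconds",
    "epsilon_sweep",
    "rr_gap_statistics",
    "analyze_cohort",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the early-warning analysis.

    Defaults: adjacency threshold 0.04 s (about the mean consecutive RR
    gap of the pre-VT records), 60-sample windows with stride 1, records
    cropped to their last 985 samples, DFA crossover at box size 15, no
    smoothing of the difference curve.
    """

    epsilon: float = 0.04
    window: int = 60
    offset: int = 1
    crop_length: int = 985
    crossover: int = 15
    seed: int = 0
    smoothing: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon < 0 or not np.isfinite(self.epsilon):
            raise ValueError("epsilon must be finite and >= 0")
        for name in ("window", "offset", "crop_length", "crossover"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.smoothing is not None and int(self.smoothing) < 1:
            raise ValueError("smoothing window must be a positive integer")


@dataclass
class WindowedDegreeCurve:
    """Per-window mean epsilon-graph degree for one record.

    ``window_index`` is 1-based: window i covers samples i .. i+w-1.
    """

    window_index: np.ndarray
    mean_degree: np.ndarray
    w: int
    offset: int
    epsilon: float
    subject_id: str = ""

    def __len__(self) -> int:
        return self.mean_degree.size

    def same_grid(self, other: "WindowedDegreeCurve") -> bool:
        return (
            self.w == other.w
            and self.offset == other.offset
            and len(self) == len(other)
            and bool(np.array_equal(self.window_index, other.window_index))
        )


@dataclass(frozen=True)
class EarlyWarning:
    """Location and value of the difference-curve minimum and the
    following local maximum (1-based window indices)."""

    min_index: int
    min_value: float
    max_index: int
    max_value: float


@dataclass
class EarlyWarningReport:
    """Early warning plus per-subject and mean lead times in seconds."""

    min_index: int
    min_value: float
    max_index: int
    max_value: float
    lead_seconds_per_subject: dict[str, float]
    mean_lead_seconds: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def crop_tail(series, L: int) -> TimeSeries:
    """Keep the last ``L`` samples (the event onset stays at the end)."""
    ts = as_series(series)
    if not 1 <= L <= len(ts):
        raise ValueError(f"cannot crop to {L} points from a series of length {len(ts)}")
    return TimeSeries(ts.values[len(ts) - L :], ts.units_label)


def subsample_segment(series, L: int, rng) -> TimeSeries:
    """A uniformly random contiguous segment of length ``L`` (seeded)."""
    ts = as_series(series)
    if not 1 <= L <= len(ts):
        raise ValueError(f"cannot subsample {L} points from a series of length {len(ts)}")
    rng = np.random.default_rng(rng)
    start = int(rng.integers(0, len(ts) - L + 1))
    return TimeSeries(ts.values[start : start + L], ts.units_label)


def _window_mean_degrees(x: np.ndarray, w: int, offset: int, eps: float) -> np.ndarray:
    """Mean epsilon-graph degree of every sliding window.

    For the short windows this pipeline uses, an all-pairs adjacency count
    per window (the literal edge predicate, vectorized across windows) is
    fastest; for long windows it falls back to sorted interval queries per
    window.  Both are extensionally identical to building the graph.
    """
    W = sliding_window_view(x, w)[::offset]
    S = np.sort(W, axis=1)
    m = S.shape[0]
    rows = np.arange(m)
    # For sorted window row S[k] and pivot column j, the neighbours of
    # S[k, j] form the index range [lo, hi): hi is the end of the prefix
    # with S - S[k, j] <= eps, lo the start of the suffix with
    # S[k, j] - S <= eps.  Both are non-decreasing in j, so a two-pointer
    # sweep over columns, vectorized across rows, costs O(m * w) total and
    # evaluates the literal edge predicate (exact IEEE comparisons).
    hi = np.zeros(m, dtype=np.int64)
    lo = np.zeros(m, dtype=np.int64)
    total = np.zeros(m, dtype=np.int64)
    for j in range(w):
        vj = S[:, j]
        while True:
            adv = (hi < w) & (S[rows, np.minimum(hi, w - 1)] - vj <= eps)
            if not adv.any():
                break
            hi[adv] += 1
        while True:
            adv = (lo < j) & (vj - S[rows, lo] > eps)
            if not adv.any():
                break
            lo[adv] += 1
        total += hi - lo - 1
    return total / w


def windowed_mean_degree(
    series, w: int = 60, offset: int = 1, epsilon: float = 0.04, subject_id: str = ""
) -> WindowedDegreeCurve:
    """Sliding-window mean epsilon-graph degree of a series.

    Window i (1-based) covers samples i .. i+w-1; degrees are raw
    (unnormalized), so values lie in [0, w-1].
    """
    ts = as_series(series)
    if len(ts) < w:
        raise ValueError(f"series of length {len(ts)} is shorter than the window {w}")
    if offset < 1:
        raise ValueError("offset must be >= 1")
    if epsilon < 0 or not np.isfinite(epsilon):
        raise ValueError("epsilon must be finite and >= 0")
    md = _window_mean_degrees(ts.values, w, offset, float(epsilon))
    idx = 1 + offset * np.arange(md.size)
    return WindowedDegreeCurve(idx, md, w, offset, float(epsilon), subject_id)


def _check_grids(curves: list[WindowedDegreeCurve]) -> None:
    if not curves:
        raise ValueError("need at least one curve")
    first = curves[0]
    for c in curves[1:]:
        if not first.same_grid(c):
            raise ValueError("curves have mismatched window grids")


def group_average_curve(curves: list[WindowedDegreeCurve]) -> WindowedDegreeCurve:
    """Arithmetic mean of several curves on an identical window grid."""
    _check_grids(curves)
    mean = np.mean([c.mean_degree for c in curves], axis=0)
    f = curves[0]
    return WindowedDegreeCurve(f.window_index.copy(), mean, f.w, f.offset, f.epsilon, subject_id="")


def difference_curve(
    vt_curves: list[WindowedDegreeCurve], cr_curves: list[WindowedDegreeCurve]
) -> WindowedDegreeCurve:
    """Per-window mean over subjects of (VT degree − CR degree).

    Curves are paired by subject_id; the per-pair difference is averaged
    (by linearity this equals the difference of the group means, which is
    asserted as an identity in the test suite, not relied on here).
    """
    _check_grids(vt_curves + cr_curves)
    vt = {c.subject_id: c for c in vt_curves}
    cr = {c.subject_id: c for c in cr_curves}
    if len(vt) != len(vt_curves) or len(cr) != len(cr_curves):
        raise ValueError("duplicate subject_id among curves")
    missing = sorted(set(vt) ^ set(cr))
    if missing:
        raise ValueError(f"unpaired subjects: {', '.join(missing)}")
    diffs = [vt[s].mean_degree - cr[s].mean_degree for s in sorted(vt)]
    f = vt_curves[0]
    return WindowedDegreeCurve(
        f.window_index.copy(), np.mean(diffs, axis=0), f.w, f.offset, f.epsilon, subject_id=""
    )


def _smooth(y: np.ndarray, k: int) -> np.ndarray:
    """Centred moving average with edge shrinking (window clipped at ends)."""
    if k <= 1:
        return y
    half = k // 2
    out = np.empty_like(y, dtype=float)
    for i in range(y.size):
        out[i] = y[max(0, i - half) : min(y.size, i + half + 1)].mean()
    return out


def detect_early_warning(diff: WindowedDegreeCurve | np.ndarray, smoothing: int | None = None) -> EarlyWarning:
    """Global minimum, then the first local maximum after it.

    The minimum takes the first window on ties.  The maximum is the first
    window i after the minimum with y[i] > y[i-1] and y[i] >= y[i+1]
    (so the first index of a plateau following a rise qualifies); if the
    curve never turns down again, the final window is reported.
    Optionally a centred moving average of width ``smoothing`` is applied
    first.
    """
    if isinstance(diff, WindowedDegreeCurve):
        idx, y = diff.window_index, diff.mean_degree
    else:
        y = np.asarray(diff, dtype=float)
        idx = 1 + np.arange(y.size)
    if y.size < 3:
        raise ValueError("need at least 3 windows to detect an early warning")
    if np.all(y == y[0]):
        raise ValueError("early-warning detection is undefined on a constant curve")
    ys = _smooth(y, smoothing) if smoothing else y
    kmin = int(np.argmin(ys))
    kmax = None
    for k in range(kmin + 1, ys.size - 1):
        if ys[k] > ys[k - 1] and ys[k] >= ys[k + 1]:
            kmax = k
            break
    if kmax is None:
        kmax = ys.size - 1
    return EarlyWarning(int(idx[kmin]), float(ys[kmin]), int(idx[kmax]), float(ys[kmax]))


def lead_time_seconds(
    vt_records: list[CohortRecord], warning_point: int, crop_length: int
) -> tuple[dict[str, float], float]:
    """Seconds from the warning point to the event onset, per subject.

    Each VT record is cropped to its last ``crop_length`` samples; the
    lead time is the sum of the RR intervals from sample ``warning_point``
    through the final sample, inclusive (both 1-based).  Returns the
    per-subject mapping and the cross-subject mean.
    """
    if not vt_records:
        raise ValueError("need at least one VT record")
    if not 1 <= warning_point <= crop_length:
        raise ValueError(f"warning point {warning_point} outside [1, {crop_length}]")
    leads = {}
    for r in vt_records:
        rr = crop_tail(r.rr, crop_length).values
        leads[r.subject_id] = float(rr[warning_point - 1 :].sum())
    return leads, float(np.mean(list(leads.values())))


def rr_gap_statistics(records: list[CohortRecord]) -> tuple[float, float, float]:
    """Mean, min and max absolute consecutive RR difference, pooled.

    Consecutive |RR[i+1] − RR[i]| gaps are pooled across all records
    before taking the statistics.  (Other readings — all pairs, or
    per-record statistics then averaged — would give different numbers;
    pooled consecutive gaps is the convention here.)
    """
    if not records:
        raise ValueError("need at least one record")
    gaps = []
    for r in records:
        if len(r.rr) < 2:
            raise ValueError(f"record {r.subject_id} too short for gap statistics")
        gaps.append(np.abs(np.diff(r.rr.values)))
    pooled = np.concatenate(gaps)
    return float(pooled.mean()), float(pooled.min()), float(pooled.max())


@dataclass
class CohortCurves:
    """Group-mean degree curves and the paired VT−CR difference curve."""

    vt_mean: WindowedDegreeCurve
    cr_mean: WindowedDegreeCurve
    hs_mean: WindowedDegreeCurve | None
    diff: WindowedDegreeCurve

    def to_frame(self) -> pd.DataFrame:
        data = {
            "window_index": self.vt_mean.window_index,
            "VT_mean": self.vt_mean.mean_degree,
            "CR_mean": self.cr_mean.mean_degree,
            "diff": self.diff.mean_degree,
        }
        if self.hs_mean is not None:
            data["HS_mean"] = self.hs_mean.mean_degree
        return pd.DataFrame(data)


def _prepare_records(
    records: list[CohortRecord], config: AnalysisConfig
) -> tuple[list[CohortRecord], list[CohortRecord], list[CohortRecord]]:
    """Crop VT/CR from the end; subsample a random HS segment (seeded)."""
    rng = np.random.default_rng(config.seed)
    vt, cr, hs = [], [], []
    for r in records:
        if r.group == "HS":
            seg = subsample_segment(r.rr, config.crop_length, rng)
            hs.append(CohortRecord(r.subject_id, r.group, seg))
        else:
            cropped = CohortRecord(r.subject_id, r.group, crop_tail(r.rr, config.crop_length))
            (vt if r.group == "VT" else cr).append(cropped)
    return vt, cr, hs


def _curves_for(records: list[CohortRecord], config: AnalysisConfig, epsilon: float) -> list[WindowedDegreeCurve]:
    return [
        windowed_mean_degree(r.rr, config.window, config.offset, epsilon, subject_id=r.subject_id)
        for r in records
    ]


def analyze_cohort(
    records: list[CohortRecord], config: AnalysisConfig = AnalysisConfig()
) -> tuple[CohortCurves, EarlyWarningReport]:
    """Run the full early-warning analysis on a cohort.

    Returns the group curves (VT mean, CR mean, optional HS mean, VT−CR
    difference) and the early-warning report: difference-curve minimum,
    following local maximum, and lead times computed at the minimum
    (the warning point).  HS records inform the group curves only; they
    never enter warning detection.
    """
    vt, cr, hs = _prepare_records(records, config)
    if not vt or not cr:
        raise ValueError("cohort must contain paired VT and CR records")
    pair_records(vt + cr)
    vt_curves = _curves_for(vt, config, config.epsilon)
    cr_curves = _curves_for(cr, config, config.epsilon)
    hs_curves = _curves_for(hs, config, config.epsilon)
    curves = CohortCurves(
        vt_mean=group_average_curve(vt_curves),
        cr_mean=group_average_curve(cr_curves),
        hs_mean=group_average_curve(hs_curves) if hs_curves else None,
        diff=difference_curve(vt_curves, cr_curves),
    )
    warning = detect_early_warning(curves.diff, config.smoothing)
    leads, mean_lead = lead_time_seconds(vt, warning.min_index, config.crop_length)
    report = EarlyWarningReport(
        warning.min_index, warning.min_value, warning.max_index, warning.max_value, leads, mean_lead
    )
    return curves, report


def epsilon_sweep(
    records: list[CohortRecord],
    epsilons=(0.01, 0.02, 0.03, 0.04, 0.05, 0.06),
    config: AnalysisConfig = AnalysisConfig(),
) -> dict[float, WindowedDegreeCurve]:
    """VT−CR difference curve for each adjacency threshold in ``epsilons``."""
    vt, cr, _ = _prepare_records(records, config)
    if not vt or not cr:
        raise ValueError("cohort must contain paired VT and CR records")
    pair_records(vt + cr)
    out = {}
    for eps in epsilons:
        vt_curves = _curves_for(vt, config, float(eps))
        cr_curves = _curves_for(cr, config, float(eps))
        out[float(eps)] = difference_curve(vt_curves, cr_curves)
    return out
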