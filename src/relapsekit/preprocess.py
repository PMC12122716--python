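"""Raw-stream cleaning: range filtering, gap handling, ectopic correction.

Cleaning runs in a fixed order per day:

1. out-of-range samples are removed (their slots become missing),
2. missing runs of at most 3 h are filled by linear interpolation between
   the bounding observations (leading/trailing runs use nearest-value
   extension); longer runs are left missing and the spanned interval is
   flagged for discard,
3. the RR stream is scanned for ectopic beats — samples deviating more
   than 20% from the running median of the preceding five cleaned samples
   are replaced by interpolation across accepted neighbours — yielding the
   NN series.

Each stage reports counts so that surviving + removed + discarded samples
always reconcile with the input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .synthio import RawDayRecord

MAX_GAP_SECONDS = 3 * 3600.0
ECTOPIC_THRESHOLD = 0.20
_MEDIAN_WINDOW = 5


@dataclass(frozen=True)
class ValidRanges:
    """Physiologically plausible value ranges; samples outside are dropped."""

    hr: Tuple[float, float] = (30.0, 220.0)  # bpm
    rr: Tuple[float, float] = (250.0, 2000.0)  # ms
    accel_norm: Tuple[float, float] = (0.0, 160.0)  # m/s^2
    ang_norm: Tuple[float, float] = (0.0, 35.0)

    def __post_init__(self):
        for name in ("hr", "rr", "accel_norm", "ang_norm"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"invalid range for {name}: [{lo}, {hi}]")


@dataclass
class StreamReport:
    n_input: int = 0
    n_removed_outlier: int = 0
    n_imputed: int = 0
    n_discarded: int = 0
    n_ectopic: int = 0


@dataclass
class CleanDayRecord:
    """Cleaned streams plus the NN series and long-gap discard intervals."""

    patient_id: str
    day_index: int
    accel_lin: np.ndarray
    accel_ang: np.ndarray
    hr: np.ndarray
    nn: np.ndarray  # ectopic-corrected RR, ms
    sleep_epochs: List[Tuple[float, float]]
    relapse_label: int
    fs_accel: float
    fs_hr: float
    discard_intervals: List[Tuple[float, float]]  # seconds, half-open
    reports: Dict[str, StreamReport] = field(default_factory=dict)
    ectopic_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def remove_outliers(stream: np.ndarray, valid_range: Tuple[float, float]
                    ) -> Tuple[np.ndarray, int]:
    """Blank samples outside ``valid_range``; returns (stream, n_removed)."""
    out = np.array(stream, dtype=np.float64, copy=True)
    if out.size == 0:
        warnings.warn("remove_outliers called on an empty stream")
        return out, 0
    lo, hi = valid_range
    bad = np.isfinite(out) & ((out < lo) | (out > hi))
    out[bad] = np.nan
    return out, int(bad.sum())


def _nan_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open index runs where ``mask`` is True."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def impute_gaps(stream: np.ndarray, fs: float,
                max_gap: float = MAX_GAP_SECONDS
                ) -> Tuple[np.ndarray, List[Tuple[float, float]], StreamReport]:
    """Fill short missing runs; discard long ones.

    Runs of missing samples no longer than ``max_gap`` seconds are filled by
    linear interpolation between the bounding observed values (averaging a
    forward and a backward linear fill reduces to exactly this).  Leading
    and trailing runs use nearest-value extension.  Longer runs stay missing
    and their time spans are returned as discard intervals.
    """
    out = np.array(stream, dtype=np.float64, copy=True)
    rep = StreamReport(n_input=out.size)
    if out.size == 0:
        return out, [], rep
    missing = ~np.isfinite(out)
    if not missing.any():
        return out, [], rep
    obs = np.flatnonzero(~missing)
    if obs.size < 2:
        rep.n_discarded = out.size
        return np.full_like(out, np.nan), [(0.0, out.size / fs)], rep
    discard: List[Tuple[float, float]] = []
    max_len = int(max_gap * fs)
    for i0, i1 in _nan_runs(missing):
        if (i1 - i0) > max_len:
            discard.append((i0 / fs, i1 / fs))
            rep.n_discarded += i1 - i0
    short = missing.copy()
    for s, e in discard:
        short[int(s * fs):int(round(e * fs))] = False
    if short.any():
        idx = np.arange(out.size)
        out[short] = np.interp(idx[short], obs, out[obs])  # nearest at edges
        rep.n_imputed = int(short.sum())
    return out, discard, rep


def correct_ectopic(rr_stream: np.ndarray, threshold: float = ECTOPIC_THRESHOLD
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Flag and repair ectopic beats in a cleaned RR stream.

    A sample is ectopic when it deviates from the running median of the
    preceding five repaired samples by more than ``threshold`` (relative).
    Flagged samples are replaced by linear interpolation across accepted
    neighbours, which at the device rate usually reproduces the same-beat
    value exactly.  Missing (NaN) samples are passed through untouched.
    Returns ``(nn_series, flagged_indices)``; output length equals input.
    """
    rr = np.asarray(rr_stream, dtype=np.float64)
    finite = np.isfinite(rr)
    if finite.sum() < 6:
        warnings.warn("correct_ectopic: fewer than 6 beats, passing through")
        return rr.copy(), np.empty(0, dtype=np.int64)
    vals = rr[finite]
    flags, _ = _ectopic_scan(vals, threshold)
    repaired = vals.copy()
    if flags.any() and (~flags).any():
        ok = np.flatnonzero(~flags)
        bad = np.flatnonzero(flags)
        repaired[bad] = np.interp(bad, ok, vals[ok])
    nn = rr.copy()
    nn[finite] = repaired
    flagged = np.flatnonzero(finite)[flags]
    return nn, flagged


def _try_numba_scan():
    try:  # pragma: no cover - environment dependent
        import numba

        @numba.njit(cache=False)
        def scan(vals, threshold):
            n = vals.shape[0]
            flags = np.zeros(n, dtype=np.bool_)
            out = vals.copy()
            win = np.empty(_MEDIAN_WINDOW, dtype=np.float64)
            for i in range(1, n):
                lo = i - _MEDIAN_WINDOW
                if lo < 0:
                    lo = 0
                m = i - lo
                for j in range(m):
                    win[j] = out[lo + j]
                med = np.median(win[:m])
                if med > 0 and abs(vals[i] - med) > threshold * med:
                    flags[i] = True
                    out[i] = med  # the repair feeds later medians
            return flags, out

        return scan
    except Exception:
        return None


def _python_scan(vals, threshold):
    n = vals.shape[0]
    flags = np.zeros(n, dtype=bool)
    out = vals.copy()
    for i in range(1, n):
        lo = max(0, i - _MEDIAN_WINDOW)
        med = float(np.median(out[lo:i]))
        if med > 0 and abs(vals[i] - med) > threshold * med:
            flags[i] = True
            out[i] = med
    return flags, out


_ectopic_scan = _try_numba_scan() or _python_scan


def _clean_triaxial(stream3: np.ndarray, valid_range, fs, max_gap):
    """Range-filter on the vector norm, then per-axis gap treatment."""
    stream3 = np.array(stream3, dtype=np.float64, copy=True)
    if stream3.size == 0:
        return stream3, [], StreamReport()
    norm = np.sqrt(np.einsum("ij,ij->i", stream3, stream3))
    lo, hi = valid_range
    bad = np.isfinite(norm) & ((norm < lo) | (norm > hi))
    stream3[bad] = np.nan
    n_removed = int(bad.sum())
    missing = ~np.isfinite(stream3).all(axis=1)
    rep = StreamReport(n_input=stream3.shape[0], n_removed_outlier=n_removed)
    if not missing.any():
        return stream3, [], rep
    stream3[missing] = np.nan
    out = np.empty_like(stream3)
    discard: List[Tuple[float, float]] = []
    for ax in range(3):
        col, disc, r = impute_gaps(stream3[:, ax], fs, max_gap)
        out[:, ax] = col
        if ax == 0:
            discard = disc
            rep.n_imputed = r.n_imputed
            rep.n_discarded = r.n_discarded
    return out, discard, rep


def preprocess_day(record: RawDayRecord,
                   ranges: Optional[ValidRanges] = None,
                   max_gap: float = MAX_GAP_SECONDS,
                   ectopic_threshold: float = ECTOPIC_THRESHOLD
                   ) -> CleanDayRecord:
    """Full cleaning chain for one day; idempotent by construction."""
    ranges = ranges or ValidRanges()
    reports: Dict[str, StreamReport] = {}

    hr, n_hr_out = remove_outliers(record.hr, ranges.hr)
    hr, disc_hr, rep_hr = impute_gaps(hr, record.fs_hr, max_gap)
    rep_hr.n_removed_outlier = n_hr_out
    reports["hr"] = rep_hr

    rr, n_rr_out = remove_outliers(record.rr, ranges.rr)
    rr, disc_rr, rep_rr = impute_gaps(rr, record.fs_hr, max_gap)
    rep_rr.n_removed_outlier = n_rr_out
    nn, ectopic_idx = correct_ectopic(rr, ectopic_threshold)
    rep_rr.n_ectopic = int(ectopic_idx.size)
    reports["rr"] = rep_rr

    lin, disc_lin, rep_lin = _clean_triaxial(
        record.accel_lin, ranges.accel_norm, record.fs_accel, max_gap)
    reports["accel_lin"] = rep_lin
    ang, disc_ang, rep_ang = _clean_triaxial(
        record.accel_ang, ranges.ang_norm, record.fs_accel, max_gap)
    reports["accel_ang"] = rep_ang

    discard = _merge_intervals(disc_hr + disc_rr + disc_lin + disc_ang)
    return CleanDayRecord(
        patient_id=record.patient_id,
        day_index=record.day_index,
        accel_lin=lin,
        accel_ang=ang,
        hr=hr,
        nn=nn,
        sleep_epochs=list(record.sleep_epochs),
        relapse_label=record.relapse_label,
        fs_accel=record.fs_accel,
        fs_hr=record.fs_hr,
        discard_intervals=discard,
        reports=reports,
        ectopic_idx=ectopic_idx,
    )


def _merge_intervals(intervals: List[Tuple[float, float]]
                     ) -> List[Tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(float(s), float(e)) for s, e in merged]
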