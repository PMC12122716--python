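"""Per-interval feature extraction: 12 activity and HRV metrics.

Every day is divided into non-overlapping 5-min slots aligned to midnight
(288 per day).  Each valid slot yields, in canonical column order:

==== ===================== ======
f1   accel_norm_mean       m/s^2   mean Euclidean norm, linear acceleration
f2   ang_norm_mean         --      mean Euclidean norm, angular motion
f3   hr_mean               bpm
f4   hr_max                bpm
f5   hr_min                bpm
f6   nn_mean               ms
f7   sdnn                  ms      sample SD (divisor n-1)
f8   rmssd                 ms      root mean square of successive diffs
f9   lf_power              ms^2    Welch power in [0.04, 0.15) Hz
f10  hf_power              ms^2    Welch power in [0.15, 0.40) Hz
f11  sd1                   ms      Poincare short-term axis = rmssd/sqrt(2)
f12  sd2                   ms      Poincare long-term axis
==== ===================== ======

Time-domain HRV uses the sample (n-1) divisor throughout, which makes the
identities sd1 = rmssd/sqrt(2) and sd1^2 + sd2^2 = 2*sdnn^2 exact.  Spectral
features interpolate the NN tachogram onto a uniform 4 Hz grid and apply
Welch's method (120 s Hann segments, 50% overlap).
"""

from __future__ import annotations

import math
import warnings
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import welch

from .preprocess import CleanDayRecord

SLOT_SECONDS = 300.0
SLOTS_PER_DAY = 288

#: canonical feature order (f1..f12)
FEATURE_COLUMNS = [
    "accel_norm_mean", "ang_norm_mean",
    "hr_mean", "hr_max", "hr_min",
    "nn_mean", "sdnn", "rmssd",
    "lf_power", "hf_power",
    "sd1", "sd2",
]

META_COLUMNS = ["patient_id", "day_index", "interval_start", "sleep_flag", "valid"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
_RESAMPLE_HZ = 4.0
_MIN_VALID_FRACTION = 0.5
_MIN_NN = 10


def accel_features(lin_slot: np.ndarray, ang_slot: np.ndarray,
                   min_fraction: float = _MIN_VALID_FRACTION
                   ) -> Tuple[float, float, bool]:
    """Mean triaxial norms (f1, f2) with a per-slot validity verdict."""
    out = []
    ok = True
    for slot in (lin_slot, ang_slot):
        norm = np.linalg.norm(slot.astype(np.float64), axis=1)
        finite = np.isfinite(norm)
        if slot.shape[0] == 0 or finite.sum() < min_fraction * slot.shape[0]:
            ok = False
            out.append(np.nan)
        else:
            out.append(float(norm[finite].mean()))
    return out[0], out[1], ok


def hr_features(hr_slot: np.ndarray,
                min_fraction: float = _MIN_VALID_FRACTION
                ) -> Tuple[float, float, float, bool]:
    """Mean, max and min heart rate (f3, f4, f5) over surviving samples."""
    finite = np.isfinite(hr_slot)
    if hr_slot.size == 0 or finite.sum() < min_fraction * hr_slot.size:
        return np.nan, np.nan, np.nan, False
    v = hr_slot[finite]
    return float(v.mean()), float(v.max()), float(v.min()), True


def hrv_time(nn_slot: np.ndarray) -> Tuple[float, float, float, bool]:
    """Mean NN, SDNN (n-1 divisor) and RMSSD (f6, f7, f8)."""
    v = nn_slot[np.isfinite(nn_slot)]
    if v.size < _MIN_NN:
        return np.nan, np.nan, np.nan, False
    diffs = np.diff(v)
    return (float(v.mean()),
            float(v.std(ddof=1)),
            float(np.sqrt(np.mean(diffs ** 2))),
            True)


def poincare(nn_slot: np.ndarray) -> Tuple[float, float, bool]:
    """Poincare axes (f11, f12) via the RMSSD/SDNN identities.

    With a common divisor convention, SD1 = RMSSD/sqrt(2) and
    SD2 = sqrt(max(0, 2*SDNN^2 - SD1^2)) hold exactly.
    """
    mean_nn, sdnn, rmssd, ok = hrv_time(nn_slot)
    if not ok:
        return np.nan, np.nan, False
    sd1 = rmssd / math.sqrt(2.0)
    sd2 = math.sqrt(max(0.0, 2.0 * sdnn ** 2 - sd1 ** 2))
    return sd1, sd2, True


def hrv_freq(nn_slot_4hz: np.ndarray, fs: float = _RESAMPLE_HZ
             ) -> Tuple[float, float, bool]:
    """LF and HF band power (f9, f10) in ms^2 from a uniform tachogram."""
    v = nn_slot_4hz
    if v.ndim == 1:
        v = v[None, :]
    n = v.shape[-1]
    if n < int(2 * 60 * fs) or not np.isfinite(v).all():
        return np.nan, np.nan, False
    lf, hf = _band_powers(v, fs)
    return float(lf[0]), float(hf[0]), True


def _band_powers(v2d: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    nperseg = min(int(120 * fs), v2d.shape[-1])
    freqs, psd = welch(v2d, fs=fs, nperseg=nperseg, axis=-1)
    df = freqs[1] - freqs[0]
    lf_mask = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_mask = (freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])
    return psd[..., lf_mask].sum(axis=-1) * df, psd[..., hf_mask].sum(axis=-1) * df


def _slot_view(arr: np.ndarray, fs: float, n_slots: int) -> np.ndarray:
    per = int(SLOT_SECONDS * fs)
    return arr[: n_slots * per].reshape(n_slots, per, *arr.shape[1:])


def _sleep_flags(n_slots: int, epochs) -> np.ndarray:
    mid = np.arange(n_slots) * SLOT_SECONDS + SLOT_SECONDS / 2
    flag = np.zeros(n_slots, dtype=bool)
    for s, e in epochs or []:
        flag |= (mid >= s) & (mid < e)
    return flag


def featurize_day(clean: CleanDayRecord,
                  min_fraction: float = _MIN_VALID_FRACTION) -> pd.DataFrame:
    """All 12 features for every 5-min slot of one preprocessed day.

    Slots overlapping a discarded span, or failing any per-feature validity
    requirement, are emitted with ``valid=False``.  The slot's sleep flag is
    set by whether its midpoint falls inside a sleep epoch.
    """
    n_slots = int(round(clean.hr.shape[0] / (SLOT_SECONDS * clean.fs_hr)))
    n_slots = max(n_slots, 0)
    lin = _slot_view(clean.accel_lin, clean.fs_accel, n_slots)
    ang = _slot_view(clean.accel_ang, clean.fs_accel, n_slots)
    hr = _slot_view(clean.hr, clean.fs_hr, n_slots)
    nn = _slot_view(clean.nn, clean.fs_hr, n_slots)

    # uniform 4 Hz tachogram for the spectral features
    t_nn = np.arange(clean.nn.shape[0]) / clean.fs_hr
    finite = np.isfinite(clean.nn)
    n4 = int(n_slots * SLOT_SECONDS * _RESAMPLE_HZ)
    t4 = np.arange(n4) / _RESAMPLE_HZ
    if finite.sum() >= 2:
        nn4 = np.interp(t4, t_nn[finite], clean.nn[finite])
        # keep discarded spans invalid on the resampled grid too
        bad4 = np.interp(t4, t_nn, (~finite).astype(float)) > 0
        nn4[bad4] = np.nan
    else:
        nn4 = np.full(n4, np.nan)
    nn4 = nn4.reshape(n_slots, int(SLOT_SECONDS * _RESAMPLE_HZ))

    discard_slots = np.zeros(n_slots, dtype=bool)
    for s, e in clean.discard_intervals:
        first = int(s // SLOT_SECONDS)
        last = int(math.ceil(e / SLOT_SECONDS))
        discard_slots[max(first, 0):min(last, n_slots)] = True

    sleep = _sleep_flags(n_slots, clean.sleep_epochs)

    rows = np.full((n_slots, len(FEATURE_COLUMNS)), np.nan)

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slots
        # motion: day-level norms, then slot means
        ok_motion = np.ones(n_slots, dtype=bool)
        for col, slot3 in ((0, lin), (1, ang)):
            norm = np.sqrt(np.einsum("spj,spj->sp", slot3, slot3))
            n_ok = np.isfinite(norm).sum(axis=1)
            rows[:, col] = np.nanmean(norm, axis=1)
            ok_motion &= n_ok >= min_fraction * norm.shape[1]
        # heart rate
        n_hr_ok = np.isfinite(hr).sum(axis=1)
        rows[:, 2] = np.nanmean(hr, axis=1)
        rows[:, 3] = np.nanmax(hr, axis=1)
        rows[:, 4] = np.nanmin(hr, axis=1)
        ok_hr = n_hr_ok >= min_fraction * hr.shape[1]
        # time-domain HRV
        n_nn_ok = np.isfinite(nn).sum(axis=1)
        rows[:, 5] = np.nanmean(nn, axis=1)
        rows[:, 6] = np.nanstd(nn, axis=1, ddof=1)
        sqdiff = np.diff(nn, axis=1) ** 2
        rows[:, 7] = np.sqrt(np.nanmean(sqdiff, axis=1))
        ok_nn = n_nn_ok >= _MIN_NN
        rows[:, 10] = rows[:, 7] / np.sqrt(2.0)
        rows[:, 11] = np.sqrt(np.maximum(0.0, 2.0 * rows[:, 6] ** 2
                                         - rows[:, 10] ** 2))

    # spectral HRV, batched across fully-finite slots
    freq_ok = np.isfinite(nn4).all(axis=1) if n4 else np.zeros(0, dtype=bool)
    if freq_ok.any():
        lf_all, hf_all = _band_powers(nn4[freq_ok], _RESAMPLE_HZ)
        rows[freq_ok, 8] = lf_all
        rows[freq_ok, 9] = hf_all

    valid = (~discard_slots) & ok_motion & ok_hr & ok_nn & freq_ok
    rows[discard_slots] = np.nan

    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.insert(0, "patient_id", clean.patient_id)
    df.insert(1, "day_index", clean.day_index)
    df.insert(2, "interval_start", np.arange(n_slots) * SLOT_SECONDS)
    df["sleep_flag"] = np.where(sleep, "sleep", "awake")
    df["valid"] = valid
    df["relapse_label"] = clean.relapse_label
    return df
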