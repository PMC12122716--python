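"""Synthetic wearable-cohort generation and the on-disk raw-data layout.

This module emulates the statistical structure of multi-month smartwatch
recordings from patients with psychotic disorders: per day, triaxial linear
and angular motion at 20 Hz, heart rate and RR intervals at 5 Hz, a nightly
device-detected sleep window, and a day-level relapse annotation.  Relapse
days occur in contiguous multi-day events, and the four behavioural states
(sleep/awake x relapse/non-relapse) each carry their own heart-rhythm and
activity parameters so that downstream feature extraction recovers
configured group differences.

The NN (normal-to-normal) interval process is built at the beat level as

    NN_k = mu_day + A_LF sin(2 pi 0.1 t_k) + A_HF sin(2 pi 0.25 t_k)
           + slow(t_k) + white_k

where ``slow`` is an Ornstein-Uhlenbeck component (time constant ~45 s) and
``white`` is i.i.d. beat noise.  The variance budget is solved so that the
5-min SDNN of the emitted stream matches ``sdnn_target`` and the
time-sampled stream mean matches ``mean_nn`` (time sampling weights long
beats more; the beat-level mean is compensated accordingly).  The 0.1 and
0.25 Hz oscillations keep the LF/HF spectral features non-degenerate.

Corruption is injected *after* clean generation: simultaneous multi-stream
gaps, isolated ectopic beats (RR scaled by 0.6), and out-of-range outliers.
Clean copies and injection ledgers are retained on the record purely as
test oracles; the analysis pipeline never reads them.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.signal import lfilter

DAY_SECONDS = 86400.0

#: canonical state keys: stratum x relapse status
STATE_KEYS = (
    "sleep_nonrelapse",
    "sleep_relapse",
    "awake_nonrelapse",
    "awake_relapse",
)

_NN_FLOOR_MS = 300.0
_SLOW_TAU_S = 45.0
_SLOT_S = 300.0
_STATE_RAMP_S = 300


class ConfigurationError(ValueError):
    """Raised for invalid generator specifications."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateParams:
    """Physiological parameters of one behavioural state.

    ``mean_nn``/``sdnn_target`` are the targets the *extracted* 5-min
    features should hit; ``nn_day_sd``/``sdnn_day_sd`` are day-to-day
    standard deviations of the daily means, matching how group statistics
    are reported (mean +/- SD of daily feature means).
    """

    mean_nn: float  # ms
    sdnn_target: float  # ms, expected 5-min SDNN (0 = noise-free limit)
    accel_mean: float  # m/s^2, daily mean linear-acceleration norm
    accel_sd: float  # m/s^2, day-to-day SD of the daily mean
    lf_amp: float = 12.0  # ms, 0.1 Hz oscillation amplitude
    hf_amp: float = 12.0  # ms, 0.25 Hz oscillation amplitude
    hr_base: float = 0.0  # bpm; 0 -> derived as 60000/mean_nn
    nn_day_sd: float = 0.0  # ms
    sdnn_day_sd: float = 0.0  # ms
    ang_mean: float = 0.5  # angular-motion norm level
    ang_sd: float = 0.1
    accel_within_cv: float = 0.25  # within-day noise as a fraction of the mean

    def __post_init__(self):
        if self.mean_nn <= 0 or self.sdnn_target < 0:
            raise ConfigurationError("mean_nn must be positive, sdnn_target >= 0")
        if self.sdnn_target >= self.mean_nn:
            raise ConfigurationError("sdnn_target must be smaller than mean_nn")
        if self.accel_mean < 0 or self.accel_sd < 0:
            raise ConfigurationError("acceleration parameters must be non-negative")
        if self.accel_sd >= self.accel_mean + 1:
            raise ConfigurationError("accel_sd implausibly large vs accel_mean")
        if min(self.lf_amp, self.hf_amp, self.nn_day_sd, self.sdnn_day_sd) < 0:
            raise ConfigurationError("amplitudes and day-level SDs must be >= 0")
        if self.hr_base == 0.0:
            object.__setattr__(self, "hr_base", 60000.0 / self.mean_nn)


@dataclass
class PatientSpec:
    """Generator specification for one synthetic patient."""

    patient_id: str
    params: Dict[str, StateParams]
    n_days: int
    relapse_rate: float = 0.2  # long-run fraction of relapse days
    relapse_event_mean_len: float = 4.0  # days
    sleep_start_mean: float = 23.5  # hours after midnight
    sleep_dur_mean: float = 8.0  # hours
    sleep_start_sd: float = 0.5
    sleep_dur_sd: float = 0.5
    gap_rate: float = 0.0  # expected gaps per day
    gap_long_frac: float = 0.1  # fraction of gaps longer than 3 h
    ectopic_rate: float = 0.0  # fraction of RR samples
    outlier_rate: float = 0.0  # fraction of samples per stream
    fs_accel: float = 20.0  # Hz (device motion rate)
    fs_hr: float = 5.0  # Hz (device HR/RR rate)
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.relapse_event_mean_len < 1:
            raise ConfigurationError("relapse_event_mean_len must be >= 1 day")
        for name in ("relapse_rate", "gap_long_frac", "ectopic_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.gap_rate < 0:
            raise ConfigurationError("gap_rate must be >= 0")
        missing = set(STATE_KEYS) - set(self.params)
        if missing:
            raise ConfigurationError(f"missing state parameters: {sorted(missing)}")


@dataclass
class RawDayRecord:
    """One patient-day of raw streams as emitted by the device."""

    patient_id: str
    day_index: int
    accel_lin: np.ndarray  # (n_accel, 3) float32, m/s^2
    accel_ang: np.ndarray  # (n_accel, 3) float32
    hr: np.ndarray  # (n_hr,) float64, bpm
    rr: np.ndarray  # (n_hr,) float64, ms
    sleep_epochs: List[Tuple[float, float]]  # [start, end) seconds from midnight
    relapse_label: int
    fs_accel: float = 20.0
    fs_hr: float = 5.0
    clean: Optional[dict] = None  # oracle-only clean copies
    injected: dict = field(default_factory=dict)  # oracle-only injection ledger

    def copy(self) -> "RawDayRecord":
        return RawDayRecord(
            patient_id=self.patient_id,
            day_index=self.day_index,
            accel_lin=self.accel_lin.copy(),
            accel_ang=self.accel_ang.copy(),
            hr=self.hr.copy(),
            rr=self.rr.copy(),
            sleep_epochs=list(self.sleep_epochs),
            relapse_label=self.relapse_label,
            fs_accel=self.fs_accel,
            fs_hr=self.fs_hr,
            clean=None if self.clean is None else dict(self.clean),
            injected=json.loads(json.dumps(self.injected)),
        )


# ---------------------------------------------------------------------------
# presets calibrated to the reported group statistics
# ---------------------------------------------------------------------------

#: Sleep-state HRV carries the relapse signal: non-relapse NN 759 +/- 89 ms
#: vs relapse 683 +/- 17 ms; SDNN 56.5 +/- 20.7 vs 27.2 +/- 7.6 ms.  Awake
#: distributions barely differ.  Acceleration carries no signal.
USER00_LIKE: Dict[str, StateParams] = {
    "sleep_nonrelapse": StateParams(
        mean_nn=759.0, nn_day_sd=89.0, sdnn_target=56.5, sdnn_day_sd=20.7,
        accel_mean=0.14, accel_sd=0.04, lf_amp=10.0, hf_amp=18.0,
        ang_mean=0.12, ang_sd=0.03,
    ),
    "sleep_relapse": StateParams(
        mean_nn=683.0, nn_day_sd=17.0, sdnn_target=27.2, sdnn_day_sd=7.6,
        accel_mean=0.14, accel_sd=0.04, lf_amp=8.0, hf_amp=12.0,
        ang_mean=0.12, ang_sd=0.03,
    ),
    "awake_nonrelapse": StateParams(
        mean_nn=697.0, nn_day_sd=60.0, sdnn_target=110.4, sdnn_day_sd=34.3,
        accel_mean=0.66, accel_sd=0.18, lf_amp=25.0, hf_amp=12.0,
        ang_mean=0.60, ang_sd=0.15,
    ),
    "awake_relapse": StateParams(
        mean_nn=681.0, nn_day_sd=16.0, sdnn_target=99.1, sdnn_day_sd=10.4,
        accel_mean=0.66, accel_sd=0.17, lf_amp=25.0, hf_amp=12.0,
        ang_mean=0.60, ang_sd=0.15,
    ),
}

#: Sleep-state acceleration carries the relapse signal: 0.14 +/- 0.04 vs
#: 0.18 +/- 0.04 m/s^2 during sleep; awake identical (0.66 +/- ~0.18).  RR
#: differs mildly during sleep (990 +/- 90 vs 956 +/- 100 ms).
USER01_LIKE: Dict[str, StateParams] = {
    "sleep_nonrelapse": StateParams(
        mean_nn=990.0, nn_day_sd=90.0, sdnn_target=60.0, sdnn_day_sd=20.0,
        accel_mean=0.14, accel_sd=0.04, lf_amp=10.0, hf_amp=18.0,
        ang_mean=0.12, ang_sd=0.03,
    ),
    "sleep_relapse": StateParams(
        mean_nn=956.0, nn_day_sd=100.0, sdnn_target=60.0, sdnn_day_sd=20.0,
        accel_mean=0.18, accel_sd=0.04, lf_amp=10.0, hf_amp=18.0,
        ang_mean=0.16, ang_sd=0.03,
    ),
    "awake_nonrelapse": StateParams(
        mean_nn=785.0, nn_day_sd=55.0, sdnn_target=100.0, sdnn_day_sd=30.0,
        accel_mean=0.66, accel_sd=0.18, lf_amp=25.0, hf_amp=12.0,
        ang_mean=0.60, ang_sd=0.15,
    ),
    "awake_relapse": StateParams(
        mean_nn=761.0, nn_day_sd=79.0, sdnn_target=100.0, sdnn_day_sd=30.0,
        accel_mean=0.66, accel_sd=0.17, lf_amp=25.0, hf_amp=12.0,
        ang_mean=0.60, ang_sd=0.15,
    ),
}

PRESETS: Dict[str, Dict[str, StateParams]] = {
    "user00_like": USER00_LIKE,
    "user01_like": USER01_LIKE,
}


def default_study_specs(n_patients: int = 10, n_days: int = 21,
                        relapse_rate: float = 0.3,
                        relapse_event_mean_len: float = 2.0,
                        gap_rate: float = 0.2,
                        ectopic_rate: float = 0.001,
                        outlier_rate: float = 0.0005) -> List[PatientSpec]:
    """The standard synthetic study cohort.

    Ten patients (presets alternating between the two calibrated
    phenotypes) of three weeks each — roughly 200 days in total — with
    relapse effect sizes concentrated in the sleep state, short contiguous
    relapse events, and mild stream corruption.  These defaults define the
    conditions under which the pipeline's discrimination properties are
    asserted.
    """
    return [
        PatientSpec(
            patient_id=f"sim_{i:02d}",
            params=USER00_LIKE if i % 2 == 0 else USER01_LIKE,
            n_days=n_days,
            relapse_rate=relapse_rate,
            relapse_event_mean_len=relapse_event_mean_len,
            gap_rate=gap_rate,
            ectopic_rate=ectopic_rate,
            outlier_rate=outlier_rate,
            seed=i,
        )
        for i in range(n_patients)
    ]


# ---------------------------------------------------------------------------
# label process
# ---------------------------------------------------------------------------


def generate_labels(spec: PatientSpec, rng: np.random.Generator) -> np.ndarray:
    """Day-level relapse labels from a two-state Markov chain.

    Exit probability 1/mean_len gives geometric event lengths with the
    configured mean; the entry probability is solved so the stationary
    relapse fraction equals ``relapse_rate``.  Relapse days therefore form
    contiguous multi-day events.
    """
    p_exit = 1.0 / spec.relapse_event_mean_len
    rate = spec.relapse_rate
    if rate <= 0.0:
        return np.zeros(spec.n_days, dtype=np.int8)
    if rate >= 1.0:
        return np.ones(spec.n_days, dtype=np.int8)
    p_enter = min(1.0, rate * p_exit / (1.0 - rate))
    labels = np.zeros(spec.n_days, dtype=np.int8)
    state = 1 if rng.random() < rate else 0  # stationary start
    u = rng.random(spec.n_days)
    for d in range(spec.n_days):
        labels[d] = state
        if state == 0:
            state = 1 if u[d] < p_enter else 0
        else:
            state = 0 if u[d] < p_exit else 1
    return labels


def relapse_events(labels: Sequence[int]) -> List[Tuple[int, int]]:
    """Maximal runs of relapse days as ``(start_day, end_day_exclusive)``."""
    labels = np.asarray(labels)
    events = []
    start = None
    for d, lab in enumerate(labels):
        if lab and start is None:
            start = d
        elif not lab and start is not None:
            events.append((start, d))
            start = None
    if start is not None:
        events.append((start, len(labels)))
    return events


# ---------------------------------------------------------------------------
# beat-level NN process
# ---------------------------------------------------------------------------


def _try_numba_beat_loop():
    try:  # pragma: no cover - environment dependent
        import numba

        @numba.njit(cache=False)
        def loop(duration, wgrid, mu, lf, hf, vlf, sig_slow, sig_white,
                 phi_lf, phi_hf, phi_vlf, slow_grid, white, t_out, nn_out):
            t = 0.0
            k = 0
            n_max = t_out.shape[0]
            while t < duration and k < n_max:
                w = wgrid[int(t)]  # smoothed sleep weight in [0, 1]
                nn = ((mu[0] + w * (mu[1] - mu[0]))
                      + (lf[0] + w * (lf[1] - lf[0]))
                      * math.sin(2.0 * math.pi * 0.1 * t + phi_lf)
                      + (hf[0] + w * (hf[1] - hf[0]))
                      * math.sin(2.0 * math.pi * 0.25 * t + phi_hf)
                      + (vlf[0] + w * (vlf[1] - vlf[0]))
                      * math.sin(2.0 * math.pi * 0.02 * t + phi_vlf)
                      + (sig_slow[0] + w * (sig_slow[1] - sig_slow[0]))
                      * slow_grid[int(t)]
                      + (sig_white[0] + w * (sig_white[1] - sig_white[0]))
                      * white[k])
                if nn < _NN_FLOOR_MS:
                    nn = _NN_FLOOR_MS
                t_out[k] = t
                nn_out[k] = nn
                t += nn / 1000.0
                k += 1
            return k

        return loop
    except Exception:
        return None


def _python_beat_loop(duration, wgrid, mu, lf, hf, vlf, sig_slow, sig_white,
                      phi_lf, phi_hf, phi_vlf, slow_grid, white, t_out, nn_out):
    t = 0.0
    k = 0
    n_max = t_out.shape[0]
    two_pi = 2.0 * math.pi
    while t < duration and k < n_max:
        w = wgrid[int(t)]
        nn = ((mu[0] + w * (mu[1] - mu[0]))
              + (lf[0] + w * (lf[1] - lf[0]))
              * math.sin(two_pi * 0.1 * t + phi_lf)
              + (hf[0] + w * (hf[1] - hf[0]))
              * math.sin(two_pi * 0.25 * t + phi_hf)
              + (vlf[0] + w * (vlf[1] - vlf[0]))
              * math.sin(two_pi * 0.02 * t + phi_vlf)
              + (sig_slow[0] + w * (sig_slow[1] - sig_slow[0]))
              * slow_grid[int(t)]
              + (sig_white[0] + w * (sig_white[1] - sig_white[0]))
              * white[k])
        if nn < _NN_FLOOR_MS:
            nn = _NN_FLOOR_MS
        t_out[k] = t
        nn_out[k] = nn
        t += nn / 1000.0
        k += 1
    return k


_beat_loop = _try_numba_beat_loop() or _python_beat_loop


def _smooth_mask(mask: np.ndarray, ramp_s: int) -> np.ndarray:
    """Moving-average smoothing of a 0/1 per-second mask (odd window)."""
    win = int(ramp_s) | 1
    pad = win // 2
    padded = np.concatenate([np.full(pad, mask[0], dtype=np.float64),
                             mask.astype(np.float64),
                             np.full(pad, mask[-1], dtype=np.float64)])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    return (csum[win:] - csum[:-win]) / win


def _ou_window_factor(tau: float, window: float) -> float:
    # expected within-window sample-variance fraction of an OU process
    r = tau / window
    return 1.0 - 2.0 * r * (1.0 - r * (1.0 - math.exp(-1.0 / r)))


def _noise_budget(sdnn_day: float, lf_amp: float, hf_amp: float, mean_day: float):
    """Split the target 5-min variance into oscillatory, slow and white parts.

    The white (beat-to-beat) share is capped at 4% of the mean NN so that
    successive-difference magnitudes stay far below the 20% ectopic
    threshold, and the drifting (OU) share at 8% so the level cannot walk
    into the physiological floor.  The bulk of any large residual goes into
    a bounded very-low-frequency oscillation (0.02 Hz, below the LF band,
    fully expressed within a 5-min window).  The OU amplitude is inflated
    by its expected within-window variance fraction so the realized 5-min
    SDNN still matches the target.
    """
    var_total = sdnn_day ** 2
    var_osc = 0.5 * lf_amp ** 2 + 0.5 * hf_amp ** 2
    scale = 1.0
    if var_osc > 0.9 * var_total and var_osc > 0:
        scale = math.sqrt(0.9 * var_total / var_osc)
        var_osc = 0.9 * var_total
    var_rem = max(var_total - var_osc, 0.0)
    var_white = min(0.3 * var_rem, (0.02 * mean_day) ** 2)
    var_slow = min(0.5 * (var_rem - var_white), (0.05 * mean_day) ** 2)
    var_vlf = max(var_rem - var_white - var_slow, 0.0)
    factor = _ou_window_factor(_SLOW_TAU_S, _SLOT_S)
    sig_slow = math.sqrt(var_slow / factor)
    vlf_amp = math.sqrt(2.0 * var_vlf)
    # only beat-scale variance biases time sampling of the tachogram; the
    # HF oscillation (4 s period) is counted at half weight
    var_fast = var_white + 0.25 * (scale * hf_amp) ** 2
    return scale * lf_amp, scale * hf_amp, vlf_amp, sig_slow, math.sqrt(var_white), var_fast


def _night_epoch(spec: PatientSpec, night_index: int, base_seed: SeedSequence) -> Tuple[float, float]:
    """Absolute [start, end) of the sleep interval beginning on ``night_index``."""
    if night_index < 0:
        night_index = -1  # virtual night before day 0, still deterministic
    rng = default_rng(SeedSequence(entropy=(base_seed.entropy, 11, night_index + 1)))
    start_h = spec.sleep_start_mean + spec.sleep_start_sd * rng.standard_normal()
    dur_h = max(1.0, spec.sleep_dur_mean + spec.sleep_dur_sd * rng.standard_normal())
    start = night_index * DAY_SECONDS + start_h * 3600.0
    return start, start + dur_h * 3600.0


def _day_sleep_epochs(spec: PatientSpec, day_index: int, base_seed: SeedSequence) -> List[Tuple[float, float]]:
    """Sleep intervals intersecting the day, clipped to [0, 86400)."""
    day0 = day_index * DAY_SECONDS
    epochs = []
    for night in (day_index - 1, day_index):
        s, e = _night_epoch(spec, night, base_seed)
        s, e = max(s, day0), min(e, day0 + DAY_SECONDS)
        if e > s:
            epochs.append((s - day0, e - day0))
    return epochs


def _sleep_mask_seconds(epochs: Sequence[Tuple[float, float]], n_sec: int) -> np.ndarray:
    mask = np.zeros(n_sec, dtype=np.int8)
    for s, e in epochs:
        mask[int(max(s, 0)):int(min(e, n_sec))] = 1
    return mask


def generate_day(spec: PatientSpec, day_index: int, label: int,
                 seed: SeedSequence | int) -> RawDayRecord:
    """Generate one clean patient-day of raw streams.

    The behavioural state switches at sleep-epoch boundaries; relapse acts
    at the day level only.  Deterministic given (spec, day_index, label,
    seed).
    """
    if label not in (0, 1):
        raise ConfigurationError("label must be 0 or 1")
    base = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    rng = default_rng(SeedSequence(entropy=(base.entropy, 13, day_index)))

    n_sec = int(DAY_SECONDS)
    epochs = _day_sleep_epochs(spec, day_index, base)
    sleep_sec = _sleep_mask_seconds(epochs, n_sec)

    status = "relapse" if label else "nonrelapse"
    p_awake = spec.params[f"awake_{status}"]
    p_sleep = spec.params[f"sleep_{status}"]

    # state-indexed arrays: 0 = awake, 1 = sleep
    mu = np.empty(2)
    lf = np.empty(2)
    hf = np.empty(2)
    vlf = np.empty(2)
    sig_slow = np.empty(2)
    sig_white = np.empty(2)
    for s, p in ((0, p_awake), (1, p_sleep)):
        mean_day = p.mean_nn + p.nn_day_sd * rng.standard_normal()
        mean_day = max(mean_day, _NN_FLOOR_MS + 50.0)
        sdnn_day = max(0.0, p.sdnn_target + p.sdnn_day_sd * rng.standard_normal())
        lf_a, hf_a, vlf_a, s_slow, s_white, var_fast = _noise_budget(
            sdnn_day, p.lf_amp, p.hf_amp, mean_day)
        # keep oscillatory excursions clear of the physiological floor: a
        # low-mean day with an extreme SDNN draw would otherwise clip there
        excursion = vlf_a + lf_a + hf_a + 2.5 * s_slow
        headroom = mean_day - (_NN_FLOOR_MS + 40.0)
        if excursion > headroom > 0:
            shrink = headroom / excursion
            lf_a *= shrink
            hf_a *= shrink
            vlf_a *= shrink
            s_slow *= shrink
        # compensate the duration-weighting bias of time sampling a tachogram
        mu[s] = mean_day - var_fast / mean_day
        lf[s], hf[s], vlf[s] = lf_a, hf_a, vlf_a
        sig_slow[s], sig_white[s] = s_slow, s_white

    # slow OU component on a 1 s grid (unit stationary SD, tails truncated
    # at 2.5 sigma so the level never approaches the physiological floor)
    a = math.exp(-1.0 / _SLOW_TAU_S)
    innov = rng.standard_normal(n_sec) * math.sqrt(1.0 - a * a)
    innov[0] = rng.standard_normal()  # stationary start
    slow_grid = np.clip(lfilter([1.0], [1.0, -a], innov), -2.5, 2.5)

    phi_lf, phi_hf, phi_vlf = rng.uniform(0, 2 * math.pi, size=3)
    n_max = int(DAY_SECONDS / (_NN_FLOOR_MS / 1000.0)) + 16
    white = rng.standard_normal(n_max)
    t_beats = np.empty(n_max)
    nn_beats = np.empty(n_max)
    # sleep<->awake cardiac transitions ramp over ~5 min rather than jumping
    wgrid = _smooth_mask(sleep_sec, _STATE_RAMP_S)
    k = _beat_loop(DAY_SECONDS, wgrid, mu, lf, hf, vlf, sig_slow, sig_white,
                   phi_lf, phi_hf, phi_vlf, slow_grid, white, t_beats, nn_beats)
    t_beats, nn_beats = t_beats[:k], nn_beats[:k]

    # 5 Hz device streams: each sample reports the beat covering that instant
    n_hr = int(DAY_SECONDS * spec.fs_hr)
    t_grid = np.arange(n_hr) / spec.fs_hr
    idx = np.searchsorted(t_beats, t_grid, side="right") - 1
    rr = nn_beats[np.clip(idx, 0, k - 1)]
    hr = 60000.0 / rr

    # motion streams: norm = state mean + noise, random slowly-varying direction
    accel_lin = _motion_stream(rng, sleep_sec, p_awake, p_sleep, spec.fs_accel, kind="lin")
    accel_ang = _motion_stream(rng, sleep_sec, p_awake, p_sleep, spec.fs_accel, kind="ang")

    return RawDayRecord(
        patient_id=spec.patient_id,
        day_index=day_index,
        accel_lin=accel_lin,
        accel_ang=accel_ang,
        hr=hr,
        rr=rr,
        sleep_epochs=epochs,
        relapse_label=int(label),
        fs_accel=spec.fs_accel,
        fs_hr=spec.fs_hr,
    )


def _motion_stream(rng, sleep_sec, p_awake, p_sleep, fs, kind) -> np.ndarray:
    n_sec = sleep_sec.shape[0]
    n = int(n_sec * fs)
    reps = max(int(round(fs)), 1)
    if kind == "lin":
        means = (p_awake.accel_mean, p_sleep.accel_mean)
        day_sds = (p_awake.accel_sd, p_sleep.accel_sd)
    else:
        means = (p_awake.ang_mean, p_sleep.ang_mean)
        day_sds = (p_awake.ang_sd, p_sleep.ang_sd)
    level = np.empty(2, dtype=np.float64)
    within = np.empty(2, dtype=np.float64)
    cvs = (p_awake.accel_within_cv, p_sleep.accel_within_cv)
    for s in (0, 1):
        level[s] = max(0.0, means[s] + day_sds[s] * rng.standard_normal())
        within[s] = cvs[s] * means[s]
    state = np.repeat(sleep_sec, reps)[:n]
    mag = (level.astype(np.float32)[state]
           + within.astype(np.float32)[state]
           * rng.standard_normal(n, dtype=np.float32))
    np.maximum(mag, np.float32(0.0), out=mag)
    # per-second random direction, piecewise constant at the sample rate
    g = rng.standard_normal((n_sec, 3), dtype=np.float32)
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    direction = np.repeat(g, reps, axis=0)[:n]
    return direction * mag[:, None]


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------


def inject_missingness(record: RawDayRecord, gap_rate: float,
                       gap_len_dist: Optional[dict] = None,
                       seed: SeedSequence | int = 0) -> RawDayRecord:
    """Blank random time spans simultaneously in every stream.

    Gap lengths come from a mixture: with probability ``p_long`` a long gap
    uniform on [3.2 h, 6 h] (exceeding the 3 h imputation limit), otherwise
    a short gap uniform on [2 min, 90 min].  Gap metadata is retained in
    ``record.injected['gaps']`` for test oracles only.
    """
    out = record.copy()
    if gap_rate == 0:
        out.injected.setdefault("gaps", [])
        return out
    dist = {"p_long": 0.1, "short": (120.0, 5400.0), "long": (11520.0, 21600.0)}
    if gap_len_dist:
        dist.update(gap_len_dist)
    if max(dist["short"][1], dist["long"][1]) > DAY_SECONDS:
        raise ConfigurationError("gap length exceeds one day")
    rng = default_rng(seed if isinstance(seed, SeedSequence) else SeedSequence(seed))
    n_gaps = rng.poisson(gap_rate)
    gaps = []
    for _ in range(n_gaps):
        lo, hi = dist["long"] if rng.random() < dist["p_long"] else dist["short"]
        length = rng.uniform(lo, hi)
        start = rng.uniform(0.0, DAY_SECONDS - length)
        gaps.append((float(start), float(start + length)))
    out.clean = out.clean or {}
    for name in ("accel_lin", "accel_ang", "hr", "rr"):
        out.clean.setdefault(name, getattr(record, name).copy())
    for s, e in gaps:
        for name, fs in (("accel_lin", out.fs_accel), ("accel_ang", out.fs_accel),
                         ("hr", out.fs_hr), ("rr", out.fs_hr)):
            arr = getattr(out, name)
            i0, i1 = int(math.ceil(s * fs)), int(e * fs)
            arr[i0:i1] = np.nan
    out.injected["gaps"] = gaps
    return out


def inject_artifacts(record: RawDayRecord, ectopic_rate: float,
                     outlier_rate: float, seed: SeedSequence | int = 0) -> RawDayRecord:
    """Inject isolated ectopic beats and out-of-range outliers.

    Ectopic beats multiply single RR samples by 0.6 (a typical premature
    beat shortening); outliers push samples outside the default valid
    ranges.  Positions are logged for ledger-style oracle tests.
    """
    out = record.copy()
    out.injected.setdefault("ectopic_idx", [])
    out.injected.setdefault("outliers", {})
    if ectopic_rate == 0 and outlier_rate == 0:
        return out
    rng = default_rng(seed if isinstance(seed, SeedSequence) else SeedSequence(seed))
    out.clean = out.clean or {}
    for name in ("accel_lin", "accel_ang", "hr", "rr"):
        out.clean.setdefault(name, getattr(record, name).copy())

    n_rr = out.rr.shape[0]
    valid = np.flatnonzero(np.isfinite(out.rr))
    if ectopic_rate > 0 and valid.size:
        n_ect = int(round(ectopic_rate * n_rr))
        pos = _isolated_choice(rng, valid, n_ect, min_sep=25)
        out.rr[pos] *= 0.6
        out.injected["ectopic_idx"] = [int(p) for p in pos]
    if outlier_rate > 0:
        taken = set(out.injected["ectopic_idx"])
        specs = {
            "hr": (out.hr, (260.0, 10.0)),
            "rr": (out.rr, (2400.0, 120.0)),
        }
        for name, (arr, bad_values) in specs.items():
            ok = np.flatnonzero(np.isfinite(arr))
            ok = ok[[i not in taken for i in ok]] if name == "rr" else ok
            n_out = int(round(outlier_rate * arr.shape[0]))
            if n_out == 0 or ok.size == 0:
                out.injected["outliers"][name] = []
                continue
            pos = rng.choice(ok, size=min(n_out, ok.size), replace=False)
            arr[pos] = rng.choice(np.asarray(bad_values), size=pos.size)
            out.injected["outliers"][name] = sorted(int(p) for p in pos)
    return out


def _isolated_choice(rng, candidates, n, min_sep):
    """Choose up to n positions pairwise separated by at least min_sep."""
    chosen: List[int] = []
    pool = rng.permutation(candidates)
    for p in pool:
        if len(chosen) >= n:
            break
        if all(abs(int(p) - c) >= min_sep for c in chosen):
            chosen.append(int(p))
    return np.array(sorted(chosen), dtype=np.int64)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Lazy view of a generated cohort.

    Labels are materialized eagerly (cheap); raw streams are regenerated
    deterministically on demand so arbitrarily long cohorts stream through
    the pipeline without holding every day in memory.
    """

    specs: List[PatientSpec]
    seed: int
    labels: pd.DataFrame  # columns: patient_id, day_index, relapse

    def patient_seed(self, patient_index: int) -> SeedSequence:
        spec = self.specs[patient_index]
        return SeedSequence(entropy=(self.seed, spec.seed, patient_index))

    def day(self, patient_index: int, day_index: int) -> RawDayRecord:
        spec = self.specs[patient_index]
        lab = self.labels
        row = lab[(lab.patient_id == spec.patient_id) & (lab.day_index == day_index)]
        if row.empty:
            raise KeyError((spec.patient_id, day_index))
        label = int(row.relapse.iloc[0])
        base = self.patient_seed(patient_index)
        rec = generate_day(spec, day_index, label, base)
        if spec.gap_rate > 0:
            rec = inject_missingness(
                rec, spec.gap_rate,
                seed=SeedSequence(entropy=(base.entropy, 17, day_index)))
        if spec.ectopic_rate > 0 or spec.outlier_rate > 0:
            rec = inject_artifacts(
                rec, spec.ectopic_rate, spec.outlier_rate,
                seed=SeedSequence(entropy=(base.entropy, 19, day_index)))
        return rec

    def iter_days(self, patient_indices: Optional[Sequence[int]] = None
                  ) -> Iterator[RawDayRecord]:
        indices = range(len(self.specs)) if patient_indices is None else patient_indices
        for i in indices:
            for d in range(self.specs[i].n_days):
                yield self.day(i, d)

    @property
    def n_days_total(self) -> int:
        return int(len(self.labels))

    def fingerprint(self) -> str:
        """SHA-256 over every serialized stream; equality => byte-identical."""
        h = hashlib.sha256()
        for rec in self.iter_days():
            for name in ("accel_lin", "accel_ang", "hr", "rr"):
                h.update(np.ascontiguousarray(getattr(rec, name)).tobytes())
            h.update(json.dumps(rec.sleep_epochs).encode())
            h.update(bytes([rec.relapse_label]))
        return h.hexdigest()


def generate_cohort(specs: Sequence[PatientSpec], seed: int) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort.

    Per-patient seeds derive from the master seed; identical (specs, seed)
    give byte-identical streams.
    """
    if not specs:
        raise ConfigurationError("specs must be non-empty")
    frames = []
    cohort = SyntheticCohort(specs=list(specs), seed=int(seed),
                             labels=pd.DataFrame())
    for i, spec in enumerate(specs):
        rng = default_rng(SeedSequence(entropy=(cohort.patient_seed(i).entropy, 5)))
        labels = generate_labels(spec, rng)
        frames.append(pd.DataFrame({
            "patient_id": spec.patient_id,
            "day_index": np.arange(spec.n_days),
            "relapse": labels.astype(int),
        }))
    cohort.labels = pd.concat(frames, ignore_index=True)
    return cohort


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def write_day(record: RawDayRecord, patient_dir: Path) -> Path:
    """Write one day as CSV streams under ``patient_dir/day_NNNN/``."""
    day_dir = Path(patient_dir) / f"day_{record.day_index:04d}"
    day_dir.mkdir(parents=True, exist_ok=True)
    t_acc = np.arange(record.accel_lin.shape[0]) / record.fs_accel
    pd.DataFrame({"t_sec": t_acc, "x": record.accel_lin[:, 0],
                  "y": record.accel_lin[:, 1], "z": record.accel_lin[:, 2]}
                 ).to_csv(day_dir / "accel.csv", index=False)
    pd.DataFrame({"t_sec": t_acc, "x": record.accel_ang[:, 0],
                  "y": record.accel_ang[:, 1], "z": record.accel_ang[:, 2]}
                 ).to_csv(day_dir / "ang.csv", index=False)
    t_hr = np.arange(record.hr.shape[0]) / record.fs_hr
    pd.DataFrame({"t_sec": t_hr, "hr_bpm": record.hr, "rr_ms": record.rr}
                 ).to_csv(day_dir / "hr_rr.csv", index=False)
    pd.DataFrame(record.sleep_epochs or [], columns=["start_sec", "end_sec"]
                 ).to_csv(day_dir / "sleep.csv", index=False)
    return day_dir


def write_cohort(cohort: SyntheticCohort, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.iter_days():
        write_day(rec, out_dir / rec.patient_id)
    cohort.labels.to_csv(out_dir / "labels.csv", index=False)
    manifest = {
        "format_version": FORMAT_VERSION,
        "seed": cohort.seed,
        "specs": [_spec_to_dict(s) for s in cohort.specs],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def _spec_to_dict(spec: PatientSpec) -> dict:
    d = asdict(spec)
    d["params"] = {k: asdict(v) for k, v in spec.params.items()}
    return d


def spec_from_dict(d: dict) -> PatientSpec:
    d = dict(d)
    d["params"] = {k: StateParams(**v) for k, v in d["params"].items()}
    return PatientSpec(**d)


def read_day(cohort_dir: Path, patient_id: str, day_index: int) -> RawDayRecord:
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    spec = next(s for s in manifest["specs"] if s["patient_id"] == patient_id)
    day_dir = cohort_dir / patient_id / f"day_{day_index:04d}"
    acc = pd.read_csv(day_dir / "accel.csv")
    ang = pd.read_csv(day_dir / "ang.csv")
    hr_rr = pd.read_csv(day_dir / "hr_rr.csv")
    sleep = pd.read_csv(day_dir / "sleep.csv")
    labels = pd.read_csv(cohort_dir / "labels.csv")
    row = labels[(labels.patient_id == patient_id) & (labels.day_index == day_index)]
    return RawDayRecord(
        patient_id=patient_id,
        day_index=day_index,
        accel_lin=acc[["x", "y", "z"]].to_numpy(dtype=np.float32),
        accel_ang=ang[["x", "y", "z"]].to_numpy(dtype=np.float32),
        hr=hr_rr["hr_bpm"].to_numpy(dtype=np.float64),
        rr=hr_rr["rr_ms"].to_numpy(dtype=np.float64),
        sleep_epochs=[(float(s), float(e)) for s, e in
                      zip(sleep.get("start_sec", []), sleep.get("end_sec", []))],
        relapse_label=int(row.relapse.iloc[0]),
        fs_accel=float(spec["fs_accel"]),
        fs_hr=float(spec["fs_hr"]),
    )
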