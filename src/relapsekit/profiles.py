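"""4-h profile assembly, sleep stratification and per-patient z-scoring.

Feature rows are stacked into 48 x 12 matrices (48 consecutive 5-min slots
by 12 features), the unit the autoencoder consumes.  Windows are aligned to
clock time with a default stride of 48 slots, i.e. six non-overlapping
windows per day; any window containing an invalid slot is dropped whole.
A window is a *sleep* window when at least half of its slot midpoints fall
inside a sleep epoch (ties count as sleep).

Normalization statistics are computed once from a patient's training rows
and then frozen: validation and test profiles are standardized with the
training mean and SD, never refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, SLOT_SECONDS

WINDOW_SLOTS = 48  # 4 h at 5-min resolution
SLEEP_THRESHOLD = 0.5


@dataclass
class Profile2D:
    """One standardizable 48 x 12 window."""

    patient_id: str
    day_index: int
    window_start: float  # seconds from midnight
    matrix: np.ndarray  # (48, 12) float64, canonical feature order
    sleep_flag: str  # "sleep" | "awake"
    relapse_label: Optional[int]  # None == unknown

    def __post_init__(self):
        if self.matrix.shape != (WINDOW_SLOTS, len(FEATURE_COLUMNS)):
            raise ValueError(f"profile must be {WINDOW_SLOTS}x{len(FEATURE_COLUMNS)}, "
                             f"got {self.matrix.shape}")


@dataclass
class NormalizationStats:
    """Frozen per-patient, per-feature training mean and SD."""

    patient_id: str
    mean: np.ndarray  # (12,)
    sd: np.ndarray  # (12,)
    feature_names: List[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))


def assign_sleep(slot_flags: Sequence[str],
                 threshold: float = SLEEP_THRESHOLD) -> str:
    """Window-level sleep flag from its slots' midpoint flags."""
    flags = np.asarray(slot_flags)
    if flags.size == 0:
        return "awake"
    frac = float((flags == "sleep").mean())
    return "sleep" if frac >= threshold else "awake"


def build_windows(feature_rows: pd.DataFrame,
                  stride: int = WINDOW_SLOTS,
                  window_slots: int = WINDOW_SLOTS,
                  sleep_threshold: float = SLEEP_THRESHOLD) -> List[Profile2D]:
    """Cut one patient-day of feature rows into fully-valid windows.

    ``feature_rows`` must cover a single (patient, day), time-sorted.
    Windows containing any invalid slot are dropped.
    """
    if feature_rows.empty:
        return []
    pids = feature_rows["patient_id"].unique()
    days = feature_rows["day_index"].unique()
    if len(pids) != 1 or len(days) != 1:
        raise ValueError("build_windows expects rows from exactly one patient-day")
    rows = feature_rows.sort_values("interval_start").reset_index(drop=True)
    mat = rows[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    valid = rows["valid"].to_numpy(dtype=bool)
    flags = rows["sleep_flag"].to_numpy()
    label = rows["relapse_label"].iloc[0] if "relapse_label" in rows else None
    n = len(rows)
    out: List[Profile2D] = []
    for start in range(0, n - window_slots + 1, stride):
        sl = slice(start, start + window_slots)
        if not valid[sl].all():
            continue
        out.append(Profile2D(
            patient_id=str(pids[0]),
            day_index=int(days[0]),
            window_start=float(rows["interval_start"].iloc[start]),
            matrix=mat[sl].copy(),
            sleep_flag=assign_sleep(flags[sl], sleep_threshold),
            relapse_label=None if label is None or pd.isna(label) else int(label),
        ))
    return out


def fit_norm(train_rows: pd.DataFrame, patient_id: Optional[str] = None
             ) -> NormalizationStats:
    """Per-feature mean/SD from a patient's *training* rows only.

    Raises if any feature is degenerate (zero variance), naming it.
    """
    rows = train_rows[train_rows["valid"]] if "valid" in train_rows else train_rows
    if rows.empty:
        raise ValueError("fit_norm requires at least one valid training row")
    x = rows[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    bad = [name for name, s in zip(FEATURE_COLUMNS, sd) if not s > 0]
    if bad:
        raise ValueError(f"degenerate (zero-variance) training features: {bad}")
    pid = patient_id or str(rows["patient_id"].iloc[0])
    return NormalizationStats(patient_id=pid, mean=mean, sd=sd)


def apply_norm(profile: Profile2D, stats: NormalizationStats) -> Profile2D:
    """Standardize a profile with frozen training statistics."""
    z = (profile.matrix - stats.mean) / stats.sd
    return Profile2D(profile.patient_id, profile.day_index, profile.window_start,
                     z, profile.sleep_flag, profile.relapse_label)


def invert_norm(profile: Profile2D, stats: NormalizationStats) -> Profile2D:
    x = profile.matrix * stats.sd + stats.mean
    return Profile2D(profile.patient_id, profile.day_index, profile.window_start,
                     x, profile.sleep_flag, profile.relapse_label)


def stack_matrices(profiles: Sequence[Profile2D]) -> np.ndarray:
    """(n, 48, 12) array from a profile list (empty-safe)."""
    if not profiles:
        return np.empty((0, WINDOW_SLOTS, len(FEATURE_COLUMNS)))
    return np.stack([p.matrix for p in profiles])


def save_profiles(profiles: Sequence[Profile2D], path) -> None:
    """Serialize profiles as an array container plus a JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), matrices=stack_matrices(profiles))
    sidecar = profile_meta(profiles).to_dict(orient="list")
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_profiles(path) -> List[Profile2D]:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        mats = data["matrices"]
    out = []
    for i in range(mats.shape[0]):
        label = meta["relapse_label"][i]
        out.append(Profile2D(
            patient_id=meta["patient_id"][i],
            day_index=int(meta["day_index"][i]),
            window_start=float(meta["window_start"][i]),
            matrix=mats[i],
            sleep_flag=meta["sleep_flag"][i],
            relapse_label=None if label is None or pd.isna(label) else int(label),
        ))
    return out


def profile_meta(profiles: Sequence[Profile2D]) -> pd.DataFrame:
    """Metadata table aligned with ``stack_matrices`` row order."""
    return pd.DataFrame({
        "patient_id": [p.patient_id for p in profiles],
        "day_index": [p.day_index for p in profiles],
        "window_start": [p.window_start for p in profiles],
        "sleep_flag": [p.sleep_flag for p in profiles],
        "relapse_label": [np.nan if p.relapse_label is None else p.relapse_label
                          for p in profiles],
    })
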