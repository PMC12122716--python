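"""Day-level scoring, AUC metrics, feature statistics and uncertainty.

The daily relapse score is the unweighted mean of the day's 4-h window
predictions.  Days are then evaluated with PR-AUC and ROC-AUC, combined
through their harmonic mean 2ab/(a+b), either pooled across all patients
or within one patient.  The positive-rate baseline (relapse days / total
days) is the expected PR-AUC of an uninformative scorer and is reported
alongside.

PR-AUC is integrated by the trapezoidal rule through every threshold's
operating point; ``method="average_precision"`` switches to the
step-function estimator.  Feature-level group comparisons use two-sample
Kolmogorov-Smirnov tests on daily feature means with Benjamini-Hochberg
adjustment across the 12 features of each (patient, stratum) family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_COLUMNS


@dataclass
class EvalReport:
    scope: str  # "aggregated" | patient id
    pr_auc: float
    roc_auc: float
    harmonic_mean: float
    baseline_positive_rate: float
    n_days_positive: int
    n_days_negative: int


@dataclass
class KSResult:
    patient_id: str
    feature: str
    stratum: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p_raw: float
    p_adjusted: float


def daily_score(window_values: Sequence[float]) -> float:
    """Unweighted mean of a day's window predictions (hard or soft)."""
    vals = np.asarray(window_values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("a day needs at least one window prediction")
    return float(vals.mean())


def harmonic_mean(a: float, b: float) -> float:
    """2ab/(a+b), defined as 0 when a + b == 0."""
    if a + b == 0:
        return 0.0
    return 2.0 * a * b / (a + b)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC-AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def pr_auc(scores: Sequence[float], labels: Sequence[int],
           method: str = "trapezoid") -> float:
    """Area under the precision-recall curve.

    ``trapezoid`` (default) integrates precision over recall through the
    operating point of every distinct threshold, grouping ties;
    ``average_precision`` uses the step-function sum instead.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("PR-AUC needs both classes present")
    if method == "average_precision":
        return float(average_precision_score(labels, scores))
    if method != "trapezoid":
        raise ValueError(f"unknown PR-AUC method {method!r}")
    order = np.argsort(-scores, kind="stable")
    y = labels[order].astype(np.float64)
    s = scores[order]
    # keep only the last index of each tied-score group
    boundary = np.flatnonzero(np.diff(s) != 0)
    idx = np.concatenate([boundary, [s.size - 1]])
    tp = np.cumsum(y)[idx]
    n_pred = idx + 1.0
    n_pos = y.sum()
    recall = np.concatenate([[0.0], tp / n_pos])
    precision = np.concatenate([[tp[0] / n_pred[0] if n_pred[0] else 1.0],
                                tp / n_pred])
    return float(np.trapezoid(precision, recall))


def evaluate(scores: Sequence[float], labels: Sequence[int],
             scope: str = "aggregated", pr_method: str = "trapezoid"
             ) -> EvalReport:
    """PR-AUC, ROC-AUC, harmonic mean and baseline for one scope."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError(f"scope {scope!r} has a single class; AUCs undefined")
    pr = pr_auc(scores, labels, method=pr_method)
    roc = roc_auc(scores, labels)
    return EvalReport(
        scope=scope,
        pr_auc=pr,
        roc_auc=roc,
        harmonic_mean=harmonic_mean(pr, roc),
        baseline_positive_rate=float(labels.mean()),
        n_days_positive=int(labels.sum()),
        n_days_negative=int((1 - labels).sum()),
    )


def evaluate_day_scores(day_scores: pd.DataFrame, scope: str = "aggregated",
                        pr_method: str = "trapezoid") -> List[EvalReport]:
    """Evaluate a day-score table (columns: patient_id, score, relapse).

    ``scope="aggregated"`` pools every patient's days before computing the
    AUCs; ``scope="per-patient"`` returns one report per patient, skipping
    (with a warning) patients whose labelled days are single-class.
    """
    if scope == "aggregated":
        return [evaluate(day_scores["score"], day_scores["relapse"],
                         scope="aggregated", pr_method=pr_method)]
    reports = []
    for pid, grp in day_scores.groupby("patient_id", sort=True):
        try:
            reports.append(evaluate(grp["score"], grp["relapse"], scope=str(pid),
                                    pr_method=pr_method))
        except ValueError:
            warnings.warn(f"patient {pid}: single-class test days, skipped")
    return reports


def positive_rate(n_relapse: int, n_total: int) -> float:
    """Relapse-day fraction: the uninformative-scorer PR-AUC baseline."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return n_relapse / n_total


def ks_compare(daily_means: pd.DataFrame, group_col: str = "relapse",
               stratum: Optional[str] = None,
               features: Sequence[str] = tuple(FEATURE_COLUMNS),
               min_days: int = 3) -> List[KSResult]:
    """Two-sample KS tests on daily feature means, BH-adjusted per family.

    ``daily_means`` holds one row per (patient, day, stratum) with feature
    columns; the BH family is the 12 features within each (patient,
    stratum).  Features with fewer than ``min_days`` days in either group
    are skipped.
    """
    results: List[KSResult] = []
    strata = [stratum] if stratum else sorted(daily_means["sleep_flag"].unique())
    for pid, pgrp in daily_means.groupby("patient_id", sort=True):
        for st in strata:
            sgrp = pgrp[pgrp["sleep_flag"] == st]
            fam: List[KSResult] = []
            for feat in features:
                a = sgrp.loc[sgrp[group_col] == 0, feat].dropna().to_numpy()
                b = sgrp.loc[sgrp[group_col] == 1, feat].dropna().to_numpy()
                if a.size < min_days or b.size < min_days:
                    continue
                stat = ks_2samp(a, b, method="asymp")
                fam.append(KSResult(
                    patient_id=str(pid), feature=feat, stratum=st,
                    mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                    mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
                    statistic=float(stat.statistic), p_raw=float(stat.pvalue),
                    p_adjusted=np.nan))
            if fam:
                adj = bh_adjust([r.p_raw for r in fam])
                for r, p in zip(fam, adj):
                    r.p_adjusted = float(p)
            results.extend(fam)
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def daily_feature_means(feature_rows: pd.DataFrame) -> pd.DataFrame:
    """Daily averages of the valid 5-min rows, per sleep stratum."""
    rows = feature_rows[feature_rows["valid"]]
    grouped = (rows.groupby(["patient_id", "day_index", "sleep_flag"],
                            sort=True, observed=True)
               [list(FEATURE_COLUMNS) + ["relapse_label"]].mean().reset_index())
    return grouped.rename(columns={"relapse_label": "relapse"})


def bootstrap_uncertainty(run_fn: Callable[[int], Tuple[pd.DataFrame, Dict[str, float]]],
                          seeds: Sequence[int],
                          max_redraws: int = 10) -> pd.DataFrame:
    """Seeded retraining plus test-day bootstrap, per patient.

    ``run_fn(seed)`` must retrain the pipeline under ``seed`` and return
    ``(day_scores, extras)`` where ``day_scores`` has columns patient_id,
    score, relapse and ``extras`` maps patient_id -> reconstruction MSE.
    For every seed the test days of each patient are resampled with
    replacement (same count); a resample that loses a class is redrawn up
    to ``max_redraws`` times, then that (patient, seed) is skipped.
    Returns per-patient mean +/- SD of MSE, PR-AUC, ROC-AUC and HM.
    """
    records = []
    for seed in seeds:
        day_scores, mse_by_patient = run_fn(int(seed))
        rng = np.random.default_rng(int(seed))
        for pid, grp in day_scores.groupby("patient_id", sort=True):
            n = len(grp)
            rep = None
            for _ in range(max_redraws):
                sample = grp.sample(n=n, replace=True, random_state=rng.integers(2**31))
                if sample["relapse"].nunique() < 2:
                    continue
                rep = evaluate(sample["score"], sample["relapse"], scope=str(pid))
                break
            if rep is None:
                warnings.warn(f"patient {pid}, seed {seed}: degenerate resamples")
                continue
            records.append({
                "patient_id": str(pid), "seed": int(seed),
                "mse": float(mse_by_patient.get(str(pid), np.nan)),
                "pr_auc": rep.pr_auc, "roc_auc": rep.roc_auc,
                "harmonic_mean": rep.harmonic_mean,
            })
    raw = pd.DataFrame(records)
    if raw.empty:
        return raw
    agg = raw.groupby("patient_id").agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.drop(columns=[c for c in agg.columns if c.startswith("seed")]
                    ).reset_index()
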