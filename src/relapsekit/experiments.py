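"""Dataset splitting, the eight-configuration grid, and orchestration.

Splitting is per-patient and per-event: a contiguous run of same-label
days is indivisible.  Non-relapse events are assigned greedily in
chronological order to approximate an 8:1:1 train/validation/test ratio by
day count; relapse events are balanced 1:1 between validation and test.
The training split therefore never contains a relapse day — an invariant
asserted again at every stage boundary.

The experiment grid crosses the data used to train the autoencoder with
the data used for clustering:

    ==  ============  =========================
    id  CAE training  clustering
    ==  ============  =========================
    1   all           separate sleep / awake
    2   sleep         separate sleep / awake
    3   awake         separate sleep / awake
    4   all           all
    5   sleep         all
    6   awake         all
    7   sleep         sleep only
    8   awake         awake only
    ==  ============  =========================

For "separate" configurations, sleep and awake windows are clustered by
independent models and their window labels merged before daily averaging.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import SeedSequence

from . import cae as cae_mod
from . import clustering as clus
from . import evalstats
from .features import featurize_day
from .preprocess import ValidRanges, preprocess_day
from .profiles import Profile2D, apply_norm, build_windows, fit_norm, profile_meta
from .synthio import PatientSpec, SyntheticCohort, generate_cohort

SPLITS = ("train", "validation", "test")

#: experiment id -> (CAE training data, clustering setup)
EXPERIMENTS: Dict[int, Tuple[str, str]] = {
    1: ("all", "separate"),
    2: ("sleep", "separate"),
    3: ("awake", "separate"),
    4: ("all", "all"),
    5: ("sleep", "all"),
    6: ("awake", "all"),
    7: ("sleep", "sleep"),
    8: ("awake", "awake"),
}


@dataclass
class ExperimentConfig:
    experiment_id: int
    cae_training_data: str = field(init=False)
    clustering_data: str = field(init=False)

    def __post_init__(self):
        if self.experiment_id not in EXPERIMENTS:
            raise ValueError(f"unknown experiment id {self.experiment_id}")
        self.cae_training_data, self.clustering_data = EXPERIMENTS[self.experiment_id]


@dataclass
class SplitPlan:
    assignments: pd.DataFrame  # patient_id, day_index, relapse, split
    events: pd.DataFrame  # patient_id, start_day, end_day, label, split

    def split_of(self, patient_id: str) -> Dict[int, str]:
        sub = self.assignments[self.assignments.patient_id == patient_id]
        return dict(zip(sub.day_index, sub.split))


def split_dataset(labels: pd.DataFrame, ratios: Tuple[float, float, float] = (8, 1, 1),
                  seed: int = 0) -> SplitPlan:
    """Per-patient, per-event assignment of days to train/validation/test."""
    del seed  # the policy is deterministic; kept for interface stability
    frames = []
    event_rows = []
    targets = np.asarray(ratios, dtype=float)
    targets = targets / targets.sum()
    for pid, grp in labels.groupby("patient_id", sort=True):
        grp = grp.sort_values("day_index")
        labs = grp["relapse"].to_numpy()
        days = grp["day_index"].to_numpy()
        events = _contiguous_events(days, labs)
        n_nonrel = int((labs == 0).sum())
        counts = np.zeros(3)
        rel_counts = {"validation": 0, "test": 0}
        rel_seen = 0
        if not any(lab for _, _, lab in events):
            warnings.warn(f"patient {pid}: no relapse event; "
                          "validation/test are non-relapse only")
        assign: Dict[int, str] = {}
        for start, end, lab in events:
            length = end - start
            if lab == 0:
                # relative deficit keeps the small validation/test buckets
                # competitive with the large training bucket
                deficits = (targets * n_nonrel - counts) / (targets * n_nonrel)
                k = int(np.argmax(np.round(deficits, 12)))
                if deficits[1] == deficits[2] and k == 1 and counts[1] > 0:
                    k = 2  # balance validation and test on exact ties
                counts[k] += length
                split = SPLITS[k]
            else:
                if rel_counts["validation"] < rel_counts["test"]:
                    split = "validation"
                elif rel_counts["validation"] > rel_counts["test"]:
                    split = "test"
                else:
                    split = "validation" if rel_seen % 2 == 0 else "test"
                rel_counts[split] += length
                rel_seen += 1
            event_rows.append({"patient_id": pid, "start_day": int(start),
                               "end_day": int(end), "label": int(lab),
                               "split": split})
            for d in range(start, end):
                assign[d] = split
        sub = grp.copy()
        sub["split"] = [assign[int(d)] for d in sub.day_index]
        frames.append(sub)
    plan = SplitPlan(assignments=pd.concat(frames, ignore_index=True),
                     events=pd.DataFrame(event_rows))
    _assert_train_clean(plan.assignments)
    return plan


def _contiguous_events(days: np.ndarray, labs: np.ndarray
                       ) -> List[Tuple[int, int, int]]:
    """(start_day, end_day_exclusive, label) runs over consecutive days."""
    events = []
    start = 0
    for i in range(1, len(days) + 1):
        boundary = (i == len(days) or labs[i] != labs[start]
                    or days[i] != days[i - 1] + 1)
        if boundary:
            events.append((int(days[start]), int(days[i - 1]) + 1, int(labs[start])))
            if i < len(days):
                start = i
    return events


def _assert_train_clean(assignments: pd.DataFrame) -> None:
    bad = assignments[(assignments.split == "train") & (assignments.relapse == 1)]
    if not bad.empty:
        raise AssertionError("relapse day assigned to the training split")


# ---------------------------------------------------------------------------
# cohort featurization and per-patient bundles
# ---------------------------------------------------------------------------


def featurize_cohort(cohort: SyntheticCohort,
                     ranges: Optional[ValidRanges] = None) -> pd.DataFrame:
    """Stream every day through preprocessing and feature extraction."""
    frames = [featurize_day(preprocess_day(rec, ranges))
              for rec in cohort.iter_days()]
    return pd.concat(frames, ignore_index=True)


@dataclass
class PatientBundle:
    """Standardized profiles of one patient, keyed by split."""

    patient_id: str
    profiles: Dict[str, List[Profile2D]]
    stats: object
    day_labels: pd.DataFrame  # day_index, relapse, split


def prepare_bundles(features_df: pd.DataFrame, plan: SplitPlan,
                    stride: int = 48) -> Dict[str, PatientBundle]:
    """Window, label and standardize every patient's feature rows."""
    _assert_train_clean(plan.assignments)
    bundles: Dict[str, PatientBundle] = {}
    for pid, grp in features_df.groupby("patient_id", sort=True):
        split_map = plan.split_of(str(pid))
        train_days = {d for d, s in split_map.items() if s == "train"}
        train_rows = grp[grp.day_index.isin(train_days)]
        stats = fit_norm(train_rows, patient_id=str(pid))
        profiles: Dict[str, List[Profile2D]] = {s: [] for s in SPLITS}
        for day, day_rows in grp.groupby("day_index"):
            split = split_map.get(int(day))
            if split is None:
                continue
            for prof in build_windows(day_rows, stride=stride):
                if split == "train" and prof.relapse_label == 1:
                    raise AssertionError("relapse window leaked into training")
                profiles[split].append(apply_norm(prof, stats))
        day_labels = (plan.assignments[plan.assignments.patient_id == pid]
                      [["day_index", "relapse", "split"]].reset_index(drop=True))
        bundles[str(pid)] = PatientBundle(str(pid), profiles, stats, day_labels)
    return bundles


# ---------------------------------------------------------------------------
# experiment execution
# ---------------------------------------------------------------------------


def _mode_filter(profiles: Sequence[Profile2D], mode: str) -> List[Profile2D]:
    if mode == "all":
        return list(profiles)
    return [p for p in profiles if p.sleep_flag == mode]


def _patient_seed(master_seed: int, patient_id: str, mode: str) -> int:
    tag = zlib.crc32(f"{patient_id}:{mode}".encode())  # stable across runs
    ss = SeedSequence([int(master_seed), int(tag)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class ExperimentResult:
    experiment_id: int
    aggregated: evalstats.EvalReport
    per_patient: List[evalstats.EvalReport]
    day_scores: pd.DataFrame  # patient_id, day_index, score, relapse
    mse_by_patient: Dict[str, float]
    selected_methods: Dict[str, str]
    silhouettes: Dict[str, float] = field(default_factory=dict)


def _train_patient_cae(bundle: PatientBundle, mode: str, seed: int,
                       cae_config: Optional[cae_mod.CAEConfig]) -> cae_mod.TrainedCAE:
    base = cae_config or cae_mod.CAEConfig()
    config = dataclasses.replace(
        base, seed=_patient_seed(seed, bundle.patient_id, mode))
    train = _mode_filter(bundle.profiles["train"], mode)
    val = _mode_filter(bundle.profiles["validation"], mode)
    if not train:
        raise ValueError(f"patient {bundle.patient_id}: no {mode} training windows")
    model = cae_mod.train_cae(train, val, config)
    model.norm_stats_patient = bundle.patient_id
    return model


def run_experiment(bundles: Dict[str, PatientBundle], experiment_id: int,
                   seed: int = 0, cae_config: Optional[cae_mod.CAEConfig] = None,
                   soft: bool = False,
                   cae_cache: Optional[Dict] = None) -> ExperimentResult:
    """Run one grid configuration end to end over every patient."""
    config = ExperimentConfig(experiment_id)
    cae_cache = cae_cache if cae_cache is not None else {}
    all_scores = []
    mse_by_patient: Dict[str, float] = {}
    selected: Dict[str, str] = {}
    silhouettes: Dict[str, float] = {}
    for pid, bundle in sorted(bundles.items()):
        cache_key = (pid, config.cae_training_data, seed)
        if cache_key not in cae_cache:
            cae_cache[cache_key] = _train_patient_cae(
                bundle, config.cae_training_data, seed, cae_config)
        model = cae_cache[cache_key]
        mse_by_patient[pid] = (min(model.history["val_mse"])
                               if model.history.get("val_mse") else float("nan"))
        strata = (["sleep", "awake"] if config.clustering_data == "separate"
                  else [config.clustering_data])
        test_preds = []
        for stratum in strata:
            pred = _cluster_stratum(bundle, model, stratum, seed, soft)
            if pred is not None:
                test_preds.append(pred)
                selected[f"{pid}:{stratum}"] = pred.attrs.get("method", "?")
                if "silhouette" in pred.attrs:
                    silhouettes[f"{pid}:{stratum}"] = pred.attrs["silhouette"]
        if not test_preds:
            warnings.warn(f"patient {pid}: no usable test windows, skipped")
            continue
        preds = pd.concat(test_preds, ignore_index=True)
        col = "soft_score" if soft else "hard_label"
        day = (preds.groupby(["patient_id", "day_index"])[col]
               .mean().rename("score").reset_index())
        labels = bundle.day_labels[bundle.day_labels.split == "test"]
        day = day.merge(labels[["day_index", "relapse"]], on="day_index",
                        how="inner")
        all_scores.append(day)
    day_scores = (pd.concat(all_scores, ignore_index=True)
                  if all_scores else pd.DataFrame(
                      columns=["patient_id", "day_index", "score", "relapse"]))
    aggregated = evalstats.evaluate_day_scores(day_scores, scope="aggregated")[0]
    per_patient = evalstats.evaluate_day_scores(day_scores, scope="per-patient")
    return ExperimentResult(experiment_id, aggregated, per_patient, day_scores,
                            mse_by_patient, selected, silhouettes)


def _cluster_stratum(bundle: PatientBundle, model: cae_mod.TrainedCAE,
                     stratum: str, seed: int, soft: bool):
    """Cluster one stratum's latents and predict its test windows."""
    fit_profiles = (_mode_filter(bundle.profiles["train"], stratum)
                    + _mode_filter(bundle.profiles["validation"], stratum))
    val_profiles = _mode_filter(bundle.profiles["validation"], stratum)
    test_profiles = _mode_filter(bundle.profiles["test"], stratum)
    if len(fit_profiles) < 2 or not test_profiles:
        return None
    latents_fit = cae_mod.encode(model, fit_profiles)
    val_labels = bundle.day_labels[bundle.day_labels.split == "validation"]
    val_labels = val_labels.assign(patient_id=bundle.patient_id)[
        ["patient_id", "day_index", "relapse"]]
    if val_profiles:
        val_latents = cae_mod.encode(model, val_profiles)
        val_meta = profile_meta(val_profiles)
    else:
        val_latents, val_meta = latents_fit[:0], profile_meta([])
    cmodel = clus.fit_oriented(latents_fit, val_latents, val_meta, val_labels,
                               seed=seed, soft=soft)
    test_latents = cae_mod.encode(model, test_profiles)
    pred = clus.predict_windows(cmodel, test_latents, profile_meta(test_profiles))
    pred.attrs["method"] = cmodel.method
    if pred["hard_label"].nunique() == 2:
        pred.attrs["silhouette"] = clus.silhouette(
            test_latents, pred["hard_label"].to_numpy())
    return pred


def run_grid(bundles: Dict[str, PatientBundle],
             experiment_ids: Sequence[int] = tuple(EXPERIMENTS),
             seed: int = 0, cae_config: Optional[cae_mod.CAEConfig] = None,
             soft: bool = False
             ) -> Tuple[pd.DataFrame, Dict[int, ExperimentResult]]:
    """Run several experiments, sharing trained autoencoders across them."""
    cache: Dict = {}
    rows = []
    results: Dict[int, ExperimentResult] = {}
    for exp_id in experiment_ids:
        res = run_experiment(bundles, exp_id, seed=seed, cae_config=cae_config,
                             soft=soft, cae_cache=cache)
        results[exp_id] = res
        rows.append({
            "experiment": exp_id,
            "pr_auc": res.aggregated.pr_auc,
            "roc_auc": res.aggregated.roc_auc,
            "harmonic_mean": res.aggregated.harmonic_mean,
            "baseline_positive_rate": res.aggregated.baseline_positive_rate,
        })
    return pd.DataFrame(rows), results


def run_uncertainty(bundles: Dict[str, PatientBundle], experiment_id: int = 7,
                    seeds: Sequence[int] = (0, 1, 2, 3, 4),
                    cae_config: Optional[cae_mod.CAEConfig] = None
                    ) -> pd.DataFrame:
    """Seed-level uncertainty of the selected configuration.

    Retrains the pipeline under each seed (autoencoder initialization) and
    bootstrap-resamples test days, reporting per-patient mean +/- SD of
    reconstruction MSE, PR-AUC, ROC-AUC and harmonic mean.
    """

    def run_fn(seed):
        res = run_experiment(bundles, experiment_id, seed=seed,
                             cae_config=cae_config)
        return res.day_scores, res.mse_by_patient

    return evalstats.bootstrap_uncertainty(run_fn, seeds=seeds)


def calibration_report(params: Optional[Dict] = None, n_days: int = 120,
                       seed: int = 1234) -> pd.DataFrame:
    """Generator-to-pipeline calibration of the state-dependent targets.

    Streams one corruption-free patient (relapse and non-relapse days
    balanced) through the full cleaning and feature pipeline and compares
    the extracted daily means of mean NN, SDNN and acceleration norm with
    the configured state targets.  Returns one row per (stratum, state,
    feature) with the extracted mean, its standard error over days, and
    the z-distance to the target.
    """
    from .synthio import USER00_LIKE
    from . import evalstats as ev

    params = params or USER00_LIKE
    spec = PatientSpec(patient_id="cal", params=params, n_days=n_days,
                       relapse_rate=0.5, relapse_event_mean_len=4.0, seed=0)
    cohort = generate_cohort([spec], seed=seed)
    features_df = featurize_cohort(cohort)
    daily = ev.daily_feature_means(features_df)
    targets = {"nn_mean": "mean_nn", "sdnn": "sdnn_target",
               "accel_norm_mean": "accel_mean"}
    rows = []
    for stratum in ("sleep", "awake"):
        for relapse, status in ((0, "nonrelapse"), (1, "relapse")):
            sub = daily[(daily.sleep_flag == stratum) & (daily.relapse == relapse)]
            state = params[f"{stratum}_{status}"]
            for feat, attr in targets.items():
                target = getattr(state, attr)
                se = sub[feat].std(ddof=1) / np.sqrt(len(sub))
                rows.append({
                    "stratum": stratum, "state": status, "feature": feat,
                    "n_days": len(sub), "extracted": sub[feat].mean(),
                    "target": target, "se": se,
                    "z": (sub[feat].mean() - target) / se,
                })
    return pd.DataFrame(rows)


def run_synthetic_study(specs: Sequence[PatientSpec], seed: int,
                        experiment_ids: Sequence[int] = tuple(EXPERIMENTS),
                        cae_config: Optional[cae_mod.CAEConfig] = None,
                        stride: int = 48, soft: bool = False
                        ) -> Tuple[pd.DataFrame, Dict[int, ExperimentResult]]:
    """Generate a cohort, run the pipeline, and evaluate the grid."""
    cohort = generate_cohort(specs, seed)
    features_df = featurize_cohort(cohort)
    plan = split_dataset(cohort.labels, seed=seed)
    bundles = prepare_bundles(features_df, plan, stride=stride)
    return run_grid(bundles, experiment_ids, seed=seed, cae_config=cae_config,
                    soft=soft)
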