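"""End-to-end orchestration: cohort → features → windows → model → report.

A *datapoint* is the unit that carries one label and one prediction.  For
side-independent targets (speed, cadence, GMFCS) the datapoint is the video
and both limbs' feature series contribute windows to it, sharing one
segment count c(i).  For per-limb targets (knee flexion at maximum
extension, the GDI-like score, SEMLS) the datapoint is a (video, side)
pair.  Patients are never split across the train/validation/test partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from videogait import evaluate, models, training, windowing
from videogait.io_keypoints import KeypointFrameSeries, filter_analyzable, gmfcs_to_int
from videogait.preprocess import FeatureSeries, build_feature_series, preprocess_series
from videogait.synthetic_gait import SyntheticTruth, truth_to_labels

SIDE_INDEPENDENT = ("speed", "cadence", "gmfcs")
PER_LIMB = ("knee_flexion_max_ext", "gdi", "semls")
CLASSIFICATION = {"gmfcs": 4, "semls": 2}


@dataclass
class SplitSpec:
    """Patient-level partition fractions (every patient's videos land in
    exactly one partition)."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1
    seed: int = 0


def split_by_patient(labels: pd.DataFrame, spec: SplitSpec) -> dict[str, str]:
    """Random patient-level assignment to train/val/test at the given
    fractions; deterministic given the seed."""
    if "patient_id" not in labels.columns or labels["patient_id"].isna().any():
        raise ValueError("every row needs a patient_id")
    patients = sorted(labels["patient_id"].astype(str).unique())
    n = len(patients)
    if n < 3:
        raise ValueError("need at least 3 patients to form three partitions")
    rng = np.random.default_rng(spec.seed)
    order = [patients[i] for i in rng.permutation(n)]
    n_test = max(1, round(spec.test * n))
    n_val = max(1, round(spec.val * n))
    assignment = {}
    for i, p in enumerate(order):
        if i < n_test:
            assignment[p] = "test"
        elif i < n_test + n_val:
            assignment[p] = "val"
        else:
            assignment[p] = "train"
    return assignment


def prepare_features(
    cohort: list[tuple[KeypointFrameSeries, SyntheticTruth]],
    target: str,
    sigma: float = 1.0,
) -> tuple[list[tuple[FeatureSeries, float]], dict[str, str]]:
    """Preprocess a cohort and assemble labeled feature series for a target.

    Returns (datapoints, patient_of) where datapoints pair each feature
    series with its label under the datapoint id convention above, and
    patient_of maps datapoint id → patient.  Non-analyzable videos
    (multi-person or never-detected) are dropped.
    """
    if target not in SIDE_INDEPENDENT + PER_LIMB:
        raise ValueError(f"unknown target {target!r}")
    datapoints: list[tuple[FeatureSeries, float]] = []
    patient_of: dict[str, str] = {}
    for series, truth in cohort:
        if not filter_analyzable(series):
            continue
        norm = preprocess_series(series, sigma=sigma)
        measured = truth.measured or {}
        if target in SIDE_INDEPENDENT:
            if target == "gmfcs":
                y = float(gmfcs_to_int(truth.gmfcs) - 1)
            else:
                y = float(measured.get(target, getattr(truth, target)))
            for side in ("left", "right"):
                feat = build_feature_series(norm, side)
                datapoints.append((feat, y))
            patient_of[series.video_id] = truth.patient_id
        else:
            attr = {"knee_flexion_max_ext": "knee_flexion_max_ext",
                    "gdi": "gdi_like", "semls": "semls"}[target]
            value = measured.get(attr, getattr(truth, attr)) \
                if target != "semls" else truth.semls
            for side in ("left", "right"):
                feat = build_feature_series(norm, side)
                feat = FeatureSeries(video_id=f"{series.video_id}:{side}",
                                     side=side, data=feat.data,
                                     channel_missing=feat.channel_missing,
                                     fps=feat.fps)
                datapoints.append((feat, float(value[side])))
                patient_of[feat.video_id] = truth.patient_id
    return datapoints, patient_of


def _segment_sets(datapoints, patient_of, assignment):
    sets = {}
    for part in ("train", "val", "test"):
        sel = [(f, y) for f, y in datapoints
               if assignment[patient_of[f.video_id]] == part]
        sets[part] = windowing.build_segment_set(sel)
    return sets


def _video_predictions(model, segset, task):
    by_vid: dict[str, list] = {}
    for seg in segset.segments:
        by_vid.setdefault(seg.video_id, []).append(seg)
    ids = sorted(by_vid)
    preds = [training.predict_video(model, by_vid[v], task=task) for v in ids]
    truths = [segset.labels[v] for v in ids]
    return ids, np.asarray(preds), np.asarray(truths, dtype=float)


def run_cnn_experiment(
    cohort: list[tuple[KeypointFrameSeries, SyntheticTruth]],
    target: str,
    cnn_config: models.CNNConfig | None = None,
    train_config: training.TrainConfig | None = None,
    split: SplitSpec | None = None,
    n_boot: int = 200,
) -> dict:
    """Train the CNN for one target on a cohort and evaluate on held-out
    patients.

    Regression targets are z-scored on the training set for optimization
    and mapped back at prediction; the averaged per-video predictions are
    then debiased with a linear calibration fitted on the training set.
    Returns a dict with the trained model, per-split predictions and an
    evaluation report.
    """
    split = split or SplitSpec()
    train_config = train_config or training.TrainConfig()
    task = "classification" if target in CLASSIFICATION else "regression"
    if cnn_config is None:
        cnn_config = models.CNNConfig(
            head="classification" if task == "classification" else "regression",
            n_classes=CLASSIFICATION.get(target, 1),
            seed=train_config.seed,
        )
    datapoints, patient_of = prepare_features(cohort, target)
    patients = pd.DataFrame({"patient_id": list(patient_of.values())})
    assignment = split_by_patient(patients, split)
    sets = _segment_sets(datapoints, patient_of, assignment)

    y_mu, y_sd = 0.0, 1.0
    if task == "regression":
        y_tr = sets["train"].y()
        y_mu, y_sd = float(y_tr.mean()), float(y_tr.std() or 1.0)
        for part in sets.values():
            part.labels = {k: (v - y_mu) / y_sd for k, v in part.labels.items()}

    model = models.build_cnn(cnn_config)
    history = training.train(model, sets["train"], train_config,
                             val_set=sets["val"], task=task)

    out: dict = {"model": model, "history": history, "assignment": assignment,
                 "segment_sets": sets, "target": target, "task": task}
    preds = {}
    for part in ("train", "val", "test"):
        ids, p, t = _video_predictions(model, sets[part], task)
        if task == "regression":
            p = p * y_sd + y_mu
            t = t * y_sd + y_mu
        preds[part] = (ids, p, t)
    if task == "regression":
        debias = training.fit_debias(preds["train"][1], preds["train"][2])
        out["debias"] = debias
        for part in preds:
            ids, p, t = preds[part]
            preds[part] = (ids, training.apply_debias(debias, p), t)
        ids, p, t = preds["test"]
        out["report"] = evaluate.regression_report(
            t, p, target=target, n_boot=n_boot, seed=train_config.seed)
    elif target == "gmfcs":
        ids, p, t = preds["test"]
        hard = p.argmax(axis=1)
        mat, acc, max_err = evaluate.confusion_and_accuracy(
            t.astype(int), hard, levels=list(range(4)))
        report = evaluate.EvalReport(target=target, n=len(ids),
                                     accuracy=acc)
        try:
            report.kappa = evaluate.weighted_kappa(mat)
        except ValueError:
            pass
        report.extra = {"confusion": mat.tolist(), "max_level_error": max_err}
        out["report"] = report
    else:  # semls
        ids, p, t = preds["test"]
        report = evaluate.EvalReport(target=target, n=len(ids))
        try:
            auc, roc = evaluate.roc_auc(t.astype(int), p[:, 1])
            report.auc = auc
            report.extra = {"roc": roc.tolist()}
        except ValueError:
            pass
        out["report"] = report
    out["predictions"] = preds
    return out


def run_baseline_experiment(
    cohort: list[tuple[KeypointFrameSeries, SyntheticTruth]],
    target: str,
    model_kind: str = "ridge",
    alpha: float = 0.0,
    split: SplitSpec | None = None,
    seed: int = 0,
    n_boot: int = 200,
) -> dict:
    """Ridge or random-forest baseline on 72 per-video summary features.

    Uses the full-length series (not windows); per-limb feature vectors of a
    side-independent target are averaged into one vector per video.
    """
    split = split or SplitSpec()
    datapoints, patient_of = prepare_features(cohort, target)
    feats: dict[str, list[np.ndarray]] = {}
    label_of: dict[str, float] = {}
    for f, y in datapoints:
        feats.setdefault(f.video_id, []).append(models.summary_features(f))
        label_of[f.video_id] = y
    ids = sorted(feats)
    X = np.stack([np.mean(feats[v], axis=0) for v in ids])
    y = np.array([label_of[v] for v in ids])
    assignment = split_by_patient(
        pd.DataFrame({"patient_id": list(patient_of.values())}), split)
    part = np.array([assignment[patient_of[v]] for v in ids])
    task = "classification" if target in CLASSIFICATION else "regression"
    tr, te = part != "test", part == "test"
    if model_kind == "ridge":
        if task == "classification":
            raise ValueError("ridge baseline is regression-only")
        fitted = models.fit_ridge(X[tr], y[tr], alpha=alpha)
        pred = fitted.predict(X[te])
    elif model_kind == "rf":
        fitted = models.fit_random_forest(X[tr], y[tr], seed=seed, task=task)
        pred = (fitted.predict_proba(X[te])[:, 1] if task == "classification"
                else fitted.predict(X[te]))
    else:
        raise ValueError(f"unknown baseline {model_kind!r}")
    out = {"model": fitted, "ids": list(np.array(ids)[te]),
           "pred": pred, "truth": y[te], "target": target}
    if task == "regression":
        out["report"] = evaluate.regression_report(y[te], pred, target=target,
                                                   n_boot=n_boot, seed=seed)
    return out


__all__ = [
    "SplitSpec", "split_by_patient", "prepare_features",
    "run_cnn_experiment", "run_baseline_experiment",
    "SIDE_INDEPENDENT", "PER_LIMB", "truth_to_labels",
]
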