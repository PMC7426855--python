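"""Evaluation statistics for gait-metric predictions.

Covers the full reporting stack: Pearson correlation with seeded bootstrap
confidence intervals, mean absolute error, a two-sided t-test on the mean
residual (bias), quadratic-weighted Cohen's kappa for ordinal GMFCS levels,
ROC/AUC for the binary surgery decision, a nested (patient / visit / trial)
sum-of-squares decomposition of prediction error, residual-vs-covariate
model selection by BIC, per-limb asymmetry and longitudinal differencing,
and logistic stacking of the CNN with a GDI-based logistic model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

N_BOOT = 200


@dataclass
class EvalReport:
    """Bundle of evaluation statistics for one target."""

    target: str = ""
    n: int = 0
    r: float = np.nan
    r_ci: tuple[float, float] = (np.nan, np.nan)
    mae: float = np.nan
    bias_mean: float = np.nan
    bias_ci: tuple[float, float] = (np.nan, np.nan)
    bias_p: float = np.nan
    kappa: float = np.nan
    accuracy: float = np.nan
    auc: float = np.nan
    n_boot: int = N_BOOT
    extra: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = {
            "target": self.target, "n": self.n, "r": self.r,
            "r_ci": list(self.r_ci), "mae": self.mae,
            "bias_mean": self.bias_mean, "bias_ci": list(self.bias_ci),
            "bias_p": self.bias_p, "kappa": self.kappa,
            "accuracy": self.accuracy, "auc": self.auc,
            "n_boot": self.n_boot, **self.extra,
        }
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class VarianceDecomposition:
    """Nested decomposition of the prediction sum of squares.

    ``ss`` = sum((truth - pred)^2) splits exactly into patient-to-patient
    (``ss_patient``), visit-to-visit within patient (``ss_visit``) and
    trial-to-trial within visit (``ss_trial``) components.
    ``unexplained_variance`` is ss divided by the sum of squares of the null
    model that predicts the grand mean of the truth.
    """

    ss: float
    ss_patient: float
    ss_visit: float
    ss_trial: float
    unexplained_variance: float


def pearson_with_bootstrap(truth: np.ndarray, pred: np.ndarray,
                           n_boot: int = N_BOOT, seed: int = 0,
                           ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Sample Pearson r with a paired-resampling bootstrap CI.

    Resampling is at the prediction (video) level; the CI is the
    (1-ci)/2 and 1-(1-ci)/2 percentiles of r over ``n_boot`` resamples.
    """
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(truth) == 0 or np.std(pred) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(truth, pred).statistic)
    rng = np.random.default_rng(seed)
    n = truth.size
    rs = []
    with np.errstate(invalid="ignore"):
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            t, p = truth[idx], pred[idx]
            if np.std(t) == 0 or np.std(p) == 0:
                continue  # degenerate resample: correlation undefined
            r_b = np.corrcoef(t, p)[0, 1]
            if np.isfinite(r_b):
                rs.append(r_b)
    if not rs:
        return r, (r, r)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(rs, [100 * alpha, 100 * (1 - alpha)])
    lo, hi = min(lo, r), max(hi, r)
    return r, (float(lo), float(hi))


def bias_test(truth: np.ndarray, pred: np.ndarray,
              ci: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """Mean residual (truth - pred) with a two-sided one-sample t-test.

    Returns (mean bias, CI, p).  With zero-variance residuals (exact
    predictions) the t statistic is undefined; this is reported as p = 1
    (no evidence of bias).
    """
    resid = np.asarray(truth, dtype=float) - np.asarray(pred, dtype=float)
    if resid.size < 2:
        raise ValueError("need at least 2 residuals")
    mean = float(resid.mean())
    sd = resid.std(ddof=1)
    if sd == 0:
        return mean, (mean, mean), 1.0
    res = stats.ttest_1samp(resid, 0.0)
    lo, hi = res.confidence_interval(ci)
    return mean, (float(lo), float(hi)), float(res.pvalue)


def weighted_kappa(confusion: np.ndarray, weighting: str = "quadratic") -> float:
    """Weighted Cohen's kappa from a K×K confusion matrix of counts.

    kappa = 1 - sum(w * observed) / sum(w * expected), with expected counts
    from the marginals under independence and disagreement weights
    w_ij = (i - j)^2 (quadratic, the default) or |i - j| (linear); any
    positive scaling of w cancels in the ratio.
    """
    x = np.asarray(confusion, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(x < 0) or x.sum() <= 0:
        raise ValueError("confusion matrix needs non-negative counts, total > 0")
    k = x.shape[0]
    i, j = np.indices((k, k))
    if weighting == "quadratic":
        w = (i - j) ** 2
    elif weighting == "linear":
        w = np.abs(i - j)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    n = x.sum()
    expected = np.outer(x.sum(axis=1), x.sum(axis=0)) / n
    denom = float(np.sum(w * expected))
    if denom == 0:
        raise ValueError("kappa undefined: no expected disagreement (single class)")
    return 1.0 - float(np.sum(w * x)) / denom


def confusion_and_accuracy(truth: np.ndarray, predicted: np.ndarray,
                           levels: list | None = None):
    """Confusion matrix (rows = predicted, columns = true), accuracy, and
    the largest ordinal level error among observed misclassifications."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if levels is None:
        levels = sorted(set(truth.tolist()) | set(predicted.tolist()))
    index = {lvl: i for i, lvl in enumerate(levels)}
    k = len(levels)
    mat = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predicted):
        mat[index[p], index[t]] += 1
    accuracy = float(np.trace(mat) / mat.sum())
    i, j = np.nonzero(mat)
    max_level_error = int(np.max(np.abs(i - j))) if i.size else 0
    return mat, accuracy, max_level_error


def roc_auc(truth: np.ndarray, scores: np.ndarray):
    """AUC by the rank (Mann-Whitney) formulation with midranks for ties,
    plus the ROC points (fpr, tpr) for plotting."""
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks
    auc = (ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="stable")
    sorted_truth = truth[order]
    tps = np.cumsum(sorted_truth)
    fps = np.cumsum(1 - sorted_truth)
    # collapse threshold ties
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), truth.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return float(auc), np.column_stack([fpr, tpr])


def variance_decomposition(records: pd.DataFrame,
                           truth_col: str = "truth",
                           pred_col: str = "pred") -> VarianceDecomposition:
    """Nested ANOVA-style split of the prediction error sum of squares.

    ``records`` needs columns patient, visit, trial, plus truth and
    prediction.  With residual r = truth - pred and nested means, the exact
    identity is

        sum r^2 = sum_p n_p rbar_p^2                       (patient)
                + sum_{p,v} n_pv (rbar_pv - rbar_p)^2      (visit)
                + sum (r - rbar_pv)^2                      (trial)

    One trial per visit makes the trial component exactly zero.
    """
    df = records.copy()
    r = df[truth_col].to_numpy(dtype=float) - df[pred_col].to_numpy(dtype=float)
    df = df.assign(_r=r)
    ss = float(np.sum(r ** 2))
    patient_means = df.groupby("patient")["_r"].transform("mean")
    visit_means = df.groupby(["patient", "visit"])["_r"].transform("mean")
    ss_patient = float(np.sum(patient_means ** 2))
    ss_visit = float(np.sum((visit_means - patient_means) ** 2))
    ss_trial = float(np.sum((df["_r"] - visit_means) ** 2))
    truth = df[truth_col].to_numpy(dtype=float)
    ss_null = float(np.sum((truth - truth.mean()) ** 2))
    unexplained = ss / ss_null if ss_null > 0 else np.nan
    return VarianceDecomposition(ss=ss, ss_patient=ss_patient, ss_visit=ss_visit,
                                 ss_trial=ss_trial, unexplained_variance=unexplained)


def residual_covariate_fit(residuals: np.ndarray, covariate: np.ndarray) -> dict:
    """Fit residual ~ covariate (linear) and ~ covariate + covariate^2
    (quadratic) by least squares; choose by BIC; report the chosen model's
    overall-regression F-test p value.

    BIC counts the noise variance as a parameter: 3 for the linear model,
    4 for the quadratic (the constant offset cancels in the comparison).
    """
    r = np.asarray(residuals, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if r.size < 4:
        raise ValueError("need at least 4 points")
    n = r.size
    fits = {}
    for name, X in (("linear", np.column_stack([x])),
                    ("quadratic", np.column_stack([x, x ** 2]))):
        res = sm.OLS(r, sm.add_constant(X)).fit()
        k = X.shape[1] + 2  # intercept + slopes + noise variance
        bic = n * np.log(res.ssr / n) + k * np.log(n)
        fits[name] = (bic, res)
    chosen = min(fits, key=lambda name: fits[name][0])
    bic, res = fits[chosen]
    return {
        "model": chosen,
        "bic": float(bic),
        "f_pvalue": float(res.f_pvalue),
        "params": res.params,
        "result": res,
    }


def asymmetry_and_longitudinal(per_limb: pd.DataFrame | None = None,
                               per_visit: pd.DataFrame | None = None) -> dict:
    """Derived quantities from per-limb and per-visit predictions.

    ``per_limb`` (columns video_id, side, pred, truth) yields per-video
    asymmetry = left - right for predictions and truths; unmatched videos
    are skipped and reported.  ``per_visit`` (columns patient, visit, pred,
    truth, ordered by visit) yields longitudinal change per consecutive
    visit pair, both with the true baseline (predicted follow-up - true
    baseline) and without (predicted follow-up - predicted baseline).
    """
    out: dict = {}
    if per_limb is not None:
        wide = per_limb.pivot_table(index="video_id", columns="side",
                                    values=["pred", "truth"], aggfunc="first")
        complete = wide.dropna()
        out["asymmetry"] = pd.DataFrame({
            "pred": complete[("pred", "left")] - complete[("pred", "right")],
            "truth": complete[("truth", "left")] - complete[("truth", "right")],
        })
        out["asymmetry_skipped"] = sorted(set(wide.index) - set(complete.index))
    if per_visit is not None:
        rows = []
        for patient, grp in per_visit.groupby("patient"):
            grp = grp.sort_values("visit")
            if len(grp) < 2:
                continue
            base, follow = grp.iloc[0], grp.iloc[1]
            rows.append({
                "patient": patient,
                "pred_change_known_baseline": follow["pred"] - base["truth"],
                "pred_change_no_baseline": follow["pred"] - base["pred"],
                "true_change": follow["truth"] - base["truth"],
            })
        out["longitudinal"] = pd.DataFrame(rows)
    return out


def ensemble_with_gdi(cnn_prob_train: np.ndarray, gdi_train: np.ndarray,
                      y_train: np.ndarray, cnn_prob_test: np.ndarray,
                      gdi_test: np.ndarray, seed: int = 0) -> dict:
    """Logistic stacking of the CNN surgery probability with a GDI model.

    Fits (on training data only) a logistic regression of the surgery label
    on GDI, then a second logistic regression on the two probability scores.
    Returns the test-set probabilities of the GDI model and the ensemble.
    """
    y_train = np.asarray(y_train).astype(int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("ensemble needs both classes in the training labels")
    gdi_model = LogisticRegression(random_state=seed)
    gdi_model.fit(np.asarray(gdi_train, dtype=float).reshape(-1, 1), y_train)
    gdi_prob_train = gdi_model.predict_proba(
        np.asarray(gdi_train, dtype=float).reshape(-1, 1))[:, 1]
    stack = LogisticRegression(random_state=seed)
    stack.fit(np.column_stack([cnn_prob_train, gdi_prob_train]), y_train)
    gdi_prob_test = gdi_model.predict_proba(
        np.asarray(gdi_test, dtype=float).reshape(-1, 1))[:, 1]
    ens_prob_test = stack.predict_proba(
        np.column_stack([cnn_prob_test, gdi_prob_test]))[:, 1]
    return {
        "gdi_model": gdi_model,
        "stack_model": stack,
        "gdi_prob_test": gdi_prob_test,
        "ensemble_prob_test": ens_prob_test,
    }


def regression_report(truth: np.ndarray, pred: np.ndarray, target: str = "",
                      n_boot: int = N_BOOT, seed: int = 0) -> EvalReport:
    """Standard regression summary: r with bootstrap CI, MAE, bias t-test."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    r, r_ci = pearson_with_bootstrap(truth, pred, n_boot=n_boot, seed=seed)
    bias, bias_ci, p = bias_test(truth, pred)
    return EvalReport(
        target=target, n=truth.size, r=r, r_ci=r_ci,
        mae=float(np.mean(np.abs(truth - pred))),
        bias_mean=bias, bias_ci=bias_ci, bias_p=p, n_boot=n_boot,
    )
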