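"""Evaluation statistics against worked numbers and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from videogait.evaluate import (
    asymmetry_and_longitudinal,
    bias_test,
    confusion_and_accuracy,
    ensemble_with_gdi,
    pearson_with_bootstrap,
    residual_covariate_fit,
    roc_auc,
    variance_decomposition,
    weighted_kappa,
)

# GMFCS confusion matrix of the study's held-out set (rows = predicted I-IV)
GMFCS_CONFUSION = np.array([
    [50, 21, 0, 0],
    [26, 47, 1, 0],
    [0, 8, 22, 4],
    [0, 0, 1, 0],
])


def _kappa_bruteforce(x):
    """Direct double-sum evaluation of the weighted-kappa definition."""
    x = np.asarray(x, dtype=float)
    k = x.shape[0]
    n = x.sum()
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (i - j) ** 2
            m = x[i].sum() * x[:, j].sum() / n
            num += w * x[i, j]
            den += w * m
    return 1.0 - num / den


def test_gmfcs_confusion_matrix_worked_numbers():
    assert weighted_kappa(GMFCS_CONFUSION) == pytest.approx(0.71, abs=0.005)
    mat_truth = np.repeat(np.arange(4), GMFCS_CONFUSION.sum(axis=0))
    # rebuild label vectors from the matrix and re-derive it
    truths, preds = [], []
    for i in range(4):
        for j in range(4):
            truths += [j] * GMFCS_CONFUSION[i, j]
            preds += [i] * GMFCS_CONFUSION[i, j]
    mat, acc, max_err = confusion_and_accuracy(truths, preds, levels=[0, 1, 2, 3])
    assert np.array_equal(mat, GMFCS_CONFUSION)
    assert acc == pytest.approx(119 / 180)
    assert round(100 * acc) == 66
    assert max_err == 1
    assert mat_truth.size == 180


def test_weighted_kappa_bounds_and_degenerate_cases():
    assert weighted_kappa(np.diag([5, 3, 2])) == pytest.approx(1.0)
    # observed equal to independence expectation -> kappa 0
    r, c = np.array([4.0, 6.0]), np.array([3.0, 7.0])
    assert weighted_kappa(np.outer(r, c) / 10.0) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        weighted_kappa(np.array([[5.0]]))


def test_weighted_kappa_equals_bruteforce_and_sklearn():
    rng = np.random.default_rng(0)
    for _ in range(200):
        k = rng.integers(2, 7)
        mat = rng.integers(0, 20, (k, k)).astype(float)
        if mat.sum() == 0 or np.sum(((np.indices((k, k))[0] - np.indices((k, k))[1]) ** 2)
                                    * np.outer(mat.sum(1), mat.sum(0))) == 0:
            continue
        assert weighted_kappa(mat) == pytest.approx(_kappa_bruteforce(mat), abs=1e-12)
    # cross-check against sklearn on label vectors
    a = rng.integers(0, 4, 300)
    b = np.clip(a + rng.integers(-1, 2, 300), 0, 3)
    mat, _, _ = confusion_and_accuracy(a, b, levels=[0, 1, 2, 3])
    assert weighted_kappa(mat) == pytest.approx(
        cohen_kappa_score(a, b, weights="quadratic"), abs=1e-12)


def _auc_pairwise(truth, scores):
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def test_roc_auc_matches_pairwise_oracle_with_ties():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = rng.integers(10, 200)
        truth = rng.integers(0, 2, n)
        if truth.sum() in (0, n):
            continue
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        auc, roc = roc_auc(truth, scores)
        assert auc == pytest.approx(_auc_pairwise(truth, scores), abs=1e-12)
        assert roc[0].tolist() == [0.0, 0.0] or roc[0, 0] == 0.0


def test_roc_auc_symmetry_and_extremes():
    truth = np.array([0, 0, 1, 1, 1])
    scores = np.array([0.1, 0.2, 0.7, 0.8, 0.9])
    auc, _ = roc_auc(truth, scores)
    assert auc == 1.0
    a_neg, _ = roc_auc(truth, -scores)
    assert auc + a_neg == pytest.approx(1.0)
    with pytest.raises(ValueError):
        roc_auc(np.ones(4), scores[:4])


def test_pearson_bootstrap_point_estimates_and_determinism():
    x = np.linspace(0, 1, 30)
    r, ci = pearson_with_bootstrap(x, x, seed=0)
    assert r == pytest.approx(1.0)
    assert ci == (pytest.approx(1.0), pytest.approx(1.0))
    r_neg, _ = pearson_with_bootstrap(x, -x, seed=0)
    assert r_neg == pytest.approx(-1.0)
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=(2, 50))
    assert pearson_with_bootstrap(a, b, seed=3) == pearson_with_bootstrap(a, b, seed=3)
    r, ci = pearson_with_bootstrap(a, b, seed=3)
    assert ci[0] <= r <= ci[1]
    with pytest.raises(ValueError):
        pearson_with_bootstrap(np.ones(10), rng.normal(size=10))


def test_pearson_bootstrap_covers_known_correlation():
    rng = np.random.default_rng(7)
    n, rho = 500, 0.7
    cov = np.array([[1, rho], [rho, 1]])
    x, y = rng.multivariate_normal([0, 0], cov, size=n).T
    r, ci = pearson_with_bootstrap(x, y, seed=1)
    assert r == pytest.approx(rho, abs=0.1)
    assert ci[0] < rho < ci[1]


def test_bias_test_reference_cases_and_power():
    mean, ci, p = bias_test(np.array([1.0, 2.0]), np.array([2.0, 1.0]))
    assert mean == 0.0
    mean, ci, p = bias_test(np.arange(5.0), np.arange(5.0))
    assert mean == 0.0 and p == 1.0
    rng = np.random.default_rng(0)
    truth = rng.normal(0.5, 1.0, 1000)  # residual mean 0.5
    mean, ci, p = bias_test(truth, np.zeros(1000))
    assert p < 0.05
    assert ci[0] < mean < ci[1]


def test_variance_decomposition_additivity_and_anchors():
    rng = np.random.default_rng(0)
    for _ in range(100):
        rows = []
        for p in range(rng.integers(2, 6)):
            for v in range(rng.integers(1, 4)):
                for t in range(rng.integers(1, 4)):
                    rows.append({"patient": p, "visit": v, "trial": t,
                                 "truth": rng.normal(), "pred": rng.normal()})
        df = pd.DataFrame(rows)
        d = variance_decomposition(df)
        assert d.ss == pytest.approx(d.ss_patient + d.ss_visit + d.ss_trial, abs=1e-10)
        assert min(d.ss_patient, d.ss_visit, d.ss_trial) >= -1e-12

    df = pd.DataFrame({"patient": [0, 0, 1, 1], "visit": [0, 1, 0, 1],
                       "trial": [0, 0, 0, 0],
                       "truth": [1.0, 2.0, 3.0, 4.0], "pred": [0.5, 2.5, 2.0, 5.0]})
    d = variance_decomposition(df)
    assert d.ss_trial == pytest.approx(0.0, abs=1e-12)  # one trial per visit
    null = df.assign(pred=df["truth"].mean())
    assert variance_decomposition(null).unexplained_variance == pytest.approx(1.0)


def test_residual_covariate_fit_selects_the_generating_model():
    rng = np.random.default_rng(1)
    x = rng.uniform(-2, 2, 200)
    quad = residual_covariate_fit(1.5 * x ** 2 - x + rng.normal(0, 0.05, 200), x)
    assert quad["model"] == "quadratic"
    assert quad["f_pvalue"] < 1e-10
    lin = residual_covariate_fit(2.0 * x + rng.normal(0, 0.05, 200), x)
    assert lin["model"] == "linear"
    assert lin["f_pvalue"] < 1e-10


def test_asymmetry_and_longitudinal_arithmetic():
    limbs = pd.DataFrame({
        "video_id": ["a", "a", "b", "b", "c"],
        "side": ["left", "right", "left", "right", "left"],
        "pred": [60.0, 60.0, 70.0, 65.0, 50.0],
        "truth": [58.0, 59.0, 71.0, 66.0, 49.0],
    })
    visits = pd.DataFrame({
        "patient": ["p", "p", "q"], "visit": [0, 1, 0],
        "pred": [55.0, 60.0, 80.0], "truth": [50.0, 58.0, 81.0],
    })
    out = asymmetry_and_longitudinal(per_limb=limbs, per_visit=visits)
    asym = out["asymmetry"]
    assert asym.loc["a", "pred"] == 0.0          # symmetric prediction
    assert asym.loc["b", "pred"] == 5.0
    assert out["asymmetry_skipped"] == ["c"]     # unmatched limb skipped
    lon = out["longitudinal"]
    assert lon.loc[0, "pred_change_known_baseline"] == 10.0  # 60 - true 50
    assert lon.loc[0, "pred_change_no_baseline"] == 5.0
    assert "q" not in lon["patient"].tolist()    # single visit: no change


def test_gdi_ensemble_stacking_sanity():
    rng = np.random.default_rng(0)
    n = 400
    y = rng.integers(0, 2, n)
    perfect = y + 0.05 * rng.normal(size=n)      # near-perfect member
    random_member = rng.random(n)
    gdi = 80 - 20 * y + rng.normal(0, 5, n)      # informative GDI
    half = n // 2
    out = ensemble_with_gdi(perfect[:half], gdi[:half], y[:half],
                            perfect[half:], gdi[half:])
    auc_perfect, _ = roc_auc(y[half:], perfect[half:])
    auc_ens, _ = roc_auc(y[half:], out["ensemble_prob_test"])
    assert auc_ens >= auc_perfect - 0.05
    # identical members preserve the ranking, so the AUC is unchanged
    out2 = ensemble_with_gdi(random_member[:half], gdi[:half], y[:half],
                             random_member[half:], gdi[half:])
    assert len(out2["ensemble_prob_test"]) == n - half
    with pytest.raises(ValueError):
        ensemble_with_gdi(perfect[:4], gdi[:4], np.zeros(4), perfect[:2], gdi[:2])
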