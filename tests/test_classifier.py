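"""Weak-label clone classifier: fitting, calibration, calling, metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import splicemut as sm
from splicemut.classifier import (CalibrationError, SingleClassError,
                                  calibrate_threshold)
from splicemut.splicing import UsageMatrix


def _usage_matrix(usage, covered_events=None):
    usage = np.asarray(usage, dtype=float)
    n, m = usage.shape
    if covered_events is None:
        covered_events = np.full(n, m)
    return UsageMatrix(
        usage=usage, covered=np.ones_like(usage, dtype=bool),
        covered_events=np.asarray(covered_events),
        cell_ids=pd.Index([f"c{i}" for i in range(n)]),
        event_ids=pd.Index([f"e{j}" for j in range(m)]),
    )


def _weak_labels(res):
    return res.expression.obs["donor"].map(res.donors["sf3b1_status"]).to_numpy()


# -- threshold calibration ------------------------------------------------

def test_threshold_bounds_calibration_false_positives():
    scores = np.arange(0.01, 0.11, 0.01)  # 10 cells
    tau = calibrate_threshold(np.tile(scores, 2), alpha=0.10)
    assert (np.tile(scores, 2) > tau).mean() <= 0.10


def test_threshold_at_half_is_upper_median():
    scores = np.arange(20) / 20.0
    tau = calibrate_threshold(scores, alpha=0.5)
    assert tau == np.quantile(scores, 0.5, method="higher")


def test_threshold_matches_analytic_beta_quantile():
    """Empirical (1-alpha) quantile of Beta-distributed scores agrees with
    the closed-form quantile within 2 SEs of the order statistic."""
    rng = np.random.default_rng(0)
    a, b, alpha, n = 2.0, 5.0, 0.10, 10_000
    scores = rng.beta(a, b, size=n)
    tau = calibrate_threshold(scores, alpha=alpha)
    q = 1 - alpha
    expected = stats.beta.ppf(q, a, b)
    dens = stats.beta.pdf(expected, a, b)
    se = np.sqrt(q * (1 - q) / n) / dens
    assert abs(tau - expected) < 2 * se


def test_too_few_calibration_cells_raises():
    with pytest.raises(CalibrationError):
        calibrate_threshold(np.linspace(0, 1, 19), alpha=0.1)


# -- fitting behaviour ----------------------------------------------------

def test_constant_features_give_prior_scores():
    """With no signal in the features the penalized fit collapses to the
    intercept: every cell scores the training class prior."""
    rng = np.random.default_rng(1)
    n = 200
    X = np.full((n, 5), 0.3)
    y = (rng.random(n) < 0.4).astype(int)
    clf = sm.CloneClassifier(cv=2, random_state=0).fit(X, y)
    assert np.abs(clf.coef_).max() < 1e-4
    # scores on fresh rows of the same constant matrix equal the prior
    fresh = np.full((4, 5), 0.3) + 0.0
    fresh[0, 0] += 1e-12  # defeat the training-matrix fingerprint
    scores = clf.predict_proba(np.full((4, 5), 0.31))
    assert np.allclose(scores, y.mean(), atol=1e-3)


def test_label_flip_mirrors_scores():
    rng = np.random.default_rng(2)
    X = rng.random((150, 6))
    y = (rng.random(150) < 0.5).astype(int)
    new = rng.random((10, 6))
    s1 = sm.CloneClassifier(random_state=0).fit(X, y).predict_proba(new)
    s2 = sm.CloneClassifier(random_state=0).fit(X, 1 - y).predict_proba(new)
    np.testing.assert_allclose(s1, 1 - s2, atol=1e-5)


def test_single_class_labels_rejected():
    X = np.random.default_rng(0).random((50, 4))
    with pytest.raises(SingleClassError):
        sm.CloneClassifier().fit(X, np.zeros(50, dtype=int))


def test_missing_values_rejected():
    X = np.full((30, 3), np.nan)
    with pytest.raises(ValueError, match="missing"):
        sm.CloneClassifier().fit(X, np.r_[np.zeros(15), np.ones(15)])


def test_fit_accepts_string_labels(small_cohort, small_usage):
    _, res = small_cohort
    _, imputed = small_usage
    clf = sm.CloneClassifier(random_state=0).fit(imputed.usage, _weak_labels(res))
    assert clf.threshold_ > 0


# -- prediction and calls -------------------------------------------------

def test_low_coverage_cells_are_unclassified(fitted_classifier, small_usage):
    _, imputed = small_usage
    clf = fitted_classifier
    covered = imputed.covered_events.copy()
    covered[:5] = 1
    calls = clf.predict(imputed.usage, covered_events=covered)
    assert (calls[:5] == "unclassified").all()
    assert set(calls[5:]) <= {"MUT", "WT"}


def test_score_equal_to_threshold_is_wild_type(fitted_classifier):
    clf = fitted_classifier
    n = clf.n_features_in_
    # solve for a feature vector whose score is exactly tau via the link
    logit_tau = np.log(clf.threshold_ / (1 - clf.threshold_))
    x = np.zeros(n)
    j = int(np.argmax(np.abs(clf.coef_)))
    x[j] = (logit_tau - clf.intercept_) / clf.coef_[j]
    score = clf.predict_proba(x[None, :])[0]
    assert score == pytest.approx(clf.threshold_, abs=1e-12)
    assert clf.predict(x[None, :])[0] == "WT"


def test_feature_mismatch_raises(fitted_classifier):
    with pytest.raises(ValueError, match="feature mismatch"):
        fitted_classifier.predict_proba(np.zeros((3, 2)))


def test_calls_cover_every_cell_once(fitted_classifier, small_usage):
    _, imputed = small_usage
    calls = fitted_classifier.calls(imputed)
    assert len(calls) == imputed.shape[0]
    assert calls["cell_id"].is_unique
    assert ((calls["call"] == "unclassified")
            == (calls["covered_events"] < 2)).all()


def test_separated_simulation_recovers_genotype(small_cohort, small_usage,
                                                fitted_classifier):
    """psi 0.02 vs 0.35 at clone fraction 0.6 is near-perfectly separable."""
    _, res = small_cohort
    _, imputed = small_usage
    calls = fitted_classifier.calls(imputed)
    metrics = sm.evaluate_calls(calls, res.truth.cell_genotype)
    assert metrics["auc"] >= 0.95


def test_auc_nondecreasing_in_psi_separation():
    """Widening psi1 - psi0 never lowers mean AUC (10 replicates/point)."""
    mean_auc = []
    for psi1 in (0.08, 0.35):
        aucs = []
        for seed in range(10):
            cfg = sm.SimConfig(n_genes=40, n_de_genes=0, n_signature_genes=5,
                               cells_per_donor=120, psi1=psi1, seed=100 + seed)
            res = sm.simulate_cohort(cfg)
            imputed = sm.impute_mean(sm.compute_usage(res.junctions))
            clf = sm.CloneClassifier(random_state=seed).fit(
                imputed.usage, _weak_labels(res))
            calls = clf.calls(imputed)
            aucs.append(sm.evaluate_calls(calls, res.truth.cell_genotype)["auc"])
        mean_auc.append(np.mean(aucs))
    assert mean_auc[1] >= mean_auc[0]


def test_heldout_fpr_within_binomial_tolerance(small_cohort, small_usage,
                                               fitted_classifier):
    """Held-out wild-type-donor cells are called mutant at a rate bounded
    by the calibration target plus 3 binomial SEs."""
    _, res = small_cohort
    _, imputed = small_usage
    clf = fitted_classifier
    scores = clf.predict_proba(imputed.usage)
    held = clf.holdout_cells_
    fpr = float((scores[held] > clf.threshold_).mean())
    n = held.size
    assert fpr <= clf.alpha + 3 * np.sqrt(clf.alpha * (1 - clf.alpha) / n)


# -- evaluation oracle ----------------------------------------------------

def test_perfect_calls_score_perfectly():
    truth = pd.Series(["MUT", "WT", "MUT", "WT"], index=list("abcd"))
    calls = pd.DataFrame({
        "cell_id": list("abcd"),
        "score": [0.9, 0.1, 0.8, 0.2],
        "call": ["MUT", "WT", "MUT", "WT"],
        "covered_events": [5] * 4,
    })
    m = sm.evaluate_calls(calls, truth)
    assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0 and m["auc"] == 1.0


def test_all_wt_calls_have_zero_sensitivity_and_fpr():
    truth = pd.Series(["MUT", "WT", "MUT"], index=list("abc"))
    calls = pd.DataFrame({
        "cell_id": list("abc"), "score": [0.4, 0.3, 0.2],
        "call": ["WT"] * 3, "covered_events": [5] * 3,
    })
    m = sm.evaluate_calls(calls, truth)
    assert m["sensitivity"] == 0.0 and m["fpr"] == 0.0


def test_metrics_equal_hand_rolled_confusion_table():
    rng = np.random.default_rng(5)
    n = 200
    truth = pd.Series(np.where(rng.random(n) < 0.4, "MUT", "WT"),
                      index=[f"c{i}" for i in range(n)])
    calls = pd.DataFrame({
        "cell_id": truth.index,
        "score": rng.random(n),
        "call": np.where(rng.random(n) < 0.3, "MUT",
                         np.where(rng.random(n) < 0.1, "unclassified", "WT")),
        "covered_events": rng.integers(2, 9, n),
    })
    m = sm.evaluate_calls(calls, truth)
    tp = fp = fn = tn = 0
    for _, row in calls.iterrows():
        if row["call"] == "unclassified":
            continue
        t = truth[row["cell_id"]]
        if row["call"] == "MUT" and t == "MUT":
            tp += 1
        elif row["call"] == "MUT" and t == "WT":
            fp += 1
        elif row["call"] == "WT" and t == "MUT":
            fn += 1
        else:
            tn += 1
    assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (tp, fp, fn, tn)
    assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
    assert m["fpr"] == pytest.approx(fp / (fp + tn))


def test_truth_mismatch_raises(fitted_classifier, small_usage):
    _, imputed = small_usage
    calls = fitted_classifier.calls(imputed)
    with pytest.raises(KeyError):
        sm.evaluate_calls(calls, pd.Series(["WT"], index=["nope"]))


def test_model_json_round_trip(fitted_classifier, tmp_path):
    import json
    path = tmp_path / "model.json"
    fitted_classifier.save(path, event_ids=[f"e{i}" for i in range(
        fitted_classifier.n_features_in_)])
    blob = json.loads(path.read_text())
    assert blob["alpha"] == fitted_classifier.alpha
    assert len(blob["weights"]) == fitted_classifier.n_features_in_
    assert blob["threshold"] == fitted_classifier.threshold_
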