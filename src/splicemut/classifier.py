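"""Weak-label clone classifier with false-positive-rate calibration.

Per-cell genotypes are not observed; each cell inherits the mutation
status of its donor as a weak training label. Cells of wild-type donors
are all truly wild type, so labels are clean for that class, while cells
of mutant donors are a mixture of mutant and wild-type cells (the clone
fraction). An L2-penalized logistic regression on the per-event
cryptic-usage features is fitted against these weak labels; the decision
threshold is then calibrated on cells of wild-type-labeled donors so that
the fraction of truly wild-type cells called mutant stays at a target
false-positive rate (default 10%).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .splicing import UsageMatrix

MIN_CALIBRATION_CELLS = 20

MUT, WT, UNCLASSIFIED = "MUT", "WT", "unclassified"


def _fingerprint(X: np.ndarray) -> str:
    import hashlib
    return hashlib.sha1(np.ascontiguousarray(X).tobytes()).hexdigest()


class SingleClassError(ValueError):
    """Training labels contain only one donor mutation status."""


class CalibrationError(ValueError):
    """Too few wild-type-donor cells to calibrate the threshold."""


def calibrate_threshold(wt_scores: np.ndarray, alpha: float = 0.10) -> float:
    """Score threshold holding the false-positive rate at ``alpha``.

    Returns the (1 - alpha) empirical quantile of the calibration scores
    with ties resolved upward, so that at most a fraction ``alpha`` of
    calibration cells scores strictly above the threshold.
    """
    wt_scores = np.asarray(wt_scores, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if wt_scores.size < MIN_CALIBRATION_CELLS:
        raise CalibrationError(
            f"need >= {MIN_CALIBRATION_CELLS} wild-type-donor cells to "
            f"calibrate, got {wt_scores.size}")
    return float(np.quantile(wt_scores, 1.0 - alpha, method="higher"))


class CloneClassifier(BaseEstimator):
    """Weakly supervised mutant-clone caller on cryptic-usage features.

    Parameters
    ----------
    alpha : float
        Target false-positive rate for threshold calibration.
    l2 : float
        L2 penalty strength (lambda); passed to the solver as C = 1/lambda.
    min_events : int
        Minimum covered mis-splicing events for a cell to be classifiable;
        cells below it are scored but always reported unclassified.
    calibration_size : float
        Fraction of wild-type-donor cells reserved for threshold
        calibration (the rest of that split is available as a held-out
        false-positive-rate check).
    holdout_calibration : bool
        When True, calibration cells are excluded from fitting; default
        False fits on all cells, which keeps the calibration and held-out
        halves exchangeable.
    standardize : bool
        Z-score the usage features before fitting.

    Attributes
    ----------
    coef_ : ndarray of shape (n_events,)
        Per-event weights.
    intercept_ : float
    threshold_ : float
        Calibrated decision threshold tau; a cell is called mutant iff its
        score is strictly above tau.
    calibration_cells_, holdout_cells_ : ndarray
        Integer row indices of the calibration and held-out wild-type
        splits.
    converged_ : bool
    """

    def __init__(self, alpha: float = 0.10, l2: float = 1.0,
                 min_events: int = 2, calibration_size: float = 0.5,
                 holdout_calibration: bool = False, standardize: bool = False,
                 cv: int = 5, max_iter: int = 2000, tol: float = 1e-8,
                 random_state: int = 0):
        self.alpha = alpha
        self.l2 = l2
        self.min_events = min_events
        self.calibration_size = calibration_size
        self.holdout_calibration = holdout_calibration
        self.standardize = standardize
        self.cv = cv
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        """Fit on imputed usage features ``X`` and weak labels ``y``.

        ``y`` holds the donor mutation status propagated to each cell
        (1/"MUT" for cells of mutant donors, 0/"WT" otherwise).
        """
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("usage features contain missing values; impute first")
        raw_fingerprint = _fingerprint(X)
        y = self._binarize(y)
        if len(np.unique(y)) < 2:
            raise SingleClassError(
                "both donor mutation statuses must be present to fit")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")

        if self.standardize:
            self._mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self._sd_ = np.where(sd > 0, sd, 1.0)
            X = (X - self._mean_) / self._sd_

        rng = np.random.default_rng(self.random_state)
        wt_idx = np.flatnonzero(y == 0)
        perm = rng.permutation(wt_idx.size)
        n_cal = int(round(self.calibration_size * wt_idx.size))
        self.calibration_cells_ = np.sort(wt_idx[perm[:n_cal]])
        self.holdout_cells_ = np.sort(wt_idx[perm[n_cal:]])

        if self.holdout_calibration:
            train = np.setdiff1d(np.arange(X.shape[0]), self.calibration_cells_)
        else:
            train = np.arange(X.shape[0])
        if len(np.unique(y[train])) < 2:
            raise SingleClassError("training split lost a label class")

        lr, converged = self._fit_logistic(X[train], y[train])
        self.converged_ = converged
        if not self.converged_:
            warnings.warn("logistic solver did not converge; results flagged",
                          ConvergenceWarning, stacklevel=2)
        self._lr_ = lr
        self.coef_ = lr.coef_.ravel().copy()
        self.intercept_ = float(lr.intercept_[0])
        self.n_features_in_ = X.shape[1]
        self.n_iter_ = int(lr.n_iter_[0])

        # cross-fitted (out-of-fold) scores for every cell seen in fitting:
        # in-sample logistic scores are biased toward the weak labels, so
        # thresholds calibrated on them would not transfer; out-of-fold
        # scores keep all cells exchangeable with the calibration set.
        oof = np.full(X.shape[0], np.nan)
        n_splits = min(self.cv, int(np.bincount(y[train]).min()))
        if n_splits >= 2:
            splitter = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                       random_state=self.random_state)
            for tr, te in splitter.split(X[train], y[train]):
                fold_lr, _ = self._fit_logistic(X[train][tr], y[train][tr])
                oof[train[te]] = fold_lr.predict_proba(X[train][te])[:, 1]
        else:
            oof[train] = lr.predict_proba(X[train])[:, 1]
        outside = np.setdiff1d(np.arange(X.shape[0]), train)
        if outside.size:
            oof[outside] = lr.predict_proba(X[outside])[:, 1]
        self.oof_scores_ = oof
        self._train_fingerprint_ = raw_fingerprint

        cal_scores = oof[self.calibration_cells_]
        self.threshold_ = calibrate_threshold(cal_scores, self.alpha)
        return self

    def _fit_logistic(self, X, y):
        C = np.inf if self.l2 == 0 else 1.0 / self.l2
        lr = LogisticRegression(penalty="l2" if np.isfinite(C) else None,
                                C=C if np.isfinite(C) else 1.0,
                                solver="lbfgs", tol=self.tol,
                                max_iter=self.max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            lr.fit(X, y)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught)
        return lr, converged

    @staticmethod
    def _binarize(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            out = np.where(pd.Index(y).astype(str).str.upper() == MUT, 1, 0)
            return out.astype(int)
        return y.astype(int)

    def _raw_scores(self, X: np.ndarray) -> np.ndarray:
        return self._lr_.predict_proba(X)[:, 1]

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Mutant-clone membership score per cell (logistic link).

        When ``X`` is exactly the matrix the model was fitted on, the
        stored cross-fitted scores are returned so that no cell is scored
        by a model that saw it; new matrices are scored with the full
        model.
        """
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: model has {self.n_features_in_} events, "
                f"matrix has {X.shape[1]}")
        if _fingerprint(X) == self._train_fingerprint_:
            return self.oof_scores_.copy()
        if self.standardize:
            X = (X - self._mean_) / self._sd_
        return self._raw_scores(X)

    def predict(self, X, covered_events=None) -> np.ndarray:
        """Genotype call per cell: MUT iff score > tau, else WT;
        unclassified when fewer than ``min_events`` events are covered."""
        scores = self.predict_proba(X)
        calls = np.where(scores > self.threshold_, MUT, WT).astype(object)
        if covered_events is not None:
            covered_events = np.asarray(covered_events)
            calls[covered_events < self.min_events] = UNCLASSIFIED
        return calls

    def calls(self, um: UsageMatrix) -> pd.DataFrame:
        """Per-cell genotype-call table from a complete usage matrix."""
        scores = self.predict_proba(um.usage)
        call = self.predict(um.usage, um.covered_events)
        return pd.DataFrame({
            "cell_id": np.asarray(um.cell_ids),
            "score": scores,
            "call": call,
            "covered_events": um.covered_events,
        })

    # -- persistence -------------------------------------------------------

    def to_json(self, event_ids=None) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps({
            "weights": self.coef_.tolist(),
            "intercept": self.intercept_,
            "threshold": self.threshold_,
            "alpha": self.alpha,
            "l2": self.l2,
            "min_events": self.min_events,
            "standardize": self.standardize,
            "event_ids": list(event_ids) if event_ids is not None else None,
            "random_state": self.random_state,
            "n_iter": self.n_iter_,
            "converged": self.converged_,
        }, indent=2)

    def save(self, path: str | Path, event_ids=None) -> None:
        Path(path).write_text(self.to_json(event_ids))


def evaluate_calls(calls: pd.DataFrame, truth: pd.Series) -> dict:
    """Confusion-derived metrics of genotype calls against simulated truth.

    Unclassified cells are counted separately and excluded from the rates;
    AUC uses the continuous scores of classified cells.
    """
    calls = calls.set_index("cell_id") if "cell_id" in calls.columns else calls
    missing = calls.index.difference(truth.index)
    if len(missing):
        raise KeyError(f"{len(missing)} called cells missing from truth")
    t = truth.reindex(calls.index)
    classified = calls["call"] != UNCLASSIFIED
    sub, tsub = calls[classified], t[classified]
    tp = int(((sub["call"] == MUT) & (tsub == MUT)).sum())
    fp = int(((sub["call"] == MUT) & (tsub == WT)).sum())
    fn = int(((sub["call"] == WT) & (tsub == MUT)).sum())
    tn = int(((sub["call"] == WT) & (tsub == WT)).sum())
    metrics = {
        "n_classified": int(classified.sum()),
        "n_unclassified": int((~classified).sum()),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "fpr": fp / (fp + tn) if fp + tn else np.nan,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
    }
    if tsub.nunique() == 2:
        metrics["auc"] = float(roc_auc_score((tsub == MUT).astype(int),
                                             sub["score"]))
    else:
        metrics["auc"] = np.nan
    return metrics
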