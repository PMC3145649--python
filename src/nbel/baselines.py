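"""Comparison classifiers: naive Bayes LR multiplication and logistic regression.

Naive Bayes integrates multi-source evidence by multiplying the per-source
likelihood ratios into a final score and multiplying in a prior odds ratio;
a pair is called interacting when the posterior odds exceed 1.  The
"alternative threshold" is a data-driven cut separating the two modes of a
bimodal score histogram, used when no calibrated odds scale is available.
Logistic regression fits additive log-odds weights on log-LR features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "NaiveBayesResult",
    "naive_bayes_predict",
    "alternative_threshold",
    "logistic_fit_predict",
]


@dataclass
class NaiveBayesResult:
    score: np.ndarray           # products of LRs, one per pair
    posterior_odds: np.ndarray  # prior odds x score
    predicted: np.ndarray       # 1 iff posterior odds strictly > 1
    log_score: np.ndarray       # sum of log LRs (underflow-safe scale)


def naive_bayes_predict(lrs: np.ndarray, prior_odds: float) -> NaiveBayesResult:
    """Multiply per-source likelihood ratios and apply the posterior-odds rule.

    Products are accumulated in log space; a pair is predicted interacting
    iff prior_odds * prod_j LR_ij > 1 strictly.
    """
    lrs = np.asarray(lrs, dtype=float)
    if lrs.ndim != 2:
        raise ValueError("lrs must be an n x p matrix")
    if prior_odds <= 0:
        raise ValueError("prior odds must be positive")
    if np.any(lrs <= 0) or not np.all(np.isfinite(lrs)):
        bad = np.argwhere(~((lrs > 0) & np.isfinite(lrs)))[0]
        raise ValueError(f"likelihood ratios must be positive and finite; row {bad[0]}, column {bad[1]}")
    log_score = np.log(lrs).sum(axis=1)
    log_odds = np.log(prior_odds) + log_score
    return NaiveBayesResult(
        score=np.exp(log_score),
        posterior_odds=np.exp(log_odds),
        predicted=(log_odds > 0).astype(np.int64),
        log_score=log_score,
    )


def alternative_threshold(values: np.ndarray) -> float:
    """Cut that best separates the two modes of a 1-D score histogram.

    Implemented as the two-class within-group-variance minimiser over all
    midpoints between consecutive distinct sorted values (an Otsu-style
    criterion on the raw values, without binning).  Applied to log final
    scores for naive Bayes and to posterior probabilities for the mixture
    classifier.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 values to estimate a separating threshold")
    if x[-1] - x[0] < 1e-12:
        raise ValueError("all values identical; no bimodal structure to split")
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    k = np.arange(1, n)  # left group sizes
    left_ss = csq[:-1] - csum[:-1] ** 2 / k
    right_sum = csum[-1] - csum[:-1]
    right_ss = (csq[-1] - csq[:-1]) - right_sum**2 / (n - k)
    within = left_ss + right_ss
    valid = np.flatnonzero(np.diff(x) > 0)
    best = valid[np.argmin(within[valid])]
    return float(0.5 * (x[best] + x[best + 1]))


def logistic_fit_predict(
    lrs: np.ndarray,
    train_labels: np.ndarray,
    mode: str = "cv",
    log_features: bool = True,
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Fit an additive log-odds model on (log-)LR features; return probabilities.

    ``train_labels`` may contain NaN for unlabeled rows.  In ``cv`` mode the
    labeled rows receive out-of-fold predictions from a stratified K-fold
    split (so the reported error is not in-sample); unlabeled rows are
    predicted from a model fit on all labeled rows.  In ``train-test`` mode
    a single model fit on the labeled rows predicts everything.  A small
    ridge penalty (1e-6) keeps the fit defined under perfect separation.
    """
    lrs = np.asarray(lrs, dtype=float)
    labels = np.asarray(train_labels, dtype=float)
    if lrs.ndim != 2 or labels.shape != (lrs.shape[0],):
        raise ValueError("lrs must be n x p with one (possibly NaN) label per row")
    if mode not in ("cv", "train-test"):
        raise ValueError(f"unknown mode {mode!r}")
    X = np.log(lrs) if log_features else lrs
    labeled = np.flatnonzero(np.isfinite(labels))
    if labeled.size == 0:
        raise ValueError("no labeled rows to train on")
    yl = labels[labeled].astype(int)
    if np.unique(yl).size < 2:
        raise ValueError("training labels contain a single class")

    def make_model() -> LogisticRegression:
        return LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)

    prob = np.empty(lrs.shape[0])
    full = make_model().fit(X[labeled], yl)
    unlabeled = np.setdiff1d(np.arange(lrs.shape[0]), labeled)
    if unlabeled.size:
        prob[unlabeled] = full.predict_proba(X[unlabeled])[:, 1]

    if mode == "train-test":
        prob[labeled] = full.predict_proba(X[labeled])[:, 1]
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(X[labeled], yl):
            m = make_model().fit(X[labeled][tr], yl[tr])
            prob[labeled[te]] = m.predict_proba(X[labeled][te])[:, 1]
    return prob
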