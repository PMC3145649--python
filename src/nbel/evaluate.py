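"""Evaluation arithmetic: misclassification, ROC curves, replicate summaries,
and the overlap-validation percentages used against curated interaction
databases.

The misclassification rate throughout is the arithmetic mean of the
false-positive rate (fraction of truly non-interacting pairs called
interacting) and the false-negative rate, weighting the two error types
equally regardless of class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "EvalReport",
    "misclassification",
    "roc_curve",
    "roc_auc",
    "overlap_validation",
    "replicate_summary",
]


@dataclass
class EvalReport:
    fp_rate: float
    fn_rate: float
    misclassification: float
    roc: list = field(default_factory=list)
    n_replicates: int = 1
    sd_fp: float = 0.0
    sd_fn: float = 0.0

    def to_dict(self) -> dict:
        return {
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
            "misclassification": self.misclassification,
            "roc": [list(pt) for pt in self.roc],
            "n_replicates": self.n_replicates,
            "sd_fp": self.sd_fp,
            "sd_fn": self.sd_fn,
        }


def _check_binary_truth(truth: np.ndarray) -> np.ndarray:
    truth = np.asarray(truth, dtype=np.int64)
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth labels must be binary")
    if np.unique(truth).size < 2:
        raise ValueError("truth must contain both classes")
    return truth


def misclassification(predicted: np.ndarray, truth: np.ndarray) -> EvalReport:
    """FP rate, FN rate and their mean for one set of binary calls."""
    predicted = np.asarray(predicted, dtype=np.int64)
    truth = _check_binary_truth(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    pos = truth == 1
    fp = float(np.mean(predicted[~pos] == 1))
    fn = float(np.mean(predicted[pos] == 0))
    return EvalReport(fp_rate=fp, fn_rate=fn, misclassification=0.5 * (fp + fn))


def roc_curve(scores: np.ndarray, truth: np.ndarray) -> list:
    """ROC points (fp_rate, tp_rate): one per distinct threshold, plus (0,0)
    and (1,1).  Tied scores collapse to a single threshold step."""
    truth = _check_binary_truth(truth)
    fpr, tpr, _ = _sk_roc_curve(truth, np.asarray(scores, dtype=float), drop_intermediate=False)
    pts = [(float(a), float(b)) for a, b in zip(fpr, tpr)]
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve."""
    pts = np.array(roc_curve(scores, truth))
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def overlap_validation(n_overlap: int, n_predicted: int) -> tuple[float, float]:
    """TP%/FN% against a curated database overlap.

    Of ``n_overlap`` database pairs present in the scored data set,
    ``n_predicted`` were called interacting: TP% = 100*n_predicted/n_overlap
    (two decimals), FN% its complement.
    """
    if n_overlap <= 0:
        raise ValueError("overlap count must be positive")
    if not 0 <= n_predicted <= n_overlap:
        raise ValueError("predicted count must lie in [0, n_overlap]")
    tp = round(100.0 * n_predicted / n_overlap, 2)
    return tp, round(100.0 - tp, 2)


def replicate_summary(reports: list) -> EvalReport:
    """Means and sample standard deviations of FP/FN across replicates."""
    if not reports:
        raise ValueError("no replicate reports to summarise")
    fp = np.array([r.fp_rate for r in reports])
    fn = np.array([r.fn_rate for r in reports])
    sd_fp = float(fp.std(ddof=1)) if fp.size > 1 else 0.0
    sd_fn = float(fn.std(ddof=1)) if fn.size > 1 else 0.0
    return EvalReport(
        fp_rate=float(fp.mean()),
        fn_rate=float(fn.mean()),
        misclassification=float(0.5 * (fp.mean() + fn.mean())),
        n_replicates=len(reports),
        sd_fp=sd_fp,
        sd_fn=sd_fn,
    )
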