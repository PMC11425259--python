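"""Evaluation metrics for the screening models.

Classification: accuracy, specificity, sensitivity, F1 and ROC-AUC from a
thresholded confusion table; AUC is the rank-based (Mann-Whitney)
probability that a random positive outscores a random negative, with ties
counted 1/2 — equivalent to the trapezoidal area under the ROC curve.

Regression (energy barriers, kcal/mol): R², MAE, RMSE, Pearson correlation,
and fold rates.  The per-sample fold error is

    fold_i = 1 + |yhat_i - y_i| / y_i   (>= 1),

and a prediction counts as successful at threshold k when fold_i < k
(strict); the 2-fold and 3-fold rates are the fractions of successful
predictions.  A barrier above ~15-20 kcal/mol marks the proton transfer as
infeasible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class ConfusionTable:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass
class ClassificationReport:
    ACC: float
    SP: float
    SE: float
    F1: float
    AUC: float
    confusion: ConfusionTable
    auc_defined: bool = True

    def to_json(self) -> str:
        return json.dumps({
            "ACC": self.ACC, "AUC": self.AUC, "F1": self.F1,
            "SP": self.SP, "SE": self.SE,
            "TP": self.confusion.TP, "TN": self.confusion.TN,
            "FP": self.confusion.FP, "FN": self.confusion.FN,
        })


@dataclass
class RegressionReport:
    R2: float
    MAE: float
    RMSE: float
    pearson_correlation: float
    fold_rates: Dict[float, float]
    folds: List[float] = field(default_factory=list, repr=False)

    def to_json(self) -> str:
        out = {"R2": self.R2, "MAE": self.MAE, "RMSE": self.RMSE,
               "Correlation": self.pearson_correlation}
        for k in sorted(self.fold_rates):
            key = f"{int(k)}-fold rate" if float(k).is_integer() else f"{k}-fold rate"
            out[key] = self.fold_rates[k]
        return json.dumps(out)


def rank_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = y_true == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(y_score)  # average ranks on ties
    rank_sum_pos = ranks[pos].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(
    y_true: Sequence[int], y_score: Sequence[float], threshold: float = 0.5
) -> ClassificationReport:
    """Confusion-table metrics plus rank AUC.

    ``y_true`` is binary (1 = positive class); predicted positive iff
    ``y_score >= threshold``.  With a single-class ``y_true`` the AUC is
    undefined (NaN, ``auc_defined=False``); the other metrics are still
    returned, with undefined ratios reported as NaN.
    """
    yt = np.asarray(y_true, dtype=int)
    ys = np.asarray(y_score, dtype=float)
    if yt.shape != ys.shape:
        raise ValueError("y_true and y_score must have equal length")
    if not np.all(np.isin(yt, (0, 1))):
        raise ValueError("y_true must be binary 0/1")

    pred = ys >= threshold
    tp = int(np.sum(pred & (yt == 1)))
    tn = int(np.sum(~pred & (yt == 0)))
    fp = int(np.sum(pred & (yt == 0)))
    fn = int(np.sum(~pred & (yt == 1)))
    conf = ConfusionTable(TP=tp, TN=tn, FP=fp, FN=fn)

    acc = _safe_div(tp + tn, conf.total)
    sp = _safe_div(tn, tn + fp)
    se = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    auc = rank_auc(yt, ys)
    return ClassificationReport(
        ACC=acc, SP=sp, SE=se, F1=f1, AUC=auc, confusion=conf,
        auc_defined=not math.isnan(auc),
    )


def fold_errors(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Per-sample fold error 1 + |yhat - y| / y (requires y > 0)."""
    return 1.0 + np.abs(y_pred - y_true) / y_true


def regression_metrics(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    fold_thresholds: Sequence[float] = (2.0, 3.0),
    ids: Optional[Sequence[str]] = None,
) -> RegressionReport:
    """R², MAE, RMSE, Pearson correlation and fold rates.

    ``y_true`` must be strictly positive (fold errors are undefined
    otherwise); offending sample ids are named in the error.  The rate at
    threshold k is the fraction of samples with fold_i strictly below k.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    bad = np.where(~(yt > 0))[0]
    if bad.size:
        labels = [ids[i] if ids is not None else str(i) for i in bad[:10]]
        raise ValueError(f"y_true must be > 0 for fold errors; offending ids: {labels}")

    resid = yp - yt
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    mae = float(np.mean(np.abs(resid)))
    rmse = float(math.sqrt(np.mean(resid ** 2)))
    if yt.size >= 2 and np.std(yt) > 0 and np.std(yp) > 0:
        corr = float(stats.pearsonr(yt, yp).statistic)
    else:
        corr = float("nan")

    folds = fold_errors(yt, yp)
    rates = {float(k): float(np.mean(folds < k)) for k in fold_thresholds}
    return RegressionReport(
        R2=r2, MAE=mae, RMSE=rmse, pearson_correlation=corr,
        fold_rates=rates, folds=folds.tolist(),
    )


def barrier_feasibility(barrier: float, cutoff: float = 15.0) -> str:
    """Classify an ESIPT energy barrier (kcal/mol) as feasible/infeasible.

    Barriers above ~15-20 kcal/mol indicate the excited-state proton
    transfer cannot occur; the boundary value itself counts as feasible.
    """
    if not math.isfinite(barrier):
        raise ValueError("barrier must be finite")
    if not 15.0 <= cutoff <= 20.0:
        raise ValueError(f"cutoff must lie in [15, 20] kcal/mol, got {cutoff}")
    return "feasible" if barrier <= cutoff else "infeasible"
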