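"""Model training, validation, feature selection and outlier exclusion.

The screening system uses three supervised models: two binary classifiers
(ESIPT vs conventional molecules; ESIPT vs other fluorophores) and one
regressor for the excited-state proton-transfer energy barrier.  Training
follows a 75/25 stratified train/test split with 5-fold cross-validation on
the training partition.  Feature selection is recursive feature elimination
(RFE) under an importance-exposing base estimator; sample curation for the
regressor uses the ECOD unsupervised outlier detector (per-dimension
empirical-CDF tail probabilities).

All fits are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
from scipy import stats
from sklearn import base as skbase
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from esipt_screen.featurize import FeatureMatrix
from esipt_screen.metrics import (
    ClassificationReport,
    RegressionReport,
    classification_metrics,
    regression_metrics,
)

ARTIFACT_VERSION = 1

ALGORITHMS = ("KNN", "DT", "RF", "SVM", "GBT", "MLP")


@dataclass
class ModelConfig:
    """Algorithm + task + hyperparameters + seed.

    Hyperparameters override the package defaults (RF: 500 trees; SVM: RBF
    kernel with cross-validated probability calibration; GBT: 300 rounds of
    depth-6 gradient boosting).  Reproducibility is favoured over tuning:
    with a fixed seed every fit is deterministic.
    """

    algorithm: str = "RF"
    task: str = "classify"
    hyperparameters: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.task not in ("classify", "regress"):
            raise ValueError(f"task must be classify or regress, got {self.task!r}")


def build_estimator(config: ModelConfig):
    """Instantiate the sklearn/xgboost estimator for a config."""
    hp = dict(config.hyperparameters)
    alg, clf = config.algorithm, config.task == "classify"
    if alg == "RF":
        hp.setdefault("n_estimators", 500)
        cls = RandomForestClassifier if clf else RandomForestRegressor
        return cls(random_state=config.seed, **hp)
    if alg == "DT":
        cls = DecisionTreeClassifier if clf else DecisionTreeRegressor
        return cls(random_state=config.seed, **hp)
    if alg == "KNN":
        cls = KNeighborsClassifier if clf else KNeighborsRegressor
        return cls(**hp)
    if alg == "SVM":
        if clf:
            # probability=True enables internal CV-calibrated probabilities,
            # which the cascade thresholds act on.
            hp.setdefault("probability", True)
            return SVC(random_state=config.seed, **hp)
        return SVR(**hp)
    if alg == "GBT":
        from xgboost import XGBClassifier, XGBRegressor

        hp.setdefault("n_estimators", 300)
        hp.setdefault("max_depth", 6)
        cls = XGBClassifier if clf else XGBRegressor
        return cls(random_state=config.seed, **hp)
    if alg == "MLP":
        hp.setdefault("max_iter", 500)
        cls = MLPClassifier if clf else MLPRegressor
        return cls(random_state=config.seed, **hp)
    raise ValueError(f"unsupported algorithm {alg!r}")


@dataclass
class SplitPlan:
    """75/25 train/test split plus k-fold CV folds over the training ids."""

    train_ids: List[str]
    test_ids: List[str]
    cv_folds: List[Tuple[List[str], List[str]]]
    seed: int = 0


def make_split(
    ids: Sequence[str],
    labels: Optional[Sequence] = None,
    test_fraction: float = 0.25,
    k: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Deterministic stratified train/test split + k-fold CV plan.

    With labels, both the test split and the folds are stratified (class
    ratio preserved within +/- 1 sample per fold); a class with fewer than
    ``k`` members cannot be stratified and raises.
    """
    ids = [str(i) for i in ids]
    if len(ids) < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for a {k}-fold plan")
    idx = np.arange(len(ids))
    y = None if labels is None else np.asarray([str(l) for l in labels])
    if y is not None:
        counts = {c: int(n) for c, n in zip(*np.unique(y, return_counts=True))}
        small = {c: n for c, n in counts.items() if n < k}
        if small:
            raise ValueError(f"classes with fewer than k={k} members: {small}")
    tr, te = train_test_split(
        idx, test_size=test_fraction, random_state=seed,
        stratify=y if y is not None else None, shuffle=True,
    )
    if y is not None:
        folder = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_iter = folder.split(tr, y[tr])
    else:
        folder = KFold(n_splits=k, shuffle=True, random_state=seed)
        fold_iter = folder.split(tr)
    folds = [
        ([ids[tr[a]] for a in f_tr], [ids[tr[b]] for b in f_va])
        for f_tr, f_va in fold_iter
    ]
    return SplitPlan(
        train_ids=[ids[i] for i in tr],
        test_ids=[ids[i] for i in te],
        cv_folds=folds,
        seed=seed,
    )


@dataclass
class TrainedModel:
    """Fitted estimator plus its feature-name manifest.

    Prediction refuses matrices whose columns do not match the manifest
    exactly (names and order) — callers re-derive or subset features by
    name instead of trusting positional alignment.
    """

    config: ModelConfig
    feature_names: List[str]
    feature_kind: str
    estimator: object
    positive_label: Optional[str] = None
    target_units: Optional[str] = None

    def _check(self, fm: FeatureMatrix) -> np.ndarray:
        if list(fm.feature_names) != list(self.feature_names):
            raise ValueError(
                "feature manifest mismatch: matrix columns do not match the "
                "model's training features (names and order must be identical)"
            )
        if not np.all(np.isfinite(fm.values)):
            raise ValueError("non-finite feature values")
        return fm.values

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        return self.estimator.predict(self._check(fm))

    def predict_proba_positive(self, fm: FeatureMatrix) -> np.ndarray:
        """P(positive class) per molecule (classifiers only)."""
        X = self._check(fm)
        return self._proba_positive_raw(X)

    def _proba_positive_raw(self, X: np.ndarray) -> np.ndarray:
        if self.config.task != "classify":
            raise ValueError("probabilities are only defined for classifiers")
        proba = self.estimator.predict_proba(X)
        classes = [str(c) for c in self.estimator.classes_]
        j = classes.index(str(self.positive_label))
        return proba[:, j]

    def decision_value(self, X: np.ndarray) -> np.ndarray:
        """Scalar model output per row: P(positive) or the regression value.

        Unlike :meth:`predict`, takes a raw array already aligned to the
        manifest; used by the attribution code and its oracles.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if self.config.task == "classify":
            return self._proba_positive_raw(X)
        return np.asarray(self.estimator.predict(X), dtype=float)

    def save(self, path) -> None:
        joblib.dump({
            "artifact_version": ARTIFACT_VERSION,
            "config": self.config,
            "feature_names": self.feature_names,
            "feature_kind": self.feature_kind,
            "estimator": self.estimator,
            "positive_label": self.positive_label,
            "target_units": self.target_units,
        }, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("artifact_version") != ARTIFACT_VERSION:
            raise ValueError(
                f"unsupported model artifact version {blob.get('artifact_version')!r}"
            )
        return cls(
            config=blob["config"],
            feature_names=blob["feature_names"],
            feature_kind=blob["feature_kind"],
            estimator=blob["estimator"],
            positive_label=blob["positive_label"],
            target_units=blob["target_units"],
        )


@dataclass
class EvalReport:
    """Cross-validation means (with per-fold reports) plus test-set metrics."""

    cv_mean: Dict[str, float]
    cv_folds: List[Union[ClassificationReport, RegressionReport]]
    test: Union[ClassificationReport, RegressionReport]


def _choose_positive_label(classes: List[str], positive_label: Optional[str]) -> str:
    if positive_label is not None:
        if str(positive_label) not in classes:
            raise ValueError(f"positive label {positive_label!r} not among classes {classes}")
        return str(positive_label)
    if "ESIPT" in classes:
        return "ESIPT"
    if set(classes) == {"0", "1"}:
        return "1"
    return sorted(classes)[-1]


def _classification_summary(rep: ClassificationReport) -> Dict[str, float]:
    return {"ACC": rep.ACC, "AUC": rep.AUC, "F1": rep.F1, "SP": rep.SP, "SE": rep.SE}


def _regression_summary(rep: RegressionReport) -> Dict[str, float]:
    out = {"R2": rep.R2, "MAE": rep.MAE, "RMSE": rep.RMSE,
           "Correlation": rep.pearson_correlation}
    for k, v in rep.fold_rates.items():
        out[f"{int(k)}-fold rate" if float(k).is_integer() else f"{k}-fold rate"] = v
    return out


def fit(
    config: ModelConfig,
    X: FeatureMatrix,
    y: Sequence,
    plan: SplitPlan,
    positive_label: Optional[str] = None,
) -> Tuple[TrainedModel, EvalReport]:
    """Fit under a split plan and report 5-CV and test metrics.

    ``y`` is aligned with ``X.molecule_ids``.  For classification the
    evaluation scores are P(positive class); the positive class defaults to
    "ESIPT" when present, else label "1", else the lexicographically last
    class (pass ``positive_label`` to override).  For regression, metrics
    include the 2-fold/3-fold success rates (targets must be positive).
    """
    values = np.asarray(X.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values; prune or impute first")
    row = {m: i for i, m in enumerate(X.molecule_ids)}
    missing = [m for m in plan.train_ids + plan.test_ids if m not in row]
    if missing:
        raise KeyError(f"plan ids missing from feature matrix: {missing[:5]}")

    classify = config.task == "classify"
    if classify:
        y_arr = np.asarray([str(v) for v in y])
        classes = sorted(set(y_arr))
        if len(classes) < 2:
            raise ValueError("degenerate single-class training labels")
        pos = _choose_positive_label(classes, positive_label)
    else:
        y_arr = np.asarray(y, dtype=float)
        pos = None

    def eval_on(est, ids_eval) -> Union[ClassificationReport, RegressionReport]:
        rows = [row[m] for m in ids_eval]
        Xe, ye = values[rows], y_arr[rows]
        if classify:
            proba = est.predict_proba(Xe)
            j = [str(c) for c in est.classes_].index(pos)
            return classification_metrics((ye == pos).astype(int), proba[:, j])
        return regression_metrics(ye, est.predict(Xe), ids=list(ids_eval))

    fold_reports = []
    for f_tr, f_va in plan.cv_folds:
        est = skbase.clone(build_estimator(config))
        rows = [row[m] for m in f_tr]
        est.fit(values[rows], y_arr[rows])
        fold_reports.append(eval_on(est, f_va))

    summarize = _classification_summary if classify else _regression_summary
    keys = summarize(fold_reports[0]).keys()
    cv_mean = {
        k: float(np.nanmean([summarize(r)[k] for r in fold_reports])) for k in keys
    }

    final = build_estimator(config)
    rows = [row[m] for m in plan.train_ids]
    final.fit(values[rows], y_arr[rows])
    test_report = eval_on(final, plan.test_ids)

    model = TrainedModel(
        config=config,
        feature_names=list(X.feature_names),
        feature_kind=X.kind,
        estimator=final,
        positive_label=pos,
        target_units=None if classify else "kcal/mol",
    )
    return model, EvalReport(cv_mean=cv_mean, cv_folds=fold_reports, test=test_report)


def _importances(est) -> np.ndarray:
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    if hasattr(est, "coef_"):
        coef = np.asarray(est.coef_, dtype=float)
        return np.abs(coef).sum(axis=0) if coef.ndim > 1 else np.abs(coef)
    raise TypeError(
        f"{type(est).__name__} exposes neither feature_importances_ nor coef_; "
        "RFE needs an importance-ranking estimator"
    )


def rfe_select(
    config: ModelConfig,
    X: FeatureMatrix,
    y: Sequence,
    target_n: int = 25,
    step: int = 1,
) -> List[str]:
    """Recursive feature elimination down to ``target_n`` features.

    Refits the configured estimator and drops the ``step`` lowest-importance
    features per round (never overshooting ``target_n``).  One elimination
    order underlies every target size, so the selected set at m features is
    a superset of the set at m-step.  Returns surviving names in the
    matrix's original feature order.
    """
    if X.n_features <= target_n:
        return list(X.feature_names)
    if target_n < 1 or step < 1:
        raise ValueError("target_n and step must be >= 1")
    classify = config.task == "classify"
    y_arr = (
        np.asarray([str(v) for v in y]) if classify else np.asarray(y, dtype=float)
    )
    values = np.asarray(X.values, dtype=float)
    remaining = list(range(X.n_features))
    while len(remaining) > target_n:
        est = build_estimator(config)
        est.fit(values[:, remaining], y_arr)
        imp = _importances(est)
        n_drop = min(step, len(remaining) - target_n)
        # stable sort: among tied importances the earlier-ordered feature drops
        drop_local = np.argsort(imp, kind="stable")[:n_drop]
        drop = {remaining[j] for j in drop_local}
        remaining = [j for j in remaining if j not in drop]
    return [X.feature_names[j] for j in remaining]


def ecod_scores(X: np.ndarray) -> np.ndarray:
    """ECOD outlier scores from per-dimension ECDF tail probabilities.

    For each dimension j the left tail probability of sample i is
    P(X_j <= x_ij) and the right tail P(X_j >= x_ij), both estimated from
    the empirical CDF of the column itself; dimensional tail scores are the
    negative log probabilities.  Three aggregates are formed per sample —
    the left-only sum, the right-only sum, and the skewness-corrected sum
    (left tail for left-skewed columns, right tail otherwise) — and the
    outlier score is the largest of the three.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    # ECDF at the sample points: fraction of values <= / >= each entry
    left = np.empty_like(X)
    right = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        left[:, j] = (col[:, None] >= col[None, :]).mean(axis=1)
        right[:, j] = (col[:, None] <= col[None, :]).mean(axis=1)
    u_l = -np.log(left)
    u_r = -np.log(right)
    skew = stats.skew(X, axis=0)
    u_skew = np.where(skew < 0, u_l, u_r)
    o_left = u_l.sum(axis=1)
    o_right = u_r.sum(axis=1)
    o_auto = u_skew.sum(axis=1)
    return np.maximum(np.maximum(o_left, o_right), o_auto)


def ecod_outliers(
    X: Union[FeatureMatrix, np.ndarray],
    contamination: float = 0.15,
    ids: Optional[Sequence[str]] = None,
) -> Tuple[List[str], List[str], Dict[str, float]]:
    """Flag the top ``contamination`` fraction of samples by ECOD score.

    Returns (inlier ids, outlier ids, score per id).  The outlier cut is the
    (1 - contamination) score percentile; samples strictly above it are
    flagged.  Ids default to the feature-matrix ids or row indices.
    """
    if isinstance(X, FeatureMatrix):
        arr = X.values
        ids = list(X.molecule_ids) if ids is None else list(ids)
    else:
        arr = np.asarray(X, dtype=float)
        ids = [str(i) for i in range(arr.shape[0])] if ids is None else list(ids)
    if arr.shape[0] < 10:
        raise ValueError("ECOD needs at least 10 samples")
    if not 0.0 < contamination <= 0.5:
        raise ValueError(f"contamination must be in (0, 0.5], got {contamination}")
    scores = ecod_scores(arr)
    threshold = np.percentile(scores, 100.0 * (1.0 - contamination))
    flagged = scores > threshold
    outlier_ids = [m for m, f in zip(ids, flagged) if f]
    inlier_ids = [m for m, f in zip(ids, flagged) if not f]
    return inlier_ids, outlier_ids, dict(zip(ids, scores.tolist()))
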