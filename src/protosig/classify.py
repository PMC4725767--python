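"""One-vs-rest maximum-margin classification with embedded feature selection.

The framework decomposes a k-class subtype problem into k binary problems.
For each binary problem, proteins are ranked by one-vs-rest t-test p-value,
and a linear support-vector machine is trained on the top-ranked features.
Predictive power of differently sized feature sets is estimated by
random-sampling cross-validation: the sample set is repeatedly split into
train and test, features are ranked on the training set only, and test
accuracy is recorded per feature count.  The earliest maximum of the
averaged accuracy curve defines the per-class signature size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.svm import SVC

from .containers import ExpressionMatrix, ParameterError, SampleAnnotation
from .diffexpr import _ttest_arrays
from .enrichment import mean_difference

__all__ = [
    "CVConfig",
    "AccuracyCurve",
    "RocResult",
    "StandardizedLinearSVM",
    "train_margin_classifier",
    "rank_features",
    "cv_feature_selection",
    "select_optimal",
    "extract_signature",
    "roc_auc",
    "predict",
]


@dataclass(frozen=True)
class CVConfig:
    """Random-sampling cross-validation configuration.

    Defaults follow the standard protocol: 15% of the samples held out as
    test set, 250 random resamplings, candidate signature sizes 1..30,
    stratified draws so that every class is represented in each test set.
    """

    test_fraction: float = 0.15
    n_runs: int = 250
    feature_grid: tuple = tuple(range(1, 31))
    regularization: float = 1.0
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ParameterError("test_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ParameterError("n_runs must be positive")
        grid = tuple(self.feature_grid)
        if not grid or any(g <= 0 for g in grid) or list(grid) != sorted(set(grid)):
            raise ParameterError("feature_grid must be strictly increasing positive ints")
        if self.regularization <= 0:
            raise ParameterError("regularization must be positive")


@dataclass
class AccuracyCurve:
    """Mean test accuracy per (class, feature count), averaged over CV runs."""

    per_class: dict  # class label -> DataFrame(feature_count, mean, sd, n_runs)

    def frame(self) -> pd.DataFrame:
        frames = []
        for cls, df in self.per_class.items():
            d = df.copy()
            d.insert(0, "class_label", cls)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


@dataclass
class RocResult:
    """ROC points (FPR, TPR) from sweeping the decision threshold, plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


class StandardizedLinearSVM:
    """Linear maximum-margin decision function with built-in standardization.

    Features with zero training variance are dropped (with a warning)
    before per-feature standardization; the transform is part of the
    returned decision function, so callers always pass raw feature values.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self.feature_ids_: list | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, feature_ids=None) -> "StandardizedLinearSVM":
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) != {0, 1}:
            raise ParameterError("binary labels {0, 1} with both present required")
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
        if not keep.any():
            raise ParameterError("no feature with nonzero training variance")
        self.keep_ = keep
        self.mean_ = X[:, keep].mean(axis=0)
        self.sd_ = sd[keep]
        self.feature_ids_ = None if feature_ids is None else list(feature_ids)
        Z = (X[:, keep] - self.mean_) / self.sd_
        # tight solver tolerance: final models are small and should satisfy
        # exact symmetries (label flip <-> score negation) to ~1e-8
        self.svm_ = SVC(kernel="linear", C=self.C, tol=1e-8)
        self.svm_.fit(Z, y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X[:, self.keep_] - self.mean_) / self.sd_
        return self.svm_.decision_function(Z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def export(self) -> dict:
        """Weights, intercept and standardization constants for exact reload."""
        w = self.svm_.coef_.ravel()
        return {
            "feature_ids": self.feature_ids_,
            "kept": self.keep_.tolist(),
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "weights": w.tolist(),
            "intercept": float(self.svm_.intercept_[0]),
            "C": self.C,
        }


def train_margin_classifier(
    X: np.ndarray, y: np.ndarray, regularization: float = 1.0, feature_ids=None
) -> StandardizedLinearSVM:
    """Train a standardized linear SVM; score > 0 predicts the positive class."""
    return StandardizedLinearSVM(C=regularization).fit(X, y, feature_ids=feature_ids)


def rank_features(
    matrix: ExpressionMatrix, annotation: SampleAnnotation, target_class
) -> pd.DataFrame:
    """Rank proteins by ascending one-vs-rest t-test p-value.

    Ties are broken by |t| descending, then protein_id lexicographically, so
    the ranking is fully deterministic.  Proteins without a valid test are
    placed last.
    """
    from .diffexpr import ttest_ovr

    res = ttest_ovr(matrix, annotation, target_class)
    res["abs_t"] = res["statistic"].abs()
    res["_pid"] = res["protein_id"].astype(str)
    res = res.sort_values(
        ["p_value", "abs_t", "_pid"],
        ascending=[True, False, True],
        na_position="last",
        kind="mergesort",
    )
    return res[["protein_id", "statistic", "p_value"]].reset_index(drop=True)


def _draw_split(rng, labels: np.ndarray, classes, test_fraction: float, stratified: bool):
    """Test-set index draw; stratified mode samples per class."""
    n = len(labels)
    if stratified:
        test_idx = []
        for cls in classes:
            members = np.flatnonzero(labels == cls)
            n_test = max(1, round(test_fraction * members.size))
            test_idx.extend(rng.choice(members, size=n_test, replace=False))
        test_idx = np.array(sorted(test_idx))
    else:
        n_test = max(1, round(test_fraction * n))
        test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
    train_mask = np.ones(n, dtype=bool)
    train_mask[test_idx] = False
    return train_mask, test_idx


def cv_feature_selection(
    matrix: ExpressionMatrix, annotation: SampleAnnotation, config: CVConfig
) -> AccuracyCurve:
    """Random-sampling CV over feature-set sizes (requires an imputed matrix).

    For each run a test set of ``round(test_fraction · N)`` samples is
    drawn (stratified by class by default), features are ranked on the
    training set only, and for each grid size g a one-vs-rest classifier is
    trained on the top-g features and scored on the test set.  Accuracy is
    the fraction of correct binary one-vs-rest calls per class model.
    Fully reproducible from ``config.seed``.
    """
    annotation.validate_against(matrix)
    if matrix.missing_mask.any():
        raise ParameterError("cv_feature_selection requires an imputed (complete) matrix")
    X = matrix.values.T  # samples x proteins
    labels = annotation.labels.reindex(matrix.sample_ids).to_numpy()
    classes = annotation.classes
    grid = [g for g in config.feature_grid if g <= matrix.n_proteins]
    if len(grid) < len(config.feature_grid):
        warnings.warn("feature_grid truncated to the number of proteins")
    rng = np.random.default_rng(config.seed)
    values = matrix.values  # materialize once
    ids_sorted = np.array([str(x) for x in matrix.protein_ids])

    acc = {cls: np.zeros((config.n_runs, len(grid))) for cls in classes}
    run = 0
    from sklearn import config_context

    with config_context(assume_finite=True):  # inner loop: data already complete
        while run < config.n_runs:
            train_mask, test_idx = _draw_split(
                rng, labels, classes, config.test_fraction, config.stratified
            )
            train_labels = labels[train_mask]
            if set(classes) - set(train_labels):
                continue  # redraw: training set must contain every class
            Xtr_all, Xte_all = X[train_mask], X[test_idx]
            Vt = values[:, train_mask]
            for cls in classes:
                in_train = train_labels == cls
                # rank on the training set only
                t, p, valid = _ttest_arrays(Vt, in_train)
                order = _rank_order(ids_sorted, t, p, valid)
                y_train = in_train.astype(int)
                y_test = (labels[test_idx] == cls).astype(int)
                for gi, g in enumerate(grid):
                    feats = order[:g]
                    Xtr = Xtr_all[:, feats]
                    mean = Xtr.mean(axis=0)
                    sd = Xtr.std(axis=0)
                    sd[sd == 0] = 1.0  # constant feature carries no signal
                    svm = SVC(kernel="linear", C=config.regularization)
                    svm.fit((Xtr - mean) / sd, y_train)
                    score = (Xte_all[:, feats] - mean) / sd @ svm.coef_.ravel()
                    pred = (score + svm.intercept_[0]) > 0
                    acc[cls][run, gi] = float(np.mean(pred == y_test))
            run += 1

    per_class = {}
    for cls in classes:
        per_class[cls] = pd.DataFrame(
            {
                "feature_count": grid,
                "mean_accuracy": acc[cls].mean(axis=0),
                "sd_accuracy": acc[cls].std(axis=0, ddof=1) if config.n_runs > 1 else 0.0,
                "n_runs": config.n_runs,
            }
        )
    return AccuracyCurve(per_class)


def _rank_order(protein_ids, t, p, valid) -> np.ndarray:
    """Indices of proteins ordered by (p asc, |t| desc, id asc); invalid last."""
    p = np.where(valid, p, np.inf)
    abs_t = np.where(valid, np.abs(t), -np.inf)
    ids = np.asarray(protein_ids, dtype=str)
    return np.lexsort((ids, -abs_t, p))


def select_optimal(curve: AccuracyCurve) -> dict:
    """Per class, the smallest feature count attaining the maximum accuracy."""
    out = {}
    for cls, df in curve.per_class.items():
        if df.empty:
            raise ParameterError("empty accuracy curve")
        best = df["mean_accuracy"].max()
        out[cls] = int(df.loc[df["mean_accuracy"] >= best, "feature_count"].iloc[0])
    return out


def extract_signature(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    optimal_counts: dict,
    regularization: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Full-data re-ranking and final per-class models.

    Features are re-ranked on the full data per class; the top ``g_class``
    proteins form the signature with direction = sign of the class mean
    difference (``positive`` marks higher expression in the class).  A
    protein may legitimately mark more than one class.  Returns the
    signature table and the trained one-vs-rest models keyed by class.
    """
    annotation.validate_against(matrix)
    if matrix.missing_mask.any():
        raise ParameterError("extract_signature requires an imputed (complete) matrix")
    X = matrix.values.T
    labels = annotation.labels.reindex(matrix.sample_ids).to_numpy()
    rows, models = [], {}
    for cls in annotation.classes:
        g = optimal_counts[cls]
        ranking = rank_features(matrix, annotation, cls)
        top = list(ranking["protein_id"].iloc[:g])
        delta = mean_difference(matrix, annotation, cls)
        for pid in top:
            rows.append(
                {
                    "class_label": cls,
                    "protein_id": pid,
                    "direction": "positive" if delta[pid] >= 0 else "negative",
                }
            )
        feat_idx = [matrix.protein_ids.get_loc(pid) for pid in top]
        y = (labels == cls).astype(int)
        models[cls] = StandardizedLinearSVM(C=regularization).fit(
            X[:, feat_idx], y, feature_ids=top
        )
    return pd.DataFrame(rows), models


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and AUC from decision scores and binary labels.

    AUC equals the Mann–Whitney probability that a random positive scores
    above a random negative, counting ties as ½; numerically it is the
    trapezoidal area under the threshold-swept curve.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels)) < 2:
        raise ParameterError("both labels must be present for a ROC curve")
    fpr, tpr, _ = skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(skmetrics.auc(fpr, tpr))
    return RocResult(fpr, tpr, auc)


def predict(models: dict, sample: pd.Series, class_order) -> str:
    """Multi-class prediction: the class whose model scores highest.

    ``sample`` maps protein_id to value and must cover every signature
    feature; ties are broken by class order.
    """
    scores = {}
    for cls in class_order:
        model = models[cls]
        if model.feature_ids_ is None:
            raise ParameterError("model was trained without feature_ids")
        missing = [f for f in model.feature_ids_ if f not in sample.index or pd.isna(sample[f])]
        if missing:
            raise ParameterError(f"missing feature value(s): {missing}")
        x = sample[model.feature_ids_].to_numpy(dtype=float)
        scores[cls] = float(model.decision_function(x)[0])
    best = max(scores.values())
    for cls in class_order:  # first class in order wins ties
        if scores[cls] == best:
            return cls
    raise AssertionError("unreachable")
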