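"""Random-forest training, repeated cross-validation and model selection.

The classifier follows the reference protocol: 500 trees, minimum node size
1, class imbalance corrected by downsampling every class to the minority
class size, stratified 5-fold cross-validation repeated 20 times, and model
selection by the highest validation kappa.  Feature scaling/centring
statistics are learned on each training fold only (leakage-safe); a
``scale_globally`` switch restores the original protocol of preprocessing
the whole matrix before the split.

Two modes are supported: ``binary`` (3'UTR vs non-3'UTR, the deployment
classifier) and ``multinomial`` (all six genomic classes, used to study
which classes 3'UTRs are confused with).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    cohen_kappa_score,
    confusion_matrix,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "THREE_UTR"

LEARNING_CURVE_FRACTIONS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.3, 0.5, 0.8, 1.0)


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 500
    min_node_size: int = 1
    seed: int = 0
    downsample: bool = True
    scale_globally: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ForestModel:
    estimator: RandomForestClassifier
    scaler: StandardScaler
    feature_names: list[str]
    classes: list[str]
    params: ForestParams
    mode: str
    format_version: int = 1

    def predict_proba(self, matrix: pd.DataFrame) -> pd.DataFrame:
        X = self.scaler.transform(matrix[self.feature_names].to_numpy(dtype=float))
        proba = self.estimator.predict_proba(X)
        return pd.DataFrame(proba, columns=list(self.estimator.classes_), index=matrix.index)

    def predict(self, matrix: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
        proba = self.predict_proba(matrix)
        if self.mode == "binary":
            positive = proba[POSITIVE_CLASS]
            negative = [c for c in proba.columns if c != POSITIVE_CLASS][0]
            return pd.Series(
                np.where(positive > threshold, POSITIVE_CLASS, negative), index=matrix.index
            )
        return proba.idxmax(axis=1)


def save_model(model: ForestModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": model.format_version,
            "estimator": model.estimator,
            "scaler": model.scaler,
            "feature_names": model.feature_names,
            "classes": model.classes,
            "params": model.params,
            "mode": model.mode,
        },
        path,
    )


def load_model(path: str | Path) -> ForestModel:
    payload = joblib.load(path)
    return ForestModel(
        estimator=payload["estimator"],
        scaler=payload["scaler"],
        feature_names=payload["feature_names"],
        classes=payload["classes"],
        params=payload["params"],
        mode=payload["mode"],
        format_version=payload["format_version"],
    )


def _downsample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Downsample every class to the minority-class size."""
    classes, counts = np.unique(y, return_counts=True)
    minority = counts.min()
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        keep.append(rng.choice(idx, size=minority, replace=False))
    order = np.sort(np.concatenate(keep))
    return X[order], y[order]


def train_forest(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    params: ForestParams = ForestParams(),
    mode: str = "binary",
) -> ForestModel:
    """Fit a random forest with scaling and downsampling.

    Scaling statistics are learned on the supplied training data and stored
    in the model for reuse at prediction time.
    """
    if mode not in ("binary", "multinomial"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(labels, dtype=object)
    if len(y) != len(matrix):
        raise ValueError("matrix rows must equal label count")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than 2 examples")
    feature_names = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    rng = np.random.default_rng(params.seed)
    if params.downsample:
        Xs, y = _downsample(Xs, y, rng)
    estimator = RandomForestClassifier(
        n_estimators=params.n_trees,
        min_samples_leaf=params.min_node_size,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    estimator.fit(Xs, y)
    return ForestModel(estimator, scaler, feature_names, sorted(classes.tolist()), params, mode)


def compute_metrics(
    truth: np.ndarray | pd.Series,
    probabilities: pd.DataFrame,
    positive_class: str = POSITIVE_CLASS,
    threshold: float = 0.5,
    curves: bool = False,
) -> dict:
    """Confusion metrics at the given threshold plus threshold-free AUCs.

    Binary metrics: accuracy, sensitivity (positive-class recall),
    specificity, Cohen's kappa, AUROC, AUPRC.  With single-class truth the
    AUCs are undefined and reported as None.  In multinomial settings the
    predicted class is the probability argmax and a row-normalised confusion
    matrix is included.
    """
    truth = np.asarray(truth, dtype=object)
    class_names = list(probabilities.columns)
    binary = len(class_names) == 2
    if binary:
        positive = probabilities[positive_class].to_numpy()
        negative_class = [c for c in class_names if c != positive_class][0]
        predicted = np.where(positive > threshold, positive_class, negative_class)
    else:
        predicted = probabilities.idxmax(axis=1).to_numpy(dtype=object)

    metrics: dict = {
        "accuracy": float(accuracy_score(truth, predicted)),
        "kappa": float(cohen_kappa_score(truth, predicted)) if len(np.unique(truth)) > 1 else 0.0,
    }
    if binary:
        truth_pos = truth == positive_class
        pred_pos = predicted == positive_class
        tp = int(np.sum(truth_pos & pred_pos))
        fn = int(np.sum(truth_pos & ~pred_pos))
        tn = int(np.sum(~truth_pos & ~pred_pos))
        fp = int(np.sum(~truth_pos & pred_pos))
        metrics["sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
        metrics["specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
        if len(np.unique(truth)) > 1:
            metrics["auroc"] = float(roc_auc_score(truth_pos, positive))
            metrics["auprc"] = float(average_precision_score(truth_pos, positive))
            if curves:
                fpr, tpr, _ = roc_curve(truth_pos, positive)
                prec, rec, _ = precision_recall_curve(truth_pos, positive)
                metrics["roc_curve"] = (fpr, tpr)
                metrics["pr_curve"] = (prec, rec)
        else:
            metrics["auroc"] = None
            metrics["auprc"] = None
    else:
        cm = confusion_matrix(truth, predicted, labels=class_names)
        row_sums = cm.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            rates = np.where(row_sums > 0, cm / row_sums, 0.0)
        metrics["confusion"] = pd.DataFrame(cm, index=class_names, columns=class_names)
        metrics["confusion_rates"] = pd.DataFrame(rates, index=class_names, columns=class_names)
    return metrics


@dataclass
class CVReport:
    per_run: list[dict] = field(default_factory=list)
    models: list[ForestModel] = field(default_factory=list)
    mode: str = "binary"

    def summary(self) -> dict:
        """Mean of every scalar metric across all k x repeats runs."""
        keys = [
            k
            for k in self.per_run[0]
            if isinstance(self.per_run[0][k], (int, float)) and self.per_run[0][k] is not None
        ]
        out = {}
        for key in keys:
            values = [run[key] for run in self.per_run if run.get(key) is not None]
            out[key] = float(np.mean(values)) if values else None
        return out

    def summary_by_repeat(self) -> pd.DataFrame:
        """Fold-averaged metrics per repeat (the alternative aggregation)."""
        frame = pd.DataFrame(
            [
                {k: v for k, v in run.items() if isinstance(v, (int, float))}
                for run in self.per_run
            ]
        )
        return frame.groupby("repeat").mean()

    def mean_confusion_rates(self) -> pd.DataFrame:
        frames = [run["confusion_rates"] for run in self.per_run if "confusion_rates" in run]
        return sum(frames[1:], frames[0].copy()) / len(frames)


def cross_validate(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 5,
    repeats: int = 20,
    params: ForestParams = ForestParams(),
    mode: str = "binary",
    positive_class: str = POSITIVE_CLASS,
    keep_models: bool = False,
) -> CVReport:
    """Stratified k-fold cross-validation repeated ``repeats`` times.

    Hold-out folds never influence scaling or downsampling of their fold's
    training data (unless ``params.scale_globally`` restores the original
    global-preprocessing protocol).
    """
    y = np.asarray(labels, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds minority-class size {counts.min()}")
    report = CVReport(mode=mode)
    global_scaler = StandardScaler().fit(matrix.to_numpy(dtype=float)) if params.scale_globally else None
    for repeat in range(repeats):
        run_seed = params.seed + repeat
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=run_seed % (2**31 - 1))
        for fold, (train_idx, test_idx) in enumerate(splitter.split(matrix, y)):
            fold_params = ForestParams(
                n_trees=params.n_trees,
                min_node_size=params.min_node_size,
                seed=(run_seed * 1000 + fold) % (2**31 - 1),
                downsample=params.downsample,
                scale_globally=params.scale_globally,
            )
            train_X = matrix.iloc[train_idx]
            test_X = matrix.iloc[test_idx]
            if global_scaler is not None:
                # original protocol: one scaler for the whole matrix
                train_X = pd.DataFrame(
                    global_scaler.transform(train_X.to_numpy(dtype=float)),
                    columns=matrix.columns, index=train_X.index,
                )
                test_X = pd.DataFrame(
                    global_scaler.transform(test_X.to_numpy(dtype=float)),
                    columns=matrix.columns, index=test_X.index,
                )
            model = train_forest(train_X, y[train_idx], fold_params, mode=mode)
            proba = model.predict_proba(test_X)
            run = compute_metrics(y[test_idx], proba, positive_class=positive_class)
            run["repeat"] = repeat
            run["fold"] = fold
            report.per_run.append(run)
            if keep_models:
                report.models.append(model)
    return report


def variable_importance(
    model: ForestModel,
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_permutations: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature mean decrease in accuracy (MDA) and Gini importance.

    MDA is the drop in accuracy after permuting one feature column in the
    supplied (validation) data, averaged over permutation repeats; Gini is
    the total impurity decrease attributed to the feature across trees.
    Both are returned ranked by MDA.
    """
    y = np.asarray(labels, dtype=object)
    X = model.scaler.transform(matrix[model.feature_names].to_numpy(dtype=float))
    result = permutation_importance(
        model.estimator, X, y, n_repeats=n_permutations, random_state=seed, scoring="accuracy"
    )
    table = pd.DataFrame(
        {
            "feature": model.feature_names,
            "mda": result.importances_mean,
            "mda_sd": result.importances_std,
            "gini": model.estimator.feature_importances_,
        }
    )
    table["mda_rank"] = table["mda"].rank(ascending=False, method="min").astype(int)
    table["gini_rank"] = table["gini"].rank(ascending=False, method="min").astype(int)
    return table.sort_values("mda", ascending=False).reset_index(drop=True)


def learning_curve(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    fractions: tuple[float, ...] = LEARNING_CURVE_FRACTIONS,
    repeats: int = 20,
    k: int = 5,
    params: ForestParams = ForestParams(),
    mode: str = "binary",
) -> pd.DataFrame:
    """Bias-variance experiment: k-fold CV on growing random subsamples.

    For each fraction and repeat a random stratified subsample is drawn and
    5-fold cross-validated; fractions too small to give k examples per class
    are skipped with a warning.  At fraction 1.0 with matching seeds the
    rows coincide with plain :func:`cross_validate` output.
    """
    y = np.asarray(labels, dtype=object)
    rows = []
    for fraction in fractions:
        for repeat in range(repeats):
            if fraction >= 1.0:
                sub_idx = np.arange(len(y))
            else:
                rng = np.random.default_rng([params.seed, int(fraction * 1e6), repeat])
                sub_idx = []
                for cls in np.unique(y):
                    idx = np.flatnonzero(y == cls)
                    n = max(1, int(round(fraction * len(idx))))
                    sub_idx.append(rng.choice(idx, size=n, replace=False))
                sub_idx = np.sort(np.concatenate(sub_idx))
            sub_y = y[sub_idx]
            _, counts = np.unique(sub_y, return_counts=True)
            if counts.min() < k:
                logger.warning(
                    "fraction %.3f leaves a class with %d < k=%d examples; skipped",
                    fraction, counts.min(), k,
                )
                break
            run_params = ForestParams(
                n_trees=params.n_trees,
                min_node_size=params.min_node_size,
                seed=params.seed + repeat,
                downsample=params.downsample,
                scale_globally=params.scale_globally,
            )
            report = cross_validate(
                matrix.iloc[sub_idx], sub_y, k=k, repeats=1, params=run_params, mode=mode
            )
            summary = report.summary()
            summary.pop("repeat", None)
            summary.pop("fold", None)
            rows.append({"fraction": fraction, "repeat": repeat, "n": len(sub_idx), **summary})
    return pd.DataFrame(rows)


def select_model(report: CVReport) -> ForestModel:
    """The fold model with the highest validation kappa.

    Ties break by higher AUPRC, then by lower model index.
    """
    if not report.models:
        raise ValueError("cross_validate must be run with keep_models=True")
    best_index = 0
    best_key = (-np.inf, -np.inf)
    for i, run in enumerate(report.per_run):
        key = (run.get("kappa", -np.inf), run.get("auprc") or -np.inf)
        if key > best_key:
            best_key = key
            best_index = i
    return report.models[best_index]
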