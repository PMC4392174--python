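"""Symptom detection and severity estimation.

Two linear-kernel SVM binary detectors (hand resting tremor present:
UPDRS tremor item >= 1; gait difficulty: UPDRS gait item >= 2) and three
L1-penalized (Lasso) linear regressors (Hoehn & Yahr stage, tremor item,
gait item), all evaluated by stratified 5-fold cross-validation with pooled
out-of-fold predictions.

Features are z-scored inside each training fold only, so no validation
statistics leak into training. The Lasso penalty is chosen by an inner
5-fold cross-validation minimizing mean squared error. Regression
predictions are clipped to the label range (stage to [1, 5], UPDRS items to
[0, 4]) before scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateLabelsError, ParameterError

__all__ = [
    "SubjectLabels",
    "FeatureTable",
    "CVReport",
    "TREMOR_FEATURE_COLUMNS",
    "GAIT_FEATURE_COLUMNS",
    "DETECTOR_TARGETS",
    "REGRESSOR_TARGETS",
    "train_detector",
    "train_severity_regressor",
    "cross_validate",
    "confusion_metrics",
    "pearson_r",
    "group_ttest",
    "model_to_json",
]

#: Tremor-detector feature set (the six spectral/amplitude tremor features).
TREMOR_FEATURE_COLUMNS = [
    "tremor_pf4_6",
    "tremor_pct_pf4_6",
    "tremor_pr",
    "tremor_pf0_20",
    "tremor_peak_power",
    "tremor_avg_acc",
]

#: Gait-detector feature set (four walking + two turning features).
GAIT_FEATURE_COLUMNS = [
    "gait_ct",
    "gait_sl",
    "gait_sp",
    "gait_avg_acc",
    "turn_num",
    "turn_sp",
]

DETECTOR_TARGETS = {"tremor_present": TREMOR_FEATURE_COLUMNS,
                    "gait_difficulty": GAIT_FEATURE_COLUMNS}

#: Regression targets and the range predictions are clipped to.
REGRESSOR_TARGETS = {
    "hoehn_yahr": (1.0, 5.0),
    "tremor_updrs": (0.0, 4.0),
    "gait_updrs": (0.0, 4.0),
}


@dataclass(frozen=True)
class SubjectLabels:
    """Expert ground truth for one subject.

    ``tremor_present`` and ``gait_difficulty`` are derived: tremor item >= 1
    and gait item >= 2 respectively.
    """

    tremor_updrs: int
    gait_updrs: int
    hoehn_yahr: int

    def __post_init__(self) -> None:
        if not 0 <= self.tremor_updrs <= 4:
            raise ParameterError("SubjectLabels: tremor_updrs must be in 0..4")
        if not 0 <= self.gait_updrs <= 4:
            raise ParameterError("SubjectLabels: gait_updrs must be in 0..4")
        if not 1 <= self.hoehn_yahr <= 5:
            raise ParameterError("SubjectLabels: hoehn_yahr must be in 1..5")

    @property
    def tremor_present(self) -> bool:
        return self.tremor_updrs >= 1

    @property
    def gait_difficulty(self) -> bool:
        return self.gait_updrs >= 2


@dataclass
class FeatureTable:
    """Per-subject features plus labels, aligned row-by-row."""

    features: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ParameterError("FeatureTable: features and labels differ in length")
        if self.features.columns.duplicated().any():
            raise ParameterError("FeatureTable: duplicate feature columns")
        if self.features.isna().any().any():
            raise ParameterError("FeatureTable: missing values in feature columns")

    def __len__(self) -> int:
        return len(self.features)

    def feature_matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else list(self.features.columns)
        missing = [c for c in cols if c not in self.features.columns]
        if missing:
            raise ParameterError(f"FeatureTable: missing feature columns {missing}")
        return self.features[cols].to_numpy(dtype=float)

    def target(self, name: str) -> np.ndarray:
        if name not in self.labels.columns:
            raise ParameterError(f"FeatureTable: no label column '{name}'")
        return self.labels[name].to_numpy()


@dataclass
class CVReport:
    """Cross-validation result with pooled and per-fold metrics."""

    target: str
    kind: str  # "detector" or "regressor"
    seed: int
    k: int
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    accuracy: Optional[float] = None
    pearson_r: Optional[float] = None
    per_fold: list[dict] = field(default_factory=list)
    predictions: Optional[np.ndarray] = None
    truth: Optional[np.ndarray] = None
    fold_assignment: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        out = {
            "target": self.target,
            "kind": self.kind,
            "seed": self.seed,
            "k": self.k,
            "per_fold": self.per_fold,
        }
        for key in ("sensitivity", "specificity", "accuracy", "pearson_r"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        return out


# ---------------------------------------------------------------------------
# estimators


def _feature_columns_for(target: str) -> list[str] | None:
    return DETECTOR_TARGETS.get(target)


def train_detector(
    table: FeatureTable,
    target: str,
    C: float = 1.0,
    kernel: str = "linear",
    seed: int = 0,
) -> Pipeline:
    """Fit an SVM detector (features z-scored with training statistics)."""
    if target not in DETECTOR_TARGETS:
        raise ParameterError(f"train_detector: unknown target '{target}'")
    X = table.feature_matrix(DETECTOR_TARGETS[target])
    y = table.target(target).astype(bool)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError(
            f"train_detector: target '{target}' has a single class"
        )
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C, random_state=seed)),
        ]
    )
    model.fit(X, y)
    return model


def train_severity_regressor(
    table: FeatureTable,
    target: str,
    seed: int = 0,
    inner_cv: int = 5,
) -> Pipeline:
    """Fit a Lasso regressor; penalty chosen by inner cross-validation."""
    if target not in REGRESSOR_TARGETS:
        raise ParameterError(f"train_severity_regressor: unknown target '{target}'")
    if len(table) < 10:
        raise ParameterError("train_severity_regressor: need at least 10 rows")
    X = table.feature_matrix()
    y = table.target(target).astype(float)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError(
            f"train_severity_regressor: target '{target}' is constant"
        )
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "lasso",
                LassoCV(
                    cv=KFold(n_splits=min(inner_cv, len(table)), shuffle=True,
                             random_state=seed),
                    max_iter=50_000,
                ),
            ),
        ]
    )
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# cross-validation


def _make_folds(
    y: np.ndarray, kind: str, k: int, seed: int
) -> np.ndarray:
    """Fold assignment per row: stratified by class, or by label quartile."""
    n = y.shape[0]
    if kind == "detector":
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise DegenerateLabelsError("cross_validate: single-class labels")
        if counts.min() < k:
            raise ParameterError(
                f"cross_validate: smallest class has {counts.min()} members, "
                f"cannot stratify into {k} folds"
            )
        strata = y.astype(int)
    else:
        quartiles = np.quantile(y, [0.25, 0.5, 0.75])
        strata = np.searchsorted(np.unique(quartiles), y)
    assignment = np.empty(n, dtype=int)
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (_, val_idx) in enumerate(splitter.split(np.zeros(n), strata)):
            assignment[val_idx] = fold
    else:
        # a stratum too small to spread over all folds: plain shuffled folds
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (_, val_idx) in enumerate(kf.split(np.zeros(n))):
            assignment[val_idx] = fold
    return assignment


def cross_validate(
    table: FeatureTable,
    target: str,
    k: int = 5,
    seed: int = 0,
    folds: np.ndarray | None = None,
    C: float = 1.0,
    kernel: str = "linear",
) -> CVReport:
    """k-fold cross-validation with pooled out-of-fold scoring.

    Detector targets are scored by sensitivity/specificity/accuracy of the
    pooled confusion table; regressor targets by the Pearson correlation of
    pooled clipped predictions against truth. The partition is reproducible
    from the seed; ``folds`` may supply an explicit fold-id array instead.
    """
    if target in DETECTOR_TARGETS:
        kind = "detector"
        y = table.target(target).astype(bool)
        X = table.feature_matrix(DETECTOR_TARGETS[target])
    elif target in REGRESSOR_TARGETS:
        kind = "regressor"
        y = table.target(target).astype(float)
        X = table.feature_matrix()
    else:
        raise ParameterError(f"cross_validate: unknown target '{target}'")
    n = len(table)
    if n < k:
        raise ParameterError(f"cross_validate: n={n} < k={k}")
    if folds is None:
        folds = _make_folds(y, kind, k, seed)
    else:
        folds = np.asarray(folds, dtype=int)
        if folds.shape[0] != n:
            raise ParameterError("cross_validate: fold array length mismatch")

    predictions = np.empty(n, dtype=float)
    per_fold: list[dict] = []
    for fold in range(k):
        val = folds == fold
        train = ~val
        sub = FeatureTable(
            features=table.features.loc[train].reset_index(drop=True),
            labels=table.labels.loc[train].reset_index(drop=True),
        )
        if kind == "detector":
            model = train_detector(sub, target, C=C, kernel=kernel, seed=seed)
            pred = model.predict(X[val]).astype(float)
        else:
            model = train_severity_regressor(sub, target, seed=seed)
            lo, hi = REGRESSOR_TARGETS[target]
            pred = np.clip(model.predict(X[val]), lo, hi)
        predictions[val] = pred
        entry: dict = {"fold": fold, "n_val": int(val.sum())}
        if kind == "detector":
            entry["accuracy"] = float((pred.astype(bool) == y[val]).mean())
        else:
            entry["mse"] = float(np.mean((pred - y[val]) ** 2))
        per_fold.append(entry)

    report = CVReport(
        target=target,
        kind=kind,
        seed=seed,
        k=k,
        per_fold=per_fold,
        predictions=predictions,
        truth=y.astype(float),
        fold_assignment=folds,
    )
    if kind == "detector":
        pred_b = predictions.astype(bool)
        tp = int(np.sum(pred_b & y))
        fp = int(np.sum(pred_b & ~y))
        tn = int(np.sum(~pred_b & ~y))
        fn = int(np.sum(~pred_b & y))
        sens, spec, acc = confusion_metrics(tp, fp, tn, fn)
        report.sensitivity, report.specificity, report.accuracy = sens, spec, acc
    else:
        report.pearson_r = pearson_r(predictions, y)
    return report


# ---------------------------------------------------------------------------
# evaluation statistics


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ParameterError("confusion_metrics: counts must be non-negative")
    if tp + fn == 0:
        raise ParameterError("confusion_metrics: no positive cases (tp+fn=0)")
    if tn + fp == 0:
        raise ParameterError("confusion_metrics: no negative cases (tn+fp=0)")
    total = tp + fp + tn + fn
    return tp / (tp + fn), tn / (tn + fp), (tp + tn) / total


def pearson_r(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson product-moment correlation between predictions and truth."""
    a = np.asarray(pred, dtype=float)
    b = np.asarray(truth, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("pearson_r: inputs must be equal-length 1-D vectors")
    if a.size < 3:
        raise ParameterError("pearson_r: need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ParameterError("pearson_r: constant vector, correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def group_ttest(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t test (unequal variances), two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("group_ttest: each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# model serialization


def model_to_json(model: Pipeline, path: str | None = None) -> dict:
    """Serialize a fitted linear pipeline (scaler statistics + coefficients)."""
    scaler: StandardScaler = model.named_steps["scale"]
    payload: dict = {
        "scaler_mean": scaler.mean_.tolist(),
        "scaler_scale": scaler.scale_.tolist(),
    }
    if "svm" in model.named_steps:
        svm: SVC = model.named_steps["svm"]
        payload["kind"] = "svm"
        payload["kernel"] = svm.kernel
        payload["C"] = svm.C
        if svm.kernel == "linear":
            payload["coef"] = svm.coef_.ravel().tolist()
            payload["intercept"] = float(svm.intercept_[0])
    else:
        lasso = model.named_steps["lasso"]
        payload["kind"] = "lasso"
        payload["alpha"] = float(lasso.alpha_) if isinstance(lasso, LassoCV) else float(lasso.alpha)
        payload["coef"] = np.asarray(lasso.coef_).tolist()
        payload["intercept"] = float(lasso.intercept_)
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    return payload
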