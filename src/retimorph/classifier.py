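"""Linear SVM morphotype classifier with cross-validated evaluation.

A linear support-vector classifier over the 34-parameter morphometric
records, evaluated by stratified 5-fold cross-validation.  Features
are z-scored with statistics fit on the training folds only; per-class
ROC curves and AUCs are computed one-vs-rest from out-of-fold decision
scores, and the confusion matrix aggregates out-of-fold predictions
across all folds.  The returned model is refit on the full table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .particle_analysis import FEATURE_COLUMNS

MODEL_FORMAT_VERSION = 1


@dataclass
class CVReport:
    """Cross-validation report of the morphotype classifier.

    ``confusion`` rows are true classes, columns predicted classes, in
    ``classes`` order.  ROC curves are one-vs-rest from out-of-fold
    decision scores.
    """

    classes: list[str]
    confusion: np.ndarray
    per_class_tpr: dict[str, float]
    per_class_fnr: dict[str, float]
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    auc: dict[str, float]
    folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "per_class_tpr": self.per_class_tpr,
            "per_class_fnr": self.per_class_fnr,
            "auc": self.auc,
            "folds": self.folds,
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def roc_frame(self) -> pd.DataFrame:
        rows = []
        for cls, (fpr, tpr) in self.roc_curves.items():
            for f, t in zip(fpr, tpr):
                rows.append({"class": cls, "fpr": f, "tpr": t})
        return pd.DataFrame(rows)


@dataclass
class TrainedClassifier:
    """A fitted scaler + linear SVM with training metadata."""

    pipeline: Pipeline
    classes: list[str]
    feature_columns: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> list[str]:
        X = _feature_matrix(table, self.feature_columns)
        return list(self.pipeline.predict(X))

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        X = _feature_matrix(table, self.feature_columns)
        return self.pipeline.decision_function(X)


def _feature_matrix(table: pd.DataFrame, columns: list[str]) -> np.ndarray:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    X = table[columns].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature table contains non-finite values")
    return X


def _make_pipeline(C: float) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", OneVsRestClassifier(SVC(kernel="linear", C=C))),
        ]
    )


def train_svm(
    table: pd.DataFrame,
    label_column: str = "morphotype",
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    feature_columns: list[str] | None = None,
) -> tuple[TrainedClassifier, CVReport]:
    """Train the linear SVM and evaluate it by stratified k-fold CV.

    Out-of-fold predictions and one-vs-rest decision scores from the
    k test folds are pooled into the confusion matrix, per-class
    TPR/FNR and per-class ROC/AUC.  The final model is refit on all
    rows.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    X = _feature_matrix(table, cols)
    y = table[label_column].to_numpy(dtype=object)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        small = counts[counts < folds]
        raise ValueError(f"classes smaller than fold count: {dict(small)}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_pred = np.empty(len(y), dtype=object)
    oof_scores = np.zeros((len(y), len(classes)))
    for train_idx, test_idx in skf.split(X, y):
        pipe = _make_pipeline(C)
        pipe.fit(X[train_idx], y[train_idx])
        oof_pred[test_idx] = pipe.predict(X[test_idx])
        scores = pipe.decision_function(X[test_idx])
        if scores.ndim == 1:  # binary: expand to two columns
            scores = np.stack([-scores, scores], axis=1)
        fold_classes = list(pipe.classes_)
        for j, cls in enumerate(classes):
            if cls in fold_classes:
                oof_scores[test_idx, j] = scores[:, fold_classes.index(cls)]
            else:
                oof_scores[test_idx, j] = -np.inf

    conf = confusion_matrix(y, oof_pred, labels=classes)
    tpr, fnr, rocs, aucs = {}, {}, {}, {}
    for j, cls in enumerate(classes):
        row = conf[j]
        total = row.sum()
        tpr[cls] = float(row[j] / total) if total else 0.0
        fnr[cls] = 1.0 - tpr[cls]
        fpr_pts, tpr_pts, _ = roc_curve((y == cls).astype(int), oof_scores[:, j])
        rocs[cls] = (fpr_pts, tpr_pts)
        aucs[cls] = float(_auc(fpr_pts, tpr_pts))

    final = _make_pipeline(C)
    final.fit(X, y)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "seed": seed,
        "folds": folds,
        "C": C,
        "classes": classes,
        "feature_columns": cols,
        "n_training_rows": int(len(y)),
        "training_hash": hashlib.sha256(
            np.ascontiguousarray(X).tobytes()
        ).hexdigest()[:16],
    }
    model = TrainedClassifier(final, classes, cols, meta)
    report = CVReport(classes, conf, tpr, fnr, rocs, aucs, folds, seed)
    return model, report


def predict(model: TrainedClassifier, table: pd.DataFrame) -> list[str]:
    """Morphotype label per record; deterministic given the model."""
    return model.predict(table)


def save_model(model: TrainedClassifier, path: str | Path) -> None:
    """Persist model + metadata; round-trips predictions bit-exactly."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "metadata": model.metadata,
            "classes": model.classes,
            "feature_columns": model.feature_columns,
            "pipeline": model.pipeline,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedClassifier:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a retimorph model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedClassifier(
        payload["pipeline"],
        payload["classes"],
        payload["feature_columns"],
        payload["metadata"],
    )
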