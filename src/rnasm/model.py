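"""Stacking classifier separating DNA-backed somatic mutations from RNA-only
variants (editing, alignment artifacts, RT noise).

Three base learners — a random forest, a gradient-boosted tree ensemble and a
multilayer perceptron (with a standardising scaler) — are tuned by 5-fold
cross-validated grid search on ROC-AUC. A logistic meta-learner is then fitted
on the base learners' *out-of-fold* probabilities only, so the meta stage never
sees a probability produced by a model that trained on the same row (no
leakage). Support-vector and plain logistic learners are available behind the
same registry but excluded from the default stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FEATURE_NAMES

__all__ = [
    "DEFAULT_STACK",
    "LEARNER_REGISTRY",
    "StackingModel",
    "train_base_learners",
    "train_stacking",
    "train",
    "classify",
    "evaluate_classifier",
]

#: Learners assembled into the default stack.
DEFAULT_STACK = ("random_forest", "xgboost", "mlp")


def _make_rf(seed: int):
    est = RandomForestClassifier(random_state=seed, class_weight="balanced", n_jobs=1)
    grid = {"n_estimators": [100, 300], "max_depth": [4, 8, None]}
    return est, grid


def _make_xgb(seed: int):
    est = XGBClassifier(n_estimators=150, random_state=seed, n_jobs=1,
                        tree_method="hist", eval_metric="logloss")
    grid = {"learning_rate": [0.05, 0.1], "max_depth": [4, 8]}
    return est, grid


def _make_mlp(seed: int):
    est = Pipeline([
        ("scaler", StandardScaler()),
        ("mlp", MLPClassifier(random_state=seed, max_iter=300)),
    ])
    grid = {"mlp__hidden_layer_sizes": [(32,), (64, 32)]}
    return est, grid


def _make_logistic(seed: int):
    est = Pipeline([
        ("scaler", StandardScaler()),
        ("lr", LogisticRegression(random_state=seed, max_iter=1000,
                                  class_weight="balanced")),
    ])
    grid = {"lr__C": [0.1, 1.0, 10.0]}
    return est, grid


def _make_svm(seed: int):
    est = Pipeline([
        ("scaler", StandardScaler()),
        ("svc", SVC(random_state=seed, probability=True, class_weight="balanced")),
    ])
    grid = {"svc__C": [0.5, 2.0]}
    return est, grid


LEARNER_REGISTRY = {
    "random_forest": _make_rf,
    "xgboost": _make_xgb,
    "mlp": _make_mlp,
    "logistic": _make_logistic,
    "svm": _make_svm,
}


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in X.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns: {missing}")
        X = X[list(FEATURE_NAMES)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def train_base_learners(X, y, seed: int = 0,
                        learners: Sequence[str] = DEFAULT_STACK,
                        n_folds: int = 5,
                        grids: Mapping[str, Mapping] | None = None
                        ) -> tuple[dict, np.ndarray, pd.DataFrame]:
    """Fit each base learner with 5-fold CV hyperparameter selection on ROC-AUC.

    Returns (fitted best estimators by name, out-of-fold probability matrix with
    one column per learner, CV report with the selected parameters and AUCs).
    The out-of-fold probabilities come from ``cross_val_predict`` on the same
    fold layout, so every training row's score was produced by a model that did
    not see that row.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if len(y) < 50:
        raise ValueError(f"need >= 50 training rows, got {len(y)}")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fitted: dict[str, object] = {}
    oof = np.zeros((len(y), len(learners)))
    report_rows = []
    for j, name in enumerate(learners):
        est, grid = LEARNER_REGISTRY[name](seed)
        if grids and name in grids:
            grid = dict(grids[name])
        search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, n_jobs=1, refit=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
            search.fit(Xm, y)
            oof[:, j] = cross_val_predict(search.best_estimator_, Xm, y, cv=cv,
                                          method="predict_proba", n_jobs=1)[:, 1]
        fitted[name] = search.best_estimator_
        report_rows.append({"learner": name, "cv_auc": float(search.best_score_),
                            "oof_auc": float(roc_auc_score(y, oof[:, j])),
                            "best_params": str(search.best_params_)})
    return fitted, oof, pd.DataFrame(report_rows)


def train_stacking(base_oof: np.ndarray, y, seed: int = 0) -> LogisticRegression:
    """Fit the logistic meta-learner on base out-of-fold probabilities."""
    base_oof = np.asarray(base_oof, dtype=float)
    if np.allclose(base_oof.std(axis=0), 0):
        warnings.warn("base learner outputs are constant; meta-learner is degenerate")
    meta = LogisticRegression(random_state=seed, max_iter=1000)
    meta.fit(base_oof, np.asarray(y, dtype=int))
    return meta


@dataclass
class StackingModel:
    """Fitted stack: named base learners + logistic meta over their probabilities.

    ``feature_names`` is the column manifest the model expects, in order;
    ``predict_proba`` is a pure function of (model, features), and a
    serialised-then-loaded bundle reproduces probabilities bit-for-bit.
    """

    base_learners: dict
    meta: LogisticRegression
    feature_names: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)

    def base_probabilities(self, X) -> np.ndarray:
        Xm = self._check(X)
        cols = [est.predict_proba(Xm)[:, 1] for est in self.base_learners.values()]
        return np.column_stack(cols)

    def predict_proba(self, X) -> np.ndarray:
        return self.meta.predict_proba(self.base_probabilities(X))[:, 1]

    def _check(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"feature columns missing: {missing}")
            X = X[list(self.feature_names)]
            return X.to_numpy(dtype=float)
        Xm = np.asarray(X, dtype=float)
        if Xm.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns "
                f"({self.feature_names[:3]}...), got {Xm.shape[1]}")
        return Xm

    def save(self, path: str | Path) -> None:
        joblib.dump({"base_learners": self.base_learners, "meta": self.meta,
                     "feature_names": self.feature_names, "metadata": self.metadata},
                    path)

    @classmethod
    def load(cls, path: str | Path) -> "StackingModel":
        d = joblib.load(path)
        return cls(base_learners=d["base_learners"], meta=d["meta"],
                   feature_names=tuple(d["feature_names"]), metadata=d["metadata"])


def train(X, y, seed: int = 0, learners: Sequence[str] = DEFAULT_STACK,
          grids: Mapping[str, Mapping] | None = None
          ) -> tuple[StackingModel, pd.DataFrame]:
    """Full training pipeline: base learners (5-fold CV tuning + out-of-fold
    probabilities) then the logistic meta-learner. Returns (model, CV report)."""
    fitted, oof, report = train_base_learners(X, y, seed=seed, learners=learners,
                                              grids=grids)
    meta = train_stacking(oof, y, seed=seed)
    model = StackingModel(
        base_learners=fitted, meta=meta,
        metadata={"seed": seed, "n_folds": 5, "learners": list(learners),
                  "n_train": int(len(np.asarray(y))),
                  "stack_oof_auc": float(roc_auc_score(y, meta.predict_proba(oof)[:, 1]))},
    )
    return model, report


def classify(model: StackingModel, X, threshold: float = 0.5
             ) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels (1 iff probability >= threshold)."""
    p = model.predict_proba(X)
    return (p >= threshold).astype(int), p


def evaluate_classifier(y, p) -> dict:
    """ROC-AUC (probability of correct pairwise ranking, ties 0.5), PR-AUC by
    step-wise interpolation, and both curves as point lists."""
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("evaluation needs both classes present")
    fpr, tpr, _ = roc_curve(y, p)
    prec, rec, _ = precision_recall_curve(y, p)
    return {
        "roc_auc": float(roc_auc_score(y, p)),
        "pr_auc": float(average_precision_score(y, p)),
        "roc_curve": list(zip(fpr.tolist(), tpr.tolist())),
        "pr_curve": list(zip(rec.tolist(), prec.tolist())),
    }
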