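"""Classifier training and evaluation on peptide feature matrices.

The harness mirrors common epitope-classification practice: per-feature
min-max normalization fitted inside each fold, stratified five-fold
cross-validated grid search scored by AUC, and a threshold-dependent
metric suite (sensitivity, specificity, accuracy, F1, MCC, Cohen's kappa)
computed on pooled out-of-fold predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier


# --------------------------------------------------------------------- metrics
@dataclass
class MetricsReport:
    """Confusion counts plus the standard threshold metrics.

    Sensitivity/specificity/accuracy are percentages; F1, MCC and kappa
    are on their natural scales; AUC is threshold-independent (NaN when
    only one class is present).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    mcc: float
    kappa: float
    auc: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int, auc: float = float("nan")) -> MetricsReport:
    n = tp + fp + tn + fn
    sens = 100.0 * _safe_div(tp, tp + fn)
    spec = 100.0 * _safe_div(tn, tn + fp)
    acc = 100.0 * _safe_div(tp + tn, n)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    p_o = _safe_div(tp + tn, n)
    p_e = _safe_div((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp), n * n)
    kappa = _safe_div(p_o - p_e, 1 - p_e)
    return MetricsReport(tp, fp, tn, fn, sens, spec, acc, f1, mcc, kappa, auc)


def evaluate_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Score a set of predictions: confusion counts at ``score >=
    threshold`` plus rank-based AUC (ties averaged)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    auc = roc_auc_score(y, s) if len(np.unique(y)) == 2 else float("nan")
    return metrics_from_counts(tp, fp, tn, fn, auc)


# ------------------------------------------------------------------- registry
def _registry(seed: int) -> dict[str, tuple[object, dict]]:
    return {
        "DT": (DecisionTreeClassifier(random_state=seed),
               {"clf__max_depth": [3, 5, None]}),
        "RF": (RandomForestClassifier(random_state=seed),
               {"clf__n_estimators": [100, 300], "clf__max_depth": [None, 8]}),
        "ET": (ExtraTreesClassifier(random_state=seed),
               {"clf__n_estimators": [100, 300], "clf__max_depth": [None, 8]}),
        "LR": (LogisticRegression(max_iter=2000, random_state=seed),
               {"clf__C": [0.1, 1.0, 10.0]}),
        "KNN": (KNeighborsClassifier(), {"clf__n_neighbors": [3, 5, 9]}),
        "GNB": (GaussianNB(), {}),
        "SVC": (SVC(kernel="rbf", probability=True, random_state=seed),
                {"clf__C": [1.0, 10.0], "clf__gamma": ["scale", 0.1]}),
        "MLP": (MLPClassifier(max_iter=1500, random_state=seed),
                {"clf__hidden_layer_sizes": [(32,), (64,)], "clf__alpha": [1e-3]}),
        "XGB": (XGBClassifier(eval_metric="logloss", random_state=seed,
                              n_jobs=1, tree_method="hist"),
                {"clf__n_estimators": [100, 200], "clf__max_depth": [3, 5],
                 "clf__learning_rate": [0.1]}),
    }


ALGORITHMS = tuple(_registry(0))


@dataclass
class ModelBundle:
    """A fitted classifier frozen together with its feature contract."""

    algorithm: str
    hyperparameters: dict
    pipeline: Pipeline
    feature_names: list[str]
    families: list[str] = field(default_factory=list)
    family_params: dict = field(default_factory=dict)
    threshold: float = 0.5

    def _matrix(self, m: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in m.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns: {missing[:5]}")
        return m[self.feature_names].to_numpy()

    def predict_proba(self, m: pd.DataFrame) -> np.ndarray:
        """Positive-class probabilities for a feature matrix."""
        return self.pipeline.predict_proba(self._matrix(m))[:, 1]

    def predict(self, m: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(m) >= self.threshold).astype(int)


@dataclass
class CVReport:
    per_fold: list[MetricsReport]
    aggregate: MetricsReport
    best_params: dict
    seed: int


def train_cv(
    m: pd.DataFrame,
    labels,
    algorithm: str = "XGB",
    grid: Mapping | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[ModelBundle, CVReport]:
    """Grid-searched, five-fold cross-validated training.

    The best grid point by mean out-of-fold AUC is refit on all data;
    normalization (min-max) lives inside the pipeline so it is fit on the
    training portion of every fold. The report's aggregate metrics are
    computed on pooled out-of-fold predictions of the best configuration.
    """
    reg = _registry(seed)
    if algorithm not in reg:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(reg)}")
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() < 5 or (y == 0).sum() < 5:
        raise ValueError("need at least 5 samples per class for 5-fold CV")
    X = m.to_numpy()
    est, default_grid = reg[algorithm]
    grid = dict(grid) if grid is not None else default_grid
    pipe = Pipeline([("scale", MinMaxScaler()), ("clf", est)])
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, n_jobs=1, refit=True)
    search.fit(X, y)
    best_pipe = search.best_estimator_

    oof = cross_val_predict(best_pipe, X, y, cv=cv, method="predict_proba")[:, 1]
    per_fold = []
    for tr, te in cv.split(X, y):
        per_fold.append(evaluate_metrics(oof[te], y[te], threshold))
    aggregate = evaluate_metrics(oof, y, threshold)
    bundle = ModelBundle(
        algorithm=algorithm,
        hyperparameters={k.removeprefix("clf__"): v for k, v in search.best_params_.items()
                         if k.startswith("clf__")},
        pipeline=best_pipe,
        feature_names=list(m.columns),
        families=list(m.attrs.get("families", [])),
        family_params=dict(m.attrs.get("params", {})),
        threshold=threshold,
    )
    report = CVReport(per_fold=per_fold, aggregate=aggregate,
                      best_params=dict(search.best_params_), seed=seed)
    return bundle, report


# ----------------------------------------------------------- feature selection
def l1_select(m: pd.DataFrame, labels, C: float = 1.0, seed: int = 0) -> list[str]:
    """Features with nonzero coefficients in an L1-penalized linear SVC
    fit on the min-max normalized matrix."""
    y = np.asarray(labels, dtype=int)
    X = MinMaxScaler().fit_transform(m.to_numpy())
    svc = LinearSVC(penalty="l1", dual=False, C=C, max_iter=20000, random_state=seed)
    svc.fit(X, y)
    coef = np.abs(svc.coef_).ravel()
    selected = [c for c, w in zip(m.columns, coef) if w > 1e-10]
    if not selected:
        import warnings

        warnings.warn("L1 selection returned no features (penalty too strong)")
    return selected


def _binned_mi(a: np.ndarray, b: np.ndarray, bins: int = 10) -> float:
    def disc(v):
        v = np.asarray(v, dtype=float)
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros(len(v), dtype=int)
        edges = np.linspace(lo, hi, bins + 1)
        return np.clip(np.digitize(v, edges[1:-1]), 0, bins - 1)

    return float(mutual_info_score(disc(a), disc(b)))


def mrmr_select(m: pd.DataFrame, labels, n_select: int, bins: int = 10) -> list[str]:
    """Greedy minimum-redundancy / maximum-relevance selection.

    Relevance and redundancy are mutual information on equal-width-binned
    values (MID variant: relevance minus mean redundancy with the already
    selected set). The first pick is the most label-relevant feature.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    if n_select > m.shape[1]:
        raise ValueError("n_select exceeds the number of features")
    y = np.asarray(labels, dtype=int)
    cols = list(m.columns)
    data = {c: m[c].to_numpy() for c in cols}
    relevance = {c: _binned_mi(data[c], y, bins) for c in cols}
    selected: list[str] = []
    remaining = set(cols)
    red_cache: dict[str, float] = {c: 0.0 for c in cols}
    while len(selected) < n_select:
        best, best_score = None, -np.inf
        for c in sorted(remaining):
            redundancy = red_cache[c] / len(selected) if selected else 0.0
            score = relevance[c] - redundancy
            if score > best_score + 1e-15:
                best, best_score = c, score
        selected.append(best)
        remaining.discard(best)
        for c in remaining:
            red_cache[c] += _binned_mi(data[c], data[best], bins)
    return selected


def write_metrics_table(reports: Mapping[str, MetricsReport], path) -> None:
    cols = ["Sensitivity", "Specificity", "Accuracy", "AUC", "Kappa", "MCC"]
    with open(path, "w") as fh:
        fh.write("Model\t" + "\t".join(cols) + "\n")
        for name, r in reports.items():
            fh.write(
                f"{name}\t{r.sensitivity:.2f}\t{r.specificity:.2f}\t"
                f"{r.accuracy:.2f}\t{r.auc:.2f}\t{r.kappa:.2f}\t{r.mcc:.2f}\n"
            )
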