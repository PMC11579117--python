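"""Confusion matrices, macro-averaged metrics, per-domain reports, baselines.

Metrics follow the macro-averaging convention: per-class precision, recall
and F1 are averaged with equal class weight, and undefined 0/0 ratios are
set to 0 with a warning.  Risk is 1 - accuracy; computed on the
target-domain test partition it is the empirical target risk the
domain-adaptive classifier is designed to lower.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import DataSplit, feature_columns

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float

    @property
    def risk(self) -> float:
        """1 - accuracy; the empirical misclassification risk."""
        return 1.0 - self.accuracy

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "risk": self.risk,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class_precision": self.precision.tolist(),
            "per_class_recall": self.recall.tolist(),
            "per_class_f1": self.f1.tolist(),
            "confusion": self.confusion.tolist(),
        }


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (y_true, y_pred), 1)
    return mat


def normalize_confusion(mat: np.ndarray, by: str = "true") -> np.ndarray:
    """Normalized view: ``by='true'`` divides each true-class row by its total
    (the convention of the study's subclass confusion figure); ``by='total'``
    divides by the grand total."""
    mat = np.asarray(mat, dtype=float)
    if by == "true":
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, mat / sums, 0.0)
        return out
    if by == "total":
        total = mat.sum()
        return mat / total if total else mat
    raise ValueError("by must be 'true' or 'total'")


def metrics(mat: np.ndarray) -> MetricsReport:
    """Macro-averaged metrics from a confusion matrix (0/0 ratios -> 0)."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = mat.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero; nothing was evaluated")
    tp = np.diag(mat).astype(float)
    pred_tot = mat.sum(axis=0).astype(float)
    true_tot = mat.sum(axis=1).astype(float)
    if np.any(pred_tot == 0) or np.any(true_tot == 0):
        warnings.warn("a class is never predicted or never true; its 0/0 "
                      "precision/recall is set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    return MetricsReport(
        confusion=mat,
        accuracy=float(tp.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


def score_labels(y_true, y_pred, n_classes: int | None = None) -> MetricsReport:
    """Convenience: metrics(confusion(...)) in one call."""
    if n_classes is None:
        n_classes = int(max(np.max(y_true), np.max(y_pred))) + 1
    return metrics(confusion(y_true, y_pred, n_classes))


def evaluate_per_domain(model, data: DataSplit, partition: str = "test") -> dict:
    """Per-organism metrics of one joint model on a partition.

    Returns ``{organism: MetricsReport}``; an organism absent from the
    partition is omitted with a warning.
    """
    table = getattr(data, partition)
    feats = feature_columns(table)
    reports = {}
    for dom in ("mouse", "human"):
        sub = table[table["organism"] == dom]
        if sub.empty:
            warnings.warn(f"domain {dom!r} absent from {partition}; omitted",
                          stacklevel=2)
            continue
        y_true = sub["broad_label"].to_numpy(dtype=int)
        y_pred = np.asarray(model.predict(sub[feats].to_numpy(dtype=float)), dtype=int)
        reports[dom] = score_labels(y_true, y_pred, n_classes=2)
    for dom in table["organism"].unique():
        if dom not in reports and dom not in ("mouse", "human"):
            sub = table[table["organism"] == dom]
            y_true = sub["broad_label"].to_numpy(dtype=int)
            y_pred = np.asarray(
                model.predict(sub[feats].to_numpy(dtype=float)), dtype=int
            )
            reports[dom] = score_labels(y_true, y_pred, n_classes=2)
    return reports


def cross_domain_ablation(cfg, data: DataSplit) -> dict:
    """Train a plain (non-adversarial) classifier on one organism only and
    test on the other, in both directions.

    Mirrors the ablation that exposes the species shift: a model fit on one
    species alone transfers poorly to the other.  Returns, per direction,
    the within-domain and transfer reports and the accuracy gap.
    """
    from .dann import DANNClassifier, _config_to_estimator_params

    feats = feature_columns(data.train)
    domains = sorted(data.train["organism"].unique())
    if len(domains) < 2:
        raise ValueError("cross-domain ablation needs both organisms in train")
    out = {}
    for src in domains:
        tgt = [d for d in domains if d != src][0]
        params = _config_to_estimator_params(cfg)
        params["lambda_"] = 0.0
        est = DANNClassifier(**params)
        tr = data.train[data.train["organism"] == src]
        est.fit(
            tr[feats].to_numpy(dtype=float),
            tr["broad_label"].to_numpy(dtype=int),
            domain=np.zeros(len(tr), dtype=int),
            check_domains=False,
        )
        reports = evaluate_per_domain(est, data)
        if src in reports and tgt in reports:
            out[f"{src}->{tgt}"] = {
                "within": reports[src],
                "transfer": reports[tgt],
                "gap": reports[src].accuracy - reports[tgt].accuracy,
            }
    return out


def fcnn_baseline(cfg, data: DataSplit, include_organism_feature: bool = False):
    """Non-adversarial counterpart trained on pooled data (lambda = 0).

    With ``include_organism_feature`` a binary organism indicator
    (0 = mouse, 1 = human) is appended as feature D+1.  Returns
    (fitted estimator, per-domain reports).
    """
    from .dann import DANNClassifier, _config_to_estimator_params, domain_codes

    feats = feature_columns(data.train)
    params = _config_to_estimator_params(cfg)
    params["lambda_"] = 0.0
    est = DANNClassifier(**params)

    def _X(table):
        X = table[feats].to_numpy(dtype=float)
        if include_organism_feature:
            X = np.column_stack([X, domain_codes(table["organism"])])
        return X

    est.fit(
        _X(data.train),
        data.train["broad_label"].to_numpy(dtype=int),
        domain=domain_codes(data.train["organism"]),
        check_domains=False,
    )
    reports = {}
    for dom in sorted(data.test["organism"].unique()):
        sub = data.test[data.test["organism"] == dom]
        y_pred = est.predict(_X(sub))
        reports[dom] = score_labels(
            sub["broad_label"].to_numpy(dtype=int), y_pred, n_classes=2
        )
    return est, reports


def classical_baselines(data: DataSplit, label_column: str = "subclass_label") -> dict:
    """Comparison hooks around established classifiers (RF / SVC; XGBoost if
    installed).  Conveniences for side-by-side tables, not part of the
    method."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC

    feats = feature_columns(data.train)
    Xtr = data.train[feats].to_numpy(dtype=float)
    ytr = pd.factorize(data.train[label_column], sort=True)[0]
    cats = pd.unique(np.sort(data.train[label_column]))
    Xte = data.test[feats].to_numpy(dtype=float)
    yte = pd.Categorical(data.test[label_column], categories=cats).codes
    models = {
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=0),
        "svc": SVC(random_state=0),
    }
    try:
        from xgboost import XGBClassifier

        models["xgboost"] = XGBClassifier(random_state=0, n_estimators=200)
    except ImportError:
        pass
    out = {}
    for name, model in models.items():
        model.fit(Xtr, ytr)
        out[name] = score_labels(yte, model.predict(Xte), n_classes=len(cats))
    return out
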