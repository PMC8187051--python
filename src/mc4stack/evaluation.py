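"""Binary-classifier evaluation: ACC, MCC, Sn, Sp, ROC/AUC and the two protocols.

Metric definitions over the confusion counts (TP, FP, TN, FN):

    ACC = (TP + TN) / n
    Sn  = TP / (TP + FN)          (sensitivity — recall of 4mC windows)
    Sp  = TN / (TN + FP)          (specificity — recall of non-4mC windows)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 whenever a denominator factor vanishes (standard
convention).  AUC is the area under the ROC curve, equal to the
Mann-Whitney probability that a random positive outscores a random
negative with ties counted one half.

Two evaluation protocols are provided: pooled k-fold cross-validation
(the full stacking procedure is re-run inside every outer training split,
so the outer folds never leak into base-model selection) and
independent-test validation (fit on one set, evaluate on a disjoint one).
Pooled CV concatenates the out-of-fold predictions and computes the
metrics once, rather than averaging per-fold metrics.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .config import StackConfig
from .sequence_io import WindowSet


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts with the four summary metrics and optional AUC."""

    counts: ConfusionCounts
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: Optional[float] = None
    protocol: str = "independent"  # "cv" | "independent"

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "protocol": self.protocol,
            "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN,
            "acc": self.acc, "sn": self.sn, "sp": self.sp,
            "mcc": self.mcc, "auc": self.auc,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def __str__(self) -> str:
        c = self.counts
        rows = [
            f"protocol : {self.protocol}",
            f"n        : {c.n}  (TP {c.TP}  FP {c.FP}  TN {c.TN}  FN {c.FN})",
            f"ACC      : {self.acc:.4f}",
            f"Sn       : {self.sn:.4f}",
            f"Sp       : {self.sp:.4f}",
            f"MCC      : {self.mcc:.4f}",
        ]
        if self.auc is not None:
            rows.append(f"AUC      : {self.auc:.4f}")
        return "\n".join(rows)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from aligned binary label vectors."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(
    counts: ConfusionCounts,
    auc: Optional[float] = None,
    protocol: str = "independent",
) -> MetricsReport:
    """ACC/Sn/Sp/MCC from confusion counts (degenerate cases well-defined)."""
    TP, FP, TN, FN = counts.TP, counts.FP, counts.TN, counts.FN
    n = counts.n
    acc = (TP + TN) / n
    sn = TP / (TP + FN) if TP + FN else 0.0
    sp = TN / (TN + FP) if TN + FP else 0.0
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = (TP * TN - FP * FN) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(
        counts=counts, acc=acc, sn=sn, sp=sp, mcc=mcc, auc=auc, protocol=protocol
    )


def roc_auc(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[float, np.ndarray]:
    """AUC plus the ROC curve points as an (m, 3) array of (fpr, tpr, threshold).

    The trapezoidal area over the full-resolution ROC curve equals the
    pairwise Mann-Whitney statistic with ties counted one half.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if np.unique(y_true).size < 2:
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, thr = _roc_curve(y_true, scores, drop_intermediate=False)
    return float(_trapezoid_auc(fpr, tpr)), np.column_stack([fpr, tpr, thr])


def write_roc_points(points: np.ndarray, path: str | Path) -> None:
    """Export ROC points as a (fpr, tpr, threshold) TSV for any plotting tool."""
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\tthreshold\n")
        for fpr, tpr, thr in points:
            fh.write(f"{fpr!r}\t{tpr!r}\t{thr!r}\n")


def _encode(ws: WindowSet, config: StackConfig):
    from .encoders import encode_set, get_scheme

    scheme = get_scheme(config.encoder, **config.encoder_params)
    X, y, _ = encode_set(ws, scheme)
    return X, y


def crossvalidate(
    ws: WindowSet,
    config: Optional[StackConfig] = None,
    k: int = 10,
    seed: int = 1,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Pooled k-fold cross-validation of the full stacking pipeline.

    Each outer fold is held out while the complete two-stage stack (with
    its own inner folds) is fitted on the remainder and scores the held-out
    fold through the deployment path.  Out-of-fold predictions are
    concatenated and the metrics computed once; a per-fold breakdown is
    returned alongside.
    """
    from .stacking import StackedEnsembleModel, make_folds

    config = config or StackConfig()
    X, y = _encode(ws, config)
    if y is None:
        raise ValueError("cross-validation requires a labelled WindowSet")
    outer = make_folds(X.shape[0], y, k=k, seed=seed)
    pooled_scores = np.empty(X.shape[0])
    pooled_pred = np.empty(X.shape[0], dtype=int)
    per_fold: list[MetricsReport] = []
    for fold in range(1, k + 1):
        tr = outer.train_indices(fold)
        held = outer.heldout_indices(fold)
        results = StackedEnsembleModel(
            X[tr], y[tr], config=config, encoder_name=config.encoder
        ).fit(seed=seed + fold)
        scores, labels = results.predict(X[held])
        pooled_scores[held] = scores
        pooled_pred[held] = labels
        fold_auc, _ = roc_auc(y[held], scores)
        per_fold.append(
            metrics(confusion(y[held], labels), auc=fold_auc, protocol="cv")
        )
    pooled_auc, _ = roc_auc(y, pooled_scores)
    report = metrics(
        confusion(y, pooled_pred), auc=pooled_auc, protocol="cv"
    )
    return report, per_fold


def independent_test(
    train: WindowSet,
    test: WindowSet,
    config: Optional[StackConfig] = None,
) -> tuple[MetricsReport, "object"]:
    """Fit the stack on ``train``, evaluate on ``test``; returns (report, results).

    Warns (but proceeds) when the two sets share sequences, since the
    protocol is only meaningful on disjoint data.
    """
    config = config or StackConfig()
    if len(test) == 0:
        raise ValueError("empty test set")
    overlap = set(w.seq for w in train) & set(w.seq for w in test)
    if overlap:
        warnings.warn(
            f"train and test sets share {len(overlap)} sequence(s); "
            "independent-test metrics will be optimistic",
            UserWarning,
            stacklevel=2,
        )
    from .stacking import StackedEnsembleModel

    X_train, y_train = _encode(train, config)
    X_test, y_test = _encode(test, config)
    if y_train is None or y_test is None:
        raise ValueError("both WindowSets must be labelled")
    model = StackedEnsembleModel(
        X_train, y_train, config=config, encoder_name=config.encoder
    )
    results = model.fit(X_test=X_test)
    scores = results.meta.score(results.meta_test.values)
    labels = (scores >= config.threshold).astype(int)
    test_auc, _ = roc_auc(y_test, scores)
    report = metrics(
        confusion(y_test, labels), auc=test_auc, protocol="independent"
    )
    return report, results
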