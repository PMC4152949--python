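"""Evaluation protocols and performance metrics.

Metrics follow the usual binary-classification definitions over the
confusion counts (positives = DHS):

    Sn  = TP / (TP + FN)                       sensitivity / recall
    Sp  = TN / (TN + FP)                       specificity
    Acc = (TP + TN) / (TP + FN + TN + FP)      accuracy
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FN)(TP+FP)(TN+FP))

When any factor of the MCC denominator is zero the coefficient is reported
as 0.0 with ``mcc_degenerate=True``.

Two protocols are provided.  The jackknife (leave-one-out) test retrains on
all-but-one sequence and classifies the held-out one, for every sequence in
turn; the encoding and SVM parameters stay frozen throughout (they are
optimized beforehand, by cross-validation, not inside the rounds).  The
k-fold test uses a seeded stratified partition; ``k == N`` degenerates to
leave-one-out and reproduces the jackknife counts exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import EvaluationError
from .io import LabeledDataset
from .properties import PropertyTable
from .psednc import encode_dataset
from .svm import ModelParams, predict, train


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"negative count {name}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == -1) & (y_pred == -1)).sum()),
            fp=int(((y_true == -1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == -1)).sum()),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/Acc as fractions in [0,1], MCC in [-1,1], plus the raw counts."""

    sn: float
    sp: float
    acc: float
    mcc: float
    counts: ConfusionCounts
    protocol: str
    mcc_degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "counts": vars(self.counts),
            "Sn": self.sn,
            "Sp": self.sp,
            "Acc": self.acc,
            "MCC": self.mcc,
            "mcc_degenerate": self.mcc_degenerate,
        }

    def as_percent(self) -> dict:
        """Sn/Sp/Acc as percentages rounded to 2 decimals; MCC to 2 decimals."""
        return {
            "Sn%": round(100.0 * self.sn, 2),
            "Sp%": round(100.0 * self.sp, 2),
            "Acc%": round(100.0 * self.acc, 2),
            "MCC": round(self.mcc, 2),
        }

    def __str__(self) -> str:
        c = self.counts
        pct = self.as_percent()
        return (
            f"{self.protocol}: "
            f"Sn={pct['Sn%']:.2f}%  Sp={pct['Sp%']:.2f}%  "
            f"Acc={pct['Acc%']:.2f}%  MCC={self.mcc:.4f}  "
            f"(TP={c.tp} FN={c.fn} TN={c.tn} FP={c.fp})"
        )


def compute_metrics(counts: ConfusionCounts, protocol: str = "holdout") -> MetricsReport:
    """Derive Sn, Sp, Acc and MCC from confusion counts.

    Class-conditional rates are 0 when the corresponding class is empty;
    a zero factor in the MCC denominator yields MCC = 0 with the degenerate
    flag set.
    """
    if counts.total == 0:
        raise EvaluationError("no evaluated examples (all counts zero)")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts,
        protocol=protocol, mcc_degenerate=degenerate,
    )


def _leave_one_out_counts(X: np.ndarray, y: np.ndarray, params: ModelParams) -> ConfusionCounts:
    n = y.size
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        model = train(X[mask], y[mask], params.C, params.gamma, params=params)
        preds[i] = predict(model, X[i : i + 1])[0][0]
    return ConfusionCounts.from_predictions(y, preds)


def jackknife(
    data: LabeledDataset, params: ModelParams, table: PropertyTable
) -> MetricsReport:
    """Leave-one-out evaluation with (w, lambda, C, gamma) frozen.

    Each sequence is in turn singled out as the test sample and the SVM is
    retrained on the remaining N-1; counts aggregate over all N rounds.
    Fully deterministic.
    """
    if min(data.n_positive, data.n_negative) < 2:
        raise EvaluationError("jackknife needs at least 2 examples per class")
    X, y = encode_dataset(data, w=params.w, lam=params.lam, table=table)
    counts = _leave_one_out_counts(X, y, params)
    return compute_metrics(counts, protocol="jackknife")


def kfold(
    data: LabeledDataset,
    params: ModelParams,
    table: PropertyTable,
    k: int,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold evaluation; ``k == N`` reduces to leave-one-out.

    Folds are assigned by a seeded stratified shuffle, so reports are
    reproducible given (data, params, k, seed).
    """
    n = len(data)
    if k < 2:
        raise EvaluationError(f"k must be >= 2, got {k}")
    X, y = encode_dataset(data, w=params.w, lam=params.lam, table=table)
    if k == n:
        # leave-one-out: stratification is vacuous, protocol equals jackknife
        counts = _leave_one_out_counts(X, y, params)
        return compute_metrics(counts, protocol="kfold")
    n_min = min(data.n_positive, data.n_negative)
    if k > n_min:
        raise EvaluationError(
            f"k ({k}) exceeds the minority class size ({n_min}); "
            f"only k == N = {n} is allowed beyond it (leave-one-out)"
        )
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.empty(n, dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], params.C, params.gamma, params=params)
        preds[test_idx] = predict(model, X[test_idx])[0]
    counts = ConfusionCounts.from_predictions(y, preds)
    return compute_metrics(counts, protocol="kfold")
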