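"""RBF-kernel support vector machine: training, prediction, parameter search.

The classifier is the standard soft-margin SVM with kernel
``K(x, y) = exp(-gamma * ||x - y||^2)``; a sample is called positive when the
decision value ``sum_i y_i alpha_i K(x, x_i) + b`` is >= 0 (ties resolve to
positive).  Training is delegated to scikit-learn's libsvm binding, which is
deterministic for fixed inputs and parameters.

``grid_search`` performs the joint optimization of the encoding parameters
(w, lambda) and the SVM parameters (C, gamma) by stratified k-fold
cross-validated accuracy, encoding the dataset once per (w, lambda) pair.
Ties are broken toward the simplest model: smaller C, then smaller gamma,
then smaller lambda, then smaller w.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import (
    DhspredError,
    DimensionMismatchError,
    EvaluationError,
    ModelIOError,
    TrainingError,
)
from .io import LabeledDataset
from .properties import PropertyTable
from .psednc import encode_dataset

#: default search grids: w and lambda stepped 0.1 / 1, C and gamma on
#: power-of-two ladders 2^-5..2^15 and 2^-15..2^-5
DEFAULT_W_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
DEFAULT_LAMBDA_GRID: tuple[int, ...] = tuple(range(1, 11))
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, -4))


@dataclass(frozen=True)
class ModelParams:
    """The four tunables: encoding weight w, tier count lambda, SVM C, gamma."""

    w: float
    lam: int
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise DhspredError(f"w must lie in [0, 1], got {self.w}")
        if int(self.lam) != self.lam or self.lam < 1:
            raise DhspredError(f"lambda must be an integer >= 1, got {self.lam}")
        object.__setattr__(self, "lam", int(self.lam))
        if self.C <= 0:
            raise DhspredError(f"C must be > 0, got {self.C}")
        if self.gamma <= 0:
            raise DhspredError(f"gamma must be > 0, got {self.gamma}")

    @property
    def feature_dim(self) -> int:
        return 16 + self.lam


@dataclass
class TrainedModel:
    """A fitted SVM plus the parameters and provenance it was trained with."""

    params: ModelParams
    svc: SVC
    feature_dim: int
    table_checksum: str | None = None
    n_training: int = 0


def train(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    params: ModelParams | None = None,
    table_checksum: str | None = None,
) -> TrainedModel:
    """Fit the RBF SVM on a feature matrix with +/-1 labels."""
    if C <= 0 or gamma <= 0:
        raise TrainingError(f"C and gamma must be > 0, got C={C}, gamma={gamma}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError(
            f"feature matrix {X.shape} incompatible with {y.shape[0]} labels"
        )
    classes = np.unique(y)
    if not np.array_equal(classes, [-1, 1]):
        raise TrainingError(
            f"training needs both classes (+1 and -1); got classes {classes.tolist()}"
        )
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    svc.fit(X, y)
    return TrainedModel(
        params=params
        if params is not None
        else ModelParams(w=0.0, lam=max(X.shape[1] - 16, 1), C=C, gamma=gamma),
        svc=svc,
        feature_dim=X.shape[1],
        table_checksum=table_checksum,
        n_training=X.shape[0],
    )


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted +/-1 labels and raw decision values for each row.

    A decision value of exactly zero is resolved to the positive class.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_dim:
        actual = X.shape[1] if X.ndim == 2 else None
        raise DimensionMismatchError(
            f"expected {model.feature_dim} feature columns, got {actual}"
        )
    decision = model.svc.decision_function(X)
    labels = np.where(decision >= 0.0, 1, -1)
    return labels, decision


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float, folds: int, seed: int
) -> float:
    """Aggregate stratified k-fold accuracy for one (C, gamma) point."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], C, gamma)
        pred, _ = predict(model, X[test_idx])
        correct += int((pred == y[test_idx]).sum())
    return correct / y.size


@dataclass
class GridSearchResult:
    best: ModelParams
    best_accuracy: float
    table: pd.DataFrame = field(repr=False)  # columns: w, lam, C, gamma, cv_accuracy


def grid_search(
    data: LabeledDataset,
    table: PropertyTable,
    w_grid: Sequence[float] = DEFAULT_W_GRID,
    lambda_grid: Sequence[int] = DEFAULT_LAMBDA_GRID,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Joint (w, lambda, C, gamma) optimization by stratified k-fold CV accuracy.

    For each (w, lambda) the dataset is encoded once; every (C, gamma) point
    is then scored by aggregate cross-validated accuracy.  The returned
    argmax is invariant to grid enumeration order: ties prefer smaller C,
    then gamma, then lambda, then w.
    """
    n_min = min(data.n_positive, data.n_negative)
    if folds < 2:
        raise EvaluationError(f"folds must be >= 2, got {folds}")
    if folds > n_min:
        raise EvaluationError(
            f"folds ({folds}) exceeds the minority class size ({n_min})"
        )
    records = []
    for lam in lambda_grid:
        for w in w_grid:
            X, y = encode_dataset(data, w=w, lam=lam, table=table)
            for C in C_grid:
                for gamma in gamma_grid:
                    acc = _cv_accuracy(X, y, C, gamma, folds, seed)
                    records.append(
                        {"w": w, "lam": lam, "C": C, "gamma": gamma, "cv_accuracy": acc}
                    )
    result = pd.DataFrame.from_records(records)
    ranked = result.sort_values(
        by=["cv_accuracy", "C", "gamma", "lam", "w"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    )
    top = ranked.iloc[0]
    best = ModelParams(w=float(top.w), lam=int(top.lam), C=float(top.C), gamma=float(top.gamma))
    return GridSearchResult(best=best, best_accuracy=float(top.cv_accuracy), table=result)


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model (parameters, provenance, solver state)."""
    joblib.dump(
        {
            "format": "dhspred-model",
            "version": 1,
            "params": {
                "w": model.params.w,
                "lam": model.params.lam,
                "C": model.params.C,
                "gamma": model.params.gamma,
            },
            "feature_dim": model.feature_dim,
            "table_checksum": model.table_checksum,
            "n_training": model.n_training,
            "svc": model.svc,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # unreadable archive
        raise ModelIOError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "dhspred-model":
        raise ModelIOError(f"{path} is not a dhspred model archive")
    return TrainedModel(
        params=ModelParams(**payload["params"]),
        svc=payload["svc"],
        feature_dim=payload["feature_dim"],
        table_checksum=payload["table_checksum"],
        n_training=payload["n_training"],
    )


def check_table_compatibility(model: TrainedModel, table: PropertyTable) -> None:
    """Refuse prediction when the property table differs from training time."""
    if model.table_checksum is not None and table.checksum() != model.table_checksum:
        raise ModelIOError(
            "property table checksum does not match the one the model was "
            "trained with; predictions would be computed in a different "
            "feature space"
        )
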