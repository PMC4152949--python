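"""Model/Results facade over the DHS prediction pipeline.

`DHSModel` bundles a labeled dataset with the encoding and SVM parameters;
``fit()`` trains the classifier and returns a :class:`DHSResults` carrying
the trained state, apparent (training) performance, and methods for honest
evaluation (jackknife / k-fold), prediction on new sequences, and a
``summary()`` table.

    >>> data = generate_dataset(GeneratorConfig(n_pos=50, n_neg=50, delta=3.0))
    >>> res = DHSModel(data).fit()
    >>> print(res.summary())                       # doctest: +SKIP
    >>> res.jackknife().as_percent()               # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, svm
from .io import LabeledDataset, read_fasta, merge_datasets, POSITIVE, NEGATIVE
from .properties import PropertyTable, default_table
from .psednc import encode_dataset
from .svm import GridSearchResult, ModelParams, TrainedModel


class DHSModel:
    """A DHS classifier specification bound to a training dataset.

    Defaults are the optimized operating point of the method:
    w = 0.2, lambda = 6, C = 512, gamma = 2**-7.
    """

    def __init__(
        self,
        data: LabeledDataset,
        w: float = 0.2,
        lam: int = 6,
        C: float = 512.0,
        gamma: float = 2.0**-7,
        property_table: PropertyTable | None = None,
    ):
        self.data = data
        self.params = ModelParams(w=w, lam=lam, C=C, gamma=gamma)
        self.property_table = property_table if property_table is not None else default_table()

    @classmethod
    def from_fasta(
        cls,
        positives: str | Path,
        negatives: str | Path,
        drop_ambiguous: bool = False,
        **kwargs,
    ) -> "DHSModel":
        """Build the model from one FASTA per class."""
        pos = read_fasta(positives, label=POSITIVE, drop_ambiguous=drop_ambiguous)
        neg = read_fasta(negatives, label=NEGATIVE, drop_ambiguous=drop_ambiguous)
        return cls(merge_datasets(pos, neg), **kwargs)

    def encode(self) -> tuple[np.ndarray, np.ndarray]:
        """PseDNC feature matrix and +/-1 label vector for the dataset."""
        return encode_dataset(
            self.data, w=self.params.w, lam=self.params.lam, table=self.property_table
        )

    def fit(self) -> "DHSResults":
        """Train the RBF SVM at the model's parameters."""
        X, y = self.encode()
        trained = svm.train(
            X,
            y,
            C=self.params.C,
            gamma=self.params.gamma,
            params=self.params,
            table_checksum=self.property_table.checksum(),
        )
        pred, _ = svm.predict(trained, X)
        counts = evaluation.ConfusionCounts.from_predictions(y, pred)
        training_report = evaluation.compute_metrics(counts, protocol="training")
        return DHSResults(model=self, trained=trained, training_report=training_report)

    def select_parameters(
        self,
        w_grid=svm.DEFAULT_W_GRID,
        lambda_grid=svm.DEFAULT_LAMBDA_GRID,
        C_grid=svm.DEFAULT_C_GRID,
        gamma_grid=svm.DEFAULT_GAMMA_GRID,
        folds: int = 5,
        seed: int = 0,
    ) -> GridSearchResult:
        """Joint (w, lambda, C, gamma) grid search by stratified k-fold CV.

        Returns the search result and re-binds this model's parameters to
        the argmax, so a subsequent ``fit()`` uses them.
        """
        result = svm.grid_search(
            self.data,
            self.property_table,
            w_grid=w_grid,
            lambda_grid=lambda_grid,
            C_grid=C_grid,
            gamma_grid=gamma_grid,
            folds=folds,
            seed=seed,
        )
        self.params = result.best
        return result


@dataclass
class DHSResults:
    """Fitted-model results: trained state, diagnostics, evaluation methods."""

    model: DHSModel
    trained: TrainedModel
    training_report: evaluation.MetricsReport
    _jackknife_cache: evaluation.MetricsReport | None = field(default=None, repr=False)

    @property
    def params(self) -> ModelParams:
        return self.trained.params

    @property
    def n_support(self) -> int:
        return int(self.trained.svc.n_support_.sum())

    def predict(self, data: LabeledDataset) -> pd.DataFrame:
        """Per-sequence predicted label and decision value for new sequences."""
        svm.check_table_compatibility(self.trained, self.model.property_table)
        X, _ = encode_dataset(
            data, w=self.params.w, lam=self.params.lam, table=self.model.property_table
        )
        labels, decision = svm.predict(self.trained, X)
        return pd.DataFrame(
            {
                "id": data.ids,
                "predicted_label": [POSITIVE if l == 1 else NEGATIVE for l in labels],
                "decision_value": decision,
            }
        )

    def jackknife(self) -> evaluation.MetricsReport:
        """Leave-one-out evaluation on the training dataset (cached)."""
        if self._jackknife_cache is None:
            self._jackknife_cache = evaluation.jackknife(
                self.model.data, self.params, self.model.property_table
            )
        return self._jackknife_cache

    def kfold(self, k: int, seed: int = 0) -> evaluation.MetricsReport:
        return evaluation.kfold(
            self.model.data, self.params, self.model.property_table, k=k, seed=seed
        )

    def save(self, path: str | Path) -> None:
        svm.save_model(self.trained, path)

    def summary(self, jackknife: bool = False) -> str:
        """Human-readable results table, statsmodels-style."""
        data = self.model.data
        t = self.training_report
        lines = [
            "                 DHS classifier (PseDNC + RBF-SVM)",
            "=" * 66,
            f"Dataset:        {data.name or '<unnamed>'}",
            f"  sequences     {len(data)}  ({data.n_positive} DHS / {data.n_negative} non-DHS)",
            f"Encoding:       w = {self.params.w:g}, lambda = {self.params.lam}"
            f"  ->  {self.params.feature_dim} features",
            f"SVM:            RBF kernel, C = {self.params.C:g}, gamma = {self.params.gamma:g}",
            f"  support vecs  {self.n_support}",
            "-" * 66,
            f"Training (apparent):  Sn={100 * t.sn:.2f}%  Sp={100 * t.sp:.2f}%  "
            f"Acc={100 * t.acc:.2f}%  MCC={t.mcc:.4f}",
        ]
        if jackknife:
            j = self.jackknife()
            lines.append(
                f"Jackknife (LOO):      Sn={100 * j.sn:.2f}%  Sp={100 * j.sp:.2f}%  "
                f"Acc={100 * j.acc:.2f}%  MCC={j.mcc:.4f}"
            )
        lines.append("=" * 66)
        return "\n".join(lines)
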