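"""Model-object interface: build from data, fit, inspect results.

`AdmetGNN` follows the fit/results convention of statistical modelling
libraries: the model object is constructed from a dataset (SMILES plus
labels, e.g. via :meth:`AdmetGNN.from_dataframe`), ``fit()`` trains one
network with validation-based epoch selection and returns an
:class:`AdmetGNNResults` carrying the fitted network, the training curve and
held-out metrics, and ``cross_validate()`` runs the full five-fold protocol
returning a :class:`~admetgnn.crossval.CVReport`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .crossval import (CVReport, TrainConfig, TrainRecord, run_cross_validation,
                       train_model)
from .losses import class_weights, density_weights
from .metrics import auprc_baseline, classification_metrics, regression_metrics
from .model import GNNModel, ModelConfig, assemble_model
from .molgraph import FeatureVocabulary, GraphBatch, parse_smiles


class AdmetGNN:
    """A bottom-up graph attention model bound to one dataset.

    Parameters
    ----------
    smiles, labels
        The training corpus: SMILES strings and scalar labels (continuous
        for regression, 0/1 for classification).
    config
        Architecture hyperparameters; defaults build the complete
        (substructure-branch) variant.
    """

    def __init__(self, smiles, labels, config: ModelConfig | None = None,
                 vocab: FeatureVocabulary | None = None):
        self.smiles = list(smiles)
        self.labels = np.asarray(labels, dtype=float)
        if len(self.smiles) != self.labels.size:
            raise ValueError("smiles and labels must have equal length")
        self.config = config or ModelConfig()
        self.vocab = vocab or FeatureVocabulary()
        self.n_max = max(parse_smiles(s).n_atoms for s in self.smiles)
        self._batch: GraphBatch | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, smiles_col: str = "smiles",
                       label_col: str = "label",
                       config: ModelConfig | None = None) -> "AdmetGNN":
        return cls(df[smiles_col].tolist(), df[label_col].to_numpy(), config)

    @property
    def batch(self) -> GraphBatch:
        if self._batch is None:
            self._batch = GraphBatch.from_smiles(self.smiles, self.vocab, self.n_max)
        return self._batch

    @property
    def is_classification(self) -> bool:
        return self.config.task == "binary_classification"

    def fit(self, epochs: int = 100, val_fraction: float = 0.2,
            learning_rate: float = 1e-3, batch_size: int = 32,
            loss: str = "weighted", alpha: float = 0.55,
            seed: int = 0) -> "AdmetGNNResults":
        """Train one network on a train/validation split of the dataset.

        The validation fraction is held out (stratified for classification),
        per-sample loss weights are computed on the training split only, and
        the epoch with the best validation score is restored.
        """
        idx = np.arange(len(self.smiles))
        strat = self.labels.astype(int) if self.is_classification else None
        train_idx, val_idx = train_test_split(idx, test_size=val_fraction,
                                              random_state=seed, stratify=strat)
        y_tr = self.labels[train_idx]
        if loss == "weighted":
            weights = (class_weights(y_tr).per_sample(y_tr)
                       if self.is_classification
                       else density_weights(y_tr, alpha).weights)
        else:
            weights = None
        network = assemble_model(self.config, self.vocab.feature_length,
                                 self.n_max, self.vocab)
        network, records = train_model(
            network, self.batch.subset(train_idx), y_tr,
            self.batch.subset(val_idx), self.labels[val_idx],
            sample_weights=weights, learning_rate=learning_rate,
            batch_size=batch_size, epochs=epochs, seed=seed)
        return AdmetGNNResults(self, network, records, val_idx)

    def cross_validate(self, train_config: TrainConfig | None = None) -> CVReport:
        """Five-fold cross-validation with per-fold validation selection."""
        return run_cross_validation(self.smiles, self.labels, self.config,
                                    train_config, self.vocab)


class AdmetGNNResults:
    """Fitted-model container: network, training curve, validation metrics."""

    def __init__(self, model: AdmetGNN, network: GNNModel,
                 records: list[TrainRecord], val_indices: np.ndarray):
        self.model = model
        self.network = network
        self.records = records
        self.val_indices = np.asarray(val_indices)

    @property
    def training_curve(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    @property
    def selected_epoch(self) -> int:
        return next(r.epoch for r in self.records if r.selected)

    def predict(self, smiles) -> np.ndarray:
        """Predictions for new SMILES (probabilities for classification)."""
        batch = GraphBatch.from_smiles(list(smiles), self.model.vocab,
                                       self.model.n_max)
        return self.network.predict(batch)

    def validation_metrics(self) -> dict[str, float]:
        y = self.model.labels[self.val_indices]
        preds = self.network.predict(self.model.batch.subset(self.val_indices))
        if self.model.is_classification:
            return classification_metrics(y, preds)
        return regression_metrics(y, preds)

    def summary(self) -> str:
        cfg = self.model.config
        metrics = self.validation_metrics()
        lines = [
            "Bottom-up graph attention network",
            "=" * 46,
            f"variant:            {cfg.variant}",
            f"task:               {cfg.task}",
            f"n molecules:        {len(self.model.smiles)}",
            f"n_max (padding):    {self.model.n_max}",
            f"trainable params:   {self.network.n_parameters}",
            f"epochs run:         {len(self.records)}",
            f"selected epoch:     {self.selected_epoch}",
            "-" * 46,
        ]
        lines += [f"val {name:<16} {value:.4f}" for name, value in metrics.items()]
        if self.model.is_classification:
            baseline = auprc_baseline(self.model.labels[self.val_indices])
            lines.append(f"val {'auprc_baseline':<16} {baseline:.4f}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        self.network.save(directory, provenance={
            "selected_epoch": self.selected_epoch,
            "epochs": len(self.records),
        })
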