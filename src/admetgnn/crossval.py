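"""Five-fold cross-validation protocol with validation-based model selection.

Each of the five steps holds out one fold as an external test set; 20% of
the remaining data is drawn (stratified for classification) as a validation
set, the rest trains the network.  After every epoch the model is scored on
the validation set — RMSE for regression (minimized), AUPRC for
classification (maximized) — and the weights of the best epoch are restored
at the end of training.  Fold metrics are aggregated as median and standard
deviation over the five values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .losses import (ClassWeighting, DegenerateTargetError, class_weights,
                     density_weights, weighted_bce_loss, weighted_rmse_loss)
from .metrics import classification_metrics, regression_metrics
from .model import GNNModel, ModelConfig, assemble_model
from .molgraph import FeatureVocabulary, GraphBatch, parse_smiles


@dataclass(frozen=True)
class FoldPlan:
    fold_id: int                 # 1-based
    train_indices: np.ndarray
    val_indices: np.ndarray
    test_indices: np.ndarray


@dataclass
class TrainRecord:
    epoch: int
    train_loss: float
    val_metric: float
    selected: bool = False


@dataclass
class TrainConfig:
    """Optimization settings: Adam with fixed learning rate, mini-batches,
    full-epoch training with best-epoch checkpoint selection (no early stop)."""

    loss: str = "weighted"       # "weighted" or "plain"
    alpha: float = 0.55          # density-weighting design parameter
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    folds: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(vars(self))


class DivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


def split_cv(n: int, labels=None, seed: int = 0, n_folds: int = 5,
             val_fraction: float = 0.2) -> list[FoldPlan]:
    """Partition ``n`` samples into test folds plus per-fold train/val splits.

    Stratified on ``labels`` when given (classification); plain random
    otherwise.  The validation draw is seeded per fold as ``seed + fold_id``.
    """
    if n < 2 * n_folds:
        raise ValueError(f"dataset of size {n} too small for {n_folds}-fold CV")
    indices = np.arange(n)
    if labels is not None:
        labels = np.asarray(labels).astype(int)
        if len(np.unique(labels)) < 2:
            raise DegenerateTargetError("stratified CV needs both classes present")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(indices, labels)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(indices)
    plans = []
    for fold_id, (rest, test) in enumerate(split_iter, start=1):
        n_val = int(round(val_fraction * rest.size))
        strat = labels[rest] if labels is not None else None
        train, val = train_test_split(rest, test_size=n_val,
                                      random_state=seed + fold_id,
                                      stratify=strat)
        plans.append(FoldPlan(fold_id=fold_id,
                              train_indices=np.sort(train),
                              val_indices=np.sort(val),
                              test_indices=np.sort(test)))
    return plans


class Adam:
    """Adam optimizer over a list of autodiff parameters."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _val_score(model: GNNModel, batch: GraphBatch, y: np.ndarray) -> float:
    preds = model.predict(batch)
    if model.config.task == "regression":
        return regression_metrics(y, preds)["rmse"]
    return classification_metrics(y, preds)["auprc"]


def train_model(model: GNNModel, train_batch: GraphBatch, y_train: np.ndarray,
                val_batch: GraphBatch, y_val: np.ndarray,
                sample_weights: np.ndarray | None = None,
                learning_rate: float = 1e-3, batch_size: int = 32,
                epochs: int = 100, seed: int = 0,
                ) -> tuple[GNNModel, list[TrainRecord]]:
    """Mini-batch Adam training with best-epoch weight restoration.

    The validation metric is RMSE (minimized) for regression and AUPRC
    (maximized) for classification; per-sample loss weights are supplied by
    the caller, computed on the training split only.
    """
    y_train = np.asarray(y_train, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32)
    if sample_weights is None:
        sample_weights = np.ones_like(y_train)
    is_regression = model.config.task == "regression"
    loss_fn = weighted_rmse_loss if is_regression else weighted_bce_loss
    sign = 1.0 if is_regression else -1.0     # minimize RMSE, maximize AUPRC

    optimizer = Adam(model.parameters(), lr=learning_rate)
    rng = np.random.default_rng(seed)
    records: list[TrainRecord] = []
    best_score = np.inf
    best_weights = model.get_weights()
    best_bn = (model.batchnorm.running_mean.copy(),
               model.batchnorm.running_var.copy())

    n = len(train_batch)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            preds = model.forward(train_batch.subset(idx), training=True)
            loss = loss_fn(preds, y_train[idx], sample_weights[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(epoch)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * idx.size
        val = _val_score(model, val_batch, y_val)
        records.append(TrainRecord(epoch=epoch, train_loss=epoch_loss / n,
                                   val_metric=val))
        if sign * val < best_score:
            best_score = sign * val
            best_weights = model.get_weights()
            best_bn = (model.batchnorm.running_mean.copy(),
                       model.batchnorm.running_var.copy())
            best_epoch = epoch
    model.set_weights(best_weights)
    model.batchnorm.running_mean, model.batchnorm.running_var = best_bn
    for rec in records:
        rec.selected = rec.epoch == best_epoch
    return model, records


@dataclass
class CVReport:
    """Per-fold metrics with median/SD aggregation and the run's provenance."""

    fold_metrics: pd.DataFrame          # one row per fold
    config: dict
    seeds: dict
    curves: list[pd.DataFrame] = field(default_factory=list)

    @property
    def summary(self) -> pd.DataFrame:
        metrics = self.fold_metrics.drop(columns=["fold"])
        return pd.DataFrame({"median": metrics.median(),
                             "sd": metrics.std(ddof=1)})

    def to_json(self) -> str:
        return json.dumps({
            "fold_metrics": self.fold_metrics.to_dict(orient="records"),
            "summary": {m: {"median": float(r["median"]), "sd": float(r["sd"])}
                        for m, r in self.summary.iterrows()},
            "config": self.config,
            "seeds": self.seeds,
        }, indent=2)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "cv_report.json").write_text(self.to_json())
        self.fold_metrics.to_csv(directory / "fold_metrics.csv", index=False)
        for i, curve in enumerate(self.curves, start=1):
            curve.to_csv(directory / f"training_curve_fold{i}.csv", index=False)


def run_cross_validation(smiles, labels, model_config: ModelConfig,
                         train_config: TrainConfig | None = None,
                         vocab: FeatureVocabulary | None = None) -> CVReport:
    """The full evaluation protocol on one dataset.

    Featurizes the corpus once (n_max = dataset-wide maximum heavy-atom
    count), then for each fold computes loss weights on the fold's training
    targets, trains with best-epoch selection, and scores the held-out test
    fold.  Returns per-fold metrics with median/SD aggregation.
    """
    train_config = train_config or TrainConfig()
    vocab = vocab or FeatureVocabulary()
    smiles = list(smiles)
    y = np.asarray(labels, dtype=float)
    is_classification = model_config.task == "binary_classification"

    n_max = max(parse_smiles(s).n_atoms for s in smiles)
    batch = GraphBatch.from_smiles(smiles, vocab, n_max)

    plans = split_cv(len(smiles), labels=y if is_classification else None,
                     seed=train_config.seed, n_folds=train_config.folds)
    rows, curves = [], []
    for plan in plans:
        cfg = ModelConfig(**{**model_config.to_dict(),
                             "seed": model_config.seed + plan.fold_id})
        model = assemble_model(cfg, vocab.feature_length, n_max, vocab)
        y_tr = y[plan.train_indices]
        if is_classification:
            weights = class_weights(y_tr).per_sample(y_tr) \
                if train_config.loss == "weighted" else None
        else:
            weights = density_weights(y_tr, train_config.alpha).weights \
                if train_config.loss == "weighted" else None
        model, records = train_model(
            model,
            batch.subset(plan.train_indices), y_tr,
            batch.subset(plan.val_indices), y[plan.val_indices],
            sample_weights=weights,
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            epochs=train_config.epochs,
            seed=train_config.seed + plan.fold_id,
        )
        preds = model.predict(batch.subset(plan.test_indices))
        y_te = y[plan.test_indices]
        metrics = (classification_metrics(y_te, preds) if is_classification
                   else regression_metrics(y_te, preds))
        rows.append({"fold": plan.fold_id, **metrics})
        curves.append(pd.DataFrame([vars(r) for r in records]))
    return CVReport(
        fold_metrics=pd.DataFrame(rows),
        config={"model": model_config.to_dict(), "training": train_config.to_dict(),
                "n_max": n_max},
        seeds={"cv": train_config.seed,
               "folds": [train_config.seed + p.fold_id for p in plans]},
        curves=curves,
    )
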