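"""Assembly of the three bottom-up GNN variants.

The *complete* network processes a molecule in three stages:

* Module 1 — four parallel substructure branches, one per bond class
  (single, double, triple, aromatic).  Each branch runs a concatenating
  multi-head attention layer followed by an averaging one over that class's
  adjacency matrix, and the branches are fused by a masked sum gated on
  substructure membership.
* Module 2 — a concatenating multi-head attention layer over the
  full-molecule adjacency, followed by a gated global attention pooling that
  reduces node features to one molecule-level vector.
* Module 3 — batch normalization and a small MLP ending in one output unit
  (sigmoid for classification, identity for regression).

The *whole-molecule* ablation drops Module 1 entirely; the *convolutional*
ablation replaces Module 2's attention with a symmetric-normalized graph
convolution of equal output width (strictly fewer parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import (BatchNorm, Dense, GlobalAttentionPool, GraphConvolution,
                     Layer, MultiHeadAttention, masked_sum)
from .molgraph import BOND_CLASSES, FeatureVocabulary, GraphBatch

VARIANTS = ("complete", "whole_molecule", "convolutional")


@dataclass
class ModelConfig:
    """Hyperparameters of one model instance.

    Defaults: 4-head attention with 32-wide heads throughout, a 128→64
    pooled representation and a (64, 32) MLP — a uniform architecture shared
    by both tasks, with only the output activation differing.
    """

    variant: str = "complete"
    task: str = "binary_classification"     # or "regression"
    n_heads: int = 4
    f_branch: int = 32                      # head width in Module-1 branches
    f_mol: int = 32                         # head width in Module 2
    pool_out: int = 64                      # P, pooled vector width
    mlp_hidden: tuple[int, ...] = (64, 32)
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.task not in ("regression", "binary_classification"):
            raise ValueError(f"unknown task {self.task!r}")
        self.mlp_hidden = tuple(self.mlp_hidden)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mlp_hidden"] = list(self.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: (tuple(v) if k == "mlp_hidden" else v) for k, v in d.items()})


class _Branch(Layer):
    """One Module-1 substructure branch: MHAL(concat) → MHAL(average)."""

    def __init__(self, d_in: int, cfg: ModelConfig, rng: np.random.Generator):
        self.mhal1 = MultiHeadAttention(d_in, cfg.f_branch, cfg.n_heads,
                                        "concat", rng, cfg.leaky_slope)
        self.mhal2 = MultiHeadAttention(self.mhal1.d_out, cfg.f_branch,
                                        cfg.n_heads, "average", rng, cfg.leaky_slope)

    def __call__(self, H: Tensor, A: np.ndarray) -> Tensor:
        return self.mhal2(self.mhal1(H, A), A)


class GNNModel(Layer):
    """One assembled network (any variant), with forward pass and prediction."""

    def __init__(self, config: ModelConfig, d_features: int | None = None,
                 n_max: int | None = None,
                 vocab: FeatureVocabulary | None = None):
        self.config = config
        self.vocab = vocab or FeatureVocabulary()
        self.d_features = d_features or self.vocab.feature_length
        self.n_max = n_max
        rng = np.random.default_rng(config.seed)

        if config.variant == "whole_molecule":
            self.branches = {}
            d_mol_in = self.d_features
        else:
            self.branches = {k: _Branch(self.d_features, config, rng)
                             for k in BOND_CLASSES}
            d_mol_in = config.f_branch

        q = config.f_mol * config.n_heads     # width entering the pool
        if config.variant == "convolutional":
            self.molecule_layer = GraphConvolution(d_mol_in, q, rng,
                                                   config.leaky_slope)
        else:
            self.molecule_layer = MultiHeadAttention(d_mol_in, config.f_mol,
                                                     config.n_heads, "concat",
                                                     rng, config.leaky_slope)
        self.pool = GlobalAttentionPool(q, config.pool_out, rng)
        self.batchnorm = BatchNorm(config.pool_out)
        widths = (config.pool_out, *config.mlp_hidden)
        self.mlp = [Dense(a, b, rng, "leaky_relu", config.leaky_slope)
                    for a, b in zip(widths[:-1], widths[1:])]
        out_act = "sigmoid" if config.task == "binary_classification" else None
        self.head = Dense(widths[-1], 1, rng, out_act)

    # -- forward -----------------------------------------------------------

    def forward(self, batch: GraphBatch, training: bool = False,
                features: Tensor | None = None) -> Tensor:
        """Predictions for a featurized batch, shape (B,).

        ``features`` optionally overrides the batch's node features with an
        autodiff tensor (e.g. to inspect input gradients).
        """
        self._check_batch(batch)
        H = features if features is not None else Tensor(batch.H)
        if self.branches:
            branch_out = {k: self.branches[k](H, batch.A_sub[k])
                          for k in BOND_CLASSES}
            node_features = masked_sum(branch_out, batch.A_sub)
        else:
            node_features = H
        H_star = self.molecule_layer(node_features, batch.A_full)
        X = self.pool(H_star, batch.node_mask)
        X = self.batchnorm(X, training=training)
        for dense in self.mlp:
            X = dense(X)
        return self.head(X).reshape(-1)

    def predict(self, batch: GraphBatch, batch_size: int = 256) -> np.ndarray:
        """Inference-mode predictions: probabilities of class 1 for
        classification (strictly inside (0, 1)), unbounded for regression."""
        outputs = []
        for start in range(0, len(batch), batch_size):
            idx = np.arange(start, min(start + batch_size, len(batch)))
            outputs.append(self.forward(batch.subset(idx), training=False).data)
        return np.concatenate(outputs)

    def predict_smiles(self, smiles_list) -> np.ndarray:
        if self.n_max is None:
            raise ValueError("model has no n_max set; featurize explicitly")
        batch = GraphBatch.from_smiles(smiles_list, self.vocab, self.n_max)
        return self.predict(batch)

    def _check_batch(self, batch: GraphBatch) -> None:
        if batch.H.shape[-1] != self.d_features:
            raise ValueError(
                f"batch feature width {batch.H.shape[-1]} != model's {self.d_features}")
        if self.n_max is not None and batch.n_max != self.n_max:
            raise ValueError(
                f"batch n_max {batch.n_max} != model's {self.n_max}")

    # -- bookkeeping ---------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def module2_parameter_count(self) -> int:
        """Trainable parameters of the whole-molecule stage (ablation metric)."""
        return self.molecule_layer.n_parameters

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list does not match parameter structure")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.astype(p.data.dtype, copy=True)

    # -- persistence ---------------------------------------------------------

    def save(self, directory, provenance: dict | None = None) -> None:
        """Write weights plus a JSON sidecar (config, vocabulary, n_max)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["bn_running_mean"] = self.batchnorm.running_mean
        arrays["bn_running_var"] = self.batchnorm.running_var
        np.savez(directory / "weights.npz", **arrays)
        sidecar = {
            "config": self.config.to_dict(),
            "vocabulary": json.loads(self.vocab.to_json()),
            "d_features": self.d_features,
            "n_max": self.n_max,
            "provenance": provenance or {},
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "GNNModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        model = cls(ModelConfig.from_dict(sidecar["config"]),
                    d_features=sidecar["d_features"], n_max=sidecar["n_max"])
        with np.load(directory / "weights.npz") as z:
            model.set_weights([z[f"param_{i}"] for i in range(len(model.parameters()))])
            model.batchnorm.running_mean = z["bn_running_mean"]
            model.batchnorm.running_var = z["bn_running_var"]
        return model


def assemble_model(config: ModelConfig, d_features: int, n_max: int,
                   vocab: FeatureVocabulary | None = None) -> GNNModel:
    """Build a :class:`GNNModel` for a given feature width and padding size."""
    return GNNModel(config, d_features=d_features, n_max=n_max, vocab=vocab)
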