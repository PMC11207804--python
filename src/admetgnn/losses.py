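"""Imbalance-aware training objectives.

Regression targets in ADMET datasets (LogD, LogS) are typically skewed, so a
plain RMSE fit concentrates accuracy on the dense part of the target range.
The weighted RMSE down-weights common targets: the target density p(y_i) is
estimated by Gaussian kernel density estimation (Silverman bandwidth),
min–max normalized to p'(y_i) ∈ [0, 1], and each sample receives

    w_i = 1 − α · p'(y_i),          α ∈ [0, 1],

so the densest target gets weight 1 − α and the rarest weight 1.

Binary labels (CYP inhibition) are imbalanced, so the binary cross-entropy
is weighted per class with the log-ratio rule

    w_c = ln(N_c* / N_c + 1),       N_c* = max_c N_c,

giving the majority class weight ln 2 and minority classes more.

Each loss has a plain NumPy evaluation (for metrics and tests) and an
autodiff evaluation used inside the training loop.  Weights are a pure
function of the training split's targets, computed once before training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-7   # probability clipping on both sides before logarithms


class DegenerateTargetError(ValueError):
    """Raised when a target vector admits no density/class weighting."""


@dataclass
class RegressionWeighting:
    """Per-sample density-based weights for skewed regression targets."""

    alpha: float
    density: np.ndarray        # p(y_i), strictly positive
    norm_density: np.ndarray   # p'(y_i) in [0, 1]
    weights: np.ndarray        # w_i = 1 - alpha * p'(y_i)

    def table(self, ids=None, targets=None) -> pd.DataFrame:
        """Diagnostics table (sample id, y, p', w) for audit."""
        n = len(self.weights)
        return pd.DataFrame({
            "id": ids if ids is not None else np.arange(n),
            "y": targets if targets is not None else np.full(n, np.nan),
            "norm_density": self.norm_density,
            "weight": self.weights,
        })


@dataclass
class ClassWeighting:
    counts: dict[int, int]
    majority: int
    weights: dict[int, float]

    def per_sample(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels).astype(int)
        return np.where(labels == 1, self.weights[1], self.weights[0])


def estimate_target_density(Y) -> np.ndarray:
    """Gaussian-KDE density of the targets evaluated at each target.

    Uses Silverman's rule-of-thumb bandwidth.  Raises
    :class:`DegenerateTargetError` for constant or too-short target vectors.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.size < 2 or np.ptp(Y) == 0:
        raise DegenerateTargetError("target vector is constant or too short for KDE")
    kde = gaussian_kde(Y, bw_method="silverman")
    return kde(Y)


def density_weights(Y, alpha: float) -> RegressionWeighting:
    """Compute w_i = 1 − α·p'(y_i) from the training targets.

    Degenerate (constant) targets fall back to all-ones weights.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    Y = np.asarray(Y, dtype=float)
    try:
        p = estimate_target_density(Y)
    except DegenerateTargetError:
        ones = np.ones_like(Y)
        return RegressionWeighting(alpha=alpha, density=ones, norm_density=ones * 0,
                                   weights=ones)
    p_norm = (p - p.min()) / (p.max() - p.min())
    return RegressionWeighting(alpha=alpha, density=p, norm_density=p_norm,
                               weights=1.0 - alpha * p_norm)


def class_weights(labels) -> ClassWeighting:
    """Log-ratio class weights ln(N_majority/N_c + 1) for binary labels."""
    labels = np.asarray(labels).astype(int)
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    if min(counts.values()) == 0:
        raise DegenerateTargetError("both classes must be present to weight them")
    majority = max(counts.values())
    weights = {c: float(np.log(majority / n + 1.0)) for c, n in counts.items()}
    return ClassWeighting(counts=counts, majority=majority, weights=weights)


# -- scalar (NumPy) evaluations -------------------------------------------

def weighted_rmse(y, y_hat, w=None) -> float:
    """sqrt(Σ w_i (y_i − ŷ_i)² / N); plain RMSE when w is omitted."""
    y, y_hat = np.asarray(y, dtype=float), np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    if w.shape != y.shape:
        raise ValueError("weights must match targets in length")
    return float(np.sqrt(np.mean(w * (y - y_hat) ** 2)))


def rmse(y, y_hat) -> float:
    return weighted_rmse(y, y_hat)


def weighted_bce(y, p, weighting: ClassWeighting | None = None) -> float:
    """−(1/N) Σ w_i [y_i log p_i + (1−y_i) log(1−p_i)], w_i by class of y_i."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("length mismatch between labels and probabilities")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, EPS, 1 - EPS)
    w = weighting.per_sample(y) if weighting is not None else np.ones_like(y)
    return float(-np.mean(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def bce(y, p) -> float:
    return weighted_bce(y, p)


# -- autodiff evaluations (training path) ---------------------------------

def weighted_rmse_loss(y_hat: Tensor, y: np.ndarray, w: np.ndarray) -> Tensor:
    resid = y_hat - Tensor(np.asarray(y, dtype=y_hat.data.dtype))
    weighted = Tensor(np.asarray(w, dtype=y_hat.data.dtype)) * resid * resid
    return ad.sqrt(weighted.mean())


def weighted_bce_loss(p_hat: Tensor, y: np.ndarray, w: np.ndarray) -> Tensor:
    y = np.asarray(y, dtype=p_hat.data.dtype)
    w = np.asarray(w, dtype=p_hat.data.dtype)
    p = ad.clip_values(p_hat, EPS, 1 - EPS)
    term = Tensor(y) * ad.log(p) + Tensor(1 - y) * ad.log(Tensor(np.ones_like(y)) - p)
    return -(Tensor(w) * term).mean()
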