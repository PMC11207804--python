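"""Graph network layers: multi-head attention, masked sum, attention pooling,
graph convolution, batch normalization and dense blocks.

Every layer operates on batched tensors — node features ``(B, N, *)`` and
adjacency ``(B, N, N)`` — and is written against :mod:`admetgnn.autodiff`
primitives so that training needs no external deep-learning framework.
Neighborhoods are defined by adjacency rows (self included when the diagonal
entry is 1); atoms with empty neighborhoods (padding, or atoms outside a
bond-class substructure) yield exactly-zero output rows.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base: parameter bookkeeping shared by all trainable layers."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Layer):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
            elif isinstance(value, dict):
                for item in value.values():
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
        return params


class AttentionHead(Layer):
    """One graph-attention head.

    Node features are first projected, ``Z = H W``; for every edge (j, l) of
    the adjacency an attention logit ``e_jl = LeakyReLU([z_j ‖ z_l] · a)`` is
    formed, softmax-normalized over the neighborhood of j, and used to
    aggregate neighbor projections, followed by a LeakyReLU.
    """

    def __init__(self, d_in: int, f_out: int, rng: np.random.Generator,
                 leaky_slope: float = 0.2):
        if f_out < 1:
            raise ValueError("head width F must be >= 1")
        self.W = Tensor(glorot_uniform(rng, (d_in, f_out), d_in, f_out),
                        requires_grad=True)
        # attention vector a in R^{2F}, split into source/destination halves
        self.a_src = Tensor(glorot_uniform(rng, (f_out, 1), 2 * f_out, 1),
                            requires_grad=True)
        self.a_dst = Tensor(glorot_uniform(rng, (f_out, 1), 2 * f_out, 1),
                            requires_grad=True)
        self.leaky_slope = leaky_slope
        self.d_in, self.f_out = d_in, f_out

    @property
    def n_parameters(self) -> int:
        return self.d_in * self.f_out + 2 * self.f_out

    def __call__(self, H: Tensor, A: np.ndarray) -> Tensor:
        if H.shape[-1] != self.d_in:
            raise ValueError(f"feature width {H.shape[-1]} != expected {self.d_in}")
        if A.shape[-1] != A.shape[-2] or A.shape[-2] != H.shape[-2]:
            raise ValueError("adjacency shape inconsistent with node features")
        Z = H @ self.W                                   # (..., N, F)
        s_src = Z @ self.a_src                           # (..., N, 1)
        s_dst = Z @ self.a_dst                           # (..., N, 1)
        swap = (*range(s_dst.ndim - 2), s_dst.ndim - 1, s_dst.ndim - 2)
        logits = s_src + s_dst.transpose(*swap)          # e_jl over all pairs
        logits = ad.leaky_relu(logits, self.leaky_slope)
        lam = ad.masked_softmax(logits, A > 0, axis=-1)  # rows sum to 1 (or 0)
        return ad.leaky_relu(lam @ Z, self.leaky_slope)

    def attention_matrix(self, H: Tensor, A: np.ndarray) -> np.ndarray:
        """Normalized attention coefficients λ (diagnostic, no gradient)."""
        Z = (H.data @ self.W.data)
        s_src = Z @ self.a_src.data
        s_dst = Z @ self.a_dst.data
        logits = s_src + np.swapaxes(s_dst, -1, -2)
        slope = self.leaky_slope
        logits = np.where(logits > 0, logits, slope * logits)
        return ad.masked_softmax(Tensor(logits), A > 0, axis=-1).data


class MultiHeadAttention(Layer):
    """K independent attention heads combined by concatenation or averaging."""

    def __init__(self, d_in: int, f_out: int, n_heads: int, combine: str,
                 rng: np.random.Generator, leaky_slope: float = 0.2):
        if n_heads < 1:
            raise ValueError("head count K must be >= 1")
        if combine not in ("concat", "average"):
            raise ValueError(f"unknown combine mode {combine!r}")
        self.heads = [AttentionHead(d_in, f_out, rng, leaky_slope)
                      for _ in range(n_heads)]
        self.combine = combine
        self.d_out = f_out * n_heads if combine == "concat" else f_out

    @property
    def n_parameters(self) -> int:
        return sum(h.n_parameters for h in self.heads)

    def __call__(self, H: Tensor, A: np.ndarray) -> Tensor:
        if H.ndim == 3:
            return self._fused(H, A)
        outputs = [head(H, A) for head in self.heads]
        return self._combine(outputs)

    def _combine(self, outputs: list[Tensor]) -> Tensor:
        if self.combine == "concat":
            return ad.concat(outputs, axis=-1)
        total = outputs[0]
        for other in outputs[1:]:
            total = total + other
        return total * (1.0 / len(outputs))

    def _fused(self, H: Tensor, A: np.ndarray) -> Tensor:
        """All K heads as stacked (B, K, N, ·) operations.

        Mathematically identical to calling each head separately (heads are
        independent); stacking removes the per-head Python overhead.
        """
        slope = self.heads[0].leaky_slope
        B, N, _ = H.shape
        K, F = len(self.heads), self.heads[0].f_out
        W = ad.stack([h.W for h in self.heads], axis=0)          # (K, D, F)
        a_src = ad.stack([h.a_src for h in self.heads], axis=0)  # (K, F, 1)
        a_dst = ad.stack([h.a_dst for h in self.heads], axis=0)
        Z = H.reshape(B, 1, N, -1) @ W                           # (B, K, N, F)
        s_src = Z @ a_src                                        # (B, K, N, 1)
        s_dst = Z @ a_dst
        logits = ad.leaky_relu(s_src + s_dst.transpose(0, 1, 3, 2), slope)
        lam = ad.masked_softmax(logits, (A > 0)[:, None, :, :], axis=-1)
        out = ad.leaky_relu(lam @ Z, slope)                      # (B, K, N, F)
        if self.combine == "concat":
            return out.transpose(0, 2, 1, 3).reshape(B, N, K * F)
        return out.sum(axis=1) * (1.0 / K)


def masked_sum(branch_outputs: dict[str, Tensor],
               A_sub: dict[str, np.ndarray]) -> Tensor:
    """Fuse substructure branches, gating each atom row by its self-loop.

    Row j of the result is the sum over bond classes k of
    ``branch_k[j] * A_sub[k][j, j]`` — an atom contributes a branch's features
    only if it participates in that substructure; atoms outside every
    substructure (and padding) map to zero rows.
    """
    keys = list(branch_outputs)
    shapes = {branch_outputs[k].shape for k in keys}
    if len(shapes) != 1:
        raise ValueError(f"branch outputs disagree in shape: {shapes}")
    total: Tensor | None = None
    for k in keys:
        diag = np.diagonal(A_sub[k], axis1=-2, axis2=-1)[..., None]  # (B, N, 1)
        term = branch_outputs[k] * Tensor(diag)
        total = term if total is None else total + term
    return total


class GlobalAttentionPool(Layer):
    """Gated attention readout: X = Σ_j sigmoid(h_j W1 + b1) ⊙ (h_j W2 + b2).

    The sum runs over real atoms only (``node_mask``), making the readout
    invariant to both atom order and padding.
    """

    def __init__(self, q_in: int, p_out: int, rng: np.random.Generator):
        self.W1 = Tensor(glorot_uniform(rng, (q_in, p_out), q_in, p_out),
                         requires_grad=True)
        self.W2 = Tensor(glorot_uniform(rng, (q_in, p_out), q_in, p_out),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros(p_out, dtype=np.float32), requires_grad=True)
        self.b2 = Tensor(np.zeros(p_out, dtype=np.float32), requires_grad=True)
        self.q_in, self.p_out = q_in, p_out

    @property
    def n_parameters(self) -> int:
        return 2 * self.q_in * self.p_out + 2 * self.p_out

    def __call__(self, H_star: Tensor, node_mask: np.ndarray) -> Tensor:
        gate = ad.sigmoid(H_star @ self.W1 + self.b1)
        value = H_star @ self.W2 + self.b2
        mask = Tensor(np.asarray(node_mask, dtype=H_star.data.dtype)[..., None])
        return (gate * value * mask).sum(axis=-2)     # (B, P)


class GraphConvolution(Layer):
    """Symmetric-normalized graph convolution (the attention-free ablation).

    Output = LeakyReLU(D̃^{-1/2} A D̃^{-1/2} H W) with D̃ the degree diagonal
    of A; zero-degree rows (padding) bypass normalization and stay zero.
    Parameter count D_in·F is strictly below any K-head attention layer of
    equal output width, which is the point of the ablation.
    """

    def __init__(self, d_in: int, f_out: int, rng: np.random.Generator,
                 leaky_slope: float = 0.2):
        self.W = Tensor(glorot_uniform(rng, (d_in, f_out), d_in, f_out),
                        requires_grad=True)
        self.leaky_slope = leaky_slope
        self.d_in, self.f_out = d_in, f_out

    @property
    def n_parameters(self) -> int:
        return self.d_in * self.f_out

    def __call__(self, H: Tensor, A: np.ndarray) -> Tensor:
        if H.shape[-1] != self.d_in:
            raise ValueError(f"feature width {H.shape[-1]} != expected {self.d_in}")
        deg = A.sum(axis=-1)
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
        A_norm = (A * inv_sqrt[..., :, None] * inv_sqrt[..., None, :]).astype(np.float32)
        return ad.leaky_relu(Tensor(A_norm) @ (H @ self.W), self.leaky_slope)


class BatchNorm(Layer):
    """1-D batch normalization with inference-time moving statistics."""

    def __init__(self, width: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(width, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(width, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(width, dtype=np.float32)
        self.running_var = np.ones(width, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.width = width

    @property
    def n_parameters(self) -> int:
        return 2 * self.width

    def __call__(self, X: Tensor, training: bool) -> Tensor:
        if training:
            mean = X.mean(axis=0)
            centered = X - mean
            var = (centered ** 2).mean(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean.data)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data)
            scale = (var + self.eps) ** -0.5
        else:
            centered = X - Tensor(self.running_mean)
            scale = Tensor((1.0 / np.sqrt(self.running_var + self.eps)).astype(np.float32))
        return centered * scale * self.gamma + self.beta


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str | None = "leaky_relu", leaky_slope: float = 0.2):
        self.W = Tensor(glorot_uniform(rng, (d_in, d_out), d_in, d_out),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)
        self.activation = activation
        self.leaky_slope = leaky_slope
        self.d_in, self.d_out = d_in, d_out

    @property
    def n_parameters(self) -> int:
        return self.d_in * self.d_out + self.d_out

    def __call__(self, X: Tensor) -> Tensor:
        out = X @ self.W + self.b
        if self.activation == "leaky_relu":
            return ad.leaky_relu(out, self.leaky_slope)
        if self.activation == "sigmoid":
            return ad.sigmoid(out)
        return out
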