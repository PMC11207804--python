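"""Brute-force per-node reference implementations used as independent oracles.

These deliberately mirror the layer definitions with explicit Python loops
and share no code with the vectorized implementations they check.
"""

import numpy as np


def leaky(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def attention_head_reference(H, A, W, a, slope=0.2):
    """Per-node double loop over neighborhoods: project, score, softmax, mix."""
    n = H.shape[0]
    F = W.shape[1]
    Z = H @ W
    out = np.zeros((n, F))
    for j in range(n):
        neigh = [l for l in range(n) if A[j, l] > 0]
        if not neigh:
            continue
        e = np.array([leaky(np.concatenate([Z[j], Z[l]]) @ a, slope) for l in neigh])
        lam = np.exp(e - e.max())
        lam = lam / lam.sum()
        out[j] = leaky(sum(lam[i] * Z[l] for i, l in enumerate(neigh)), slope)
    return out


def graph_convolution_reference(H, A, W, slope=0.2):
    """Explicit loop over edges with 1/sqrt(d_i d_j) weights."""
    n = H.shape[0]
    HW = H @ W
    deg = A.sum(axis=1)
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        if deg[i] == 0:
            continue
        for j in range(n):
            if A[i, j] > 0 and deg[j] > 0:
                out[i] += HW[j] / np.sqrt(deg[i] * deg[j])
    return leaky(out, slope)


def average_precision_reference(y, scores):
    """Explicit step-wise precision-recall sum: AP = Σ (R_k − R_{k−1}) P_k."""
    y = np.asarray(y)
    scores = np.asarray(scores)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    n_pos = y.sum()
    ap, tp, prev_recall = 0.0, 0, 0.0
    thresholds = np.unique(scores)[::-1]
    k = 0
    for t in thresholds:
        while k < len(scores) and scores[order[k]] >= t:
            tp += y_sorted[k]
            k += 1
        precision = tp / k
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def auroc_trapezoid_reference(y, scores):
    """ROC curve traced over all thresholds, integrated with the trapezoid rule."""
    y = np.asarray(y)
    scores = np.asarray(scores)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
    P, N = y.sum(), (1 - y).sum()
    tpr = [(scores >= t)[y == 1].mean() for t in thresholds]
    fpr = [(scores >= t)[y == 0].mean() for t in thresholds]
    return float(np.trapezoid(tpr, fpr))
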