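"""Independent brute-force reference implementations used only by tests.

Every function here is written straight from the defining formula with
explicit Python loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def dcor_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Distance correlation via explicit O(n^2) double centering."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    A = np.empty((n, n))
    B = np.empty((n, n))
    for j in range(n):
        for k in range(n):
            A[j, k] = abs(x[j] - x[k])
            B[j, k] = abs(y[j] - y[k])

    def center(D):
        out = np.empty_like(D)
        row = D.mean(axis=1)
        col = D.mean(axis=0)
        grand = D.mean()
        for j in range(n):
            for k in range(n):
                out[j, k] = D[j, k] - row[j] - col[k] + grand
        return out

    A = center(A)
    B = center(B)
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    denom = math.sqrt(dvarx * dvary)
    if denom < 1e-10:
        return 0.0
    return math.sqrt(max(dcov2, 0.0)) / math.sqrt(denom)


def kg_aggregate_oracle(neighbor_lists, states: np.ndarray,
                        rel_table: np.ndarray) -> np.ndarray:
    """Per-entity loop over N_i of the relation-product mean."""
    n, d = states.shape
    out = np.zeros((n, d))
    for i in range(n):
        nbrs = neighbor_lists[i]
        if not nbrs:
            continue
        acc = np.zeros(d)
        for r, j in nbrs:
            acc += rel_table[r] * states[j]
        out[i] = acc / len(nbrs)
    return out


def factor_attention_oracle(h: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Explicit exp/sum softmax over factors of e_p . h_i."""
    n, P = h.shape[0], factors.shape[0]
    beta = np.zeros((n, P))
    for i in range(n):
        logits = np.array([factors[p] @ h[i] for p in range(P)])
        e = np.exp(logits - logits.max())
        beta[i] = e / e.sum()
    return beta


def gat_oracle(adj_lists, e: np.ndarray, W: np.ndarray, a: np.ndarray,
               slope: float = 0.2) -> np.ndarray:
    """Per-gene loop GAT: LeakyReLU-scored softmax over neighbors."""
    n, d = e.shape
    out = np.zeros((n, d))
    z = e @ W
    for i in range(n):
        nbrs = adj_lists[i]
        if not nbrs:
            continue
        logits = []
        for j in nbrs:
            s = a[:d] @ z[i] + a[d:] @ z[j]
            logits.append(s if s > 0 else slope * s)
        logits = np.array(logits)
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        for wj, j in zip(w, nbrs):
            out[i] += wj * e[j]
    return out


def fuse_oracle(beta: np.ndarray, factors: np.ndarray, per_factor) -> np.ndarray:
    n, d = per_factor[0].shape
    out = np.zeros((n, d))
    for i in range(n):
        for p in range(factors.shape[0]):
            out[i] += beta[i, p] * factors[p] * per_factor[p][i]
    return out


def auc_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive positive-negative pair counting; ties count 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def aupr_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive step-interpolated precision-recall curve area:
    sum over thresholds of (R_k - R_{k-1}) * P_k."""
    order = np.argsort(-scores, kind="mergesort")
    scores = scores[order]
    labels = labels[order]
    n_pos = labels.sum()
    area = 0.0
    tp = 0
    fp = 0
    prev_recall = 0.0
    k = 0
    n = len(scores)
    while k < n:
        # advance through ties as one threshold
        j = k
        while j < n and scores[j] == scores[k]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        k = j
    return float(area)
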