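"""Factor-based message aggregation over the SL graph.

Per layer, each gene attends over the latent factors (softmax of the inner
products between its current SL-side state and the factor embeddings), one
graph attention network (GAT) per factor aggregates the KG-side gene
embeddings of the next layer over SL neighbors, and the per-factor outputs
are fused with the factor attention:

    beta(i,p)      = softmax_p( e_p . h_i^(l) )
    h_{i,p}^(l+1)  = sum_{j in N_i} gamma_p(i,j) * e_j^(l+1)
    gamma_p(i,j)   = softmax_{j in N_i} LeakyReLU( a_p . [W_p e_i^(l+1) || W_p e_j^(l+1)] )
    h_i^(l+1)      = sum_p beta(i,p) * e_p (*) h_{i,p}^(l+1)

The SL-side states h enter only through beta; GAT messages and attention
logits both use the KG-side states e^(l+1).  The final gene embedding is the
layer sum h_i = h_i^(0) + ... + h_i^(L).  Genes with no SL neighbors get a
zero aggregated message, so their final embedding keeps h^(0).

An auxiliary loss sums, per layer, pairwise distance correlation between
the gene-averaged outputs of different factors' GATs, pushing the factor
channels to carry distinct information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, segment_sum
from .factor_bank import distance_correlation
from .kg_data import SLGraph

__all__ = [
    "GATParams",
    "factor_attention",
    "gat_layer",
    "neighbor_mean",
    "fuse_factors",
    "gat_independence_loss",
    "encode_genes",
]


@dataclass
class GATParams:
    """One factor's GAT parameters: projection ``W`` (d x d), attention
    vector ``a`` (2d,), and the LeakyReLU negative slope."""

    W: Tensor
    a: Tensor
    negative_slope: float = 0.2

    @classmethod
    def init(cls, dim: int, rng: np.random.Generator,
             negative_slope: float = 0.2) -> "GATParams":
        # Glorot/Xavier init, the GAT default
        limit_w = np.sqrt(6.0 / (dim + dim))
        limit_a = np.sqrt(6.0 / (2 * dim + 1))
        return cls(
            W=Tensor(rng.uniform(-limit_w, limit_w, size=(dim, dim)), requires_grad=True),
            a=Tensor(rng.uniform(-limit_a, limit_a, size=2 * dim), requires_grad=True),
            negative_slope=negative_slope,
        )


def _maybe_plain(out: Tensor, plain: bool):
    return out.data if plain else out


def factor_attention(h_l, factor_embs):
    """Row-wise softmax over factors of the logits ``e_p . h_i`` -> (|V|, |P|)."""
    plain = not isinstance(h_l, Tensor) and not isinstance(factor_embs, Tensor)
    h_l, factor_embs = astensor(h_l), astensor(factor_embs)
    if h_l.shape[1] != factor_embs.shape[1]:
        raise ValueError("gene state and factor embedding dimensions differ")
    logits = h_l @ factor_embs.T  # (|V|, |P|)
    shifted = logits - logits.data.max(axis=1, keepdims=True)  # constant shift
    expl = shifted.exp()
    beta = expl / expl.sum(axis=1, keepdims=True)
    return _maybe_plain(beta, plain)


def gat_layer(sl: SLGraph, e_l1, params: GATParams, return_attention: bool = False,
              attn_dropout_mask: np.ndarray | None = None):
    """One factor's GAT over the SL graph on KG-side states ``e^(l+1)``.

    Returns the (|V|, d) aggregated states; with ``return_attention`` also
    the per-directed-edge attention weights (aligned with
    ``sl.directed_edge_arrays()``).  ``attn_dropout_mask`` is an optional
    inverted-dropout mask applied to the attention weights during training.
    """
    plain = not isinstance(e_l1, Tensor)
    e_l1 = astensor(e_l1)
    if e_l1.shape[0] != sl.n_genes:
        raise ValueError(f"state rows ({e_l1.shape[0]}) != gene count ({sl.n_genes})")
    dim = e_l1.shape[1]
    if params.W.shape != (dim, dim) or params.a.shape != (2 * dim,):
        raise ValueError("GAT parameter shapes do not match embedding dimension")
    src, dst = sl.directed_edge_arrays()
    if len(src) == 0:
        zero = Tensor(np.zeros((sl.n_genes, dim)))
        out = (zero, np.zeros(0)) if return_attention else zero
        return out if not plain else ((zero.data, np.zeros(0)) if return_attention else zero.data)
    z = e_l1 @ params.W
    a_src = params.a.take(np.arange(dim))
    a_dst = params.a.take(np.arange(dim, 2 * dim))
    s_src = z @ a_src  # (|V|,)
    s_dst = z @ a_dst
    logits = (s_src.take(src) + s_dst.take(dst)).leaky_relu(params.negative_slope)
    # per-source-segment softmax, max-shifted for stability (constant shift)
    seg_max = np.full(sl.n_genes, -np.inf)
    np.maximum.at(seg_max, src, logits.data)
    expv = (logits - seg_max[src]).exp()
    denom = segment_sum(expv, src, sl.n_genes)
    gamma = expv / denom.take(src)
    if attn_dropout_mask is not None:
        gamma = gamma * attn_dropout_mask
    weighted = e_l1.take(dst) * gamma.reshape((-1, 1))
    out = segment_sum(weighted, src, sl.n_genes)
    if plain:
        return (out.data, gamma.data) if return_attention else out.data
    return (out, gamma) if return_attention else out


def neighbor_mean(sl: SLGraph, e_l1):
    """Plain SL-neighbor mean of ``e^(l+1)`` (the GAT-free ablation path)."""
    plain = not isinstance(e_l1, Tensor)
    e_l1 = astensor(e_l1)
    src, dst = sl.directed_edge_arrays()
    summed = segment_sum(e_l1.take(dst), src, sl.n_genes)
    inv_deg = 1.0 / np.maximum(sl.degree(), 1)
    out = summed * inv_deg[:, None]
    return out.data if plain else out


def fuse_factors(beta, factor_embs, per_factor):
    """Fuse per-factor states: ``h_i = sum_p beta(i,p) * e_p (*) h_{i,p}``."""
    plain = (not isinstance(beta, Tensor) and not isinstance(factor_embs, Tensor)
             and not any(isinstance(m, Tensor) for m in per_factor))
    beta, factor_embs = astensor(beta), astensor(factor_embs)
    per_factor = [astensor(m) for m in per_factor]
    n_factors = factor_embs.shape[0]
    if beta.shape[1] != n_factors or len(per_factor) != n_factors:
        raise ValueError("factor count mismatch between beta, embeddings, and states")
    out = None
    for p in range(n_factors):
        unit = np.zeros((n_factors, 1))
        unit[p, 0] = 1.0
        beta_col = beta @ unit  # (|V|, 1)
        e_p = factor_embs.take(np.array([p]))  # (1, d)
        term = beta_col * (e_p * per_factor[p])
        out = term if out is None else out + term
    return out.data if plain else out


def gat_independence_loss(per_factor_states):
    """Pairwise dCor of the gene-averaged per-factor states, summed over
    unordered factor pairs; 0 for a single factor."""
    plain = not any(isinstance(m, Tensor) for m in per_factor_states)
    averages = [astensor(m).mean(axis=0) for m in per_factor_states]
    total = Tensor(0.0)
    for p in range(len(averages)):
        for q in range(p + 1, len(averages)):
            total = total + distance_correlation(averages[p], averages[q])
    return float(total.data) if plain else total


def encode_genes(sl: SLGraph, entity_layers, factor_embs, gat_params, h0,
                 n_layers: int, no_gat: bool = False,
                 attn_dropout: float = 0.0,
                 dropout_rng: np.random.Generator | None = None):
    """Run the factor-based SL encoder for ``n_layers`` layers.

    Parameters
    ----------
    entity_layers : list of (|V|, d)
        KG-encoder layer states restricted to gene rows, in SL gene order;
        must have ``n_layers + 1`` entries (layer 0 through L).
    factor_embs : (|P|, d)
        Current factor embeddings.
    gat_params : list of list of GATParams
        ``gat_params[l][p]`` for layer ``l`` (0-based) and factor ``p``.
    h0 : (|V|, d)
        Trainable SL-side initial gene states.
    no_gat : bool
        Replace every GAT with the plain neighbor mean (ablation); the GAT
        independence loss is 0 in this mode.
    attn_dropout, dropout_rng :
        Inverted dropout on attention weights during training.

    Returns
    -------
    layers, h_final, betas, l_gat
        All SL-side layer states, their sum, the per-layer factor-attention
        matrices, and the accumulated GAT independence loss.
    """
    if len(entity_layers) != n_layers + 1:
        raise ValueError(f"need {n_layers + 1} entity layers, got {len(entity_layers)}")
    plain = not isinstance(h0, Tensor)
    h0 = astensor(h0)
    factor_embs = astensor(factor_embs)
    entity_layers = [astensor(e) for e in entity_layers]
    n_factors = factor_embs.shape[0]
    src, _ = sl.directed_edge_arrays()
    layers = [h0]
    betas = []
    l_gat = Tensor(0.0)
    for layer in range(n_layers):
        beta = factor_attention(layers[-1], factor_embs)
        betas.append(beta)
        e_next = entity_layers[layer + 1]
        if no_gat:
            shared = neighbor_mean(sl, e_next)
            per_factor = [shared for _ in range(n_factors)]
        else:
            per_factor = []
            for p in range(n_factors):
                mask = None
                if attn_dropout > 0 and dropout_rng is not None:
                    keep = 1.0 - attn_dropout
                    mask = (dropout_rng.random(len(src)) < keep) / keep
                per_factor.append(gat_layer(sl, e_next, gat_params[layer][p],
                                            attn_dropout_mask=mask))
            l_gat = l_gat + gat_independence_loss(per_factor)
        layers.append(fuse_factors(beta, factor_embs, per_factor))
    h_final = layers[0]
    for h in layers[1:]:
        h_final = h_final + h
    if plain:
        return ([l.data for l in layers], h_final.data,
                [b.data for b in betas], float(l_gat.data))
    return layers, h_final, betas, l_gat
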