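"""Relation-wise message aggregation over the knowledge graph.

Entity embeddings are propagated layer by layer with an explicit relation
product rather than learned attention: each entity's next state is the mean
over its KG neighbors ``(r, j)`` of the elementwise product ``e_r * e_j``,

    e_i^(l+1) = (1 / |N_i|) * sum_{(r,j) in N_i} e_r (*) e_j^(l),

and the final entity embedding is the sum of all layer states
``e_i = e_i^(0) + ... + e_i^(L)``.  No nonlinearity or projection sits
between layers.  Entities with no KG neighbors receive a zero message, so
their final embedding reduces to the trainable layer-0 state.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, astensor, segment_sum
from .kg_data import KnowledgeGraph

__all__ = ["aggregate_layer", "encode_entities"]


def aggregate_layer(kg: KnowledgeGraph, states, rel_table):
    """One layer of relation-product neighbor-mean aggregation.

    Parameters
    ----------
    kg : KnowledgeGraph
        Provides the (possibly dropout-thinned) triple arrays; a duplicated
        triple counts twice, i.e. ``N_i`` is a multiset.
    states : (|V_e|, d) array or Tensor
        Current entity states ``e^(l)``.
    rel_table : (|E_r|, d) array or Tensor
        Relation embeddings ``e_r``.
    """
    plain = not isinstance(states, Tensor) and not isinstance(rel_table, Tensor)
    states = astensor(states)
    rel_table = astensor(rel_table)
    if states.shape[0] != kg.n_entities:
        raise ValueError(f"states rows ({states.shape[0]}) != entity count ({kg.n_entities})")
    if rel_table.shape[0] != kg.n_relations:
        raise ValueError(f"relation table rows ({rel_table.shape[0]}) != "
                         f"relation count ({kg.n_relations})")
    if states.shape[1] != rel_table.shape[1]:
        raise ValueError("embedding dimensions differ between states and relations")
    messages = rel_table.take(kg.rel) * states.take(kg.tail)
    summed = segment_sum(messages, kg.head, kg.n_entities)
    inv_degree = 1.0 / np.maximum(kg.degree, 1)  # degree-0 rows stay zero
    out = summed * inv_degree[:, None]
    return out.data if plain else out


def encode_entities(kg: KnowledgeGraph, states0, rel_table, n_layers: int):
    """Run ``n_layers`` of aggregation; return all layer states and their sum.

    Returns
    -------
    layers : list of (|V_e|, d)
        ``[e^(0), e^(1), ..., e^(L)]``.
    summed : (|V_e|, d)
        ``e_i = e_i^(0) + ... + e_i^(L)``.
    """
    if n_layers < 1:
        raise ValueError("layer count must be >= 1")
    plain = not isinstance(states0, Tensor) and not isinstance(rel_table, Tensor)
    states0 = astensor(states0)
    rel_table = astensor(rel_table)
    layers = [states0]
    for _ in range(n_layers):
        layers.append(aggregate_layer(kg, layers[-1], rel_table))
    summed = layers[0]
    for layer in layers[1:]:
        summed = summed + layer
    if plain:
        return [l.data for l in layers], summed.data
    return layers, summed
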