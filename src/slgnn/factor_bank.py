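"""SL-related factors as trainable combinations of KG relation embeddings.

Each latent factor ``p`` — a hypothesized molecular mechanism behind SL
interactions (e.g. co-participation in DNA repair) — is embedded as a
weighted sum of relation embeddings,

    e_p = sum_r alpha(r, p) * e_r,

which ties factors to nameable KG relations and makes them reportable.  To
keep distinct factors carrying distinct information, pairwise distance
correlation between factor embeddings is penalized during training.

Distance correlation here treats the ``d`` embedding coordinates as ``d``
paired scalar observations, uses the classical biased estimator
(double-centered pairwise-distance matrices), and defines dCor = 0 when
either argument is constant (zero distance variance).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, astensor

__all__ = [
    "RelationEmbeddings",
    "FactorBank",
    "factor_embeddings",
    "distance_correlation",
    "independence_loss",
]

#: distance-variance threshold below which dCor is defined to be 0
DVAR_EPS = 1e-10
#: tiny offset inside sqrt to keep the gradient finite at dCov = 0
_SQRT_EPS = 1e-20


class RelationEmbeddings:
    """Trainable table of one d-vector per (post-symmetrization) relation."""

    def __init__(self, n_relations: int, dim: int, rng: np.random.Generator):
        self.table = Tensor(rng.standard_normal((n_relations, dim)), requires_grad=True)

    @property
    def n_relations(self) -> int:
        return self.table.shape[0]

    @property
    def dim(self) -> int:
        return self.table.shape[1]


class FactorBank:
    """Trainable factor coefficients ``alpha`` of shape (|P|, |E_r|).

    Factor embeddings are recomputed from the live coefficient and relation
    tables on every access, so they always reflect the current optimizer
    state.
    """

    def __init__(self, n_factors: int, rel_embs: RelationEmbeddings,
                 rng: np.random.Generator):
        self.rel_embs = rel_embs
        n_rel = rel_embs.n_relations
        # scaled init keeps e_p at unit scale regardless of relation count
        self.coefficients = Tensor(
            rng.standard_normal((n_factors, n_rel)) / np.sqrt(n_rel),
            requires_grad=True)

    @property
    def n_factors(self) -> int:
        return self.coefficients.shape[0]

    def embeddings(self) -> Tensor:
        return factor_embeddings(self.coefficients, self.rel_embs.table)


def factor_embeddings(coefficients, rel_table):
    """Factor embedding matrix ``e_p = sum_r alpha(r,p) e_r`` (|P| x d).

    Accepts NumPy arrays or autodiff tensors; returns the matching kind.
    """
    plain = not isinstance(coefficients, Tensor) and not isinstance(rel_table, Tensor)
    coefficients = astensor(coefficients)
    rel_table = astensor(rel_table)
    if coefficients.shape[1] != rel_table.shape[0]:
        raise ValueError(
            f"coefficient columns ({coefficients.shape[1]}) must match "
            f"relation count ({rel_table.shape[0]})")
    out = coefficients @ rel_table
    return out.data if plain else out


def _centered_distance_matrix(v: Tensor) -> Tensor:
    n = v.shape[0]
    D = (v.reshape((n, 1)) - v.reshape((1, n))).abs()
    return (D - D.mean(axis=0, keepdims=True) - D.mean(axis=1, keepdims=True)
            + D.mean())


def distance_correlation(x, y):
    """Distance correlation between two same-length vectors, in [0, 1].

    ``dCor = dCov(x, y) / sqrt(dVar(x) * dVar(y))`` with the biased
    estimator; returns 0 when either vector is (numerically) constant.
    Differentiable when called with autodiff tensors.
    """
    plain = not isinstance(x, Tensor) and not isinstance(y, Tensor)
    x, y = astensor(x), astensor(y)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    A = _centered_distance_matrix(x)
    B = _centered_distance_matrix(y)
    dcov2 = (A * B).mean()
    dvarx2 = (A * A).mean()
    dvary2 = (B * B).mean()
    if float(np.sqrt(dvarx2.data * dvary2.data)) < DVAR_EPS:
        out = Tensor(0.0)
    else:
        dcov = (dcov2.maximum(0.0) + _SQRT_EPS).sqrt()
        # sqrt(dVar_x * dVar_y) = (dVar2_x * dVar2_y)^(1/4)
        denom = ((dvarx2 * dvary2) + _SQRT_EPS).sqrt().sqrt()
        out = dcov / denom
    return float(out.data) if plain else out


def independence_loss(factor_embs):
    """Sum of dCor over unordered distinct factor pairs; 0 for one factor."""
    plain = not isinstance(factor_embs, Tensor)
    factor_embs = astensor(factor_embs)
    n_factors = factor_embs.shape[0]
    total = Tensor(0.0)
    for p in range(n_factors):
        row_p = factor_embs.take(np.array([p])).reshape((factor_embs.shape[1],))
        for q in range(p + 1, n_factors):
            row_q = factor_embs.take(np.array([q])).reshape((factor_embs.shape[1],))
            total = total + distance_correlation(row_p, row_q)
    return float(total.data) if plain else total


def mean_pairwise_dcor(factor_embs: np.ndarray) -> float:
    """Mean dCor over unordered factor pairs (0 if fewer than two factors)."""
    n_factors = factor_embs.shape[0]
    n_pairs = n_factors * (n_factors - 1) // 2
    if n_pairs == 0:
        return 0.0
    return independence_loss(np.asarray(factor_embs)) / n_pairs
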