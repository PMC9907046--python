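"""Pair scoring, composite loss, training, evaluation, and interpretability.

A gene pair ``(i, j)`` is scored by the sigmoid of the inner product of the
SL-side embedding ``h_i`` and the KG-side embedding ``e_j``; training
minimizes

    L = L_BCE + lambda1 * (L_IND + L_GAT) + lambda2 * L_norm

with Adam, early stopping on validation AUC, and per-epoch KG edge dropout.
``L_norm`` is the sum of squared entries of the entity embeddings (KG-side
and SL-side), relation embeddings, and GAT projection matrices.

Because an SL interaction is unordered (A_ij = A_ji), the default score is
the mean of the two orientations sigmoid(h_i.e_j) and sigmoid(h_j.e_i); the
literal one-sided form is available via ``symmetric_score=False``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .autodiff import Adam, Tensor, astensor
from .factor_bank import (FactorBank, RelationEmbeddings, independence_loss,
                          mean_pairwise_dcor)
from .kg_data import (EntityVocab, KnowledgeGraph, LabeledPairSet, SLGraph,
                      kg_edge_dropout, sample_negatives, split_pairs, symmetrize_kg)
from .kg_encoder import encode_entities
from .sl_encoder import GATParams, encode_genes

__all__ = [
    "TrainConfig",
    "Metrics",
    "InterpretabilityReport",
    "SLGNN",
    "score_pair",
    "score_pair_symmetric",
    "bce_loss",
    "total_loss",
    "train",
    "evaluate",
    "cross_validate",
    "explain",
    "run_experiment",
    "degree_null_scores",
]

_PROB_EPS = 1e-12


@dataclass
class TrainConfig:
    """Hyperparameters of the model and its training loop.

    Defaults are the full-scale settings (d=256, L=3, |P|=4, lambda1=1e-4,
    lambda2=1e-3, lr=0.002, KG edge dropout 0.5); :meth:`small` gives the
    desk-scale variant (d=32, L=2) used on synthetic benchmarks.
    """

    dim: int = 256
    n_layers: int = 3
    n_factors: int = 4
    lam1: float = 1e-4
    lam2: float = 1e-3
    lr: float = 0.002
    kg_dropout: float = 0.5
    attn_dropout: float = 0.6
    negative_slope: float = 0.2
    patience: int = 10
    max_epochs: int = 200
    threshold: float = 0.5
    seed: int = 0
    symmetric_score: bool = True
    no_factors: bool = False
    no_gat: bool = False
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.dim < 1 or self.n_layers < 1 or self.n_factors < 1:
            raise ValueError("dim, n_layers and n_factors must be positive")
        if self.lam1 < 0 or self.lam2 < 0:
            raise ValueError("lam1 and lam2 must be non-negative")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if not 0 <= self.kg_dropout < 1 or not 0 <= self.attn_dropout < 1:
            raise ValueError("dropout ratios must be in [0, 1)")

    @classmethod
    def small(cls, **overrides) -> "TrainConfig":
        """Desk-scale preset for synthetic benchmarks: smaller embeddings,
        fewer layers, and a faster-converging optimizer setting."""
        base = dict(dim=32, n_layers=2, lr=0.02, max_epochs=300, patience=40)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class Metrics:
    """Held-out AUC, AUPR and F1 (optionally per CV fold, as mean +/- sd)."""

    auc: float
    aupr: float
    f1: float
    auc_sd: float = 0.0
    aupr_sd: float = 0.0
    f1_sd: float = 0.0
    per_fold: list = field(default_factory=list)

    def __str__(self) -> str:
        if self.per_fold:
            return (f"AUC {self.auc:.4f} ± {self.auc_sd:.4f}  "
                    f"AUPR {self.aupr:.4f} ± {self.aupr_sd:.4f}  "
                    f"F1 {self.f1:.4f} ± {self.f1_sd:.4f}")
        return f"AUC {self.auc:.4f}  AUPR {self.aupr:.4f}  F1 {self.f1:.4f}"


@dataclass
class InterpretabilityReport:
    """Per-factor relation rankings, optional per-pair factor attention,
    and the mean pairwise factor distance correlation."""

    factor_rankings: list  # per factor: [(relation_name, alpha), ...] by |alpha| desc
    mean_factor_dcor: float
    pair: tuple[str, str] | None = None
    pair_beta: dict | None = None  # gene name -> per-factor attention row
    top_factor: int | None = None


# ---------------------------------------------------------------------------
# scoring and losses

def score_pair(h_i, e_j):
    """Literal one-sided score: sigmoid(h_i . e_j)."""
    h_i, e_j = np.asarray(h_i, dtype=float), np.asarray(e_j, dtype=float)
    if h_i.shape != e_j.shape or h_i.ndim != 1:
        raise ValueError("score_pair expects two vectors of equal dimension")
    z = float(h_i @ e_j)
    return float(1.0 / (1.0 + np.exp(-z))) if z >= 0 else float(np.exp(z) / (1 + np.exp(z)))


def score_pair_symmetric(h_i, e_i, h_j, e_j):
    """Orientation-free score: mean of sigmoid(h_i.e_j) and sigmoid(h_j.e_i)."""
    return 0.5 * (score_pair(h_i, e_j) + score_pair(h_j, e_i))


def bce_loss(scores, labels):
    """Mean binary cross-entropy with probabilities clamped at 1e-12."""
    plain = not isinstance(scores, Tensor)
    scores = astensor(scores)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    pos = scores.maximum(_PROB_EPS).log() * labels
    neg = (1.0 - scores).maximum(_PROB_EPS).log() * (1.0 - labels)
    loss = -(pos + neg).mean()
    return float(loss.data) if plain else loss


def total_loss(bce, l_ind, l_gat, l2_norm, lam1: float, lam2: float):
    """Composite objective ``L_BCE + lam1 (L_IND + L_GAT) + lam2 L_norm``."""
    for name, v in (("bce", bce), ("l_ind", l_ind), ("l_gat", l_gat), ("l2_norm", l2_norm)):
        val = float(v.data) if isinstance(v, Tensor) else float(v)
        if not np.isfinite(val):
            raise ValueError(f"non-finite loss component {name}: {val}")
    out = astensor(bce) + lam1 * (astensor(l_ind) + astensor(l_gat)) + lam2 * astensor(l2_norm)
    plain = not any(isinstance(v, Tensor) for v in (bce, l_ind, l_gat, l2_norm))
    return float(out.data) if plain else out


# ---------------------------------------------------------------------------
# the model

class SLGNN:
    """Factor-aware KG neural network over a symmetrized KG and an SL graph.

    ``sl`` is the aggregation graph (training-split SL edges only — held-out
    edges never enter message passing).  SL genes missing from the KG get
    fresh entity rows with no triples, so their KG-side embedding reduces to
    the trainable layer-0 state.
    """

    def __init__(self, kg: KnowledgeGraph, sl: SLGraph, config: TrainConfig):
        if not kg.symmetrized:
            kg = symmetrize_kg(kg)
        self.config = config
        self.sl = sl
        rng = np.random.default_rng(config.seed)
        # align SL genes with KG entities; append rows for unmatched genes
        ent_names = list(kg.vocab.entity_names)
        ent_index = dict(kg.vocab.entity_index)
        gene_rows = []
        for g in sl.gene_vocab:
            if g not in ent_index:
                ent_index[g] = len(ent_names)
                ent_names.append(g)
            gene_rows.append(ent_index[g])
        self.gene_rows = np.array(gene_rows, dtype=np.int64)
        vocab = EntityVocab(ent_names, list(kg.vocab.relation_names))
        self.kg = KnowledgeGraph(vocab, kg.triples, symmetrized=True,
                                 n_forward_relations=kg.n_forward_relations)
        d, L, P = config.dim, config.n_layers, config.n_factors
        self.n_factors = 1 if config.no_factors else P
        # trainable tables, standard-normal init
        self.ent0 = Tensor(rng.standard_normal((len(ent_names), d)), requires_grad=True)
        self.rel_embs = RelationEmbeddings(self.kg.n_relations, d, rng)
        self.h0 = Tensor(rng.standard_normal((sl.n_genes, d)), requires_grad=True)
        self.factor_bank = (None if config.no_factors
                            else FactorBank(self.n_factors, self.rel_embs, rng))
        self.gat_params = [[GATParams.init(d, rng, config.negative_slope)
                            for _ in range(self.n_factors)] for _ in range(L)]

    # -- parameters -------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = [self.ent0, self.rel_embs.table, self.h0]
        if self.factor_bank is not None:
            params.append(self.factor_bank.coefficients)
        if not self.config.no_gat:
            for layer in self.gat_params:
                for gp in layer:
                    params.extend([gp.W, gp.a])
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, arr in zip(self.parameters(), state):
            p.data = arr.copy()

    # -- forward ----------------------------------------------------------
    def factor_embeddings(self) -> Tensor:
        if self.factor_bank is None:
            return Tensor(np.ones((1, self.config.dim)))
        return self.factor_bank.embeddings()

    def forward(self, training: bool = False, epoch: int = 0):
        """Full forward pass; returns a dict with gene embeddings and losses."""
        cfg = self.config
        kg = self.kg
        dropout_rng = None
        if training:
            if cfg.kg_dropout > 0:
                seed = int(np.random.SeedSequence([cfg.seed, 11, epoch])
                           .generate_state(1)[0] % (2**31))
                kg = kg_edge_dropout(kg, cfg.kg_dropout, seed)
            if cfg.attn_dropout > 0:
                dseed = int(np.random.SeedSequence([cfg.seed, 13, epoch])
                            .generate_state(1)[0] % (2**31))
                dropout_rng = np.random.default_rng(dseed)
        ent_layers, e_sum = encode_entities(kg, self.ent0, self.rel_embs.table,
                                            cfg.n_layers)
        gene_layers = [layer.take(self.gene_rows) for layer in ent_layers]
        e_gene = e_sum.take(self.gene_rows)
        factor_embs = self.factor_embeddings()
        _, h_final, betas, l_gat = encode_genes(
            self.sl, gene_layers, factor_embs, self.gat_params, self.h0,
            cfg.n_layers, no_gat=cfg.no_gat,
            attn_dropout=cfg.attn_dropout if training else 0.0,
            dropout_rng=dropout_rng)
        l_ind = (independence_loss(factor_embs) if self.factor_bank is not None
                 else Tensor(0.0))
        return {"e_gene": e_gene, "h_final": h_final, "betas": betas,
                "l_ind": l_ind, "l_gat": l_gat, "factor_embs": factor_embs}

    def pair_scores(self, fwd, pairs: np.ndarray) -> Tensor:
        """Scores for an (n, 2) array of gene-index pairs."""
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        h, e = fwd["h_final"], fwd["e_gene"]
        logit_ij = (h.take(pairs[:, 0]) * e.take(pairs[:, 1])).sum(axis=1)
        if not self.config.symmetric_score:
            return logit_ij.sigmoid()
        logit_ji = (h.take(pairs[:, 1]) * e.take(pairs[:, 0])).sum(axis=1)
        return 0.5 * (logit_ij.sigmoid() + logit_ji.sigmoid())

    def l2_norm(self) -> Tensor:
        """Sum of squared entries of the entity embeddings (both the KG-side
        table and the SL-side initial gene states), relation embeddings, and
        GAT projection matrices."""
        total = ((self.ent0 * self.ent0).sum()
                 + (self.rel_embs.table * self.rel_embs.table).sum()
                 + (self.h0 * self.h0).sum())
        if not self.config.no_gat:
            for layer in self.gat_params:
                for gp in layer:
                    total = total + (gp.W * gp.W).sum()
        return total

    def predict(self, pairs: np.ndarray) -> np.ndarray:
        """Probabilities for gene-index pairs with the trained parameters."""
        return self.pair_scores(self.forward(training=False), pairs).data

    def predict_names(self, name_pairs: list[tuple[str, str]]) -> np.ndarray:
        idx = []
        for a, b in name_pairs:
            for g in (a, b):
                if g not in self.sl.gene_index:
                    raise KeyError(f"unknown gene name: {g}")
            idx.append((self.sl.gene_index[a], self.sl.gene_index[b]))
        return self.predict(np.array(idx, dtype=np.int64))

    # -- persistence ------------------------------------------------------
    def save(self, run_dir) -> None:
        import pathlib

        run_dir = pathlib.Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(run_dir / "config.yaml")
        np.savez(run_dir / "params.npz",
                 **{f"param_{i}": arr for i, arr in enumerate(self.state_dict())})
        meta = {
            "gene_vocab": self.sl.gene_vocab,
            "sl_edges": sorted(self.sl.edges),
            "entity_names": self.kg.vocab.entity_names,
            "relation_names": self.kg.vocab.relation_names,
            "triples": self.kg.triples.tolist(),
            "n_forward_relations": self.kg.n_forward_relations,
        }
        with open(run_dir / "model.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, run_dir) -> "SLGNN":
        import pathlib

        run_dir = pathlib.Path(run_dir)
        config = TrainConfig.from_yaml(run_dir / "config.yaml")
        with open(run_dir / "model.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        vocab = EntityVocab(meta["entity_names"], meta["relation_names"])
        kg = KnowledgeGraph(vocab, np.array(meta["triples"], dtype=np.int64),
                            symmetrized=True,
                            n_forward_relations=meta["n_forward_relations"])
        sl = SLGraph(meta["gene_vocab"], {tuple(e) for e in meta["sl_edges"]})
        model = cls(kg, sl, config)
        data = np.load(run_dir / "params.npz")
        model.load_state_dict([data[f"param_{i}"] for i in range(len(data.files))])
        return model


# ---------------------------------------------------------------------------
# training

def train(kg: KnowledgeGraph, sl: SLGraph,
          splits: tuple[LabeledPairSet, LabeledPairSet, LabeledPairSet],
          config: TrainConfig):
    """Train on the train split with early stopping on validation AUC.

    The SL aggregation graph is built from the train split's positive pairs
    only.  Returns the trained model (parameters restored to the best
    validation epoch) and the per-epoch history.
    """
    train_set, val_set, _ = splits
    pos = train_set.pairs[train_set.labels == 1]
    agg_graph = SLGraph(sl.gene_vocab, {(int(i), int(j)) for i, j in pos})
    model = SLGNN(kg, agg_graph, config)
    opt = Adam(model.parameters(), lr=config.lr)
    history = []
    best_auc, best_epoch, best_state = -np.inf, -1, None
    for epoch in range(config.max_epochs):
        fwd = model.forward(training=True, epoch=epoch)
        scores = model.pair_scores(fwd, train_set.pairs)
        if not np.isfinite(scores.data).all():
            raise RuntimeError(f"training diverged at epoch {epoch}: non-finite scores")
        bce = bce_loss(scores, train_set.labels.astype(float))
        loss = total_loss(bce, fwd["l_ind"], fwd["l_gat"],
                          model.l2_norm(), config.lam1, config.lam2)
        if not np.isfinite(float(loss.data)):
            raise RuntimeError(f"training diverged at epoch {epoch}: loss={float(loss.data)}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        eval_fwd = model.forward(training=False)
        val_scores = model.pair_scores(eval_fwd, val_set.pairs).data
        val_auc = roc_auc_score(val_set.labels, val_scores)
        history.append({
            "epoch": epoch,
            "train_loss": float(loss.data),
            "val_auc": float(val_auc),
            "mean_factor_dcor": mean_pairwise_dcor(eval_fwd["factor_embs"].data),
        })
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_state = model.state_dict()
        elif epoch - best_epoch >= config.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.best_epoch = best_epoch
    return model, history


def evaluate(scores, labels, threshold: float = 0.5) -> Metrics:
    """AUC (rank-based, ties 0.5), AUPR (step interpolation), F1 at threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation requires both classes present")
    return Metrics(
        auc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        f1=float(f1_score(labels, (scores >= threshold).astype(int))),
    )


def cross_validate(kg: KnowledgeGraph, sl: SLGraph, all_pairs: LabeledPairSet,
                   config: TrainConfig, k: int = 5):
    """Stratified k-fold CV; per fold, the remainder is split 8:1 into
    train/val for early stopping.  Returns aggregate Metrics and the models."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    fold_metrics, models = [], []
    for fold, (rest_idx, test_idx) in enumerate(skf.split(all_pairs.pairs, all_pairs.labels)):
        test_set = all_pairs.subset(test_idx, "test")
        if len(np.unique(test_set.labels)) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        rest = all_pairs.subset(rest_idx)
        tr_idx, va_idx = train_test_split(
            np.arange(len(rest)), test_size=1.0 / 9.0,
            random_state=config.seed + fold, stratify=rest.labels)
        splits = (rest.subset(tr_idx, "train"), rest.subset(va_idx, "val"), test_set)
        fold_config = replace(config, seed=config.seed + 1000 * (fold + 1))
        model, _ = train(kg, sl, splits, fold_config)
        scores = model.predict(test_set.pairs)
        fold_metrics.append(evaluate(scores, test_set.labels, config.threshold))
        models.append(model)
    aucs = np.array([m.auc for m in fold_metrics])
    auprs = np.array([m.aupr for m in fold_metrics])
    f1s = np.array([m.f1 for m in fold_metrics])
    agg = Metrics(auc=float(aucs.mean()), aupr=float(auprs.mean()), f1=float(f1s.mean()),
                  auc_sd=float(aucs.std(ddof=1)), aupr_sd=float(auprs.std(ddof=1)),
                  f1_sd=float(f1s.std(ddof=1)), per_fold=fold_metrics)
    return agg, models


def explain(model: SLGNN, pair: tuple[str, str] | None = None) -> InterpretabilityReport:
    """Rank KG relations per factor by |alpha|; optionally report both genes'
    factor-attention rows (last SL layer) for a queried pair."""
    rel_names = model.kg.vocab.relation_names
    rankings = []
    if model.factor_bank is not None:
        alpha = model.factor_bank.coefficients.data
        for p in range(alpha.shape[0]):
            order = np.argsort(-np.abs(alpha[p]))
            rankings.append([(rel_names[r], float(alpha[p, r])) for r in order])
    else:
        rankings.append([(n, 1.0) for n in rel_names])
    fwd = model.forward(training=False)
    report = InterpretabilityReport(
        factor_rankings=rankings,
        mean_factor_dcor=mean_pairwise_dcor(fwd["factor_embs"].data),
    )
    if pair is not None:
        a, b = pair
        for g in (a, b):
            if g not in model.sl.gene_index:
                raise KeyError(f"unknown gene name: {g}")
        beta = fwd["betas"][-1].data
        ia, ib = model.sl.gene_index[a], model.sl.gene_index[b]
        report.pair = (a, b)
        report.pair_beta = {a: beta[ia].tolist(), b: beta[ib].tolist()}
        report.top_factor = int(np.argmax(beta[ia] + beta[ib]))
    return report


# ---------------------------------------------------------------------------
# experiment drivers

def degree_null_scores(sl_train: SLGraph, pairs: np.ndarray) -> np.ndarray:
    """Baseline: score a pair by the product of its SL-graph degrees."""
    deg = sl_train.degree().astype(float)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return deg[pairs[:, 0]] * deg[pairs[:, 1]]


def build_pair_splits(sl: SLGraph, seed: int,
                      ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)):
    """Positives + an equal number of sampled negatives, split at ``ratios``."""
    from .kg_data import concat_pair_sets, positive_pair_set

    positives = positive_pair_set(sl)
    negatives = sample_negatives(sl, sl.n_edges, seed)
    labeled = concat_pair_sets([positives, negatives])
    return split_pairs(labeled, ratios, seed)


def run_experiment(kg: KnowledgeGraph, sl: SLGraph, config: TrainConfig):
    """Single 8:1:1 experiment: sample negatives, split, train, evaluate.

    Returns (model, history, test metrics, splits).
    """
    splits = build_pair_splits(sl, config.seed)
    model, history = train(kg, sl, splits, config)
    test_set = splits[2]
    metrics = evaluate(model.predict(test_set.pairs), test_set.labels, config.threshold)
    return model, history, metrics, splits
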