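"""Scoring, losses, metrics, training loop, CV and interpretability."""

import numpy as np
import pytest

from slgnn.autodiff import Tensor
from slgnn.kg_data import concat_pair_sets, positive_pair_set, sample_negatives
from slgnn.train_predict import (SLGNN, TrainConfig, bce_loss, build_pair_splits,
                                 cross_validate, evaluate, explain, run_experiment,
                                 score_pair, score_pair_symmetric, total_loss, train)

from _oracles import auc_oracle, aupr_oracle


# ---------------------------------------------------------------------------
# score_pair

def test_zero_embedding_scores_half():
    assert score_pair(np.zeros(4), np.ones(4)) == pytest.approx(0.5)


def test_literal_score_hand_value():
    v = np.array([1.0, 1.0])
    assert score_pair(v, v) == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-12)


def test_symmetric_score_orientation_free(rng):
    for _ in range(100):
        hi, ei, hj, ej = (rng.standard_normal(6) for _ in range(4))
        assert score_pair_symmetric(hi, ei, hj, ej) == pytest.approx(
            score_pair_symmetric(hj, ej, hi, ei), abs=1e-14)


def test_score_pair_dimension_mismatch():
    with pytest.raises(ValueError):
        score_pair(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# losses

def test_bce_maximal_entropy_is_ln2():
    scores = np.full(10, 0.5)
    labels = np.tile([0, 1], 5)
    assert bce_loss(scores, labels) == pytest.approx(np.log(2), abs=1e-12)


def test_bce_perfect_scores_near_zero():
    scores = np.array([1.0 - 1e-12, 1e-12])
    labels = np.array([1, 0])
    assert bce_loss(scores, labels) == pytest.approx(0.0, abs=1e-9)


def test_bce_matches_direct_sum(rng):
    scores = rng.uniform(0.01, 0.99, 10)
    labels = rng.integers(0, 2, 10)
    expected = -np.mean(labels * np.log(scores) + (1 - labels) * np.log(1 - scores))
    assert bce_loss(scores, labels) == pytest.approx(expected, abs=1e-10)


def test_bce_length_mismatch():
    with pytest.raises(ValueError):
        bce_loss(np.zeros(3), np.zeros(4))


def test_total_loss_reduces_to_bce_without_weights():
    assert total_loss(0.7, 5.0, 3.0, 10.0, 0.0, 0.0) == pytest.approx(0.7)


def test_total_loss_hand_value():
    assert total_loss(0.6, 0.1, 0.2, 1.0, 0.01, 0.001) == pytest.approx(0.604, abs=1e-12)


def test_total_loss_random_affine(rng):
    for _ in range(20):
        b, i, g, n = rng.uniform(0, 2, 4)
        l1, l2 = rng.uniform(0, 0.1, 2)
        assert total_loss(b, i, g, n, l1, l2) == pytest.approx(
            b + l1 * (i + g) + l2 * n, abs=1e-12)


def test_total_loss_rejects_non_finite():
    with pytest.raises(ValueError):
        total_loss(np.inf, 0.0, 0.0, 0.0, 0.1, 0.1)


# ---------------------------------------------------------------------------
# evaluate

def test_perfect_separation_metrics():
    m = evaluate(np.array([0.9, 0.8, 0.4, 0.2]), np.array([1, 1, 0, 0]))
    assert m.auc == 1.0
    assert m.f1 == 1.0


def test_auc_matches_pair_counting_hand_case():
    m = evaluate(np.array([0.9, 0.8, 0.4, 0.2]), np.array([1, 0, 1, 0]))
    assert m.auc == pytest.approx(0.75)


def test_metrics_match_oracles_random(rng):
    for _ in range(30):
        n = int(rng.integers(20, 60))
        scores = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        m = evaluate(scores, labels)
        assert m.auc == pytest.approx(auc_oracle(scores, labels), abs=1e-6)
        assert m.aupr == pytest.approx(aupr_oracle(scores, labels), abs=1e-6)


def test_evaluate_rejects_single_class():
    with pytest.raises(ValueError):
        evaluate(np.array([0.1, 0.9]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# config

def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(dim=0)
    with pytest.raises(ValueError):
        TrainConfig(threshold=1.5)
    with pytest.raises(ValueError):
        TrainConfig(lam1=-1.0)


def test_config_yaml_roundtrip(tmp_path):
    cfg = TrainConfig.small(seed=9, lam1=0.01)
    cfg.to_yaml(tmp_path / "c.yaml")
    assert TrainConfig.from_yaml(tmp_path / "c.yaml") == cfg


# ---------------------------------------------------------------------------
# training

def small_cfg(**kw):
    base = dict(dim=16, n_layers=2, n_factors=2, max_epochs=25, patience=25, seed=0)
    base.update(kw)
    return TrainConfig.small(**base)


def test_training_reduces_loss(mini_benchmark):
    kg, sl, _ = mini_benchmark
    model, hist, metrics, _ = run_experiment(kg, sl, small_cfg())
    assert hist[-1]["train_loss"] < hist[0]["train_loss"]
    assert 0.0 <= metrics.auc <= 1.0


def test_training_deterministic_under_seed(mini_benchmark):
    kg, sl, _ = mini_benchmark
    _, hist1, m1, _ = run_experiment(kg, sl, small_cfg(seed=5))
    _, hist2, m2, _ = run_experiment(kg, sl, small_cfg(seed=5))
    assert m1.auc == m2.auc
    assert [h["train_loss"] for h in hist1] == [h["train_loss"] for h in hist2]


def test_early_stopping_restores_best_epoch(mini_benchmark):
    kg, sl, _ = mini_benchmark
    splits = build_pair_splits(sl, 3)
    cfg = small_cfg(seed=3, max_epochs=40, patience=5)
    model, hist = train(kg, sl, splits, cfg)
    val_aucs = [h["val_auc"] for h in hist]
    assert model.best_epoch == int(np.argmax(val_aucs))
    # restored parameters reproduce the best epoch's validation AUC
    from sklearn.metrics import roc_auc_score
    val = splits[1]
    auc = roc_auc_score(val.labels, model.predict(val.pairs))
    assert auc == pytest.approx(max(val_aucs), abs=1e-12)


def test_full_loss_gradient_matches_finite_difference(rng):
    # tiny instance: 20 KG entities, 10 genes
    from slgnn.kg_data import EntityVocab, KnowledgeGraph, SLGraph, symmetrize_kg
    from slgnn.train_predict import bce_loss as bce
    triples = np.unique(np.column_stack([
        rng.integers(0, 20, 40), rng.integers(0, 3, 40), rng.integers(0, 20, 40)]), axis=0)
    vocab = EntityVocab([f"g{i}" for i in range(10)] + [f"c{i}" for i in range(10)],
                        ["r0", "r1", "r2"])
    kg = symmetrize_kg(KnowledgeGraph(vocab, triples))
    sl = SLGraph([f"g{i}" for i in range(10)], {(0, 1), (1, 2), (2, 3), (4, 5), (6, 7)})
    cfg = TrainConfig(dim=4, n_layers=2, n_factors=2, seed=0,
                      kg_dropout=0.0, attn_dropout=0.0)
    model = SLGNN(kg, sl, cfg)
    pairs = np.array([[0, 2], [3, 5], [6, 9], [1, 4]])
    labels = np.array([1.0, 0.0, 1.0, 0.0])

    def loss_value():
        fwd = model.forward(training=False)
        scores = model.pair_scores(fwd, pairs)
        return total_loss(bce(scores, labels), fwd["l_ind"], fwd["l_gat"],
                          model.l2_norm(), cfg.lam1, cfg.lam2)

    loss = loss_value()
    for p in model.parameters():
        p.grad = None
    loss.backward()
    eps = 1e-5
    for p in [model.ent0, model.rel_embs.table, model.h0,
              model.factor_bank.coefficients, model.gat_params[0][0].W]:
        flat_idx = (0, 1) if p.data.ndim == 2 else (0,)
        orig = p.data[flat_idx]
        p.data[flat_idx] = orig + eps
        up = float(loss_value().data)
        p.data[flat_idx] = orig - eps
        down = float(loss_value().data)
        p.data[flat_idx] = orig
        num = (up - down) / (2 * eps)
        if abs(num) > 1e-8:
            assert p.grad[flat_idx] == pytest.approx(num, rel=1e-3, abs=1e-6)


def test_divergence_aborts(mini_benchmark):
    kg, sl, _ = mini_benchmark
    cfg = small_cfg(lr=1e200, max_epochs=5)  # absurd rate to force overflow
    with pytest.raises((RuntimeError, ValueError)):
        run_experiment(kg, sl, cfg)


# ---------------------------------------------------------------------------
# cross-validation

def test_cross_validate_partitions_and_reports(mini_benchmark):
    kg, sl, _ = mini_benchmark
    labeled = concat_pair_sets([positive_pair_set(sl), sample_negatives(sl, sl.n_edges, 0)])
    cfg = small_cfg(max_epochs=10, patience=10)
    metrics, models = cross_validate(kg, sl, labeled, cfg, k=3)
    assert len(metrics.per_fold) == 3
    assert len(models) == 3
    assert metrics.auc == pytest.approx(np.mean([m.auc for m in metrics.per_fold]))
    assert "±" in str(metrics)


def test_cross_validate_deterministic(mini_benchmark):
    kg, sl, _ = mini_benchmark
    labeled = concat_pair_sets([positive_pair_set(sl), sample_negatives(sl, sl.n_edges, 0)])
    cfg = small_cfg(max_epochs=6, patience=6)
    m1, _ = cross_validate(kg, sl, labeled, cfg, k=2)
    m2, _ = cross_validate(kg, sl, labeled, cfg, k=2)
    assert m1.auc == m2.auc


def test_cross_validate_requires_two_folds(mini_benchmark):
    kg, sl, _ = mini_benchmark
    labeled = positive_pair_set(sl)
    with pytest.raises(ValueError):
        cross_validate(kg, sl, labeled, small_cfg(), k=1)


# ---------------------------------------------------------------------------
# explain

def test_explain_rankings_and_pair(mini_benchmark):
    kg, sl, _ = mini_benchmark
    model, _, _, _ = run_experiment(kg, sl, small_cfg(max_epochs=5, patience=5))
    report = explain(model, pair=(sl.gene_vocab[0], sl.gene_vocab[1]))
    assert len(report.factor_rankings) == 2
    weights = [abs(w) for _, w in report.factor_rankings[0]]
    assert weights == sorted(weights, reverse=True)
    assert report.top_factor in (0, 1)
    for beta in report.pair_beta.values():
        assert np.sum(beta) == pytest.approx(1.0, abs=1e-6)


def test_explain_one_hot_alpha_ranks_that_relation_first(mini_benchmark):
    kg, sl, _ = mini_benchmark
    model, _, _, _ = run_experiment(kg, sl, small_cfg(max_epochs=2, patience=2))
    alpha = np.zeros_like(model.factor_bank.coefficients.data)
    alpha[0, 3] = 2.5
    model.factor_bank.coefficients.data = alpha
    report = explain(model)
    top_rel, top_w = report.factor_rankings[0][0]
    assert top_rel == model.kg.vocab.relation_names[3]
    assert top_w == pytest.approx(2.5)


def test_explain_unknown_gene_rejected(mini_benchmark):
    kg, sl, _ = mini_benchmark
    model, _, _, _ = run_experiment(kg, sl, small_cfg(max_epochs=2, patience=2))
    with pytest.raises(KeyError):
        explain(model, pair=("nope", sl.gene_vocab[0]))


# ---------------------------------------------------------------------------
# persistence

def test_model_save_load_roundtrip(tmp_path, mini_benchmark):
    kg, sl, _ = mini_benchmark
    model, _, _, splits = run_experiment(kg, sl, small_cfg(max_epochs=3, patience=3))
    model.save(tmp_path / "run")
    loaded = SLGNN.load(tmp_path / "run")
    pairs = splits[2].pairs
    assert np.allclose(loaded.predict(pairs), model.predict(pairs), atol=1e-12)
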