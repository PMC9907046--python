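"""Planted-factor synthetic KG + SL benchmark generator.

The generator embodies the model's core assumption — SL interactions arise
from a small number of latent mechanisms ("factors"), each expressed
through particular KG relation types — and plants that structure with known
ground truth:

1. relation types are partitioned across K planted factors;
2. each gene belongs to one (occasionally two) factors and is linked, via
   its factors' relations, to typed context entities (process/pathway/
   compound pools) owned by those factors, plus uniform noise triples;
3. SL edges are drawn preferentially between genes sharing a factor
   (with probability ``signal``), the rest uniformly at random.

Everything is deterministic under the spec's seed, and the ground truth
(relation -> factor map, per-gene memberships, per-edge generating factor)
is returned so factor-recovery claims can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .kg_data import EntityVocab, KnowledgeGraph, SLGraph

__all__ = ["SyntheticSpec", "GroundTruth", "generate_benchmark", "write_benchmark"]

_VERBS = ["participates", "regulates", "binds", "associates", "expresses", "interacts"]
_TYPES = ["BiologicalProcess", "Pathway", "Compound"]


@dataclass
class SyntheticSpec:
    """Benchmark parameters; defaults are the standard desk-scale study
    conditions (300 genes, 6 relation types, 4 planted factors, 3000 KG
    triples, 900 SL edges, signal 0.9)."""

    n_genes: int = 300
    n_relations: int = 6
    n_factors: int = 4
    n_triples: int = 3000
    n_sl_edges: int = 900
    signal: float = 0.9
    noise_fraction: float = 0.1
    second_factor_prob: float = 0.15
    context_per_factor_type: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.signal <= 1:
            raise ValueError("signal must be in [0, 1]")
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.n_relations < self.n_factors:
            raise ValueError("need at least one relation per planted factor")
        if self.n_sl_edges > self.n_genes * (self.n_genes - 1) // 2:
            raise ValueError("more SL edges requested than gene pairs exist")


@dataclass
class GroundTruth:
    """Planted structure: relation -> factor, gene memberships, and the
    factor (or None, for noise) that generated each SL edge."""

    relation_factor: dict[str, int]
    gene_factors: list[tuple[int, ...]]
    edge_factors: dict[tuple[int, int], int | None] = field(default_factory=dict)

    def factor_relations(self, factor: int) -> list[str]:
        return [r for r, f in self.relation_factor.items() if f == factor]

    def pair_shares_factor(self, i: int, j: int) -> bool:
        return bool(set(self.gene_factors[i]) & set(self.gene_factors[j]))

    def share_base_rate(self) -> float:
        """Exact probability that a uniform random gene pair shares a factor."""
        n = len(self.gene_factors)
        shared = sum(self.pair_shares_factor(i, j)
                     for i in range(n) for j in range(i + 1, n))
        return shared / (n * (n - 1) / 2)

    def to_json(self, path) -> None:
        data = {
            "relation_factor": self.relation_factor,
            "gene_factors": [list(f) for f in self.gene_factors],
            "edge_factors": [[list(e), f] for e, f in sorted(self.edge_factors.items())],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh)


def generate_benchmark(spec: SyntheticSpec) -> tuple[KnowledgeGraph, SLGraph, GroundTruth]:
    """Generate a planted-factor benchmark; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    K = spec.n_factors

    # relations: partitioned across factors; each carries a context type
    rel_names = [f"r{k}_{_VERBS[k % len(_VERBS)]}" for k in range(spec.n_relations)]
    rel_factor = {k: k % K for k in range(spec.n_relations)}
    rel_type = {k: k % len(_TYPES) for k in range(spec.n_relations)}
    factor_rels: list[list[int]] = [[] for _ in range(K)]
    for k, f in rel_factor.items():
        factor_rels[f].append(k)

    # gene memberships: one factor each, a minority get a second
    gene_names = [f"g{i:04d}" for i in range(spec.n_genes)]
    gene_factors: list[tuple[int, ...]] = []
    for _ in range(spec.n_genes):
        first = int(rng.integers(K))
        if rng.random() < spec.second_factor_prob:
            second = int(rng.integers(K - 1))
            if second >= first:
                second += 1
            gene_factors.append(tuple(sorted((first, second))))
        else:
            gene_factors.append((first,))

    # typed context entity pools, one pool per (factor, type)
    ctx_names: list[str] = []
    pool: dict[tuple[int, int], list[int]] = {}
    for f in range(K):
        for t, tname in enumerate(_TYPES):
            ids = []
            for c in range(spec.context_per_factor_type):
                ids.append(spec.n_genes + len(ctx_names))
                ctx_names.append(f"{tname}_f{f}_{c:02d}")
            pool[(f, t)] = ids

    entity_names = gene_names + ctx_names
    vocab = EntityVocab(entity_names, rel_names)

    # KG triples: factor-consistent signal plus uniform noise
    n_signal = int(round((1 - spec.noise_fraction) * spec.n_triples))
    triples: dict[tuple[int, int, int], None] = {}
    attempts = 0
    while len(triples) < n_signal:
        attempts += 1
        if attempts > 200 * spec.n_triples:
            raise ValueError("infeasible spec: cannot place requested signal triples")
        g = int(rng.integers(spec.n_genes))
        f = gene_factors[g][int(rng.integers(len(gene_factors[g])))]
        r = factor_rels[f][int(rng.integers(len(factor_rels[f])))]
        ctx = pool[(f, rel_type[r])][int(rng.integers(spec.context_per_factor_type))]
        triples.setdefault((g, r, ctx), None)
    while len(triples) < spec.n_triples:
        attempts += 1
        if attempts > 400 * spec.n_triples:
            raise ValueError("infeasible spec: cannot place requested noise triples")
        g = int(rng.integers(spec.n_genes))
        r = int(rng.integers(spec.n_relations))
        f_any = int(rng.integers(K))
        ctx = pool[(f_any, rel_type[r])][int(rng.integers(spec.context_per_factor_type))]
        triples.setdefault((g, r, ctx), None)
    kg = KnowledgeGraph(vocab, np.array(list(triples), dtype=np.int64))

    # SL edges: within-factor with probability `signal`, else uniform
    members: list[list[int]] = [[] for _ in range(K)]
    for g, fs in enumerate(gene_factors):
        for f in fs:
            members[f].append(g)
    factor_weights = np.array([len(m) * (len(m) - 1) / 2 for m in members], dtype=float)
    if factor_weights.sum() == 0:
        raise ValueError("infeasible spec: no within-factor gene pairs")
    factor_weights /= factor_weights.sum()
    edges: dict[tuple[int, int], int | None] = {}
    attempts = 0
    while len(edges) < spec.n_sl_edges:
        attempts += 1
        if attempts > 400 * spec.n_sl_edges:
            raise ValueError("infeasible spec: cannot place requested SL edges")
        if rng.random() < spec.signal:
            f = int(rng.choice(K, p=factor_weights))
            pair_pool = members[f]
            if len(pair_pool) < 2:
                continue
            i, j = rng.choice(len(pair_pool), size=2, replace=False)
            a, b = pair_pool[int(i)], pair_pool[int(j)]
            origin: int | None = f
        else:
            a, b = (int(x) for x in rng.integers(0, spec.n_genes, size=2))
            if a == b:
                continue
            origin = None
        key = (min(a, b), max(a, b))
        if key not in edges:
            edges[key] = origin
    sl = SLGraph(gene_names, set(edges))
    gt = GroundTruth(relation_factor={rel_names[k]: f for k, f in rel_factor.items()},
                     gene_factors=gene_factors, edge_factors=edges)
    return kg, sl, gt


def write_benchmark(spec: SyntheticSpec, out_dir) -> None:
    """Write kg.tsv, sl.tsv, ground_truth.json and the spec snapshot."""
    import pathlib

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kg, sl, gt = generate_benchmark(spec)
    kg.write_tsv(out_dir / "kg.tsv")
    sl.write_tsv(out_dir / "sl.tsv")
    gt.to_json(out_dir / "ground_truth.json")
    with open(out_dir / "spec.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(spec), fh, indent=2)


def match_factors_to_planted(alpha: np.ndarray, relation_names: list[str],
                             gt: GroundTruth) -> list[int]:
    """Map each learned factor to the planted factor owning its top-|alpha|
    relation (reverse relations count toward their forward twin)."""
    from .kg_data import REVERSE_SUFFIX

    mapping = []
    for p in range(alpha.shape[0]):
        order = np.argsort(-np.abs(alpha[p]))
        top = relation_names[order[0]]
        if top.endswith(REVERSE_SUFFIX):
            top = top[: -len(REVERSE_SUFFIX)]
        mapping.append(gt.relation_factor[top])
    return mapping


def recovery_is_bijection(alpha: np.ndarray, relation_names: list[str],
                          gt: GroundTruth) -> bool:
    """True when the learned->planted factor map is a permutation."""
    mapping = match_factors_to_planted(alpha, relation_names, gt)
    n_planted = len(set(gt.relation_factor.values()))
    return len(set(mapping)) == len(mapping) == n_planted
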