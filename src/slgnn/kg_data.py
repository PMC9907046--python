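"""Knowledge-graph and SL-graph containers, loaders, and sampling utilities.

The knowledge graph is a heterogeneous triple list ``(head, relation, tail)``
over named entities (genes, biological processes, compounds, ...); the SL
graph is an undirected simple graph over genes whose edges are known
synthetic-lethal interactions.  Both are stored with contiguous 0-based
integer indices internally; files always carry names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EntityVocab",
    "KnowledgeGraph",
    "SLGraph",
    "LabeledPairSet",
    "load_kg_triples",
    "symmetrize_kg",
    "load_sl_pairs",
    "sample_negatives",
    "split_pairs",
    "kg_edge_dropout",
]

REVERSE_SUFFIX = "_rev"


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class EntityVocab:
    """Bidirectional name <-> contiguous-index maps for entities and relations."""

    entity_names: list[str]
    relation_names: list[str]
    entity_index: dict[str, int] = field(init=False, repr=False)
    relation_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.entity_index = {n: i for i, n in enumerate(self.entity_names)}
        self.relation_index = {n: i for i, n in enumerate(self.relation_names)}
        if len(self.entity_index) != len(self.entity_names):
            raise ValueError("duplicate entity names in vocabulary")
        if len(self.relation_index) != len(self.relation_names):
            raise ValueError("duplicate relation names in vocabulary")

    @property
    def n_entities(self) -> int:
        return len(self.entity_names)

    @property
    def n_relations(self) -> int:
        return len(self.relation_names)


class KnowledgeGraph:
    """Triple list plus a per-entity neighbor index ``N_i = {(r, j)}``.

    ``triples`` is a ``(m, 3)`` int array of ``(head, relation, tail)``
    index rows, de-duplicated.  After :func:`symmetrize_kg` every forward
    triple has a reverse twin under a fresh reverse relation, and
    ``n_forward_relations`` records the pre-symmetrization relation count.
    """

    def __init__(self, vocab: EntityVocab, triples: np.ndarray,
                 symmetrized: bool = False, n_forward_relations: int | None = None):
        triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
        if triples.size:
            if triples[:, [0, 2]].max() >= vocab.n_entities or triples.min() < 0:
                raise ValueError("triple entity index out of vocabulary bounds")
            if triples[:, 1].max() >= vocab.n_relations:
                raise ValueError("triple relation index out of vocabulary bounds")
        self.vocab = vocab
        self.triples = triples
        self.symmetrized = symmetrized
        self.n_forward_relations = (n_forward_relations if n_forward_relations is not None
                                    else vocab.n_relations)
        # flat arrays for vectorized aggregation
        self.head = triples[:, 0].copy()
        self.rel = triples[:, 1].copy()
        self.tail = triples[:, 2].copy()
        self.degree = np.bincount(self.head, minlength=vocab.n_entities)

    @property
    def n_entities(self) -> int:
        return self.vocab.n_entities

    @property
    def n_relations(self) -> int:
        return self.vocab.n_relations

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def neighbors(self, entity: int) -> list[tuple[int, int]]:
        """Return ``N_i`` as a list of ``(relation, neighbor)`` pairs."""
        mask = self.head == entity
        return list(zip(self.rel[mask].tolist(), self.tail[mask].tolist()))

    def triple_set(self) -> set[tuple[int, int, int]]:
        return {tuple(t) for t in self.triples.tolist()}

    def to_frame(self) -> pd.DataFrame:
        ent, rel = self.vocab.entity_names, self.vocab.relation_names
        return pd.DataFrame({
            "head": [ent[h] for h in self.head],
            "relation": [rel[r] for r in self.rel],
            "tail": [ent[t] for t in self.tail],
        })

    def write_tsv(self, path, header: bool = False) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=header)


class SLGraph:
    """Undirected simple graph of synthetic-lethal gene pairs."""

    def __init__(self, gene_vocab: list[str], edges: set[tuple[int, int]]):
        self.gene_vocab = list(gene_vocab)
        self.gene_index = {g: i for i, g in enumerate(self.gene_vocab)}
        if len(self.gene_index) != len(self.gene_vocab):
            raise ValueError("duplicate gene names")
        for i, j in edges:
            if i == j:
                raise ValueError("self-loop in SL graph")
            if not (0 <= i < len(self.gene_vocab) and 0 <= j < len(self.gene_vocab)):
                raise ValueError("edge gene index out of bounds")
        self.edges = {(min(i, j), max(i, j)) for i, j in edges}
        self._adj: list[list[int]] = [[] for _ in self.gene_vocab]
        for i, j in sorted(self.edges):
            self._adj[i].append(j)
            self._adj[j].append(i)

    @property
    def n_genes(self) -> int:
        return len(self.gene_vocab)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: int) -> list[int]:
        return self._adj[gene]

    def degree(self) -> np.ndarray:
        return np.array([len(a) for a in self._adj], dtype=np.int64)

    def directed_edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Both orientations of every edge: ``dst[k]`` is a neighbor of ``src[k]``.

        Rows are sorted by (src, dst) so aggregation order is deterministic.
        """
        src, dst = [], []
        for i, adj in enumerate(self._adj):
            for j in adj:
                src.append(i)
                dst.append(j)
        return np.array(src, dtype=np.int64), np.array(dst, dtype=np.int64)

    def write_tsv(self, path) -> None:
        names = self.gene_vocab
        pd.DataFrame([(names[i], names[j]) for i, j in sorted(self.edges)]).to_csv(
            path, sep="\t", index=False, header=False)


@dataclass
class LabeledPairSet:
    """Gene pairs with 0/1 labels, tagged with the split they belong to."""

    pairs: np.ndarray  # (n, 2) gene indices
    labels: np.ndarray  # (n,) in {0, 1}
    split_tag: str = "all"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        seen: dict[tuple[int, int], int] = {}
        for (i, j), y in zip(self.pairs.tolist(), self.labels.tolist()):
            key = (min(i, j), max(i, j))
            if seen.setdefault(key, y) != y:
                raise ValueError(f"pair {key} appears with both labels")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def subset(self, idx: np.ndarray, split_tag: str | None = None) -> "LabeledPairSet":
        return LabeledPairSet(self.pairs[idx], self.labels[idx],
                              split_tag if split_tag is not None else self.split_tag)

    def write_tsv(self, path, gene_names: list[str]) -> None:
        pd.DataFrame({
            "geneA": [gene_names[i] for i in self.pairs[:, 0]],
            "geneB": [gene_names[j] for j in self.pairs[:, 1]],
            "label": self.labels,
            "split": self.split_tag,
        }).to_csv(path, sep="\t", index=False)


def concat_pair_sets(sets: list[LabeledPairSet], split_tag: str = "all") -> LabeledPairSet:
    return LabeledPairSet(np.concatenate([s.pairs for s in sets]),
                          np.concatenate([s.labels for s in sets]), split_tag)


# ---------------------------------------------------------------------------
# loaders

def _read_rows(path, n_cols: int, header: bool) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if header and lineno == 1:
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise ParseError(f"{path}: line {lineno}: expected {n_cols} "
                                 f"tab-separated columns, found {len(fields)}")
            rows.append(fields)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return rows


def load_kg_triples(path, header: bool = False) -> KnowledgeGraph:
    """Load a ``head<TAB>relation<TAB>tail`` triple file.

    Vocabularies are built from the names observed in the file, in order of
    first appearance; duplicate triple lines are dropped.
    """
    rows = _read_rows(path, 3, header)
    entities: dict[str, int] = {}
    relations: dict[str, int] = {}
    seen: set[tuple[int, int, int]] = set()
    triples: list[tuple[int, int, int]] = []
    for h, r, t in rows:
        hi = entities.setdefault(h, len(entities))
        ri = relations.setdefault(r, len(relations))
        ti = entities.setdefault(t, len(entities))
        key = (hi, ri, ti)
        if key not in seen:
            seen.add(key)
            triples.append(key)
    vocab = EntityVocab(list(entities), list(relations))
    return KnowledgeGraph(vocab, np.array(triples, dtype=np.int64))


def symmetrize_kg(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Make the KG undirected by adding a reverse twin for every triple.

    Each relation ``r`` gains a fresh reverse relation ``r_rev`` with its own
    embedding slot, so the relation vocabulary doubles; for every ``(h, r, t)``
    a triple ``(t, r_rev, h)`` is added.
    """
    if kg.symmetrized:
        raise ValueError("knowledge graph is already symmetrized")
    n_rel = kg.vocab.n_relations
    rel_names = kg.vocab.relation_names + [n + REVERSE_SUFFIX for n in kg.vocab.relation_names]
    vocab = EntityVocab(list(kg.vocab.entity_names), rel_names)
    reverse = np.column_stack([kg.tail, kg.rel + n_rel, kg.head])
    triples = np.concatenate([kg.triples, reverse])
    # drop exact duplicates while preserving forward-then-reverse order
    _, first = np.unique(triples, axis=0, return_index=True)
    keep = np.zeros(len(triples), dtype=bool)
    keep[first] = True
    return KnowledgeGraph(vocab, triples[keep], symmetrized=True, n_forward_relations=n_rel)


def load_sl_pairs(path, header: bool = False) -> SLGraph:
    """Load a two-column TSV of SL gene pairs into an undirected graph.

    Self-pairs are skipped with a warning; ``(a, b)`` and ``(b, a)`` collapse
    to one edge.
    """
    rows = _read_rows(path, 2, header)
    genes: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    n_self = 0
    for a, b in rows:
        ai = genes.setdefault(a, len(genes))
        bi = genes.setdefault(b, len(genes))
        if ai == bi:
            n_self += 1
            continue
        edges.add((min(ai, bi), max(ai, bi)))
    if n_self:
        warnings.warn(f"{path}: skipped {n_self} self-pair line(s)", stacklevel=2)
    sl = SLGraph(list(genes), edges)
    sl.n_self_pairs_skipped = n_self
    return sl


# ---------------------------------------------------------------------------
# sampling

def positive_pair_set(sl: SLGraph, split_tag: str = "all") -> LabeledPairSet:
    edges = np.array(sorted(sl.edges), dtype=np.int64).reshape(-1, 2)
    return LabeledPairSet(edges, np.ones(len(edges), dtype=np.int64), split_tag)


def sample_negatives(sl: SLGraph, n: int, seed: int) -> LabeledPairSet:
    """Sample ``n`` unordered non-edges uniformly without replacement."""
    n_genes = sl.n_genes
    total_pairs = n_genes * (n_genes - 1) // 2
    available = total_pairs - sl.n_edges
    if n > available:
        raise ValueError(f"requested {n} negatives but only {available} non-edges exist")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    if n > available // 2:
        # dense regime: enumerate all non-edges and choose directly
        all_pairs = [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)
                     if (i, j) not in sl.edges]
        idx = rng.choice(len(all_pairs), size=n, replace=False)
        chosen = {all_pairs[k] for k in idx}
    else:
        while len(chosen) < n:
            i, j = rng.integers(0, n_genes, size=2)
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in sl.edges or key in chosen:
                continue
            chosen.add(key)
    pairs = np.array(sorted(chosen), dtype=np.int64)
    return LabeledPairSet(pairs, np.zeros(n, dtype=np.int64))


def split_pairs(pairs: LabeledPairSet, ratios: tuple[float, float, float],
                seed: int) -> tuple[LabeledPairSet, LabeledPairSet, LabeledPairSet]:
    """Stratified train/val/test partition at the given ratios."""
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    buckets: list[list[int]] = [[], [], []]
    for label in (0, 1):
        idx = np.flatnonzero(pairs.labels == label)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        n_val = min(n_val, n - n_train)
        buckets[0].extend(idx[:n_train])
        buckets[1].extend(idx[n_train:n_train + n_val])
        buckets[2].extend(idx[n_train + n_val:])
    tags = ("train", "val", "test")
    out = []
    for tag, bucket in zip(tags, buckets):
        if not bucket:
            raise ValueError(f"{tag} split received zero pairs")
        out.append(pairs.subset(np.array(sorted(bucket), dtype=np.int64), split_tag=tag))
    return tuple(out)


def kg_edge_dropout(kg: KnowledgeGraph, ratio: float, seed: int) -> KnowledgeGraph:
    """Drop each forward/reverse triple pair jointly with probability ``ratio``.

    The vocabulary is unchanged; only the triple list (and hence the
    neighbor index) shrinks.  On a non-symmetrized graph triples are dropped
    independently.
    """
    if not 0 <= ratio < 1:
        raise ValueError("dropout ratio must be in [0, 1)")
    if ratio == 0:
        return kg
    rng = np.random.default_rng(seed)
    if kg.symmetrized:
        n_fwd_rel = kg.n_forward_relations
        fwd_mask = kg.rel < n_fwd_rel
        fwd = kg.triples[fwd_mask]
        keep = rng.random(len(fwd)) >= ratio
        kept_fwd = fwd[keep]
        kept_keys = {tuple(t) for t in kept_fwd.tolist()}
        out_rows = []
        for h, r, t in kg.triples.tolist():
            if r < n_fwd_rel:
                if (h, r, t) in kept_keys:
                    out_rows.append((h, r, t))
            else:
                if (t, r - n_fwd_rel, h) in kept_keys:
                    out_rows.append((h, r, t))
        triples = np.array(out_rows, dtype=np.int64).reshape(-1, 3)
    else:
        keep = rng.random(kg.n_triples) >= ratio
        triples = kg.triples[keep]
    return KnowledgeGraph(kg.vocab, triples, symmetrized=kg.symmetrized,
                          n_forward_relations=kg.n_forward_relations)
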