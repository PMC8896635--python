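"""KG backbone: random-walk node embeddings and the TransE alternative.

The walk-based path follows the node2vec recipe: biased second-order random
walks over the graph (treated as undirected for traversal), a skip-gram
model with negative sampling trained on the walk corpus, and a per-node
embedding table.  A triple is turned into a *sequence* by concatenating a
walk from its head and a walk from its tail, each terminated by a [SEP]
entry — with walk length L the sequence has 2L+2 positions, which is
co-designed with the KG half of the cross-encoder's combined input
(L=127 gives the full-scale 256).

The translational alternative embeds entities and relations so that
``e_head + e_relation ≈ e_tail`` and represents a triple as the 3-sequence
(head, relation, tail).
"""

from __future__ import annotations

import csv
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .data import KnowledgeGraph, Triple
from .exceptions import ConfigError, DataError

logger = logging.getLogger(__name__)

KG_SEP = "[SEP]"
KG_UNK = "[UNK]"


@dataclass
class RandomWalk:
    nodes: list[str]

    def __len__(self) -> int:
        return len(self.nodes)


def sample_walk(
    kg: KnowledgeGraph,
    start: str,
    length: int,
    p: float = 1.0,
    q: float = 1.0,
    rng: np.random.Generator | int | None = None,
    undirected: bool = True,
) -> RandomWalk:
    """Second-order biased random walk of ``length`` nodes from ``start``.

    The return parameter ``p`` and in-out parameter ``q`` reweight the step
    back to the previous node (1/p), steps to common neighbors of the
    previous node (1), and outward steps (1/q); ``p = q = 1`` is the uniform
    walk.  A node with no traversable neighbor repeats itself until the walk
    reaches full length, so sequences are always fixed-length.
    """
    if start not in kg.nodes:
        raise DataError(f"start node {start!r} not in graph")
    if length < 1:
        raise ConfigError("walk length must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    walk = [start]
    prev: str | None = None
    while len(walk) < length:
        cur = walk[-1]
        nbrs = kg.neighbors(cur, undirected=undirected)
        if not nbrs:
            walk.append(cur)  # dead end: pad by repetition
            continue
        if prev is None or (p == 1.0 and q == 1.0):
            nxt = nbrs[int(rng.integers(0, len(nbrs)))]
        else:
            prev_nbrs = set(kg.neighbors(prev, undirected=undirected))
            w = np.array([
                1.0 / p if x == prev else (1.0 if x in prev_nbrs else 1.0 / q)
                for x in nbrs
            ])
            w /= w.sum()
            nxt = nbrs[int(rng.choice(len(nbrs), p=w))]
        prev = cur
        walk.append(nxt)
    return RandomWalk(walk)


class NodeEmbeddingTable:
    """node identifier -> vector, with reserved [UNK] and [SEP] entries.

    The [SEP] entry separates the head- and tail-walk subsequences; [UNK]
    absorbs nodes unseen at training time.  Reserved entries sit at the end
    of the vocabulary so node ids are stable.
    """

    def __init__(self, nodes: list[str], matrix: np.ndarray):
        if matrix.shape[0] != len(nodes) + 2:
            raise DataError("matrix must have len(nodes) + 2 rows ([UNK], [SEP])")
        self.nodes = list(nodes)
        self.matrix = matrix
        self.node_to_id = {n: i for i, n in enumerate(self.nodes)}
        self.unk_id = len(self.nodes)
        self.sep_id = len(self.nodes) + 1

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def vocab_size(self) -> int:
        return self.matrix.shape[0]

    def id(self, node: str) -> int:
        return self.node_to_id.get(node, self.unk_id)

    def vector(self, node: str) -> np.ndarray:
        return self.matrix[self.id(node)]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "nodes.txt").write_text(
            "\n".join(self.nodes + [KG_UNK, KG_SEP]) + "\n", encoding="utf-8")
        np.save(directory / "vectors.npy", self.matrix)

    @classmethod
    def load(cls, directory: str | Path) -> "NodeEmbeddingTable":
        directory = Path(directory)
        entries = (directory / "nodes.txt").read_text(encoding="utf-8").splitlines()
        if entries[-2:] != [KG_UNK, KG_SEP]:
            raise DataError("node vocabulary must end with [UNK], [SEP]")
        matrix = np.load(directory / "vectors.npy")
        return cls(entries[:-2], matrix)


def _walk_corpus(kg: KnowledgeGraph, walk_length: int, walks_per_node: int,
                 p: float, q: float, rng: np.random.Generator) -> list[list[int]]:
    order = sorted(kg.nodes)
    index = {n: i for i, n in enumerate(order)}
    corpus = []
    for _ in range(walks_per_node):
        for n in order:
            walk = sample_walk(kg, n, walk_length, p=p, q=q, rng=rng)
            corpus.append([index[x] for x in walk.nodes])
    return corpus


def train_node_embeddings(
    kg: KnowledgeGraph,
    dim: int = 64,
    walk_length: int = 15,
    walks_per_node: int = 10,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    p: float = 1.0,
    q: float = 1.0,
    negatives: int = 5,
    lr: float = 0.025,
) -> NodeEmbeddingTable:
    """Skip-gram-with-negative-sampling over a random-walk corpus.

    Nodes co-occurring within ``window`` positions of a walk are trained to
    have similar vectors; negatives are drawn from the unigram^0.75
    distribution.  Deterministic under a fixed seed (single-threaded,
    full-batch vectorized updates in minibatches).
    """
    if dim <= 0:
        raise ConfigError("embedding dimension must be positive")
    if not kg.nodes:
        raise DataError("knowledge graph is empty")
    rng = np.random.default_rng(seed)
    order = sorted(kg.nodes)
    n = len(order)
    corpus = _walk_corpus(kg, walk_length, walks_per_node, p, q, rng)

    centers, contexts = [], []
    counts = np.zeros(n, dtype=np.float64)
    for walk in corpus:
        for i, c in enumerate(walk):
            counts[c] += 1
            lo, hi = max(0, i - window), min(len(walk), i + window + 1)
            for j in range(lo, hi):
                if j != i and walk[j] != c:
                    centers.append(c)
                    contexts.append(walk[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)
    noise = counts ** 0.75
    noise /= noise.sum()

    w_in = (rng.random((n, dim)) - 0.5) / dim
    w_out = np.zeros((n, dim))
    n_pairs = len(centers)
    batch = 1024
    total_steps = max(1, epochs * ((n_pairs + batch - 1) // batch))
    step = 0
    for _ in range(epochs):
        perm = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            idx = perm[s:s + batch]
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(n, size=(len(idx), negatives), p=noise)
            cur_lr = lr * max(1e-4, 1.0 - step / total_steps)
            vc = w_in[c]                              # (B, d)
            uo = w_out[o]                             # (B, d)
            un = w_out[neg]                           # (B, K, d)
            pos_score = expit(np.sum(vc * uo, axis=1))
            neg_score = expit(np.einsum("bd,bkd->bk", vc, un))
            g_pos = (pos_score - 1.0)[:, None]        # d/duo of -log sigma
            g_neg = neg_score[..., None]
            grad_vc = g_pos * uo + np.einsum("bk,bkd->bd", neg_score, un)
            np.add.at(w_out, o, -cur_lr * g_pos * vc)
            np.add.at(w_out, neg.ravel(),
                      -cur_lr * (g_neg * vc[:, None, :]).reshape(-1, dim))
            np.add.at(w_in, c, -cur_lr * grad_vc)
            step += 1

    reserved = (rng.random((2, dim)) - 0.5) / dim     # [UNK], [SEP]
    return NodeEmbeddingTable(order, np.vstack([w_in, reserved]))


@dataclass
class TripleSequence:
    """Embedding sequence for one triple, in walk or translational mode."""

    token_ids: np.ndarray     # ids into the node vocabulary (walk mode) or -1
    embeddings: np.ndarray    # (len, d)
    mode: str                 # "walk" | "transe"

    def __len__(self) -> int:
        return len(self.token_ids)


def triple_to_walk_sequence(
    triple: Triple,
    table: NodeEmbeddingTable,
    kg: KnowledgeGraph,
    length: int,
    rng: np.random.Generator | int | None = None,
    p: float = 1.0,
    q: float = 1.0,
) -> TripleSequence:
    """walk(head) + [SEP] + walk(tail) + [SEP]: 2*length + 2 positions.

    Endpoints absent from the graph fall back to the [UNK] entry repeated
    over the walk span, so the sequence length law always holds.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    ids: list[int] = []
    for endpoint in (triple.head, triple.tail):
        if endpoint in kg.nodes:
            walk = sample_walk(kg, endpoint, length, p=p, q=q, rng=rng)
            ids.extend(table.id(x) for x in walk.nodes)
        else:
            logger.warning("node %s not in KG; using [UNK] span", endpoint)
            ids.extend([table.unk_id] * length)
        ids.append(table.sep_id)
    token_ids = np.asarray(ids, dtype=np.int64)
    return TripleSequence(token_ids, table.matrix[token_ids], mode="walk")


class TranseModel:
    """Translational triple embeddings: score = ||e_h + e_r - e_t||."""

    def __init__(self, entities: list[str], relations: list[str],
                 ent_matrix: np.ndarray, rel_matrix: np.ndarray, norm: int = 2):
        if ent_matrix.shape[0] != len(entities) + 1:
            raise DataError("entity matrix must include an [UNK] row")
        if rel_matrix.shape[0] != len(relations) + 1:
            raise DataError("relation matrix must include an [UNK] row")
        self.entities = list(entities)
        self.relations = list(relations)
        self.ent = ent_matrix
        self.rel = rel_matrix
        self.norm = norm
        self._eid = {e: i for i, e in enumerate(self.entities)}
        self._rid = {r: i for i, r in enumerate(self.relations)}
        self.ent_unk = len(self.entities)
        self.rel_unk = len(self.relations)

    @property
    def dim(self) -> int:
        return self.ent.shape[1]

    def entity_id(self, e: str) -> int:
        return self._eid.get(e, self.ent_unk)

    def relation_id(self, r: str) -> int:
        return self._rid.get(r, self.rel_unk)

    def score(self, triple: Triple) -> float:
        """Plausibility distance; 0 iff e_h + e_r = e_t exactly."""
        d = (self.ent[self.entity_id(triple.head)]
             + self.rel[self.relation_id(triple.relation)]
             - self.ent[self.entity_id(triple.tail)])
        return float(np.linalg.norm(d, ord=self.norm))


def train_transe(
    kg: KnowledgeGraph,
    dim: int = 32,
    margin: float = 1.0,
    norm: int = 2,
    epochs: int = 50,
    negatives_per_positive: int = 1,
    lr: float = 0.01,
    seed: int = 0,
) -> TranseModel:
    """Margin-ranking training with uniform head-or-tail corruption.

    Entity vectors are renormalized to the unit sphere after every epoch.
    """
    if dim <= 0:
        raise ConfigError("embedding dimension must be positive")
    if margin <= 0:
        raise ConfigError("margin must be positive")
    if not kg.edges:
        raise DataError("knowledge graph is empty")
    rng = np.random.default_rng(seed)
    entities = sorted(kg.nodes)
    relations = sorted(kg.relations)
    eid = {e: i for i, e in enumerate(entities)}
    rid = {r: i for i, r in enumerate(relations)}
    ne, nr = len(entities), len(relations)
    bound = 6.0 / np.sqrt(dim)
    ent = rng.uniform(-bound, bound, size=(ne + 1, dim))
    rel = rng.uniform(-bound, bound, size=(nr + 1, dim))
    rel[:nr] /= np.maximum(np.linalg.norm(rel[:nr], axis=1, keepdims=True), 1e-12)

    h = np.array([eid[e.head] for e in kg.edges])
    r = np.array([rid[e.relation] for e in kg.edges])
    t = np.array([eid[e.tail] for e in kg.edges])
    m = len(h)
    for _ in range(epochs):
        ent[:ne] /= np.maximum(np.linalg.norm(ent[:ne], axis=1, keepdims=True), 1e-12)
        perm = rng.permutation(m)
        for k in range(negatives_per_positive):
            hh, rr, tt = h[perm], r[perm], t[perm]
            corrupt_head = rng.random(m) < 0.5
            rand_ent = rng.integers(0, ne, size=m)
            ch = np.where(corrupt_head, rand_ent, hh)
            ct = np.where(corrupt_head, tt, rand_ent)
            d_pos = ent[hh] + rel[rr] - ent[tt]
            d_neg = ent[ch] + rel[rr] - ent[ct]
            if norm == 1:
                s_pos = np.abs(d_pos).sum(axis=1)
                s_neg = np.abs(d_neg).sum(axis=1)
                g_pos, g_neg = np.sign(d_pos), np.sign(d_neg)
            else:
                s_pos = np.linalg.norm(d_pos, axis=1)
                s_neg = np.linalg.norm(d_neg, axis=1)
                g_pos = d_pos / np.maximum(s_pos[:, None], 1e-12)
                g_neg = d_neg / np.maximum(s_neg[:, None], 1e-12)
            active = (margin + s_pos - s_neg) > 0
            if not active.any():
                continue
            gp = lr * g_pos[active]
            gn = lr * g_neg[active]
            np.add.at(ent, hh[active], -gp)
            np.add.at(ent, tt[active], gp)
            np.add.at(rel, rr[active], -gp + gn)
            np.add.at(ent, ch[active], gn)
            np.add.at(ent, ct[active], -gn)
    ent[:ne] /= np.maximum(np.linalg.norm(ent[:ne], axis=1, keepdims=True), 1e-12)
    return TranseModel(entities, relations, ent, rel, norm=norm)


def triple_to_transe_sequence(triple: Triple, model: TranseModel) -> TripleSequence:
    """The 3-sequence (e_head, e_relation, e_tail); unknowns hit [UNK] rows."""
    hid = model.entity_id(triple.head)
    rid = model.relation_id(triple.relation)
    tid = model.entity_id(triple.tail)
    if hid == model.ent_unk or tid == model.ent_unk:
        logger.warning("unknown entity in %s; using [UNK] embedding", triple)
    if rid == model.rel_unk:
        logger.warning("unknown relation in %s; using [UNK] embedding", triple)
    emb = np.stack([model.ent[hid], model.rel[rid], model.ent[tid]])
    # token ids are in the *entity* vocabulary; the relation position carries
    # no entity id and is marked -1 (never a masking target)
    token_ids = np.asarray([hid, -1, tid], dtype=np.int64)
    return TripleSequence(token_ids, emb, mode="transe")


class WalkSequencer:
    """Deterministic triple -> walk-sequence builder with a per-node cache.

    One walk is sampled per node, seeded by (seed, crc32(node)), so the
    sequence for a triple is identical no matter when or how often it is
    requested; ``resample(epoch)`` switches to a fresh deterministic set of
    walks for callers that prefer per-epoch resampling.
    """

    def __init__(self, kg: KnowledgeGraph, table: NodeEmbeddingTable,
                 length: int, seed: int = 0, p: float = 1.0, q: float = 1.0):
        self.kg = kg
        self.table = table
        self.length = length
        self.seed = seed
        self.p = p
        self.q = q
        self.epoch = 0
        self._cache: dict[str, list[int]] = {}

    def resample(self, epoch: int) -> None:
        if epoch != self.epoch:
            self.epoch = epoch
            self._cache.clear()

    def _walk_ids(self, node: str) -> list[int]:
        if node not in self._cache:
            if node in self.kg.nodes:
                rng = np.random.default_rng(
                    [self.seed, self.epoch, zlib.crc32(node.encode())])
                walk = sample_walk(self.kg, node, self.length,
                                   p=self.p, q=self.q, rng=rng)
                self._cache[node] = [self.table.id(x) for x in walk.nodes]
            else:
                logger.warning("node %s not in KG; using [UNK] span", node)
                self._cache[node] = [self.table.unk_id] * self.length
        return self._cache[node]

    def __call__(self, triple: Triple) -> TripleSequence:
        ids = (self._walk_ids(triple.head) + [self.table.sep_id]
               + self._walk_ids(triple.tail) + [self.table.sep_id])
        token_ids = np.asarray(ids, dtype=np.int64)
        return TripleSequence(token_ids, self.table.matrix[token_ids], mode="walk")


class TranseSequencer:
    """triple -> (head, relation, tail) 3-sequence builder."""

    def __init__(self, model: TranseModel):
        self.model = model

    def __call__(self, triple: Triple) -> TripleSequence:
        return triple_to_transe_sequence(triple, self.model)


def write_walk_cache(walks: list[RandomWalk], path: str | Path) -> None:
    """TSV cache: one walk per row, node ids as columns."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for walk in walks:
            w.writerow(walk.nodes)


def read_walk_cache(path: str | Path) -> list[RandomWalk]:
    with open(path, encoding="utf-8", newline="") as fh:
        return [RandomWalk(row) for row in csv.reader(fh, delimiter="\t") if row]
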