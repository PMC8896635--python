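"""Synthetic knowledge graphs and text-triple corpora for desk-scale runs.

Real corpora of this kind pair a large assembled KG (millions of triples
over grounded, namespace-prefixed identifiers) with one evidence sentence
per triple, of which only a small annotated minority carries task labels.
This module emulates that shape at toy scale so every downstream stage —
walk embeddings, cross-encoder pre-training, fine-tuning, benchmarking —
can be exercised without any download.

Label functions come in four kinds, chosen so each modality's usefulness is
controlled by construction:

``text_determined``
    the label is carried by a context keyword injected into the sentence and
    is statistically independent of the nodes;
``node_determined``
    the label is a deterministic function of the head node's numeric id (a
    stand-in for id-encoded side information, e.g. species-specific
    namespaces); the sentence carries no keyword;
``relation_determined``
    the label is a function of the relation type (whose verb phrase also
    appears in the sentence, so both modalities can recover it);
``fused``
    the label is ``(keyword + node attribute) mod n_classes``, so neither
    modality alone determines it but the two jointly do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import KnowledgeGraph, TextTriplePair, Triple, copy_pair
from .exceptions import ConfigError, DataError

TASK_KINDS = ("text_determined", "node_determined", "relation_determined", "fused")

NAMESPACE = "toy"

# verb phrases per relation type, cycled; surface analogue of typed edges
_RELATION_NAMES = [
    "directlyIncreases", "directlyDecreases", "bindsTo", "regulates",
    "phosphorylates", "transcribes", "inhibits", "associatesWith",
]
_VERB_PHRASES = {
    "directlyIncreases": "directly increases",
    "directlyDecreases": "directly decreases",
    "bindsTo": "binds to",
    "regulates": "regulates",
    "phosphorylates": "phosphorylates",
    "transcribes": "transcribes",
    "inhibits": "inhibits",
    "associatesWith": "associates with",
}

N_KEYWORDS = 10  # one possible context keyword per maximum class count


@dataclass
class SynthConfig:
    """Generator settings; the defaults define the package's desk-scale corpus."""

    n_nodes: int = 120
    n_relations: int = 4
    mean_degree: float = 6.0
    n_pairs: int = 2000
    vocab_size: int = 200
    annotation_fraction: float = 0.5
    seed: int = 0
    n_blocks: int = 2
    homophily: float = 0.85

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ConfigError("n_nodes must be >= 2")
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if not 0.0 <= self.homophily <= 1.0:
            raise ConfigError("homophily must be in [0, 1]")
        if self.n_relations < 1:
            raise ConfigError("n_relations must be >= 1")
        if self.mean_degree <= 0:
            raise ConfigError("mean_degree must be positive")
        if self.n_pairs < 0:
            raise ConfigError("n_pairs must be >= 0")
        if self.vocab_size < 1:
            raise ConfigError("vocab_size must be >= 1")
        if not 0.0 <= self.annotation_fraction <= 1.0:
            raise ConfigError("annotation_fraction must be in [0, 1]")


def node_id(i: int) -> str:
    return f"{NAMESPACE}:{i:04d}"


def node_index(node: str) -> int:
    """Numeric part of a synthetic node identifier."""
    try:
        return int(node.split(":", 1)[1])
    except (IndexError, ValueError) as exc:
        raise DataError(f"not a synthetic node id: {node!r}") from exc


def surface_name(node: str) -> str:
    """Distinct human-readable name for a grounded identifier (g17 for toy:0017)."""
    return f"g{node_index(node)}"


def relation_name(r: int) -> str:
    if r < len(_RELATION_NAMES):
        return _RELATION_NAMES[r]
    return f"rel{r}"


def verb_phrase(relation: str) -> str:
    return _VERB_PHRASES.get(relation, "interacts with")


def node_attribute(node: str, n_values: int) -> int:
    """Deterministic per-node attribute in [0, n_values)."""
    return node_index(node) % n_values


def generate_kg(cfg: SynthConfig) -> KnowledgeGraph:
    """Sample a relation-typed block-structured random graph, no isolates.

    ``round(n_nodes * mean_degree / 2)`` directed edges are drawn with heads
    uniform over nodes; each tail comes from the head's block (``id mod
    n_blocks``) with probability ``homophily`` and from the other blocks
    otherwise (self-loops excluded), a stochastic-block-model-style layout
    that lets node neighborhoods encode block membership — the synthetic
    analogue of identifier-encoded side information such as species-specific
    namespaces.  Isolated nodes are then connected by one extra edge each.
    Identical configs give byte-identical edge lists.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    blocks = [[i for i in range(n) if i % cfg.n_blocks == b]
              for b in range(cfg.n_blocks)]
    blocks = [b for b in blocks if b]

    def sample_tail(head: int) -> int:
        own = blocks[head % cfg.n_blocks] if cfg.n_blocks > 1 else blocks[0]
        same = (len(blocks) == 1 or len(own) > 1 and
                rng.random() < cfg.homophily)
        pool = own if same else [i for i in range(n)
                                 if i % cfg.n_blocks != head % cfg.n_blocks]
        t = head
        while t == head:
            t = pool[int(rng.integers(0, len(pool)))]
        return t

    n_edges = max(1, round(n * cfg.mean_degree / 2))
    edges = []
    touched = set()
    for _ in range(n_edges):
        h = int(rng.integers(0, n))
        t = sample_tail(h)
        r = int(rng.integers(0, cfg.n_relations))
        edges.append(Triple(node_id(h), relation_name(r), node_id(t)))
        touched.add(h)
        touched.add(t)
    for i in range(n):
        if i not in touched:
            t = sample_tail(i)
            r = int(rng.integers(0, cfg.n_relations))
            edges.append(Triple(node_id(i), relation_name(r), node_id(t)))
    return KnowledgeGraph(edges)


def _sentence(rng: np.random.Generator, triple: Triple, vocab_size: int) -> str:
    """Template: '<head-name> <verb-phrase> <tail-name> <filler...>'."""
    n_filler = int(rng.integers(2, 7))
    filler = [f"w{int(j)}" for j in rng.integers(0, vocab_size, size=n_filler)]
    tokens = [surface_name(triple.head), verb_phrase(triple.relation),
              surface_name(triple.tail), *filler]
    return " ".join(tokens)


def generate_pairs(kg: KnowledgeGraph, cfg: SynthConfig) -> list[TextTriplePair]:
    """Draw triples from the KG and render one evidence sentence per triple.

    Exactly ``round(annotation_fraction * n_pairs)`` pairs are marked
    annotation-capable (``annotations == {}``); the rest carry ``None`` and
    feed the unlabeled pretraining corpus.
    """
    if kg.n_edges == 0:
        raise DataError("knowledge graph has no edges")
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_pairs
    edge_idx = rng.integers(0, kg.n_edges, size=n)
    n_annotated = round(cfg.annotation_fraction * n)
    annotated = set(rng.choice(n, size=n_annotated, replace=False).tolist()) if n else set()
    pairs = []
    for i in range(n):
        triple = kg.edges[int(edge_idx[i])]
        pairs.append(TextTriplePair(
            pair_id=f"p{i:06d}",
            evidence=_sentence(rng, triple, cfg.vocab_size),
            triple=triple,
            annotations={} if i in annotated else None,
        ))
    return pairs


def _fail_if_class_empty(labels: list[int], n_classes: int) -> None:
    seen = set(labels)
    missing = [c for c in range(n_classes) if c not in seen]
    if missing:
        raise ConfigError(
            f"classes {missing} unrealizable: n_classes={n_classes} exceeds the "
            "distinct labels the task function can produce on these pairs")


def generate_task_labels(
    pairs: list[TextTriplePair],
    task_kind: str,
    n_classes: int,
    seed: int,
    task_name: str | None = None,
) -> list[TextTriplePair]:
    """Label the annotation-capable pairs with a task of the given kind.

    Returns copies of the annotated pairs with ``annotations[task_name]``
    set to the class label (``"c0"``..) and, for text-dependent kinds, the
    class keyword token injected into the evidence sentence.
    """
    if task_kind not in TASK_KINDS:
        raise ConfigError(f"unknown task_kind {task_kind!r}; expected one of {TASK_KINDS}")
    if not 2 <= n_classes <= 10:
        raise ConfigError("n_classes must be in [2, 10]")
    name = task_name or f"{task_kind}{n_classes}"
    capable = [p for p in pairs if p.annotations is not None]
    if not capable:
        raise DataError("no annotation-capable pairs to label")
    rng = np.random.default_rng(seed)

    labeled: list[TextTriplePair] = []
    labels: list[int] = []
    if task_kind == "relation_determined":
        rels = sorted({p.triple.relation for p in capable})
        if len(rels) < n_classes:
            raise ConfigError(
                f"n_classes={n_classes} exceeds the {len(rels)} distinct relation types")
        rel_to_class = {r: i % n_classes for i, r in enumerate(rels)}
    for p in capable:
        kw: int | None = None
        if task_kind == "text_determined":
            label = kw = int(rng.integers(0, n_classes))
        elif task_kind == "node_determined":
            label = node_attribute(p.triple.head, n_classes)
        elif task_kind == "relation_determined":
            label = rel_to_class[p.triple.relation]
        else:  # fused: joint function of a text keyword and a node attribute
            a, b = fused_factorization(n_classes)
            kw = int(rng.integers(0, a))
            attr = node_attribute(p.triple.head, b)
            label = (kw * b + attr) if a * b == n_classes \
                else (kw + attr) % n_classes
        evidence = p.evidence if kw is None else f"{p.evidence} ctx{kw}"
        q = copy_pair(p, evidence=evidence)
        q.annotations = dict(p.annotations)
        q.annotations[name] = f"c{label}"
        labeled.append(q)
        labels.append(label)
    _fail_if_class_empty(labels, n_classes)
    return labeled


def fused_factorization(n_classes: int) -> tuple[int, int]:
    """Keyword/attribute cardinalities (a, b) for the fused label function.

    Composite ``n_classes`` factorizes as a * b with the smallest prime
    factor as a (so 4 -> 2x2, 6 -> 2x3, 9 -> 3x3); primes fall back to
    a = b = n_classes with a modular-sum label.
    """
    for a in range(2, int(n_classes ** 0.5) + 1):
        if n_classes % a == 0:
            return a, n_classes // a
    return n_classes, n_classes


def fused_truth_table(n_classes: int) -> np.ndarray:
    """Label of the fused task for every (keyword, node attribute) combination.

    For composite ``n_classes`` the table is ``table[kw, attr] = kw * b +
    attr`` over an (a, b) grid: the keyword selects a block of classes and
    the node attribute the class within it, so keyword alone achieves Bayes
    accuracy 1/b and the attribute alone 1/a.  For prime ``n_classes`` the
    label is ``(kw + attr) % n_classes`` over an (n, n) grid, where either
    factor alone leaves a uniform posterior (Bayes accuracy 1/n).  In both
    cases neither modality determines the label by itself.
    """
    a, b = fused_factorization(n_classes)
    kw = np.arange(a)[:, None]
    attr = np.arange(b)[None, :]
    if a * b == n_classes:
        return kw * b + attr
    return (kw + attr) % n_classes
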