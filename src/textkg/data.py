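"""Data model and I/O for knowledge graphs and text-triple pairs.

A *triple* is a (head, relation, tail) statement over grounded node
identifiers (namespace-prefixed strings such as ``hgnc:6307``).  A
*text-triple pair* couples a triple with the evidence sentence it was
extracted from, plus optional per-task class annotations.  This module
provides the on-disk formats (TSV edge lists, TSV pair tables with a JSON
annotation column), the corpus-cleaning filter (grounded endpoints, non-empty
evidence), the pretraining/fine-tuning partition, and deterministic
cross-validation splits shared by every model in a benchmark.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ConfigError, DataError, ParseError

PAIR_COLUMNS = ["pair_id", "evidence", "head", "relation", "tail", "annotations"]


@dataclass(frozen=True)
class Triple:
    """A directed, typed edge: (head, relation, tail)."""

    head: str
    relation: str
    tail: str

    def __post_init__(self):
        if not (self.head and self.relation and self.tail):
            raise DataError(f"triple fields must be non-empty: {self!r}")

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.head, self.relation, self.tail)


@dataclass
class TextTriplePair:
    """An evidence sentence paired with the triple it supports.

    ``annotations`` is ``None`` for pairs that can never carry task labels,
    and a (possibly empty) ``task name -> class label`` mapping for pairs in
    the annotated minority.
    """

    pair_id: str
    evidence: str
    triple: Triple
    annotations: dict[str, str] | None = None

    @property
    def is_annotated(self) -> bool:
        return bool(self.annotations)


class KnowledgeGraph:
    """Node set plus typed directed edges, with adjacency for random walks."""

    def __init__(self, edges: list[Triple]):
        self.edges: list[Triple] = list(edges)
        self.nodes: set[str] = set()
        self.out_neighbors: dict[str, set[str]] = {}
        self.in_neighbors: dict[str, set[str]] = {}
        for e in self.edges:
            self.nodes.add(e.head)
            self.nodes.add(e.tail)
            self.out_neighbors.setdefault(e.head, set()).add(e.tail)
            self.in_neighbors.setdefault(e.tail, set()).add(e.head)
        for n in self.nodes:
            self.out_neighbors.setdefault(n, set())
            self.in_neighbors.setdefault(n, set())
        self.relations: list[str] = sorted({e.relation for e in self.edges})
        self._edge_set = {e.as_tuple() for e in self.edges}

    def __contains__(self, triple: Triple) -> bool:
        return triple.as_tuple() in self._edge_set

    def neighbors(self, node: str, undirected: bool = True) -> list[str]:
        """Traversable neighbors of ``node`` (sorted for determinism)."""
        if undirected:
            return sorted(self.out_neighbors[node] | self.in_neighbors[node])
        return sorted(self.out_neighbors[node])

    def degree(self, node: str) -> int:
        return len(self.out_neighbors[node]) + len(self.in_neighbors[node])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_edgelist(kg: KnowledgeGraph, path: str | Path) -> None:
    """Write a headerless ``head<TAB>relation<TAB>tail`` edge list (UTF-8)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for e in kg.edges:
            w.writerow([e.head, e.relation, e.tail])


def read_edgelist(path: str | Path) -> KnowledgeGraph:
    edges = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"expected 3 columns, got {len(row)}", line=lineno)
            edges.append(Triple(*row))
    return KnowledgeGraph(edges)


def write_pairs(pairs: list[TextTriplePair], path: str | Path) -> None:
    """Write the TSV pair table.

    Columns: pair_id, evidence, head, relation, tail, annotations.  The
    annotations column holds a JSON object for annotation-capable pairs and
    is empty otherwise, so the file stays greppable and diff-able.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PAIR_COLUMNS)
        for p in pairs:
            ann = "" if p.annotations is None else json.dumps(p.annotations, sort_keys=True)
            w.writerow([p.pair_id, p.evidence, p.triple.head, p.triple.relation,
                        p.triple.tail, ann])


def read_pairs(path: str | Path) -> list[TextTriplePair]:
    pairs = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file: missing header", line=1)
        if header != PAIR_COLUMNS:
            raise ParseError(f"bad header {header!r}, expected {PAIR_COLUMNS!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(PAIR_COLUMNS):
                raise ParseError(
                    f"expected {len(PAIR_COLUMNS)} columns, got {len(row)}", line=lineno)
            pair_id, evidence, head, relation, tail, ann_raw = row
            try:
                triple = Triple(head, relation, tail)
            except DataError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if ann_raw == "":
                annotations = None
            else:
                try:
                    annotations = json.loads(ann_raw)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"bad annotations JSON: {exc}", line=lineno) from exc
            pairs.append(TextTriplePair(pair_id, evidence, triple, annotations))
    return pairs


# ---------------------------------------------------------------------------
# Corpus preparation
# ---------------------------------------------------------------------------

def is_grounded(node: str, kg: KnowledgeGraph) -> bool:
    """A node is grounded if it carries a namespace prefix and is in the KG."""
    return ":" in node and node in kg.nodes


def filter_pairs(pairs: list[TextTriplePair], kg: KnowledgeGraph) -> list[TextTriplePair]:
    """Drop pairs with empty evidence or ungrounded endpoints; keep order.

    Idempotent: running the filter twice returns the same list.
    """
    return [
        p for p in pairs
        if p.evidence.strip()
        and is_grounded(p.triple.head, kg)
        and is_grounded(p.triple.tail, kg)
    ]


def split_corpus(
    pairs: list[TextTriplePair],
) -> tuple[list[TextTriplePair], dict[str, list[TextTriplePair]]]:
    """Partition a filtered corpus into pretraining and fine-tuning sides.

    Unannotated pairs go to the (unlabeled) pretraining corpus; a pair
    annotated for task T appears under ``finetuning[T]`` (and under every
    other task it is annotated for).
    """
    pretraining: list[TextTriplePair] = []
    finetuning: dict[str, list[TextTriplePair]] = {}
    for p in pairs:
        if p.is_annotated:
            for task in p.annotations:
                finetuning.setdefault(task, []).append(p)
        else:
            pretraining.append(p)
    return pretraining, finetuning


@dataclass
class CvSplit:
    """A deterministic k-fold partition keyed by pair id."""

    k: int
    fold_assignment: dict[str, int] = field(default_factory=dict)

    def test_ids(self, fold: int) -> list[str]:
        return [pid for pid, f in self.fold_assignment.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [pid for pid, f in self.fold_assignment.items() if f != fold]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.fold_assignment.values():
            sizes[f] += 1
        return sizes


def make_cv_splits(
    dataset: list[TextTriplePair],
    k: int,
    seed: int,
    labels: list[str] | None = None,
) -> CvSplit:
    """Deterministic k-fold assignment; optionally stratified by class label.

    The same (dataset, k, seed) always yields the same assignment, so every
    model in a benchmark can be trained and scored on identical splits.
    Unstratified folds differ in size by at most one; stratified folds keep
    each class's per-fold count within one of the even allocation.
    """
    n = len(dataset)
    if n < k:
        raise ConfigError(f"need at least k={k} examples, got {n}")
    if k < 2:
        raise ConfigError("k must be >= 2")
    ids = [p.pair_id for p in dataset]
    if len(set(ids)) != n:
        raise DataError("pair_ids must be unique within a CV dataset")
    assignment: dict[str, int] = {}
    if labels is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids)
    else:
        if len(labels) != n:
            raise DataError("labels length must match dataset length")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids, labels)
    for fold, (_, test_idx) in enumerate(split_iter):
        for i in test_idx:
            assignment[ids[i]] = fold
    return CvSplit(k=k, fold_assignment=assignment)


def subset_by_ids(pairs: list[TextTriplePair], ids: list[str]) -> list[TextTriplePair]:
    wanted = set(ids)
    return [p for p in pairs if p.pair_id in wanted]


def copy_pair(pair: TextTriplePair, **changes) -> TextTriplePair:
    """Shallow copy with field overrides (annotations dict is copied)."""
    out = replace(pair, **changes)
    if out.annotations is not None and "annotations" not in changes:
        out.annotations = dict(out.annotations)
    return out
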