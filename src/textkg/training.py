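"""Pre-training and fine-tuning loops for the cross encoder and baselines.

All transformer training uses AdamW with a linearly decaying learning rate
and no early stopping; epochs/steps are fixed by configuration.  The
default fine-tuning profile is 5 epochs, batch size 16, initial learning
rate 5e-5.  The KG baseline trains only a linear + softmax head on
dimension-wise-max-pooled static embedding sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import nn
from .data import TextTriplePair, Triple
from .embeddings import TripleSequence
from .exceptions import ConfigError, DataError
from .model import (CombinedInput, CrossEncoder, TextEncoder, apply_masking,
                    assemble_input, collate, compute_losses,
                    make_nsp_examples)
from .text import TextVocabulary, tokenize

VARIANTS = ("full", "no_nsp", "transe_input")


@dataclass
class TrainConfig:
    """Optimization settings shared by pre-training and fine-tuning."""

    batch_size: int = 16
    epochs: int = 5
    lr: float = 5e-5
    weight_decay: float = 0.01
    seed: int = 0
    steps: int | None = None            # pre-training step budget
    checkpoint_steps: tuple[int, ...] = ()
    variant: str = "full"
    mask_prob: float = 0.15
    nsp_negative_fraction: float = 0.25
    log_every: int = 10

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigError("learning rate must be positive")
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}")
        if list(self.checkpoint_steps) != sorted(self.checkpoint_steps):
            raise ConfigError("checkpoint_steps must be sorted ascending")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


def default_finetune_config(seed: int = 0, **overrides) -> TrainConfig:
    """The standard fine-tuning profile: 5 epochs, batch 16, lr 5e-5."""
    return TrainConfig(batch_size=16, epochs=5, lr=5e-5, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Pre-training
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    step: int
    state: dict[str, np.ndarray]


def pretrain(
    pairs: list[TextTriplePair],
    model: CrossEncoder,
    text_vocab: TextVocabulary,
    seq_builder: Callable[[Triple], TripleSequence],
    cfg: TrainConfig,
    node_matrix: np.ndarray | None = None,
    metrics_path: str | Path | None = None,
) -> tuple[list[Checkpoint], list[dict]]:
    """Masked-objective pre-training on an unlabeled corpus.

    The corpus is NSP-augmented (negatives are randomly re-paired
    evidence/triple combinations) unless the variant is ``no_nsp``; every
    example, matched or random, contributes to the MLM and MEM objectives.
    A checkpoint (deep-copied weights) is emitted at each configured step
    and at the final step, so an interim checkpoint is exactly the state of
    the longer run at that step.  Returns the checkpoints and the metrics
    log (one JSON-able record per logged step).
    """
    if not pairs:
        raise ConfigError("pre-training corpus is empty")
    if cfg.steps is None or cfg.steps < 1:
        raise ConfigError("cfg.steps must be set for pre-training")
    loss_variant = "no_nsp" if cfg.variant == "no_nsp" else "full"
    rng = np.random.default_rng(cfg.seed)
    if loss_variant == "no_nsp" or cfg.nsp_negative_fraction == 0:
        examples = [(p, 0) for p in pairs]
    else:
        examples = make_nsp_examples(pairs, cfg.nsp_negative_fraction,
                                     seed=cfg.seed)
    assembled: list[CombinedInput] = []
    for p, nsp_label in examples:
        inp = assemble_input(p, text_vocab, seq_builder, model.config)
        inp.nsp_label = nsp_label
        assembled.append(inp)

    params = model.trainable_parameters()
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay,
                   total_steps=cfg.steps)
    mem_vocab = model.config.node_vocab_size
    checkpoints: list[Checkpoint] = []
    metrics: list[dict] = []
    pending = list(cfg.checkpoint_steps)
    n = len(assembled)
    for step in range(1, cfg.steps + 1):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        masked = [apply_masking(assembled[i], text_vocab, mem_vocab,
                                cfg.mask_prob, rng, node_matrix)
                  for i in idx]
        batch = collate(masked)
        _, mlm_logits, mem_logits, nsp_logits = model.forward(batch)
        losses = compute_losses(mlm_logits, mem_logits, nsp_logits, batch,
                                variant=loss_variant)
        opt.zero_grad()
        losses.total.backward()
        opt.step()
        if step % cfg.log_every == 0 or step == 1 or step == cfg.steps:
            metrics.append({"step": step, **losses.as_floats()})
        while pending and step == pending[0]:
            checkpoints.append(Checkpoint(step, model.state_dict()))
            pending.pop(0)
    if not checkpoints or checkpoints[-1].step != cfg.steps:
        checkpoints.append(Checkpoint(cfg.steps, model.state_dict()))
    if metrics_path is not None:
        with open(metrics_path, "w", encoding="utf-8") as fh:
            for rec in metrics:
                fh.write(json.dumps(rec) + "\n")
    return checkpoints, metrics


def smoothed(values: list[float], window: int = 20) -> list[float]:
    """Trailing moving average used to judge loss trends."""
    out = []
    for i in range(len(values)):
        lo = max(0, i - window + 1)
        out.append(float(np.mean(values[lo:i + 1])))
    return out


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class Classifier:
    """A fitted model predicting task classes for text-triple pairs."""

    def __init__(self, classes: list[str]):
        self.classes = list(classes)

    def predict(self, pairs: list[TextTriplePair]) -> list[str]:
        raise NotImplementedError


def _label_indices(labels: list[str], classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    bad = [l for l in labels if l not in index]
    if bad:
        raise DataError(f"labels outside task classes: {sorted(set(bad))[:5]}")
    return np.asarray([index[l] for l in labels], dtype=np.int64)


class CrossEncoderClassifier(Classifier):
    def __init__(self, model: CrossEncoder, head: nn.Linear,
                 text_vocab: TextVocabulary,
                 seq_builder: Callable[[Triple], TripleSequence],
                 classes: list[str]):
        super().__init__(classes)
        self.model = model
        self.head = head
        self.text_vocab = text_vocab
        self.seq_builder = seq_builder

    def _logits(self, pairs: list[TextTriplePair]) -> np.ndarray:
        out = []
        for s in range(0, len(pairs), 64):
            chunk = pairs[s:s + 64]
            batch = collate([assemble_input(p, self.text_vocab,
                                            self.seq_builder, self.model.config)
                             for p in chunk])
            hidden, _, _, _ = self.model.forward(batch)
            cls = hidden.slice((slice(None), 0))
            out.append(self.head(cls).data)
        return np.vstack(out)

    def predict(self, pairs: list[TextTriplePair]) -> list[str]:
        return [self.classes[i] for i in self._logits(pairs).argmax(axis=1)]


class TextClassifier(Classifier):
    def __init__(self, encoder: TextEncoder, head: nn.Linear,
                 text_vocab: TextVocabulary, target_length: int,
                 classes: list[str]):
        super().__init__(classes)
        self.encoder = encoder
        self.head = head
        self.text_vocab = text_vocab
        self.target_length = target_length

    def _logits(self, pairs: list[TextTriplePair]) -> np.ndarray:
        out = []
        for s in range(0, len(pairs), 64):
            chunk = pairs[s:s + 64]
            toks = [tokenize(p.evidence, self.text_vocab, self.target_length)
                    for p in chunk]
            ids = np.stack([t.token_ids for t in toks])
            mask = np.stack([t.attention_mask for t in toks])
            hidden = self.encoder.forward(ids, mask)
            cls = hidden.slice((slice(None), 0))
            out.append(self.head(cls).data)
        return np.vstack(out)

    def predict(self, pairs: list[TextTriplePair]) -> list[str]:
        return [self.classes[i] for i in self._logits(pairs).argmax(axis=1)]


class StaticSequenceClassifier(Classifier):
    """Linear + softmax head over max-pooled static embedding sequences."""

    def __init__(self, head: LogisticRegression,
                 seq_builder: Callable[[Triple], TripleSequence],
                 classes: list[str], single_class: str | None = None):
        super().__init__(classes)
        self.head = head
        self.seq_builder = seq_builder
        self.single_class = single_class

    def predict(self, pairs: list[TextTriplePair]) -> list[str]:
        if self.single_class is not None:
            return [self.single_class] * len(pairs)
        feats = np.stack([pool_max(self.seq_builder(p.triple).embeddings)
                          for p in pairs])
        return [str(c) for c in self.head.predict(feats)]


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------

def _epoch_batches(n: int, batch_size: int, epochs: int,
                   rng: np.random.Generator):
    for _ in range(epochs):
        perm = rng.permutation(n)
        for s in range(0, n, batch_size):
            yield perm[s:s + batch_size]


def finetune(
    model: CrossEncoder,
    pairs: list[TextTriplePair],
    labels: list[str],
    classes: list[str],
    text_vocab: TextVocabulary,
    seq_builder: Callable[[Triple], TripleSequence],
    cfg: TrainConfig,
) -> CrossEncoderClassifier:
    """Fine-tune every parameter of the cross encoder plus a fresh head.

    [CLS] pooling into a single linear + softmax classification layer;
    deterministic under a fixed seed (single-threaded).
    """
    if len(pairs) != len(labels):
        raise DataError("pairs and labels must align")
    y = _label_indices(labels, classes)
    rng = np.random.default_rng(cfg.seed)
    head = nn.Linear(model.config.hidden, len(classes), rng)
    assembled = [assemble_input(p, text_vocab, seq_builder, model.config)
                 for p in pairs]
    n = len(assembled)
    steps = cfg.epochs * ((n + cfg.batch_size - 1) // cfg.batch_size)
    params = model.trainable_parameters() + head.parameters()
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay,
                   total_steps=max(steps, 1))
    for idx in _epoch_batches(n, cfg.batch_size, cfg.epochs, rng):
        batch = collate([assembled[i] for i in idx])
        hidden, _, _, _ = model.forward(batch)
        cls = hidden.slice((slice(None), 0))
        loss = nn.cross_entropy_logits(head(cls), y[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
    return CrossEncoderClassifier(model, head, text_vocab, seq_builder, classes)


def finetune_text_baseline(
    encoder: TextEncoder,
    pairs: list[TextTriplePair],
    labels: list[str],
    classes: list[str],
    text_vocab: TextVocabulary,
    target_length: int,
    cfg: TrainConfig,
) -> TextClassifier:
    """Fine-tune the text-only baseline end to end ([CLS] pooling + head)."""
    if len(pairs) != len(labels):
        raise DataError("pairs and labels must align")
    y = _label_indices(labels, classes)
    rng = np.random.default_rng(cfg.seed)
    hidden_size = encoder.token_emb.weight.data.shape[1]
    head = nn.Linear(hidden_size, len(classes), rng)
    toks = [tokenize(p.evidence, text_vocab, target_length) for p in pairs]
    ids = np.stack([t.token_ids for t in toks])
    mask = np.stack([t.attention_mask for t in toks])
    n = len(pairs)
    steps = cfg.epochs * ((n + cfg.batch_size - 1) // cfg.batch_size)
    params = encoder.parameters() + head.parameters()
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay,
                   total_steps=max(steps, 1))
    for idx in _epoch_batches(n, cfg.batch_size, cfg.epochs, rng):
        hidden = encoder.forward(ids[idx], mask[idx])
        cls = hidden.slice((slice(None), 0))
        loss = nn.cross_entropy_logits(head(cls), y[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
    return TextClassifier(encoder, head, text_vocab, target_length, classes)


# ---------------------------------------------------------------------------
# KG baseline (static embeddings, head-only training)
# ---------------------------------------------------------------------------

def pool_max(embeddings: np.ndarray) -> np.ndarray:
    """Dimension-wise maximum over a sequence of embedding vectors."""
    embeddings = np.asarray(embeddings)
    if embeddings.ndim != 2 or embeddings.shape[0] == 0:
        raise DataError("expected a non-empty (length, dim) embedding sequence")
    return embeddings.max(axis=0)


def fit_kg_baseline(
    sequences: list[TripleSequence],
    labels: list[str],
    cfg: TrainConfig,
    seq_builder: Callable[[Triple], TripleSequence] | None = None,
) -> StaticSequenceClassifier:
    """Train only the linear + softmax head; the embeddings stay static.

    Sequences are pooled by per-dimension maximum into one feature vector
    each and fed to a multinomial logistic-regression head.
    """
    if len(sequences) != len(labels):
        raise DataError("sequences and labels must align")
    if not sequences:
        raise DataError("no sequences to fit")
    dims = {s.embeddings.shape[1] for s in sequences}
    if len(dims) != 1:
        raise DataError(f"ragged embedding dimensions: {sorted(dims)}")
    feats = np.stack([pool_max(s.embeddings) for s in sequences])
    classes = sorted(set(labels))
    if len(classes) == 1:
        return StaticSequenceClassifier(None, seq_builder, classes,
                                        single_class=classes[0])
    head = LogisticRegression(max_iter=2000, random_state=cfg.seed)
    head.fit(feats, np.asarray(labels))
    return StaticSequenceClassifier(head, seq_builder, classes)


__all__ = [
    "TrainConfig", "default_finetune_config", "Checkpoint", "pretrain",
    "smoothed", "Classifier", "CrossEncoderClassifier", "TextClassifier",
    "StaticSequenceClassifier", "finetune", "finetune_text_baseline",
    "pool_max", "fit_kg_baseline",
]
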