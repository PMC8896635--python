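"""Benchmarkable model adapters: one ``fit`` interface for all three models.

Each runner builds a fresh classifier per CV fold — the cross-encoder
runners start from a shared pre-trained checkpoint, the text baseline
trains from scratch (standing in for a pre-trained language model at desk
scale), and the KG baseline fits only its linear head on static pooled
embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .data import TextTriplePair, Triple
from .embeddings import TripleSequence
from .model import CrossEncoder, ModelConfig, TextEncoder
from .text import TextVocabulary
from .training import (Classifier, TrainConfig, finetune,
                       finetune_text_baseline, fit_kg_baseline)


@dataclass
class CrossEncoderRunner:
    """Fine-tunes the full cross encoder from a pre-trained state."""

    name: str
    config: ModelConfig
    state: dict[str, np.ndarray]
    text_vocab: TextVocabulary
    seq_builder: Callable[[Triple], TripleSequence]
    train_cfg: TrainConfig
    uses_transe_input: bool = False
    transe_input_dim: int | None = None

    def fit(self, pairs: list[TextTriplePair], labels: list[str],
            classes: list[str], seed: int) -> Classifier:
        model = CrossEncoder(self.config, seed=seed,
                             transe_input_dim=self.transe_input_dim)
        model.load_state_dict(self.state)
        cfg = replace(self.train_cfg, seed=seed)
        return finetune(model, pairs, labels, classes, self.text_vocab,
                        self.seq_builder, cfg)


@dataclass
class TextBaselineRunner:
    """Text-only transformer fine-tuned end to end on each fold."""

    name: str
    text_vocab: TextVocabulary
    hidden: int
    n_layers: int
    n_heads: int
    ffn: int
    target_length: int
    train_cfg: TrainConfig
    uses_transe_input: bool = False

    def fit(self, pairs: list[TextTriplePair], labels: list[str],
            classes: list[str], seed: int) -> Classifier:
        encoder = TextEncoder(self.hidden, self.n_layers, self.n_heads,
                              self.ffn, self.target_length,
                              self.text_vocab.size, seed=seed)
        cfg = replace(self.train_cfg, seed=seed)
        return finetune_text_baseline(encoder, pairs, labels, classes,
                                      self.text_vocab, self.target_length, cfg)


@dataclass
class KgBaselineRunner:
    """Static embedding sequences, dimension-wise-max pooling, linear head."""

    name: str
    seq_builder: Callable[[Triple], TripleSequence]
    train_cfg: TrainConfig
    uses_transe_input: bool = False

    def fit(self, pairs: list[TextTriplePair], labels: list[str],
            classes: list[str], seed: int) -> Classifier:
        sequences = [self.seq_builder(p.triple) for p in pairs]
        cfg = replace(self.train_cfg, seed=seed)
        return fit_kg_baseline(sequences, labels, cfg,
                               seq_builder=self.seq_builder)
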