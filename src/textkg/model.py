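"""The multimodal cross-encoder and its pre-training objectives.

One transformer stack attends jointly over a combined input sequence whose
first half is the tokenized evidence sentence and whose second half is the
triple's node sequence (random-walk mode: walk(head) + [SEP] + walk(tail) +
[SEP]; translational mode: the (head, relation, tail) 3-sequence padded to
the half length).  Segment embeddings distinguish the halves; position ids
run over the whole combined sequence.  Pre-training optimizes three heads:

- masked language modeling (MLM) over the text half,
- masked entity modeling (MEM) over the KG half, predicting masked node
  positions from the node vocabulary (which includes the KG-side [SEP]),
- next-"sentence" prediction (NSP) from the [CLS] hidden state: does this
  evidence sentence belong to this triple, or were they paired at random?

The total pre-training loss is the plain sum L_MLM + L_MEM + L_NSP (the
NO-NSP ablation drops the last term).  Fine-tuning pools the [CLS] hidden
state through a single linear + softmax head and updates every parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import nn
from .data import TextTriplePair, Triple, copy_pair
from .embeddings import TripleSequence
from .exceptions import ConfigError, DataError
from .nn import IGNORE_INDEX, Tensor
from .text import TextVocabulary, tokenize

NSP_MATCHED = 0
NSP_RANDOM = 1


@dataclass
class ModelConfig:
    """Cross-encoder hyperparameters.

    The full-scale profile mirrors the BERT-base geometry (hidden 768, 12
    layers/heads, 512 positions split 256 text + 256 KG, walk length 127);
    desk-scale profiles shrink every dimension but keep the length laws.
    """

    hidden: int = 64
    n_layers: int = 2
    n_heads: int = 4
    ffn: int = 256
    max_len: int = 64
    text_half: int = 32
    kg_half: int = 32
    dropout: float = 0.0
    node_vocab_size: int = 0
    text_vocab_size: int = 0
    freeze_kg_embeddings: bool = False

    def __post_init__(self):
        if self.text_half + self.kg_half != self.max_len:
            raise ConfigError(
                f"text_half ({self.text_half}) + kg_half ({self.kg_half}) "
                f"must equal max_len ({self.max_len})")
        if self.hidden % self.n_heads:
            raise ConfigError("hidden size must be divisible by head count")
        if self.kg_half % 2:
            raise ConfigError("kg_half must be even (2 * walk_length + 2)")

    @property
    def walk_length(self) -> int:
        """Walk length L implied by the KG half: kg_half = 2L + 2."""
        return (self.kg_half - 2) // 2

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class CombinedInput:
    """One assembled (optionally masked) 2-modality example."""

    pair_id: str
    mode: str                       # "walk" | "transe"
    text_ids: np.ndarray            # (text_half,)
    kg_ids: np.ndarray              # (kg_half,) node-vocab ids; -1 = no id
    segment_ids: np.ndarray         # (max_len,) 0 = text, 1 = KG
    position_ids: np.ndarray        # (max_len,) 0..max_len-1
    attention_mask: np.ndarray      # (max_len,) 1 = attend
    mlm_labels: np.ndarray          # (text_half,) original id or IGNORE
    mem_labels: np.ndarray          # (kg_half,)
    nsp_label: int = NSP_MATCHED
    kg_vectors: np.ndarray | None = None   # (kg_half, d_in) translational mode
    kg_mask_flags: np.ndarray = field(default=None)  # (kg_half,) bool: use [MASK] emb

    def __post_init__(self):
        if self.kg_mask_flags is None:
            self.kg_mask_flags = np.zeros(len(self.kg_ids), dtype=bool)

    @property
    def total_length(self) -> int:
        return len(self.text_ids) + len(self.kg_ids)


def assemble_input(
    pair: TextTriplePair,
    text_vocab: TextVocabulary,
    seq_builder: Callable[[Triple], TripleSequence],
    config: ModelConfig,
) -> CombinedInput:
    """Build the combined input for one text-triple pair.

    In walk mode the triple sequence must fill the KG half exactly
    (2 * walk_length + 2 == kg_half); in translational mode the 3-sequence
    is right-padded with unattended zero vectors.
    """
    tok = tokenize(pair.evidence, text_vocab, config.text_half)
    seq = seq_builder(pair.triple)
    t2 = config.kg_half
    if seq.mode == "walk":
        if len(seq) != t2:
            raise ConfigError(
                f"walk sequence length {len(seq)} != kg_half {t2}; "
                "walk length and KG half length must be co-designed (2L+2)")
        kg_ids = seq.token_ids.astype(np.int64)
        kg_vectors = None
        kg_attn = np.ones(t2, dtype=np.int64)
    elif seq.mode == "transe":
        if len(seq) > t2:
            raise ConfigError("translational sequence longer than kg_half")
        kg_ids = np.full(t2, -1, dtype=np.int64)
        kg_ids[: len(seq)] = seq.token_ids
        kg_vectors = np.zeros((t2, seq.embeddings.shape[1]))
        kg_vectors[: len(seq)] = seq.embeddings
        kg_attn = np.zeros(t2, dtype=np.int64)
        kg_attn[: len(seq)] = 1
    else:
        raise DataError(f"unknown sequence mode {seq.mode!r}")
    return CombinedInput(
        pair_id=pair.pair_id,
        mode=seq.mode,
        text_ids=tok.token_ids,
        kg_ids=kg_ids,
        segment_ids=np.concatenate([np.zeros(config.text_half, dtype=np.int64),
                                    np.ones(t2, dtype=np.int64)]),
        position_ids=np.arange(config.max_len, dtype=np.int64),
        attention_mask=np.concatenate([tok.attention_mask, kg_attn]),
        mlm_labels=np.full(config.text_half, IGNORE_INDEX, dtype=np.int64),
        mem_labels=np.full(t2, IGNORE_INDEX, dtype=np.int64),
        kg_vectors=kg_vectors,
    )


def apply_masking(
    inp: CombinedInput,
    text_vocab: TextVocabulary,
    mem_vocab_size: int,
    mask_prob: float = 0.15,
    rng: np.random.Generator | int | None = None,
    node_matrix: np.ndarray | None = None,
) -> CombinedInput:
    """BERT-style masking of both halves of an assembled input.

    Each maskable position is selected independently with ``mask_prob``; of
    the selected positions 80% are replaced by [MASK] (in the KG half this
    means the *text-side* [MASK] embedding vector), 10% by a random id from
    that half's vocabulary and 10% left unchanged.  Labels store the
    original id at selected positions and the ignore marker elsewhere.

    Maskable are: text positions that are not [CLS]/[SEP]/[PAD]; KG
    positions carrying a node or separator id (walk mode: every position;
    translational mode: the head and tail entity positions).  In
    translational mode ``node_matrix`` supplies the vectors for random
    replacements.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    out = CombinedInput(
        pair_id=inp.pair_id, mode=inp.mode,
        text_ids=inp.text_ids.copy(), kg_ids=inp.kg_ids.copy(),
        segment_ids=inp.segment_ids, position_ids=inp.position_ids,
        attention_mask=inp.attention_mask,
        mlm_labels=np.full_like(inp.mlm_labels, IGNORE_INDEX),
        mem_labels=np.full_like(inp.mem_labels, IGNORE_INDEX),
        nsp_label=inp.nsp_label,
        kg_vectors=None if inp.kg_vectors is None else inp.kg_vectors.copy(),
        kg_mask_flags=inp.kg_mask_flags.copy(),
    )
    if mask_prob <= 0:
        return out

    special = {text_vocab.pad_id, text_vocab.cls_id, text_vocab.sep_id}
    text_maskable = ~np.isin(out.text_ids, list(special))
    kg_maskable = out.kg_ids >= 0

    for half, maskable in (("text", text_maskable), ("kg", kg_maskable)):
        idx = np.nonzero(maskable)[0]
        selected = idx[rng.random(len(idx)) < mask_prob]
        if len(selected) == 0:
            continue
        u = rng.random(len(selected))
        for pos, roll in zip(selected, u):
            if half == "text":
                out.mlm_labels[pos] = out.text_ids[pos]
                if roll < 0.8:
                    out.text_ids[pos] = text_vocab.mask_id
                elif roll < 0.9:
                    out.text_ids[pos] = int(rng.integers(0, text_vocab.size))
            else:
                out.mem_labels[pos] = out.kg_ids[pos]
                if roll < 0.8:
                    out.kg_mask_flags[pos] = True
                elif roll < 0.9:
                    rand_id = int(rng.integers(0, mem_vocab_size))
                    out.kg_ids[pos] = rand_id
                    if out.kg_vectors is not None:
                        if node_matrix is None:
                            raise DataError(
                                "node_matrix required for random replacement "
                                "in translational mode")
                        out.kg_vectors[pos] = node_matrix[rand_id]
    return out


def make_nsp_examples(
    pairs: list[TextTriplePair],
    negative_fraction: float = 0.25,
    seed: int = 0,
) -> list[tuple[TextTriplePair, int]]:
    """Augment a corpus with randomly re-paired negatives for NSP.

    Returns every original pair labeled *matched* plus
    ``round(negative_fraction * len(pairs))`` synthetic pairs labeled
    *random*, each combining the evidence of one original with the triple of
    a different one; a negative never reproduces an (evidence, triple)
    combination that occurs in the originals.
    """
    n = len(pairs)
    n_neg = round(negative_fraction * n)
    if n < 2 and n_neg > 0:
        raise ConfigError("need at least 2 pairs to build NSP negatives")
    out: list[tuple[TextTriplePair, int]] = [(p, NSP_MATCHED) for p in pairs]
    if n_neg == 0:
        return out
    originals = {(p.evidence, p.triple.as_tuple()) for p in pairs}
    rng = np.random.default_rng(seed)
    made = 0
    while made < n_neg:
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n - 1))
        if j >= i:
            j += 1
        combo = (pairs[i].evidence, pairs[j].triple.as_tuple())
        if combo in originals:
            continue
        neg = copy_pair(pairs[i], pair_id=f"neg:{pairs[i].pair_id}|{pairs[j].pair_id}",
                        triple=pairs[j].triple, annotations=None)
        out.append((neg, NSP_RANDOM))
        made += 1
    return out


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    text_ids: np.ndarray        # (B, T1)
    kg_ids: np.ndarray          # (B, T2)
    kg_mask_flags: np.ndarray   # (B, T2) bool
    segment_ids: np.ndarray     # (B, T)
    position_ids: np.ndarray    # (B, T)
    attention_mask: np.ndarray  # (B, T)
    mlm_labels: np.ndarray      # (B, T1)
    mem_labels: np.ndarray      # (B, T2)
    nsp_labels: np.ndarray      # (B,)
    kg_vectors: np.ndarray | None  # (B, T2, d_in) or None
    mode: str


def collate(inputs: list[CombinedInput]) -> Batch:
    if not inputs:
        raise DataError("cannot collate an empty batch")
    modes = {i.mode for i in inputs}
    if len(modes) != 1:
        raise DataError("cannot mix walk and translational inputs in a batch")
    kg_vectors = None
    if inputs[0].kg_vectors is not None:
        kg_vectors = np.stack([i.kg_vectors for i in inputs])
    return Batch(
        text_ids=np.stack([i.text_ids for i in inputs]),
        kg_ids=np.stack([i.kg_ids for i in inputs]),
        kg_mask_flags=np.stack([i.kg_mask_flags for i in inputs]),
        segment_ids=np.stack([i.segment_ids for i in inputs]),
        position_ids=np.stack([i.position_ids for i in inputs]),
        attention_mask=np.stack([i.attention_mask for i in inputs]),
        mlm_labels=np.stack([i.mlm_labels for i in inputs]),
        mem_labels=np.stack([i.mem_labels for i in inputs]),
        nsp_labels=np.asarray([i.nsp_label for i in inputs], dtype=np.int64),
        kg_vectors=kg_vectors,
        mode=modes.pop(),
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class CrossEncoder(nn.Module):
    """Joint transformer over the combined text + KG input sequence.

    The KG-half embedding table is trainable and may be initialized from a
    pre-trained node-embedding matrix (projected once through a seeded
    random map when the dimensions differ); set
    ``config.freeze_kg_embeddings`` to keep it static.  In translational
    mode the input vectors bypass the table and pass through a learned
    linear projection instead.
    """

    def __init__(self, config: ModelConfig, seed: int = 0,
                 node_init: np.ndarray | None = None,
                 transe_input_dim: int | None = None):
        if config.node_vocab_size <= 0 or config.text_vocab_size <= 0:
            raise ConfigError("vocabulary sizes must be set on the config")
        self.config = config
        rng = np.random.default_rng(seed)
        h = config.hidden
        self.text_emb = nn.Embedding(config.text_vocab_size, h, rng)
        self.node_emb = nn.Embedding(config.node_vocab_size, h, rng)
        if node_init is not None:
            if node_init.shape[0] != config.node_vocab_size:
                raise ConfigError("node_init row count != node_vocab_size")
            if node_init.shape[1] == h:
                self.node_emb.weight.data = node_init.astype(np.float64).copy()
            else:
                proj = rng.normal(0.0, 1.0 / np.sqrt(node_init.shape[1]),
                                  size=(node_init.shape[1], h))
                self.node_emb.weight.data = node_init @ proj
        self.segment_emb = nn.Embedding(2, h, rng)
        self.position_emb = nn.Embedding(config.max_len, h, rng)
        self.emb_norm = nn.LayerNorm(h)
        self.encoder = nn.TransformerEncoder(
            h, config.n_heads, config.ffn, config.n_layers, rng, config.dropout)
        self.mlm_head = nn.Linear(h, config.text_vocab_size, rng)
        self.mem_head = nn.Linear(h, config.node_vocab_size, rng)
        self.nsp_head = nn.Linear(h, 2, rng)
        self.transe_proj = (nn.Linear(transe_input_dim, h, rng)
                            if transe_input_dim else None)

    def trainable_parameters(self) -> list[nn.Parameter]:
        params = self.named_parameters()
        if self.config.freeze_kg_embeddings:
            params = {k: v for k, v in params.items()
                      if k != "node_emb.weight"}
        return list(params.values())

    def _kg_embeddings(self, batch: Batch) -> Tensor:
        if batch.mode == "walk":
            ids = np.where(batch.kg_ids >= 0, batch.kg_ids, 0)
            kg = self.node_emb(ids)
        else:
            if self.transe_proj is None:
                raise ConfigError("model built without translational input "
                                  "projection; pass transe_input_dim")
            kg = self.transe_proj(Tensor(batch.kg_vectors))
        # positions flagged [MASK] carry the text-side [MASK] embedding
        flags = batch.kg_mask_flags.astype(np.float64)[..., None]
        if flags.any():
            mask_vec = self.text_emb.weight.slice(
                (slice(self._mask_id, self._mask_id + 1),))
            kg = kg * Tensor(1.0 - flags) + mask_vec * Tensor(flags)
        return kg

    _mask_id: int = 4  # reserved [MASK] id in the text vocabulary

    def forward(self, batch: Batch,
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Hidden states plus MLM / MEM / NSP logits.

        Softmaxing any logit row yields a distribution over that head's
        vocabulary; NSP logits come from the [CLS] (first) position.
        """
        t1 = self.config.text_half
        text = self.text_emb(batch.text_ids)
        kg = self._kg_embeddings(batch)
        x = nn.concat([text, kg], axis=1)
        x = x + self.segment_emb(batch.segment_ids) \
              + self.position_emb(batch.position_ids)
        x = self.emb_norm(x)
        hidden = self.encoder(x, batch.attention_mask, rng)
        text_hidden = hidden.slice((slice(None), slice(0, t1)))
        kg_hidden = hidden.slice((slice(None), slice(t1, self.config.max_len)))
        cls_hidden = hidden.slice((slice(None), 0))
        return (hidden,
                self.mlm_head(text_hidden),
                self.mem_head(kg_hidden),
                self.nsp_head(cls_hidden))


class TextEncoder(nn.Module):
    """Text-only transformer classifier backbone (the NLP baseline).

    Same encoder geometry as the cross encoder but consuming only the
    tokenized evidence; [CLS] pooling for classification.
    """

    def __init__(self, hidden: int, n_layers: int, n_heads: int, ffn: int,
                 max_len: int, vocab_size: int, seed: int = 0,
                 dropout: float = 0.0):
        rng = np.random.default_rng(seed)
        self.max_len = max_len
        self.token_emb = nn.Embedding(vocab_size, hidden, rng)
        self.position_emb = nn.Embedding(max_len, hidden, rng)
        self.emb_norm = nn.LayerNorm(hidden)
        self.encoder = nn.TransformerEncoder(hidden, n_heads, ffn, n_layers,
                                             rng, dropout)

    def forward(self, token_ids: np.ndarray, attention_mask: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        pos = np.broadcast_to(np.arange(token_ids.shape[1]), token_ids.shape)
        x = self.token_emb(token_ids) + self.position_emb(pos)
        x = self.emb_norm(x)
        return self.encoder(x, attention_mask, rng)


# ---------------------------------------------------------------------------
# Losses and pooling
# ---------------------------------------------------------------------------

@dataclass
class LossComponents:
    """The three pre-training loss terms and their sum."""

    mlm: Tensor
    mem: Tensor
    nsp: Tensor
    variant: str = "full"

    @property
    def total(self) -> Tensor:
        if self.variant == "no_nsp":
            return self.mlm + self.mem
        return self.mlm + self.mem + self.nsp

    def as_floats(self) -> dict[str, float]:
        return {"L_MLM": self.mlm.item(), "L_MEM": self.mem.item(),
                "L_NSP": self.nsp.item(), "L_total": self.total.item()}


def compute_losses(mlm_logits: Tensor, mem_logits: Tensor, nsp_logits: Tensor,
                   batch: Batch, variant: str = "full") -> LossComponents:
    """Mean cross-entropy per objective over its supervised positions only."""
    if variant not in ("full", "no_nsp"):
        raise ConfigError(f"unknown loss variant {variant!r}")
    mlm = nn.cross_entropy_logits(mlm_logits, batch.mlm_labels)
    mem = nn.cross_entropy_logits(mem_logits, batch.mem_labels)
    if variant == "no_nsp":
        nsp = Tensor(0.0)
    else:
        nsp = nn.cross_entropy_logits(nsp_logits, batch.nsp_labels)
    return LossComponents(mlm=mlm, mem=mem, nsp=nsp, variant=variant)


def pool_and_classify(cls_hidden: Tensor, head: nn.Linear) -> Tensor:
    """Class probabilities from the [CLS] hidden state: softmax(linear(h))."""
    return nn.softmax(head(cls_hidden), axis=-1)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: nn.Module, path: str | Path,
                    extra: dict | None = None) -> None:
    """Bundle = config.json (+extras) and a weights archive, round-trippable."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"class": type(model).__name__}
    if isinstance(model, CrossEncoder):
        meta["config"] = model.config.to_dict()
        meta["transe_input_dim"] = (None if model.transe_proj is None
                                    else model.transe_proj.weight.data.shape[0])
    if extra:
        meta["extra"] = extra
    (path / "config.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    np.savez(path / "weights.npz", **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[nn.Module, dict]:
    path = Path(path)
    meta = json.loads((path / "config.json").read_text(encoding="utf-8"))
    weights = dict(np.load(path / "weights.npz"))
    if meta["class"] == "CrossEncoder":
        model = CrossEncoder(ModelConfig(**meta["config"]),
                             transe_input_dim=meta.get("transe_input_dim"))
    else:
        raise DataError(f"cannot reconstruct checkpoint class {meta['class']}")
    model.load_state_dict(weights)
    return model, meta.get("extra", {})
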