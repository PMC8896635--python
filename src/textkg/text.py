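"""Text-side input pipeline: vocabulary, tokenization, token embeddings.

At desk scale the tokenizer is whitespace splitting over a frequency-built
vocabulary (no subwords); the contract downstream code relies on — integer
ids, the reserved [PAD]/[UNK]/[CLS]/[SEP]/[MASK] tokens, fixed-length
padding/truncation, attention masks — is the same one a pre-trained
WordPiece tokenizer would provide, and an external embedding matrix plus
vocabulary file can be loaded through the same interface.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, DataError

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
RESERVED = [PAD, UNK, CLS, SEP, MASK]


@dataclass
class TextVocabulary:
    tokens: list[str]
    token_to_id: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    def id(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TextVocabulary":
        tokens = Path(path).read_text(encoding="utf-8").splitlines()
        vocab = cls(tokens, {t: i for i, t in enumerate(tokens)})
        for r in RESERVED:
            if r not in vocab.token_to_id:
                raise DataError(f"vocabulary file missing reserved token {r}")
        return vocab


@dataclass
class TokenizedText:
    token_ids: np.ndarray     # (target_length,) int
    attention_mask: np.ndarray  # (target_length,) 0/1 int
    length: int               # target length


def build_vocabulary(corpus: list[str], max_size: int = 10000,
                     min_freq: int = 1) -> TextVocabulary:
    """Frequency vocabulary over whitespace tokens, reserved tokens first.

    Ties are broken lexicographically so the id assignment is deterministic.
    Tokens below ``min_freq`` or beyond ``max_size`` map to [UNK] later.
    """
    if not corpus:
        raise DataError("corpus must be non-empty")
    counts = Counter()
    for sentence in corpus:
        counts.update(sentence.split())
    kept = sorted(
        (t for t, c in counts.items() if c >= min_freq),
        key=lambda t: (-counts[t], t),
    )[:max_size]
    tokens = RESERVED + kept
    return TextVocabulary(tokens, {t: i for i, t in enumerate(tokens)})


def tokenize(text: str, vocab: TextVocabulary, target_length: int) -> TokenizedText:
    """[CLS] + tokens + [SEP], padded or truncated to ``target_length``.

    Truncation keeps the leading tokens (evidence is sentence-level, so the
    relation mention sits near the head) and always terminates the kept
    span with [SEP].
    """
    if target_length < 2:
        raise ConfigError("target_length must be >= 2 to fit [CLS] and [SEP]")
    body = [vocab.id(t) for t in text.split()]
    body = body[: target_length - 2]
    ids = [vocab.cls_id] + body + [vocab.sep_id]
    n = len(ids)
    ids = ids + [vocab.pad_id] * (target_length - n)
    mask = [1] * n + [0] * (target_length - n)
    return TokenizedText(
        token_ids=np.asarray(ids, dtype=np.int64),
        attention_mask=np.asarray(mask, dtype=np.int64),
        length=target_length,
    )


def detokenize(token_ids: np.ndarray, vocab: TextVocabulary) -> list[str]:
    """Token strings for a tokenized sequence, dropping specials/padding."""
    special = {vocab.pad_id, vocab.cls_id, vocab.sep_id, vocab.mask_id}
    return [vocab.tokens[int(i)] for i in token_ids if int(i) not in special]


def embed_tokens(token_ids: np.ndarray, embedding_table: np.ndarray) -> np.ndarray:
    """Row lookups: one vector per position; hard error on out-of-range ids."""
    ids = np.asarray(token_ids)
    if ids.size and (ids.min() < 0 or ids.max() >= embedding_table.shape[0]):
        raise DataError(
            f"token id out of range for table of {embedding_table.shape[0]} rows")
    return embedding_table[ids]


def load_embedding_table(matrix_path: str | Path,
                         vocab_path: str | Path) -> tuple[np.ndarray, TextVocabulary]:
    """Load an external (text-format) embedding matrix with its vocabulary."""
    vocab = TextVocabulary.load(vocab_path)
    table = np.loadtxt(matrix_path, dtype=np.float64, ndmin=2)
    if table.shape[0] != vocab.size:
        raise DataError(
            f"matrix has {table.shape[0]} rows but vocabulary has {vocab.size} tokens")
    return table, vocab
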