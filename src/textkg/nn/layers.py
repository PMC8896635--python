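"""Transformer building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, concat, dropout, embedding, gelu, layer_norm,
                       softmax)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Named-parameter bookkeeping with nested submodules."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 0.02
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out))
                                if scale else np.zeros((n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_embeddings, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    def __init__(self, hidden: int, heads: int, rng: np.random.Generator,
                 attn_dropout: float = 0.0):
        if hidden % heads:
            raise ValueError("hidden size must be divisible by head count")
        self.heads = heads
        self.head_dim = hidden // heads
        self.q = Linear(hidden, hidden, rng)
        self.k = Linear(hidden, hidden, rng)
        self.v = Linear(hidden, hidden, rng)
        self.out = Linear(hidden, hidden, rng)
        self.attn_dropout = attn_dropout

    def __call__(self, x: Tensor, additive_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        b, t, h = x.shape
        def split(z: Tensor) -> Tensor:
            return z.reshape(b, t, self.heads, self.head_dim).swapaxes(1, 2)
        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_dim))
        scores = scores + Tensor(additive_mask)     # (b, 1, 1, t) broadcast
        attn = softmax(scores, axis=-1)
        attn = dropout(attn, self.attn_dropout, rng)
        ctx = (attn @ v).swapaxes(1, 2).reshape(b, t, h)
        return self.out(ctx)


class TransformerLayer(Module):
    """Post-norm encoder layer (attention + GELU feed-forward), as in BERT."""

    def __init__(self, hidden: int, heads: int, ffn: int,
                 rng: np.random.Generator, p_dropout: float = 0.0):
        self.attn = MultiHeadSelfAttention(hidden, heads, rng, p_dropout)
        self.ln1 = LayerNorm(hidden)
        self.ff1 = Linear(hidden, ffn, rng)
        self.ff2 = Linear(ffn, hidden, rng)
        self.ln2 = LayerNorm(hidden)
        self.p_dropout = p_dropout

    def __call__(self, x: Tensor, additive_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        a = self.attn(x, additive_mask, rng)
        x = self.ln1(x + dropout(a, self.p_dropout, rng))
        f = self.ff2(gelu(self.ff1(x)))
        return self.ln2(x + dropout(f, self.p_dropout, rng))


class TransformerEncoder(Module):
    def __init__(self, hidden: int, heads: int, ffn: int, n_layers: int,
                 rng: np.random.Generator, p_dropout: float = 0.0):
        self.layers = [TransformerLayer(hidden, heads, ffn, rng, p_dropout)
                       for _ in range(n_layers)]

    def __call__(self, x: Tensor, attention_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        """``attention_mask`` is (batch, seq) with 1 = attend, 0 = pad."""
        mask = np.asarray(attention_mask, dtype=np.float64)
        additive = (1.0 - mask)[:, None, None, :] * -1e9
        for layer in self.layers:
            x = layer(x, additive, rng)
        return x


__all__ = ["Parameter", "Module", "Linear", "Embedding", "LayerNorm",
           "MultiHeadSelfAttention", "TransformerLayer", "TransformerEncoder",
           "concat"]
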