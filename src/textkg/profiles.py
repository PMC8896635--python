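"""Scale profiles co-designing the interacting sequence lengths.

The text half, KG half and walk length must satisfy kg_half = 2L + 2 and
text_half + kg_half = max_len; a profile fixes them together with the
model geometry and the training budgets appropriate at that scale.

``full`` is the BERT-base-geometry reference configuration (hidden 768,
12 layers/heads, 512 positions split 256/256, walk length 127); ``tiny``
is the desk-scale profile used by the test suite and example runs; ``desk``
sits in between.
"""

from __future__ import annotations

from .exceptions import ConfigError
from .model import ModelConfig

PROFILES: dict[str, dict] = {
    "tiny": dict(
        hidden=64, n_layers=2, n_heads=4, ffn=256,
        max_len=64, text_half=32, kg_half=32,
        embed_dim=64,
        pretrain_steps=300, pretrain_lr=1e-3, pretrain_batch=16,
        finetune_epochs=5, finetune_lr=3e-4, finetune_batch=16,
    ),
    "desk": dict(
        hidden=128, n_layers=4, n_heads=4, ffn=512,
        max_len=128, text_half=64, kg_half=64,
        embed_dim=128,
        pretrain_steps=2000, pretrain_lr=5e-4, pretrain_batch=16,
        finetune_epochs=5, finetune_lr=1e-4, finetune_batch=16,
    ),
    "full": dict(
        hidden=768, n_layers=12, n_heads=12, ffn=3072,
        max_len=512, text_half=256, kg_half=256,
        embed_dim=768,
        pretrain_steps=300_000, pretrain_lr=5e-5, pretrain_batch=16,
        finetune_epochs=5, finetune_lr=5e-5, finetune_batch=16,
    ),
}


def get_profile(name: str) -> dict:
    if name not in PROFILES:
        raise ConfigError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    return dict(PROFILES[name])


def model_config_from_profile(profile: dict, node_vocab_size: int,
                              text_vocab_size: int, **overrides) -> ModelConfig:
    cfg = dict(
        hidden=profile["hidden"], n_layers=profile["n_layers"],
        n_heads=profile["n_heads"], ffn=profile["ffn"],
        max_len=profile["max_len"], text_half=profile["text_half"],
        kg_half=profile["kg_half"],
        node_vocab_size=node_vocab_size, text_vocab_size=text_vocab_size,
    )
    cfg.update(overrides)
    return ModelConfig(**cfg)
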