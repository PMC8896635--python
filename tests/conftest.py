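import numpy as np
import pytest

import textkg as tk
from textkg.profiles import model_config_from_profile


@pytest.fixture(scope="session")
def synth_cfg():
    return tk.SynthConfig(n_nodes=60, n_relations=4, mean_degree=6.0,
                          n_pairs=400, vocab_size=100,
                          annotation_fraction=0.3, seed=11)


@pytest.fixture(scope="session")
def kg(synth_cfg):
    return tk.generate_kg(synth_cfg)


@pytest.fixture(scope="session")
def pairs(kg, synth_cfg):
    return tk.generate_pairs(kg, synth_cfg)


@pytest.fixture(scope="session")
def node_table(kg):
    return tk.train_node_embeddings(kg, dim=32, walk_length=7,
                                    walks_per_node=4, epochs=2, seed=11)


@pytest.fixture(scope="session")
def text_vocab(pairs):
    corpus = [p.evidence for p in pairs] + [f"ctx{i}" for i in range(10)]
    return tk.build_vocabulary(corpus)


@pytest.fixture(scope="session")
def micro_config(node_table, text_vocab):
    """Smallest coherent cross-encoder geometry: 16 text + 16 KG (L=7)."""
    return tk.ModelConfig(hidden=32, n_layers=1, n_heads=2, ffn=64,
                          max_len=32, text_half=16, kg_half=16,
                          node_vocab_size=node_table.vocab_size,
                          text_vocab_size=text_vocab.size)


@pytest.fixture(scope="session")
def walk_seq(kg, node_table, micro_config):
    return tk.WalkSequencer(kg, node_table, micro_config.walk_length, seed=11)


@pytest.fixture(scope="session")
def micro_model(micro_config, node_table):
    return tk.CrossEncoder(micro_config, seed=11)
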