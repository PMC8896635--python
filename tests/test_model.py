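"""Combined-input assembly, masking, forward pass, losses and NSP."""

import numpy as np
import pytest

import textkg as tk
from textkg import nn
from textkg.exceptions import ConfigError
from textkg.model import NSP_MATCHED, NSP_RANDOM, load_checkpoint, save_checkpoint


@pytest.fixture()
def assembled(pairs, text_vocab, walk_seq, micro_config):
    return tk.assemble_input(pairs[0], text_vocab, walk_seq, micro_config)


class TestModelConfig:
    def test_full_scale_lengths(self):
        cfg = tk.ModelConfig(hidden=768, n_layers=12, n_heads=12, ffn=3072,
                             max_len=512, text_half=256, kg_half=256,
                             node_vocab_size=10, text_vocab_size=10)
        assert cfg.max_len == 512
        assert cfg.walk_length == 127          # 2*127 + 2 == 256

    def test_inconsistent_halves_rejected(self):
        with pytest.raises(ConfigError):
            tk.ModelConfig(max_len=64, text_half=32, kg_half=16,
                           node_vocab_size=10, text_vocab_size=10)

    def test_hidden_head_divisibility(self):
        with pytest.raises(ConfigError):
            tk.ModelConfig(hidden=30, n_heads=4, max_len=64, text_half=32,
                           kg_half=32, node_vocab_size=10, text_vocab_size=10)


class TestAssembleInput:
    def test_lengths_and_segments(self, assembled, micro_config):
        assert assembled.total_length == micro_config.max_len
        t1 = micro_config.text_half
        assert (assembled.segment_ids[:t1] == 0).all()
        assert (assembled.segment_ids[t1:] == 1).all()
        assert assembled.position_ids.tolist() == list(range(micro_config.max_len))

    def test_desk_scale_length_law(self, pairs, text_vocab, kg, node_table):
        cfg = tk.ModelConfig(hidden=32, n_layers=1, n_heads=2, ffn=64,
                             max_len=64, text_half=32, kg_half=32,
                             node_vocab_size=node_table.vocab_size,
                             text_vocab_size=text_vocab.size)
        seq = tk.WalkSequencer(kg, node_table, cfg.walk_length, seed=0)
        inp = tk.assemble_input(pairs[0], text_vocab, seq, cfg)
        assert inp.total_length == 64
        assert len(inp.kg_ids) == 32 == 2 * 15 + 2

    def test_mismatched_walk_length_rejected(self, pairs, text_vocab, kg,
                                             node_table, micro_config):
        wrong = tk.WalkSequencer(kg, node_table, 5, seed=0)  # 12 != kg_half
        with pytest.raises(ConfigError):
            tk.assemble_input(pairs[0], text_vocab, wrong, micro_config)

    def test_labels_start_ignored(self, assembled):
        assert (assembled.mlm_labels == nn.IGNORE_INDEX).all()
        assert (assembled.mem_labels == nn.IGNORE_INDEX).all()
        assert assembled.nsp_label == NSP_MATCHED

    def test_transe_mode_pads_kg_half(self, kg, pairs, text_vocab, micro_config):
        transe = tk.train_transe(kg, dim=16, epochs=1, seed=0)
        seq = tk.TranseSequencer(transe)
        inp = tk.assemble_input(pairs[0], text_vocab, seq, micro_config)
        assert inp.total_length == micro_config.max_len
        assert inp.kg_vectors.shape == (micro_config.kg_half, 16)
        assert inp.attention_mask[micro_config.text_half:].sum() == 3
        assert (inp.kg_ids[3:] == -1).all()


class TestMasking:
    def test_zero_probability_is_identity(self, assembled, text_vocab,
                                          micro_config):
        out = tk.apply_masking(assembled, text_vocab,
                               micro_config.node_vocab_size, mask_prob=0.0,
                               rng=0)
        np.testing.assert_array_equal(out.text_ids, assembled.text_ids)
        np.testing.assert_array_equal(out.kg_ids, assembled.kg_ids)
        assert (out.mlm_labels == nn.IGNORE_INDEX).all()
        assert (out.mem_labels == nn.IGNORE_INDEX).all()

    def test_labels_partition_and_reconstruction(self, assembled, text_vocab,
                                                 micro_config):
        rng = np.random.default_rng(1)
        out = tk.apply_masking(assembled, text_vocab,
                               micro_config.node_vocab_size, mask_prob=0.5,
                               rng=rng)
        sup = out.mlm_labels != nn.IGNORE_INDEX
        # labels at supervised positions reconstruct the original sequence
        np.testing.assert_array_equal(out.mlm_labels[sup],
                                      assembled.text_ids[sup])
        unsup = ~sup
        np.testing.assert_array_equal(out.text_ids[unsup & (assembled.text_ids
                                      != text_vocab.pad_id)][:0],
                                      np.array([], dtype=np.int64))
        sup_kg = out.mem_labels != nn.IGNORE_INDEX
        np.testing.assert_array_equal(out.mem_labels[sup_kg],
                                      assembled.kg_ids[sup_kg])

    def test_specials_never_masked(self, assembled, text_vocab, micro_config):
        rng = np.random.default_rng(2)
        out = tk.apply_masking(assembled, text_vocab,
                               micro_config.node_vocab_size, mask_prob=1.0,
                               rng=rng)
        specials = np.isin(assembled.text_ids,
                           [text_vocab.cls_id, text_vocab.sep_id,
                            text_vocab.pad_id])
        assert (out.mlm_labels[specials] == nn.IGNORE_INDEX).all()
        np.testing.assert_array_equal(out.text_ids[specials],
                                      assembled.text_ids[specials])

    def test_selection_and_replacement_statistics(self, pairs, text_vocab,
                                                  walk_seq, micro_config):
        # aggregate >= 10,000 maskable KG positions across examples
        rng = np.random.default_rng(3)
        n_maskable = n_selected = n_masked = n_random = n_kept = 0
        for p in pairs * 2:
            inp = tk.assemble_input(p, text_vocab, walk_seq, micro_config)
            out = tk.apply_masking(inp, text_vocab,
                                   micro_config.node_vocab_size,
                                   mask_prob=0.15, rng=rng)
            n_maskable += len(inp.kg_ids)
            sel = out.mem_labels != nn.IGNORE_INDEX
            n_selected += int(sel.sum())
            n_masked += int(out.kg_mask_flags.sum())
            changed = sel & ~out.kg_mask_flags & (out.kg_ids != inp.kg_ids)
            n_random += int(changed.sum())
            n_kept += int((sel & ~out.kg_mask_flags
                           & (out.kg_ids == inp.kg_ids)).sum())
        assert n_maskable >= 10_000
        p_sel = 0.15
        sigma = np.sqrt(n_maskable * p_sel * (1 - p_sel))
        assert abs(n_selected - n_maskable * p_sel) < 3 * sigma
        for count, frac in ((n_masked, 0.8), (n_random, 0.1), (n_kept, 0.1)):
            s = np.sqrt(n_selected * frac * (1 - frac))
            # random-replacement draws can coincide with the original id,
            # which shifts a sliver of mass from "random" to "kept"
            slack = 3 * s + 0.01 * n_selected
            assert abs(count - n_selected * frac) < slack


class TestForward:
    def test_logit_shapes_and_softmax_rows(self, micro_model, assembled,
                                           text_vocab, micro_config):
        batch = tk.collate([assembled, assembled])
        hidden, mlm, mem, nsp = micro_model.forward(batch)
        assert hidden.shape == (2, micro_config.max_len, micro_config.hidden)
        assert mlm.shape == (2, micro_config.text_half,
                             micro_config.text_vocab_size)
        assert mem.shape == (2, micro_config.kg_half,
                             micro_config.node_vocab_size)
        assert nsp.shape == (2, 2)
        for t in (mlm, mem, nsp):
            probs = nn.softmax(t, axis=-1).data
            np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_pad_content_cannot_leak_into_attended_states(
            self, micro_model, pairs, text_vocab, walk_seq, micro_config):
        inp = tk.assemble_input(pairs[0], text_vocab, walk_seq, micro_config)
        batch1 = tk.collate([inp])
        hidden1, *_ = micro_model.forward(batch1)
        # rewrite the pad positions' token ids; attention mask unchanged
        pad = inp.attention_mask == 0
        assert pad.any(), "fixture pair should produce padding"
        inp2 = tk.CombinedInput(
            pair_id=inp.pair_id, mode=inp.mode,
            text_ids=inp.text_ids.copy(), kg_ids=inp.kg_ids,
            segment_ids=inp.segment_ids, position_ids=inp.position_ids,
            attention_mask=inp.attention_mask,
            mlm_labels=inp.mlm_labels, mem_labels=inp.mem_labels,
            kg_vectors=inp.kg_vectors)
        text_pad = pad[:micro_config.text_half]
        inp2.text_ids[text_pad] = text_vocab.unk_id
        hidden2, *_ = micro_model.forward(tk.collate([inp2]))
        attended = inp.attention_mask == 1
        np.testing.assert_allclose(hidden1.data[0, attended],
                                   hidden2.data[0, attended], atol=1e-8)


class TestLosses:
    def test_all_ignored_no_nsp_gives_zero_total(self, micro_model, assembled):
        batch = tk.collate([assembled])
        _, mlm, mem, nsp = micro_model.forward(batch)
        lc = tk.compute_losses(mlm, mem, nsp, batch, variant="no_nsp")
        assert lc.total.item() == 0.0

    def test_one_hot_logits_zero_loss(self):
        labels = np.array([1, 2])
        logits = nn.Tensor(np.eye(3)[labels] * 1e4)
        loss = nn.cross_entropy_logits(logits, labels)
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_total_is_sum_of_components(self, micro_model, assembled,
                                        text_vocab, micro_config):
        rng = np.random.default_rng(4)
        masked = tk.apply_masking(assembled, text_vocab,
                                  micro_config.node_vocab_size, 0.3, rng)
        masked.nsp_label = NSP_RANDOM
        batch = tk.collate([masked])
        _, mlm, mem, nsp = micro_model.forward(batch)
        lc = tk.compute_losses(mlm, mem, nsp, batch, variant="full")
        # independent per-component oracle
        def ce(logits, labels):
            z = logits - logits.max(axis=-1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
            flat = labels.reshape(-1)
            rows = flat != nn.IGNORE_INDEX
            lp = logp.reshape(-1, logp.shape[-1])[rows, flat[rows]]
            return -lp.mean() if rows.any() else 0.0
        expect = (ce(mlm.data, batch.mlm_labels)
                  + ce(mem.data, batch.mem_labels)
                  + ce(nsp.data, batch.nsp_labels))
        assert lc.total.item() == pytest.approx(expect, abs=1e-9)
        assert lc.total.item() == pytest.approx(
            lc.mlm.item() + lc.mem.item() + lc.nsp.item(), abs=1e-12)


class TestNspExamples:
    def test_augmentation_count_law(self, pairs):
        out = tk.make_nsp_examples(pairs[:100], negative_fraction=0.25, seed=0)
        assert len(out) == 125
        assert sum(lab == NSP_RANDOM for _, lab in out) == 25

    def test_zero_fraction_returns_originals(self, pairs):
        out = tk.make_nsp_examples(pairs[:10], negative_fraction=0.0, seed=0)
        assert [p.pair_id for p, _ in out] == [p.pair_id for p in pairs[:10]]

    def test_negatives_never_cooccur_in_originals(self, pairs):
        originals = {(p.evidence, p.triple.as_tuple()) for p in pairs}
        out = tk.make_nsp_examples(pairs, negative_fraction=0.25, seed=1)
        for p, lab in out:
            if lab == NSP_RANDOM:
                assert (p.evidence, p.triple.as_tuple()) not in originals

    def test_too_few_pairs_rejected(self, pairs):
        with pytest.raises(ConfigError):
            tk.make_nsp_examples(pairs[:1], negative_fraction=1.0, seed=0)


class TestPoolAndClassify:
    def test_probabilities_sum_to_one(self, micro_model, assembled):
        batch = tk.collate([assembled])
        hidden, *_ = micro_model.forward(batch)
        rng = np.random.default_rng(0)
        head = nn.Linear(micro_model.config.hidden, 3, rng)
        probs = tk.pool_and_classify(hidden.slice((slice(None), 0)), head)
        assert probs.shape == (1, 3)
        assert probs.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_head_uniform(self, micro_model, assembled):
        batch = tk.collate([assembled])
        hidden, *_ = micro_model.forward(batch)
        head = nn.Linear(micro_model.config.hidden, 4,
                         np.random.default_rng(0), zero_init=True)
        probs = tk.pool_and_classify(hidden.slice((slice(None), 0)), head)
        np.testing.assert_allclose(probs.data, 0.25, atol=1e-12)


def test_checkpoint_round_trip(tmp_path, micro_model):
    save_checkpoint(micro_model, tmp_path / "ck", extra={"step": 3})
    model, extra = load_checkpoint(tmp_path / "ck")
    assert extra == {"step": 3}
    for k, v in model.state_dict().items():
        np.testing.assert_array_equal(v, micro_model.state_dict()[k])
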