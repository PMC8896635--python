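"""Training-loop contracts: checkpointing, variants, determinism, baselines."""

import numpy as np
import pytest

import textkg as tk
from textkg.exceptions import ConfigError, DataError
from textkg.training import pool_max, smoothed


@pytest.fixture(scope="module")
def micro_setup(kg, pairs, node_table, text_vocab, micro_config):
    seq = tk.WalkSequencer(kg, node_table, micro_config.walk_length, seed=11)
    corpus, _ = tk.split_corpus(pairs)
    return corpus[:120], seq


class TestTrainConfig:
    def test_default_finetune_profile(self):
        cfg = tk.default_finetune_config()
        assert (cfg.epochs, cfg.batch_size, cfg.lr) == (5, 16, 5e-5)

    def test_validation(self):
        with pytest.raises(ConfigError):
            tk.TrainConfig(lr=0.0)
        with pytest.raises(ConfigError):
            tk.TrainConfig(checkpoint_steps=(20, 10))
        with pytest.raises(ConfigError):
            tk.TrainConfig(variant="bogus")


class TestPretrain:
    def test_checkpoints_emitted_and_prefix_property(self, micro_setup,
                                                     micro_config, text_vocab):
        corpus, seq = micro_setup
        cfg = tk.TrainConfig(batch_size=8, lr=1e-3, seed=5, steps=20,
                             checkpoint_steps=(10, 20))
        m1 = tk.CrossEncoder(micro_config, seed=5)
        cks1, log1 = tk.pretrain(corpus, m1, text_vocab, seq, cfg)
        assert [c.step for c in cks1] == [10, 20]
        # identical rerun: the interim checkpoint is the state of the same
        # deterministic trajectory at the shared step
        m2 = tk.CrossEncoder(micro_config, seed=5)
        cks2, log2 = tk.pretrain(corpus, m2, text_vocab, seq, cfg)
        for a, b in zip(cks1, cks2):
            assert a.step == b.step
            for k in a.state:
                np.testing.assert_array_equal(a.state[k], b.state[k])
        assert log1 == log2

    def test_no_nsp_variant_logs_zero_nsp(self, micro_setup, micro_config,
                                          text_vocab):
        corpus, seq = micro_setup
        cfg = tk.TrainConfig(batch_size=8, lr=1e-3, seed=5, steps=6,
                             variant="no_nsp", log_every=1)
        model = tk.CrossEncoder(micro_config, seed=5)
        _, log = tk.pretrain(corpus, model, text_vocab, seq, cfg)
        assert all(rec["L_NSP"] == 0.0 for rec in log)
        assert all(rec["L_total"] == pytest.approx(rec["L_MLM"] + rec["L_MEM"])
                   for rec in log)

    def test_empty_corpus_rejected(self, micro_setup, micro_config, text_vocab):
        _, seq = micro_setup
        model = tk.CrossEncoder(micro_config, seed=0)
        with pytest.raises(ConfigError):
            tk.pretrain([], model, text_vocab, seq,
                        tk.TrainConfig(steps=5, seed=0))

    def test_metrics_written_as_json_lines(self, micro_setup, micro_config,
                                           text_vocab, tmp_path):
        import json
        corpus, seq = micro_setup
        model = tk.CrossEncoder(micro_config, seed=1)
        path = tmp_path / "metrics.jsonl"
        tk.pretrain(corpus, model, text_vocab, seq,
                    tk.TrainConfig(batch_size=8, lr=1e-3, seed=1, steps=5,
                                   log_every=1), metrics_path=path)
        recs = [json.loads(l) for l in path.read_text().splitlines()]
        assert len(recs) == 5
        assert set(recs[0]) == {"step", "L_MLM", "L_MEM", "L_NSP", "L_total"}


class TestFinetune:
    def test_zero_epochs_leaves_head_at_init(self, micro_setup, micro_config,
                                             text_vocab, pairs):
        corpus, seq = micro_setup
        model = tk.CrossEncoder(micro_config, seed=3)
        labeled = tk.generate_task_labels(pairs, "fused", 2, seed=0)[:20]
        labels = [p.annotations["fused2"] for p in labeled]
        before = model.state_dict()
        clf = tk.finetune(model, labeled, labels, ["c0", "c1"], text_vocab,
                          seq, tk.TrainConfig(epochs=0, seed=3))
        rng = np.random.default_rng(3)
        expect_head = tk.nn.Linear(micro_config.hidden, 2, rng)
        np.testing.assert_array_equal(clf.head.weight.data,
                                      expect_head.weight.data)
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_backbone_weights_change_during_finetune(self, micro_setup,
                                                     micro_config, text_vocab,
                                                     pairs):
        corpus, seq = micro_setup
        model = tk.CrossEncoder(micro_config, seed=3)
        labeled = tk.generate_task_labels(pairs, "fused", 2, seed=0)[:32]
        labels = [p.annotations["fused2"] for p in labeled]
        before = model.state_dict()
        tk.finetune(model, labeled, labels, ["c0", "c1"], text_vocab, seq,
                    tk.TrainConfig(epochs=1, lr=1e-3, seed=3))
        changed = any(
            not np.array_equal(v, before[k])
            for k, v in model.state_dict().items())
        assert changed

    def test_label_outside_classes_rejected(self, micro_setup, micro_config,
                                            text_vocab, pairs):
        _, seq = micro_setup
        model = tk.CrossEncoder(micro_config, seed=3)
        with pytest.raises(DataError):
            tk.finetune(model, pairs[:4], ["zz"] * 4, ["c0", "c1"],
                        text_vocab, seq, tk.TrainConfig(epochs=1, seed=0))

    def test_linearly_separable_task_fits_to_one(self, kg, node_table,
                                                 text_vocab):
        # keyword-determined labels, text baseline: training accuracy -> 1
        cfg = tk.SynthConfig(n_nodes=60, n_pairs=200, annotation_fraction=1.0,
                             seed=13)
        ps = tk.generate_pairs(kg, cfg)
        labeled = tk.generate_task_labels(ps, "text_determined", 2, seed=13)
        labels = [p.annotations["text_determined2"] for p in labeled]
        vocab = tk.build_vocabulary([p.evidence for p in labeled])
        enc = tk.TextEncoder(32, 1, 2, 64, 16, vocab.size, seed=13)
        clf = tk.finetune_text_baseline(
            enc, labeled, labels, ["c0", "c1"], vocab, 16,
            tk.TrainConfig(batch_size=16, epochs=12, lr=1e-3, seed=13))
        acc = np.mean(np.asarray(clf.predict(labeled)) == np.asarray(labels))
        assert acc == 1.0


class TestKgBaseline:
    def test_pool_max_definition(self):
        np.testing.assert_array_equal(pool_max([[1, 5], [3, 2]]), [3, 5])
        np.testing.assert_array_equal(pool_max([[7, -1, 2]]), [7, -1, 2])

    def test_pool_max_matches_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        seq = rng.normal(size=(13, 9))
        oracle = [max(seq[i][d] for i in range(13)) for d in range(9)]
        np.testing.assert_allclose(pool_max(seq), oracle)

    def test_pool_max_rejects_bad_shapes(self):
        with pytest.raises(DataError):
            pool_max(np.zeros((0, 3)))
        with pytest.raises(DataError):
            pool_max(np.zeros(3))

    def test_embeddings_static_during_fit(self, kg, node_table, pairs):
        seq = tk.WalkSequencer(kg, node_table, 7, seed=1)
        labeled = tk.generate_task_labels(pairs, "node_determined", 2, seed=1)
        labels = [p.annotations["node_determined2"] for p in labeled]
        sequences = [seq(p.triple) for p in labeled]
        before = node_table.matrix.copy()
        clf = tk.fit_kg_baseline(sequences, labels,
                                 tk.TrainConfig(seed=0), seq_builder=seq)
        np.testing.assert_array_equal(node_table.matrix, before)
        preds = clf.predict(labeled[:10])
        assert set(preds) <= {"c0", "c1"}

    def test_ragged_dimensions_rejected(self):
        a = tk.TripleSequence(np.zeros(2, dtype=np.int64),
                              np.zeros((2, 4)), "walk")
        b = tk.TripleSequence(np.zeros(2, dtype=np.int64),
                              np.zeros((2, 5)), "walk")
        with pytest.raises(DataError):
            tk.fit_kg_baseline([a, b], ["x", "y"], tk.TrainConfig(seed=0))


def test_smoothed_moving_average():
    assert smoothed([1.0, 2.0, 3.0], window=2) == [1.0, 1.5, 2.5]


class TestTranseInputVariant:
    def test_pretrain_and_finetune_with_translational_input(
            self, kg, pairs, node_table, text_vocab, micro_config):
        import numpy as np
        transe = tk.train_transe(kg, dim=16, epochs=2, seed=4)
        seq = tk.TranseSequencer(transe)
        # random-replacement vectors: entity rows plus a separator stand-in
        node_matrix = np.vstack([
            transe.ent,
            np.zeros((micro_config.node_vocab_size - transe.ent.shape[0], 16)),
        ])
        model = tk.CrossEncoder(micro_config, seed=4, transe_input_dim=16)
        cfg = tk.TrainConfig(batch_size=8, lr=1e-3, seed=4, steps=5,
                             variant="transe_input", log_every=1)
        _, log = tk.pretrain(pairs[:60], model, text_vocab, seq, cfg,
                             node_matrix=node_matrix)
        assert len(log) == 5
        assert all(np.isfinite(rec["L_total"]) for rec in log)
        labeled = tk.generate_task_labels(pairs, "fused", 2, seed=4)[:24]
        labels = [p.annotations["fused2"] for p in labeled]
        clf = tk.finetune(model, labeled, labels, ["c0", "c1"], text_vocab,
                          seq, tk.TrainConfig(epochs=1, lr=1e-3, seed=4))
        assert set(clf.predict(labeled[:8])) <= {"c0", "c1"}

    def test_transe_runner_excluded_on_relation_tasks(self, kg, node_table):
        from textkg.runners import KgBaselineRunner
        seq = tk.TranseSequencer(tk.train_transe(kg, dim=8, epochs=1, seed=0))
        runner = KgBaselineRunner("kg-transe", seq, tk.TrainConfig(seed=0),
                                  uses_transe_input=True)
        cfg = tk.SynthConfig(n_nodes=60, n_pairs=200, annotation_fraction=1.0,
                             seed=11)
        ps = tk.generate_pairs(kg, cfg)
        labeled = tk.generate_task_labels(ps, "relation_determined", 2, seed=0)
        labels = [p.annotations["relation_determined2"] for p in labeled]
        task = tk.TaskSpec("polarity_like", ["c0", "c1"], "relation_type")
        res = tk.run_benchmark([runner], [task],
                               {"polarity_like": (labeled, labels)},
                               k=2, seed=0)
        assert res[0].excluded and res[0].mean_f1 is None
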