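"""Numpy BiGRU student: gradients, training schemes, prediction, persistence."""

import numpy as np
import pytest

from passforge import (
    LabelledExample,
    StudentConfig,
    load_model,
    predict,
    predict_batch,
    save_model,
    tiny_student_config,
    train_student,
)
from passforge.student_model import (
    _backward,
    _forward,
    _init_params,
    _loss_and_dlogits,
)


def _plain_config(**kw):
    base = dict(embed_dim=6, hidden_size=5, num_layers=2, dropout_embed=0.0,
                dropout_recurrent_weight=0.0, dropout_between_layers=0.0, seed=0)
    base.update(kw)
    return StudentConfig(**base)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = _plain_config()
        rng = np.random.default_rng(0)
        params = _init_params(cfg, rng)
        ids = np.array([[1, 2, 3, 4, 0], [5, 6, 7, 0, 0]])
        mask = np.array([[1, 1, 1, 1, 1.0], [1, 1, 1, 0, 0.0]])
        targets = np.array([[0, 1, 2, 1, -1], [2, 2, 0, -1, -1]])

        def loss_of(p):
            logits, _ = _forward(p, cfg, ids, mask, train=False, rng=None)
            return _loss_and_dlogits(logits, targets, mask)[0]

        logits, cache = _forward(params, cfg, ids, mask, train=True,
                                 rng=np.random.default_rng(1))
        _, dlogits, _ = _loss_and_dlogits(logits, targets, mask)
        grads = _backward(params, cfg, dlogits, cache)
        eps = 1e-5
        check_rng = np.random.default_rng(2)
        for name, value in params.items():
            for flat in check_rng.choice(value.size, size=min(8, value.size), replace=False):
                idx = np.unravel_index(flat, value.shape)
                orig = value[idx]
                value[idx] = orig + eps
                lp = loss_of(params)
                value[idx] = orig - eps
                lm = loss_of(params)
                value[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - grads[name][idx]) < 1e-7, name


class TestTraining:
    def test_memorizes_single_example(self):
        ex = LabelledExample("f1", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL",
                             "HHHHHHEEEEEECCCCCCHHHHHEEEEECC")
        val = LabelledExample("g1", ex.sequence, ex.labels)
        cfg = StudentConfig(embed_dim=16, hidden_size=16, num_layers=1,
                            dropout_embed=0.0, dropout_recurrent_weight=0.0,
                            dropout_between_layers=0.0, learning_rate=1e-2,
                            batch_size=1, max_epochs=150, patience=150, seed=0)
        model, _ = train_student([], [ex], [val], cfg, scheme="supervised_only")
        _, labels, _ = predict(model, ex.sequence)
        assert labels == ex.labels

    def test_same_seed_same_history_and_predictions(self, universe):
        cfg = tiny_student_config(seed=5)
        sub = universe.labelled_train[:8]
        runs = [train_student([], sub, universe.labelled_val, cfg,
                              scheme="supervised_only") for _ in range(2)]
        assert runs[0][1].rows == runs[1][1].rows
        seq = universe.labelled_test[0].sequence
        p1, _, _ = predict(runs[0][0], seq)
        p2, _, _ = predict(runs[1][0], seq)
        assert np.array_equal(p1, p2)

    def test_leaking_validation_family_refused(self, universe):
        ex = universe.labelled_train[0]
        with pytest.raises(ValueError, match="overlap"):
            train_student([], [ex], [ex], tiny_student_config(),
                          scheme="supervised_only")

    def test_pseudo_scheme_requires_pseudo_data(self, universe):
        with pytest.raises(ValueError, match="pseudo"):
            train_student([], universe.labelled_train, universe.labelled_val,
                          tiny_student_config(), scheme="pseudo_only")

    def test_unknown_scheme_rejected(self, universe):
        with pytest.raises(ValueError, match="scheme"):
            train_student([], universe.labelled_train, universe.labelled_val,
                          tiny_student_config(), scheme="distillation")

    def test_early_stopping_best_at_least_final(self, universe):
        cfg = tiny_student_config(seed=1)
        _, hist = train_student([], universe.labelled_train, universe.labelled_val,
                                cfg, scheme="supervised_only")
        phase_rows = [r for r in hist.rows if r[0] == "supervised"]
        best_epoch, best_q3 = hist.best["supervised"]
        assert best_q3 >= phase_rows[-1][3]
        assert best_q3 == max(r[3] for r in phase_rows)

    def test_finetune_phase_sees_only_labelled_families(self, universe, teacher):
        from passforge import ScreenConfig, build_pass_dataset
        pseudo = build_pass_dataset(
            universe.unlabelled_clusters[:80], teacher,
            universe.labelled_val, universe.labelled_test, ScreenConfig(),
        ).examples
        cfg = tiny_student_config(seed=2)
        cfg.max_epochs = 3
        _, hist = train_student(pseudo, universe.labelled_train,
                                universe.labelled_val, cfg,
                                scheme="pretrain_finetune")
        labelled_fams = {e.family for e in universe.labelled_train}
        pseudo_fams = {e.family for e in pseudo}
        assert set(hist.families_seen["finetune"]) <= labelled_fams
        assert not (set(hist.families_seen["finetune"]) & pseudo_fams)
        assert set(hist.families_seen["pretrain"]) <= pseudo_fams


class TestPredict:
    @pytest.fixture(scope="class")
    def model(self, universe):
        cfg = tiny_student_config(seed=3)
        cfg.max_epochs = 4
        model, _ = train_student([], universe.labelled_train,
                                 universe.labelled_val, cfg,
                                 scheme="supervised_only")
        return model

    @pytest.mark.parametrize("length", [1, 20, 500])
    def test_output_length_matches_input(self, model, rng, length):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        probs, labels, entropy = predict(model, seq)
        assert probs.shape == (length, 3)
        assert len(labels) == length
        assert entropy >= 0.0

    def test_probabilities_normalized(self, model, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=64))
        probs, _, _ = predict(model, seq)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_sequence_rejected(self, model):
        with pytest.raises(ValueError):
            predict(model, "")

    def test_batch_equals_single(self, model, rng):
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                   size=rng.integers(5, 90))) for _ in range(6)]
        batched = predict_batch(model, seqs)
        for seq, bp in zip(seqs, batched):
            single, _, _ = predict(model, seq)
            assert np.allclose(single, bp, atol=1e-12)


class TestPersistence:
    def test_save_load_round_trip(self, universe, tmp_path):
        cfg = tiny_student_config(seed=4)
        cfg.max_epochs = 2
        model, _ = train_student([], universe.labelled_train,
                                 universe.labelled_val, cfg,
                                 scheme="supervised_only")
        path = tmp_path / "m.npz"
        save_model(model, path)
        back = load_model(path)
        seq = universe.labelled_test[0].sequence
        assert np.array_equal(predict(model, seq)[0], predict(back, seq)[0])
        assert back.config == model.config

    def test_corrupted_file_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"PK\x03\x04 garbage not a real archive")
        with pytest.raises(ValueError):
            load_model(path)
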