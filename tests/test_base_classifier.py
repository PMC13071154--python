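import numpy as np
import pytest

from etpfam.base_classifier import (
    BaseModelConfig,
    TrainedBaseModel,
    WindowClassifier,
    build_model,
    score_sequence,
    score_window,
    train,
)
from etpfam.data_model import DomainAnnotation
from etpfam.embedder import EmbeddedSequence
from etpfam.windowing import Window, WindowSpec, pad_window


def small_config(**kw):
    base = dict(W=8, lr=1e-3, F=12, Fb=6, E=5, K=4, seed=0, max_epochs=10,
                batch_size=32, windows_per_seq=2)
    base.update(kw)
    return BaseModelConfig(**base)


def make_window(slice_, W, label=None):
    sl, mask = pad_window(np.asarray(slice_, float), W)
    return Window("s", 0, W, sl, mask, label)


class TestBuild:
    def test_output_length_is_K(self, rng):
        model = build_model(small_config(K=5))
        w = make_window(rng.standard_normal((5, 8)), 8)
        assert score_window(model, w).shape == (5,)

    def test_same_seed_identical_initial_parameters(self):
        a = build_model(small_config(seed=3))
        b = build_model(small_config(seed=3))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_different_seed_differs(self):
        a = build_model(small_config(seed=0))
        b = build_model(small_config(seed=1))
        assert any(
            not np.array_equal(a.params[k], b.params[k]) for k in a.params
        )

    def test_default_config_follows_protocol(self):
        cfg = BaseModelConfig(E=1280, K=10)
        assert (cfg.F, cfg.Fb, cfg.patience) == (1100, 550, 5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            small_config(F=4, Fb=8)
        with pytest.raises(ValueError):
            small_config(lr=0.0)


class TestScoreWindow:
    def test_softmax_contract(self, rng):
        model = build_model(small_config())
        for _ in range(5):
            w = make_window(rng.standard_normal((5, 8)), 8)
            s = score_window(model, w)
            assert abs(s.sum() - 1.0) < 1e-6
            assert np.all((s >= 0) & (s <= 1))

    def test_zeroed_head_gives_uniform(self, rng):
        model = build_model(small_config(K=4))
        model.params["w_fc"][:] = 0.0
        model.params["b_fc"][:] = 0.0
        w = make_window(rng.standard_normal((5, 8)), 8)
        np.testing.assert_allclose(score_window(model, w), 0.25, atol=1e-12)

    def test_masked_padding_does_not_change_score(self, rng):
        # a width-3 slice padded to W scores identically regardless of what
        # the padded columns contain, because pooling is masked
        model = build_model(small_config())
        content = rng.standard_normal((5, 3))
        w_zero = make_window(content, 8)
        w_junk = Window(
            "s", 0, 8,
            np.concatenate([content, 1e3 * np.ones((5, 5))], axis=1),
            w_zero.mask, None,
        )
        np.testing.assert_allclose(
            score_window(model, w_zero), score_window(model, w_junk), atol=1e-9
        )

    def test_shape_mismatch_rejected(self, rng):
        model = build_model(small_config())
        w = make_window(rng.standard_normal((5, 4)), 4)
        with pytest.raises(ValueError, match="shape"):
            score_window(model, w)


def toy_task(n_seq, K=3, E=5, L=20, seed=0):
    """Label is a deterministic function of one embedding coordinate: the
    domain span of class k carries +2 on coordinate k."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_seq):
        k = int(rng.integers(0, K))
        m = rng.normal(0, 0.3, size=(E, L))
        m[k, 4:16] += 2.0
        out.append(
            EmbeddedSequence(f"t{i}", m, [DomainAnnotation(f"F{k}", 5, 16)])
        )
    return out, {f"F{k}": k for k in range(K)}


class TestTraining:
    def test_learnable_toy_task(self):
        train_seqs, fidx = toy_task(120, seed=1)
        dev_seqs, _ = toy_task(40, seed=2)
        cfg = small_config(K=3, max_epochs=20, windows_per_seq=4)
        tm = train(WindowClassifier(cfg), train_seqs, dev_seqs, fidx)
        assert tm.history[tm.best_epoch - 1]["dev_error"] < 0.05

    def test_same_seed_same_history(self):
        train_seqs, fidx = toy_task(30, seed=1)
        dev_seqs, _ = toy_task(10, seed=2)
        cfg = small_config(K=3, max_epochs=4)
        h1 = train(WindowClassifier(cfg), train_seqs, dev_seqs, fidx).history
        h2 = train(WindowClassifier(cfg), train_seqs, dev_seqs, fidx).history
        assert h1 == h2

    def test_empty_training_stream_rejected(self):
        dev_seqs, fidx = toy_task(5)
        with pytest.raises(ValueError, match="empty training"):
            train(WindowClassifier(small_config(K=3)), [], dev_seqs, fidx)

    def test_early_stop_on_worsening_dev_loss(self):
        # injected dev metric worsens monotonically after epoch 1: training
        # must stop at epoch 1 + patience and restore epoch-1 parameters
        train_seqs, fidx = toy_task(20, seed=1)
        cfg = small_config(K=3, max_epochs=50, patience=5)
        model = WindowClassifier(cfg)
        snapshots = {}
        losses = iter([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])

        def evaluator(m):
            loss = next(losses)
            snapshots[loss] = {k: v.copy() for k, v in m.params.items()}
            return loss, 0.5

        tm = train(model, train_seqs, [], fidx, dev_evaluator=evaluator)
        assert tm.best_epoch == 1
        assert len(tm.history) == 6  # stopped after epoch 1 + patience
        for k, v in snapshots[1.0].items():
            np.testing.assert_array_equal(tm.model.params[k], v)

    def test_best_epoch_metric_is_minimal(self):
        train_seqs, fidx = toy_task(40, seed=3)
        dev_seqs, _ = toy_task(15, seed=4)
        cfg = small_config(K=3, max_epochs=8)
        tm = train(WindowClassifier(cfg), train_seqs, dev_seqs, fidx)
        losses = [h["dev_loss"] for h in tm.history]
        assert losses[tm.best_epoch - 1] == min(losses)


class TestScoreSequence:
    def test_track_matches_slide_enumeration(self, rng):
        model = build_model(small_config(W=4, step=4))
        emb = EmbeddedSequence("s", rng.standard_normal((5, 10)))
        track = score_sequence(model, emb)
        assert track.n_positions == 3  # starts 0, 4, 6

    def test_single_window_equals_score_window(self, rng):
        model = build_model(small_config(W=8))
        emb = EmbeddedSequence("s", rng.standard_normal((5, 8)))
        track = score_sequence(model, emb)
        w = make_window(emb.matrix, 8)
        np.testing.assert_allclose(track.scores[0], score_window(model, w))

    def test_deterministic_inference(self, rng):
        model = build_model(small_config(W=4))
        emb = EmbeddedSequence("s", rng.standard_normal((5, 17)))
        a = score_sequence(model, emb)
        b = score_sequence(model, emb)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        train_seqs, fidx = toy_task(20, seed=1)
        dev_seqs, _ = toy_task(8, seed=2)
        cfg = small_config(K=3, max_epochs=3)
        tm = train(WindowClassifier(cfg), train_seqs, dev_seqs, fidx)
        p = tmp_path / "ckpt.npz"
        tm.save(p)
        back = TrainedBaseModel.load(p)
        assert back.best_epoch == tm.best_epoch
        assert back.history == tm.history
        for k in tm.model.params:
            np.testing.assert_array_equal(back.model.params[k], tm.model.params[k])
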