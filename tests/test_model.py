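"""Encoder, loss, and training-loop behavior at desk scale."""
import numpy as np
import pytest

import phoskin.nn.autograd as autograd
from phoskin.encoding import Vocabulary, encode_pair, mlm_corrupt
from phoskin.nn.autograd import AdamW, Tensor, gelu, layer_norm, log_softmax
from phoskin.nn.transformer import ModelConfig, TransformerEncoder
from phoskin.records import KinaseRecord, LabeledPair, PairLabel, PeptideWindow
from phoskin.training import (
    TrainConfig,
    _focal_batch_loss,
    classify,
    finetune,
    focal_loss,
    mlm_loss,
    pretrain,
)


class TestAutograd:
    def test_gradients_match_finite_differences(self):
        autograd.set_default_dtype(np.float64)
        try:
            rng = np.random.default_rng(0)
            wd = rng.standard_normal((4, 6))

            def f(w_data):
                w = Tensor(w_data, requires_grad=True)
                x = Tensor(np.linspace(-1, 1, 12).reshape(3, 4))
                g = Tensor(np.ones(6), requires_grad=True)
                b = Tensor(np.zeros(6), requires_grad=True)
                h = gelu(layer_norm(x @ w, g, b))
                s = log_softmax(h, axis=-1)
                return (s * s).mean(), w

            loss, w = f(wd)
            loss.backward()
            eps = 1e-6
            numeric = np.zeros_like(wd)
            for i in range(wd.shape[0]):
                for j in range(wd.shape[1]):
                    up, down = wd.copy(), wd.copy()
                    up[i, j] += eps
                    down[i, j] -= eps
                    numeric[i, j] = (f(up)[0].item() - f(down)[0].item()) / (2 * eps)
            assert np.abs(w.grad - numeric).max() < 1e-7
        finally:
            autograd.set_default_dtype(np.float32)

    def test_shared_gradient_buffers_not_corrupted(self):
        # y = a + a uses one incoming buffer for both accumulations
        a = Tensor(np.ones(3), requires_grad=True)
        (a + a).sum().backward()
        assert np.allclose(a.grad, 2.0)


class TestEncoderForward:
    def test_output_shape_tracks_config(self, vocab, peptide):
        for dim in (32, 64):
            model = TransformerEncoder(
                ModelConfig(n_layers=2, n_heads=4, embed_dim=dim, ffn_dim=2 * dim, max_len=128),
                seed=0,
            )
            pair = encode_pair(peptide, "M" * 50, vocab)
            hidden, _ = model.forward(pair.token_ids[None, :])
            assert hidden.data.shape == (1, 65, dim)

    def test_paper_configuration_returns_768_dims(self, vocab, peptide):
        model = TransformerEncoder(ModelConfig(), seed=0)  # 6 layers, 12 heads, 768 dims
        pair = encode_pair(peptide, "MKAYL", vocab)
        hidden, _ = model.forward(pair.token_ids[None, :])
        assert hidden.data.shape == (1, 11 + 5 + 4, 768)

    def test_deterministic_forward(self, tiny_model, vocab, peptide):
        pair = encode_pair(peptide, "M" * 30, vocab)
        a, _ = tiny_model.forward(pair.token_ids[None, :])
        b, _ = tiny_model.forward(pair.token_ids[None, :])
        assert np.array_equal(a.data, b.data)

    def test_over_length_input_rejected(self, tiny_model):
        ids = np.zeros((1, 500), dtype=np.int64)
        with pytest.raises(ValueError, match="max_len"):
            tiny_model.forward(ids)

    def test_attention_rows_sum_to_one(self, tiny_model, vocab, peptide):
        pair = encode_pair(peptide, "M" * 30, vocab)
        _, attns = tiny_model.forward(pair.token_ids[None, :], collect_attention=True)
        for layer in attns:
            assert np.allclose(layer.sum(axis=-1), 1.0, atol=1e-5)

    def test_save_load_round_trip(self, tiny_model, vocab, peptide, tmp_path):
        pair = encode_pair(peptide, "MKAYL", vocab)
        before, _ = tiny_model.forward(pair.token_ids[None, :])
        tiny_model.save(tmp_path / "ckpt")
        again = TransformerEncoder.load(tmp_path / "ckpt")
        after, _ = again.forward(pair.token_ids[None, :])
        assert np.array_equal(before.data, after.data)


class TestLosses:
    def test_focal_reduces_to_cross_entropy_at_gamma_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1 - 1e-6, size=1000)
        assert np.allclose(focal_loss(p, gamma=0.0), -np.log(p), rtol=0, atol=1e-15)

    def test_focal_value_at_half_with_gamma_two(self):
        assert focal_loss(0.5, gamma=2.0) == pytest.approx(0.25 * np.log(2), rel=1e-12)

    def test_focal_vanishes_as_confidence_grows(self):
        assert focal_loss(1 - 1e-9, gamma=2.0) < 1e-15
        p = np.linspace(0.05, 0.95, 50)
        assert (np.diff(focal_loss(p, gamma=2.0)) < 0).all()

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(0.5, gamma=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(gamma=-0.5)

    def test_uniform_predictor_mlm_loss_is_log_vocab(self, vocab):
        # zero-initialized MLM head -> exactly uniform over the 25 tokens
        model = TransformerEncoder(ModelConfig.tiny(), seed=0)
        batch = mlm_corrupt(
            [vocab.encode_sequence("ACDEFGHIKLMNPQRSTVWY" * 3)],
            0.15,
            np.random.default_rng(0),
            vocab,
        )
        loss = mlm_loss(model, batch, vocab)
        assert loss.item() == pytest.approx(np.log(25), rel=1e-6)

    def test_mlm_loss_requires_masked_tokens(self, vocab):
        model = TransformerEncoder(ModelConfig.tiny(), seed=0)
        batch = mlm_corrupt(
            [np.array([vocab.sos_id, vocab.eos_id])], 0.5, np.random.default_rng(0), vocab
        )
        with pytest.raises(ValueError):
            mlm_loss(model, batch, vocab)

    def test_batch_duplication_leaves_mean_loss_unchanged(self, vocab):
        model = TransformerEncoder(ModelConfig.tiny(), seed=3)
        seq = vocab.encode_sequence("ACDEFGHIKLMNPQRSTVWY")
        single = mlm_corrupt([seq], 0.3, np.random.default_rng(5), vocab)
        double = type(single)(
            corrupted=single.corrupted * 2,
            masked_positions=single.masked_positions * 2,
            originals=single.originals * 2,
            n_masked=single.n_masked * 2,
        )
        assert mlm_loss(model, single, vocab).item() == pytest.approx(
            mlm_loss(model, double, vocab).item(), rel=1e-6
        )

    def test_focal_batch_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = Tensor(rng.standard_normal((64, 2)))
        labels = rng.integers(2, size=64)
        focal = _focal_batch_loss(logits, labels, 0.0).item()
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        ce = -np.log(p[np.arange(64), labels]).mean()
        assert focal == pytest.approx(ce, rel=1e-6)


class TestClassifier:
    def test_zeroed_head_scores_exactly_half(self, vocab, peptide):
        model = TransformerEncoder(ModelConfig.tiny(), seed=0)
        model.zero_classifier_head()
        pair = encode_pair(peptide, "MKAYLQWERT", vocab)
        assert classify(model, pair) == pytest.approx(0.5)

    def test_probabilities_sum_to_one(self, tiny_model, vocab, peptide):
        pair = encode_pair(peptide, "MKAYLQWERT", vocab)
        hidden, _ = tiny_model.forward(pair.token_ids[None, :])
        logits = tiny_model.classifier_logits(hidden, 6).data
        p = np.exp(logits) / np.exp(logits).sum()
        assert p.sum() == pytest.approx(1.0)

    def test_score_depends_only_on_center_embedding(self, tiny_model, vocab, peptide):
        pair = encode_pair(peptide, "MKAYLQWERT", vocab)
        hidden, _ = tiny_model.forward(pair.token_ids[None, :])
        full = tiny_model.classifier_logits(hidden, 6).data
        zeroed = hidden.data.copy()
        zeroed[:, :6] = 0.0
        zeroed[:, 7:] = 0.0
        masked = tiny_model.classifier_logits(Tensor(zeroed), 6).data
        assert np.allclose(full, masked, atol=1e-6)

    def test_kinase_perturbation_changes_score(self, vocab, peptide):
        model = TransformerEncoder(ModelConfig.tiny(), seed=1)
        a = classify(model, encode_pair(peptide, "MKAYLQWERTM", vocab))
        b = classify(model, encode_pair(peptide, "MKAYLQWERTW", vocab))
        assert a != b


def _toy_task(n=60, seed=0):
    """Tiny classification task: P at +1 marks a positive."""
    rng = np.random.default_rng(seed)
    kinome = {
        "K1": KinaseRecord("K1", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40)), 5, 35)
    }
    aa = list("ACDEFGHIKLMNQRVW")
    pairs = []
    for i in range(n):
        body = [str(x) for x in rng.choice(aa, size=11)]
        body[5] = "S"
        label = i % 2
        body[6] = "P" if label else "A"
        pairs.append(
            LabeledPair(
                "K1",
                PeptideWindow("".join(body), f"S{i}", 7),
                PairLabel.POSITIVE if label else PairLabel.EASY_NEGATIVE,
            )
        )
    return pairs, kinome


class TestTrainingLoops:
    def test_pretrain_loss_decreases_on_tiny_corpus(self, vocab):
        rng = np.random.default_rng(0)
        corpus = ["".join(rng.choice(list("ACDEFG"), size=60)) for _ in range(40)]
        model = TransformerEncoder(ModelConfig.tiny(), seed=0)
        cfg = TrainConfig(stage="pretrain", learning_rate=1e-3, epochs=3, batch_size=16, seed=0)
        trace = pretrain(model, corpus, cfg, vocab)
        assert len(trace) == 3
        assert trace[-1] < trace[0]

    def test_zero_epochs_leaves_parameters_unchanged(self, vocab):
        model = TransformerEncoder(ModelConfig.tiny(), seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainConfig(stage="pretrain", epochs=0, seed=0)
        assert pretrain(model, ["ACDEFGHIKL"], cfg, vocab) == []
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_same_seed_gives_identical_loss_traces(self, vocab):
        rng = np.random.default_rng(1)
        corpus = ["".join(rng.choice(list("ACDEFG"), size=40)) for _ in range(20)]
        traces = []
        for _ in range(2):
            model = TransformerEncoder(ModelConfig.tiny(), seed=7)
            cfg = TrainConfig(stage="pretrain", learning_rate=1e-3, epochs=2, batch_size=8, seed=7)
            traces.append(pretrain(model, corpus, cfg, vocab))
        assert traces[0] == traces[1]

    def test_finetune_requires_validation_pairs(self, vocab):
        pairs, kinome = _toy_task()
        model = TransformerEncoder(ModelConfig.tiny(), seed=0)
        with pytest.raises(ValueError):
            finetune(model, pairs, [], kinome, TrainConfig(epochs=1, seed=0), None, vocab)

    def test_patience_one_stops_after_one_bad_eval(self, vocab):
        pairs, kinome = _toy_task()
        model = TransformerEncoder(ModelConfig.tiny(), seed=0)
        # learning rate 0 freezes the model: validation loss can never improve
        cfg = TrainConfig(
            stage="finetune", learning_rate=0.0, epochs=10, patience=1, batch_size=16, seed=0
        )
        log = finetune(model, pairs[:40], pairs[40:], kinome, cfg, None, vocab)
        assert log.stopped_early
        assert len(log.val_loss) == 2  # first eval sets the best; second triggers the stop

    def test_finetune_learns_toy_motif(self, vocab):
        from phoskin.training import score_examples

        pairs, kinome = _toy_task(n=120)
        model = TransformerEncoder(ModelConfig.tiny(), seed=0)
        cfg = TrainConfig(
            stage="finetune", learning_rate=1e-3, epochs=12, patience=99, batch_size=8, seed=0
        )
        finetune(model, pairs[:100], pairs[100:], kinome, cfg, None, vocab)
        held = pairs[100:]
        scores = score_examples(model, held, kinome, vocab)
        labels = np.array([p.label is PairLabel.POSITIVE for p in held])
        assert scores[labels].mean() > scores[~labels].mean()

    def test_gradients_are_finite_on_random_batch(self, vocab, peptide):
        model = TransformerEncoder(ModelConfig.tiny(), seed=0)
        pair = encode_pair(peptide, "MKAYLQWERTY", vocab)
        ids = np.stack([pair.token_ids] * 8)
        hidden, _ = model.forward(ids)
        loss = _focal_batch_loss(
            model.classifier_logits(hidden, 6), np.array([0, 1] * 4), 2.0
        )
        loss.backward()
        for p in model.parameters():
            if p.grad is not None:
                assert np.isfinite(p.grad).all()
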