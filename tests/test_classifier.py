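"""Schedule, loss, tokenizer, backprop and the training harness."""

import math

import numpy as np
import pytest

from inhalertech import (
    EncoderSpec,
    Label,
    LabeledSentence,
    Provenance,
    TrainingConfig,
    cyclical_lr,
    predict,
    tokenize_and_pad,
    train,
    weighted_cross_entropy,
)
from inhalertech.classifier import (
    PAD,
    SentenceClassifier,
    TransformerModel,
    WordTokenizer,
    _softmax,
)
from inhalertech.synthetic_notes import default_bank

# ---------------------------------------------------------------------------
# cyclical learning rate


class TestCyclicalLR:
    def test_starts_at_init_rate(self):
        assert cyclical_lr(0, TrainingConfig()) == pytest.approx(3e-5)

    def test_bounded_everywhere(self):
        cfg = TrainingConfig()
        for t in range(0, 20_000, 37):
            assert 2e-5 - 1e-12 <= cyclical_lr(t, cfg) <= 5e-5 + 1e-12

    def test_periodicity(self):
        cfg = TrainingConfig()
        for t in (0, 1, 999, 2500, 4999):
            assert cyclical_lr(t, cfg) == pytest.approx(cyclical_lr(t + 5000, cfg))

    def test_bounds_attained_exactly_at_turning_points(self):
        cfg = TrainingConfig()
        s = cfg.lr_step_size
        offset = s * (cfg.lr_init - cfg.lr_lower) / (cfg.lr_upper - cfg.lr_lower)
        assert cyclical_lr(s - offset, cfg) == pytest.approx(5e-5, abs=0)
        assert cyclical_lr(2 * s - offset, cfg) == pytest.approx(2e-5, abs=0)

    def test_canonical_start_begins_at_lower_bound(self):
        cfg = TrainingConfig(canonical_start=True)
        assert cyclical_lr(0, cfg) == pytest.approx(2e-5)
        assert cyclical_lr(cfg.lr_step_size, cfg) == pytest.approx(5e-5)

    def test_bad_ordering_rejected_at_construction(self):
        with pytest.raises(ValueError, match="lr_lower"):
            TrainingConfig(lr_init=1e-5)


# ---------------------------------------------------------------------------
# weighted cross-entropy


class TestWeightedCrossEntropy:
    def test_uniform_softmax_unit_weights(self):
        assert weighted_cross_entropy((0.0, 0.0), 1) == pytest.approx(math.log(2))

    def test_cost_ratio_forced_by_formula(self):
        lp = weighted_cross_entropy((0.0, 0.0), 1, (0.52, 5.52))
        la = weighted_cross_entropy((0.0, 0.0), 0, (0.52, 5.52))
        assert lp / la == pytest.approx(5.52 / 0.52)

    def test_hand_computed_confident_correct(self):
        # softmax(2, -2)[0] = e^2/(e^2+e^-2)
        want = -math.log(math.exp(2) / (math.exp(2) + math.exp(-2)))
        assert weighted_cross_entropy((2.0, -2.0), 0) == pytest.approx(
            want, rel=1e-6
        )
        assert want == pytest.approx(0.0181, abs=5e-5)

    def test_unit_weights_reduce_to_standard_ce_in_mean(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(50, 2))
        labels = rng.integers(0, 2, size=50)
        got = weighted_cross_entropy(logits, labels, (1.0, 1.0), reduction="mean")
        probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        want = -np.log(probs[np.arange(50), labels]).mean()
        assert got == pytest.approx(want, rel=1e-9)

    def test_non_finite_logits_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            weighted_cross_entropy((float("nan"), 0.0), 0)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy((0.0, 0.0), 0, (0.0, 1.0))


# ---------------------------------------------------------------------------
# tokenizer


@pytest.fixture(scope="module")
def tok():
    return WordTokenizer.build(["discussed correct inhaler technique today"])


class TestTokenizeAndPad:

    def test_default_length_is_256(self, tok):
        ids = tokenize_and_pad("short sentence", tok, 256)
        assert len(ids) == 256

    def test_empty_string_is_specials_plus_padding(self, tok):
        ids = tokenize_and_pad("", tok, 16)
        assert ids[:2] == [2, 3]  # [CLS] [SEP]
        assert set(ids[2:]) == {PAD}

    def test_overlong_input_truncated(self, tok):
        ids = tokenize_and_pad(" ".join(["word"] * 300), tok, 256)
        assert len(ids) == 256
        assert PAD not in ids  # fully occupied after truncation

    def test_unknown_words_map_to_unk(self, tok):
        ids = tokenize_and_pad("xylophone", tok, 8)
        assert ids[1] == 1  # [UNK]


# ---------------------------------------------------------------------------
# backprop correctness


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        spec = EncoderSpec(n_layers=2, hidden_size=16, n_heads=2, ffn_size=24,
                           vocab_size=30)
        m = TransformerModel(spec, max_position=10, rng=rng, dtype=np.float64)
        ids = rng.integers(0, 30, size=(3, 8))
        ids[:, 0] = 2
        ids[0, 5:] = PAD
        y = np.array([1, 0, 1])
        w = np.array([0.52, 5.52])

        def loss():
            logits, _ = m.forward(ids)
            return float(
                np.sum(weighted_cross_entropy(logits, y, (0.52, 5.52)))
                / w[y].sum()
            )

        logits, cache = m.forward(ids, train=True, dropout_p=0.0, rng=rng)
        probs = _softmax(logits)
        onehot = np.zeros_like(probs)
        onehot[np.arange(3), y] = 1.0
        grads = m.backward(cache, w[y][:, None] * (probs - onehot) / w[y].sum())

        eps = 1e-6
        for name in ("tok_emb", "l0.Wq", "l0.ln1.g", "l1.W2", "head.W"):
            flat = m.params[name].reshape(-1)
            for i in rng.choice(flat.size, size=4, replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name].reshape(-1)[i]
                assert abs(num - ana) < 1e-7, name


# ---------------------------------------------------------------------------
# training harness

_bank = default_bank()


def _separable_dataset(n: int, pos_frac: float, seed: int):
    """Balanced-ish labeled sentences from the template bank (explicit
    positives vs filler), spread over many synthetic patients."""
    rng = np.random.default_rng(seed)
    n_pos = int(round(pos_frac * n))
    items = []
    for i in range(n):
        positive = i < n_pos
        pool = _bank.explicit_positive if positive else _bank.filler
        text = _bank.instantiate(pool[int(rng.integers(len(pool)))], rng)
        items.append(LabeledSentence(
            note_id=f"n{i:05d}", section_name="HPI", sentence_index=0,
            text=text, char_span=(0, len(text)), patient_id=f"p{i % 40:03d}",
            label=Label.PRESENT if positive else Label.ABSENT,
            provenance=Provenance.WEAK,
        ))
    perm = rng.permutation(n)
    return [items[i] for i in perm]


_TINY = EncoderSpec(n_layers=2, hidden_size=64, n_heads=2, ffn_size=128)


@pytest.fixture(scope="module")
def trained():
    data = _separable_dataset(2000, 0.05, seed=21)
    cfg = TrainingConfig.tiny_profile(
        class_weights=(0.52, 5.52), epochs=10, seed=21
    )
    return train(data, cfg, _TINY, seed=21), data


class TestTrain:

    def test_separable_templates_reach_val_f1(self, trained):
        clf, _ = trained
        best = max(v for v in clf.history.val_f1 if v is not None)
        assert best >= 0.9

    def test_lr_history_equals_schedule(self, trained):
        clf, _ = trained
        cfg = clf.config
        want = [cyclical_lr(t, cfg) for t in range(len(clf.history.learning_rates))]
        assert clf.history.learning_rates == pytest.approx(want)

    def test_predict_is_deterministic_and_order_preserving(self, trained):
        clf, data = trained
        sents = data[:64]
        a = predict(clf, sents)
        b = predict(clf, sents)
        assert [s.label for s in a] == [s.label for s in b]
        assert [s.text for s in a] == [s.text for s in sents]
        assert all(s.provenance is Provenance.MODEL for s in a)

    def test_predict_empty_is_empty(self, trained):
        clf, _ = trained
        assert predict(clf, []) == []

    def test_heldout_accuracy_beats_majority_baseline(self, trained):
        clf, _ = trained
        held = _separable_dataset(400, 0.3, seed=99)
        preds = predict(clf, held)
        acc = np.mean([
            p.label == g.label for p, g in zip(preds, held)
        ])
        assert acc > 0.7  # majority baseline on this set is 0.7

    def test_checkpoint_round_trip(self, trained, tmp_path):
        clf, data = trained
        clf.save(tmp_path / "model")
        again = SentenceClassifier.load(tmp_path / "model")
        texts = [s.text for s in data[:32]]
        np.testing.assert_array_equal(
            clf.predict_logits(texts), again.predict_logits(texts)
        )

    def test_same_seed_identical_weights(self):
        data = _separable_dataset(300, 0.2, seed=5)
        cfg = TrainingConfig.tiny_profile(epochs=2, seed=5)
        a = train(data, cfg, _TINY, seed=5)
        b = train(data, cfg, _TINY, seed=5)
        for k in a.model.params:
            np.testing.assert_array_equal(a.model.params[k], b.model.params[k])

    def test_single_class_training_data_rejected(self):
        data = [s for s in _separable_dataset(200, 0.0, seed=1)]
        cfg = TrainingConfig.tiny_profile(epochs=1)
        with pytest.raises(ValueError, match="both classes"):
            train(data, cfg, _TINY, seed=1)
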