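"""LC-CNN: label encoding, hinge loss, forward pass, gradients, training."""

import numpy as np
import pytest

from ddae.context_features import fit_vocabulary
from ddae.corpus import enumerate_candidates
from ddae.embeddings import EmbeddingTable
from ddae.lc_cnn import (CLASS_ORDER, FeatureSet, LcCnnConfig, LcCnnModel,
                         decode_label, encode_label, featurize, hinge_loss,
                         train)
from ddae.sentence_features import max_sentence_length
from ddae.synthetic import GeneratorConfig, generate


def brute_force_hinge(out, y):
    """Independent evaluation of the published loss formula."""
    total = 0.0
    for i in range(3):
        total += max(1.0 - y[i] * out[i], 0.0)
    return total / 3.0


# -- labels -----------------------------------------------------------------

@pytest.mark.parametrize("label,expected", [
    ("Positive", (1, -1, -1)),
    ("Negative", (-1, 1, -1)),
    ("Null", (-1, -1, 1)),
])
def test_encode_label(label, expected):
    np.testing.assert_array_equal(encode_label(label), expected)


def test_label_round_trip_and_sum():
    for label in CLASS_ORDER:
        y = encode_label(label)
        assert y.sum() == -1.0  # exactly one +1 among three
        assert decode_label(y) == label
    with pytest.raises(ValueError):
        encode_label("Maybe")


# -- hinge loss -------------------------------------------------------------

def test_hinge_zero_when_margins_exceed_boundary():
    assert hinge_loss([2.0, -2.0, -2.0], encode_label("Positive")) == 0.0


def test_hinge_at_origin():
    assert hinge_loss([0.0, 0.0, 0.0], encode_label("Positive")) == 1.0


def test_hinge_all_signs_disagree():
    assert hinge_loss([-1.0, 1.0, 1.0], encode_label("Positive")) == 2.0


def test_hinge_matches_brute_force_on_random_draws():
    rng = np.random.default_rng(12345)
    for _ in range(1000):
        out = rng.normal(scale=3.0, size=3)
        y = encode_label(CLASS_ORDER[rng.integers(3)])
        assert hinge_loss(out, y) == pytest.approx(
            brute_force_hinge(out, y), abs=1e-12)


def test_hinge_zero_iff_all_margins_at_least_one():
    rng = np.random.default_rng(99)
    for _ in range(500):
        out = rng.normal(scale=2.0, size=3)
        y = encode_label(CLASS_ORDER[rng.integers(3)])
        assert (hinge_loss(out, y) == 0.0) == bool(np.all(y * out >= 1.0))


def test_hinge_above_one_when_every_sign_disagrees():
    rng = np.random.default_rng(7)
    for _ in range(500):
        y = encode_label(CLASS_ORDER[rng.integers(3)])
        out = -y * rng.uniform(0.01, 5.0, size=3)  # all signs flipped
        assert hinge_loss(out, y) > 1.0


# -- forward pass -----------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_setup():
    docs, _ = generate(GeneratorConfig(n_docs=6, seed=31))
    vocab = fit_vocabulary(docs, min_count=1)
    emb = EmbeddingTable(dim=8, oov_policy="random_fixed", seed=5)
    T = max_sentence_length(docs)
    cfg = LcCnnConfig(windows=(2, 3), n_filters=4, n_sr=6, seed=13, T=T)
    model = LcCnnModel.initialize(cfg, vocab, emb, T)
    fs = featurize(docs, vocab, emb, T, cfg.clip)
    return docs, vocab, emb, model, fs


def test_zero_parameters_give_zero_scores(tiny_setup):
    docs, vocab, emb, model, fs = tiny_setup
    zero = LcCnnModel(model.config, vocab, emb, model.T,
                      {k: np.zeros_like(v) for k, v in model.params.items()})
    out = zero._forward_batch(fs.X, fs.C, fs.valid, fs.word_ids)
    np.testing.assert_array_equal(out, 0.0)


def test_forward_matches_naive_loop(tiny_setup):
    """Vectorized conv/pool agrees with a direct per-window evaluation."""
    docs, vocab, emb, model, fs = tiny_setup
    i = 2
    x, c, valid = fs.X[i], fs.C[i], int(fs.valid[i])
    pools = []
    for f in model.config.windows:
        W, b = model.params[f"conv_W_{f}"], model.params[f"conv_b_{f}"]
        n_pos = max(1, valid - f + 1)
        acts = np.full((model.config.n_filters, n_pos), -np.inf)
        for p in range(n_pos):
            col = x[:, p:p + f].reshape(-1)
            acts[:, p] = np.maximum(W @ col + b, 0.0)
        pools.append(acts.max(axis=1))
    pool = np.concatenate(pools)
    sr = np.maximum(model.params["W_sr"] @ pool + model.params["b_sr"], 0.0)
    m = np.concatenate([sr, c])
    expected = model.params["W_out"] @ m + model.params["b_out"]
    got = model._forward_batch(fs.X[i:i + 1], fs.C[i:i + 1], fs.valid[i:i + 1],
                               fs.word_ids[i:i + 1])[0]
    np.testing.assert_allclose(got, expected, rtol=1e-10)


def test_appending_padding_does_not_change_scores(tiny_setup):
    docs, vocab, emb, model, fs = tiny_setup
    # positive conv bias would leak through pooling if padding were pooled
    for f in model.config.windows:
        model.params[f"conv_b_{f}"] += 0.5
    out1 = model._forward_batch(fs.X, fs.C, fs.valid, fs.word_ids)
    extra = 4
    Xp = np.concatenate([fs.X, np.zeros(fs.X.shape[:2] + (extra,))], axis=2)
    Wp = np.concatenate([fs.word_ids,
                         -np.ones((len(fs.word_ids), extra), int)], axis=1)
    out2 = model._forward_batch(Xp, fs.C, fs.valid, Wp)
    np.testing.assert_allclose(out1, out2, rtol=1e-12)
    for f in model.config.windows:
        model.params[f"conv_b_{f}"] -= 0.5


def test_forward_deterministic(tiny_setup):
    docs, vocab, emb, model, fs = tiny_setup
    a = model._forward_batch(fs.X, fs.C, fs.valid, fs.word_ids)
    b = model._forward_batch(fs.X, fs.C, fs.valid, fs.word_ids)
    np.testing.assert_array_equal(a, b)


def test_predict_argmax_and_tie_break(tiny_setup):
    docs, vocab, emb, model, fs = tiny_setup
    assert CLASS_ORDER[int(np.argmax([0.7, -1.2, 0.1]))] == "Positive"
    assert CLASS_ORDER[int(np.argmax([0.5, 0.5, 0.5]))] == "Positive"
    assert CLASS_ORDER[int(np.argmax([-1.0, 0.5, 0.5]))] == "Negative"
    doc = docs[0]
    cand = enumerate_candidates(doc)[0]
    l1, s1 = model.predict(doc, cand)
    l2, s2 = model.predict(doc, cand)
    assert l1 == l2
    np.testing.assert_array_equal(s1, s2)


# -- gradients --------------------------------------------------------------

def _numeric_grad(model, name, fs, Y, eps=1e-6):
    """Central finite differences of the batch hinge loss."""
    param = model.params[name]
    grad = np.zeros_like(param)
    it = np.nditer(param, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = param[idx]
        for sign in (+1, -1):
            param[idx] = orig + sign * eps
            out = model._forward_batch(fs.X, fs.C, fs.valid, fs.word_ids)
            loss = np.sum(np.maximum(1 - Y * out, 0)) / (3 * len(fs.labels))
            grad[idx] += sign * loss / (2 * eps)
        param[idx] = orig
        it.iternext()
    return grad


@pytest.mark.parametrize("point", range(4))
def test_analytic_gradient_matches_finite_differences(point):
    """Backprop through conv/pool/dense/hinge vs central differences."""
    docs, _ = generate(GeneratorConfig(n_docs=2, seed=41 + point))
    vocab = fit_vocabulary(docs, min_count=1)
    emb = EmbeddingTable(dim=5, oov_policy="random_fixed", seed=point)
    cfg = LcCnnConfig(windows=(2, 3), n_filters=3, n_sr=4,
                      seed=100 + point, T=12)
    model = LcCnnModel.initialize(cfg, vocab, emb, 12)
    fs = featurize(docs[:1], vocab, emb, 12, cfg.clip)
    # keep the fixture small: 5 candidates max
    k = min(5, len(fs.labels))
    fs = FeatureSet(fs.X[:k], fs.C[:k], fs.valid[:k], fs.word_ids[:k],
                    fs.labels[:k], fs.keys[:k])
    Y = np.stack([encode_label(l) for l in fs.labels])
    _, grads = model.batch_loss_and_grads(fs.X, fs.C, fs.valid,
                                          fs.word_ids, Y)
    for name in ("W_out", "b_out", "W_sr", "b_sr", "conv_W_2", "conv_b_3"):
        num = _numeric_grad(model, name, fs, Y)
        denom = max(np.linalg.norm(num), np.linalg.norm(grads[name]), 1e-8)
        rel = np.linalg.norm(grads[name] - num) / denom
        assert rel < 1e-4, f"{name}: rel error {rel}"


def test_trainable_embedding_gradient():
    docs, _ = generate(GeneratorConfig(n_docs=2, seed=61))
    vocab = fit_vocabulary(docs, min_count=1)
    from ddae.lc_cnn import build_word_index
    widx = build_word_index(docs)
    emb = EmbeddingTable(dim=4, oov_policy="zeros")
    cfg = LcCnnConfig(windows=(2,), n_filters=3, n_sr=4, seed=3, T=12,
                      trainable_embeddings=True, embedding_dim=4)
    model = LcCnnModel.initialize(cfg, vocab, emb, 12, word_index=widx)
    fs = featurize(docs[:1], vocab, emb, 12, cfg.clip, word_index=widx)
    k = min(4, len(fs.labels))
    fs = FeatureSet(fs.X[:k], fs.C[:k], fs.valid[:k], fs.word_ids[:k],
                    fs.labels[:k], fs.keys[:k])
    Y = np.stack([encode_label(l) for l in fs.labels])
    _, grads = model.batch_loss_and_grads(fs.X, fs.C, fs.valid,
                                          fs.word_ids, Y)
    num = _numeric_grad(model, "E", fs, Y)
    denom = max(np.linalg.norm(num), np.linalg.norm(grads["E"]), 1e-8)
    assert np.linalg.norm(grads["E"] - num) / denom < 1e-4


# -- training ---------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_small():
    docs, _ = generate(GeneratorConfig(n_docs=40, seed=71,
                                       context_dependence=0.0))
    cfg = LcCnnConfig(epochs=8, n_filters=16, n_sr=16, embedding_dim=16,
                      seed=7)
    return docs, cfg, train(docs, cfg)


def test_training_loss_decreases(trained_small):
    docs, cfg, model = trained_small
    losses = model.loss_history
    assert len(losses) == cfg.epochs
    increases = sum(b > a for a, b in zip(losses, losses[1:]))
    assert increases <= 1
    assert losses[-1] < losses[0]


def test_training_deterministic(trained_small):
    docs, cfg, model = trained_small
    again = train(docs, cfg)
    for name, value in model.params.items():
        np.testing.assert_array_equal(value, again.params[name])


def test_empty_training_set_rejected():
    from ddae.corpus import Document, segment_and_tag
    doc = segment_and_tag(Document("e", "No diseases here", "None at all."))
    with pytest.raises(ValueError):
        train([doc], LcCnnConfig(epochs=1))


def test_save_load_round_trip(tmp_path, trained_small):
    docs, cfg, model = trained_small
    model.save(tmp_path / "model")
    back = LcCnnModel.load(tmp_path / "model")
    for name, value in model.params.items():
        np.testing.assert_array_equal(value, back.params[name])
    preds_a = model.predict_documents(docs[:5])
    preds_b = back.predict_documents(docs[:5])
    assert preds_a == preds_b
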