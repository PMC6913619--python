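"""Large-margin context-aware CNN (LC-CNN) for DDA classification.

Architecture: per-candidate sentence matrix -> multi-window 1-D convolution
(+ bias, ReLU) -> max-pool over valid token positions -> dense ReLU layer
(sentence vector ``sr``) -> concatenation with the hand-crafted context
vector ``cr`` -> linear 3-way output layer.  Scores are unbounded reals;
training minimizes the categorical hinge loss

    loss(out, y) = sum_i max(1 - y_i * out_i, 0) / n_out

with labels encoded as sign vectors (exactly one +1), by mini-batch SGD.
The forward/backward pass is written directly in numpy; gradients are
validated against central finite differences in the test suite.

Max-pooling is restricted to convolution windows lying inside the unpadded
token range (with a minimum of one position), so appending padding columns
never changes the output even when a convolution bias is positive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .context_features import (DEFAULT_COUNT_SCALE, FeatureVocabulary,
                               build_context_vector, fit_vocabulary)
from .corpus import Document, enumerate_candidates
from .embeddings import EmbeddingTable
from .sentence_features import (N_DISTANCE, N_POS_GROUPS, SentenceMatrix,
                                build_sentence_matrix, max_sentence_length)

logger = logging.getLogger(__name__)

#: Fixed class order; argmax ties resolve to the earliest class.
CLASS_ORDER = ("Positive", "Negative", "Null")
N_OUT = 3

_NEG_INF = -1e30


# ---------------------------------------------------------------------------
# Labels and loss
# ---------------------------------------------------------------------------

def encode_label(label: str) -> np.ndarray:
    """Relation label -> sign vector: one +1 component, the rest -1."""
    if label not in CLASS_ORDER:
        raise ValueError(f"unknown relation label {label!r}")
    y = -np.ones(N_OUT)
    y[CLASS_ORDER.index(label)] = 1.0
    return y


def decode_label(y: np.ndarray) -> str:
    y = np.asarray(y)
    if y.shape != (N_OUT,) or not np.isclose(y.sum(), 2 - N_OUT):
        raise ValueError(f"not a valid label vector: {y!r}")
    return CLASS_ORDER[int(np.argmax(y))]


def hinge_loss(out: np.ndarray, y: np.ndarray) -> float:
    """Categorical hinge loss, averaged over the three classes."""
    out = np.asarray(out, dtype=float)
    y = np.asarray(y, dtype=float)
    if out.shape != (N_OUT,) or y.shape != (N_OUT,):
        raise ValueError("out and y must both have 3 components")
    return float(np.sum(np.maximum(1.0 - y * out, 0.0)) / N_OUT)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class LcCnnConfig:
    """Hyperparameters; every architecture choice lives here."""

    windows: tuple[int, ...] = (3, 4, 5)
    n_filters: int = 100
    n_sr: int = 64
    T: int | None = None          # None: longest training sentence
    clip: int = 30
    learning_rate: float = 0.05
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0
    momentum: float = 0.0
    min_count: int = 2
    count_scale: float = DEFAULT_COUNT_SCALE
    use_context: bool = True      # False: the CNN-only baseline
    trainable_embeddings: bool = False  # the no-pretrain mode
    embedding_dim: int = 50       # used only when trainable_embeddings

    def to_dict(self) -> dict:
        d = asdict(self)
        d["windows"] = list(self.windows)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LcCnnConfig":
        d = dict(d)
        d["windows"] = tuple(d["windows"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Featurized dataset
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Stacked model inputs for a list of candidates."""

    X: np.ndarray           # (N, n_emb, T) sentence matrices
    C: np.ndarray           # (N, n_cr) context vectors
    valid: np.ndarray       # (N,) valid lengths
    word_ids: np.ndarray    # (N, T) token-vocabulary ids (-1 = pad/OOV)
    labels: list[str]
    keys: list[tuple]


def featurize(docs: list[Document], vocab: FeatureVocabulary,
              emb: EmbeddingTable, T: int, clip: int,
              count_scale: float = DEFAULT_COUNT_SCALE,
              word_index: dict[str, int] | None = None) -> FeatureSet:
    xs, cs, valids, wids, labels, keys = [], [], [], [], [], []
    for doc in docs:
        for cand in enumerate_candidates(doc):
            sent = doc.sentences[cand.sentence_index]
            sm = build_sentence_matrix(sent, cand, emb, T=T, clip=clip,
                                       doc=doc, word_index=word_index)
            xs.append(sm.values)
            wids.append(sm.word_ids)
            valids.append(sm.valid_length)
            cs.append(build_context_vector(doc, cand, vocab,
                                           count_scale=count_scale))
            labels.append(cand.label)
            keys.append(cand.key(doc))
    if not xs:
        raise ValueError("no candidate pairs in the given documents")
    return FeatureSet(np.stack(xs), np.stack(cs),
                      np.asarray(valids), np.stack(wids), labels, keys)


def build_word_index(docs: list[Document]) -> dict[str, int]:
    words = sorted({t.surface.lower()
                    for d in docs for s in d.sentences for t in s.tokens})
    return {w: i for i, w in enumerate(words)}


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class LcCnnModel:
    """All learned parameters plus the frozen feature configuration.

    Construct untrained via :meth:`initialize`, or train end-to-end with
    :func:`train`.  ``params`` maps names to numpy arrays:
    ``conv_W_<f>`` (K, n_emb*f), ``conv_b_<f>`` (K,), ``W_sr``, ``b_sr``,
    ``W_out``, ``b_out`` and, in the no-pretrain mode, the embedding matrix
    ``E`` (V, dim).
    """

    def __init__(self, config: LcCnnConfig, vocab: FeatureVocabulary,
                 embedding: EmbeddingTable, T: int,
                 params: dict[str, np.ndarray],
                 word_index: dict[str, int] | None = None):
        self.config = config
        self.vocab = vocab
        self.embedding = embedding
        self.T = T
        self.params = params
        self.word_index = word_index
        self.loss_history: list[float] = []

    # -- shapes -------------------------------------------------------------
    @property
    def dim(self) -> int:
        return (self.config.embedding_dim if self.config.trainable_embeddings
                else self.embedding.dim)

    @property
    def n_emb(self) -> int:
        return self.dim + N_POS_GROUPS + N_DISTANCE

    @property
    def n_pool(self) -> int:
        return self.config.n_filters * len(self.config.windows)

    @property
    def n_cr(self) -> int:
        return self.vocab.n_cr if self.config.use_context else 0

    @property
    def n_concat(self) -> int:
        return self.config.n_sr + self.n_cr

    @classmethod
    def initialize(cls, config: LcCnnConfig, vocab: FeatureVocabulary,
                   embedding: EmbeddingTable, T: int,
                   word_index: dict[str, int] | None = None) -> "LcCnnModel":
        rng = np.random.default_rng(config.seed)
        model = cls(config, vocab, embedding, T, params={},
                    word_index=word_index)
        n_emb, K = model.n_emb, config.n_filters
        p: dict[str, np.ndarray] = {}
        for f in config.windows:
            D = n_emb * f
            p[f"conv_W_{f}"] = rng.normal(0.0, np.sqrt(2.0 / D), (K, D))
            p[f"conv_b_{f}"] = np.zeros(K)
        p["W_sr"] = rng.normal(0.0, np.sqrt(2.0 / model.n_pool),
                               (config.n_sr, model.n_pool))
        p["b_sr"] = np.zeros(config.n_sr)
        p["W_out"] = rng.normal(0.0, np.sqrt(1.0 / model.n_concat),
                                (N_OUT, model.n_concat))
        p["b_out"] = np.zeros(N_OUT)
        if config.trainable_embeddings:
            if word_index is None:
                raise ValueError("trainable embeddings need a word index")
            p["E"] = rng.uniform(-0.05, 0.05,
                                 (len(word_index), config.embedding_dim))
        model.params = p
        return model

    # -- forward / backward -------------------------------------------------
    def _compose_X(self, X: np.ndarray, word_ids: np.ndarray) -> np.ndarray:
        """Fill the word-embedding rows from the trainable table if present."""
        if not self.config.trainable_embeddings:
            return X
        E = self.params["E"]
        Epad = np.vstack([E, np.zeros((1, E.shape[1]))])
        ids = np.where(word_ids < 0, E.shape[0], word_ids)
        X = X.copy()
        X[:, :self.dim, :] = Epad[ids].transpose(0, 2, 1)
        return X

    def _forward_batch(self, X: np.ndarray, C: np.ndarray | None,
                       valid: np.ndarray, word_ids: np.ndarray,
                       want_cache: bool = False):
        cfg = self.config
        X = self._compose_X(X, word_ids)
        B = X.shape[0]
        pooled_banks, cache_banks = [], []
        for f in cfg.windows:
            # (B, n_emb, P, f) -> (B, P, n_emb*f)
            win = np.lib.stride_tricks.sliding_window_view(X, f, axis=2)
            P = win.shape[2]
            cols = win.transpose(0, 2, 1, 3).reshape(B, P, -1)
            z = np.einsum("bpd,kd->bkp", cols, self.params[f"conv_W_{f}"])
            z += self.params[f"conv_b_{f}"][None, :, None]
            z = np.maximum(z, 0.0)
            n_valid = np.maximum(valid - f + 1, 1)
            mask = np.arange(P)[None, :] < n_valid[:, None]     # (B, P)
            zm = np.where(mask[:, None, :], z, _NEG_INF)
            arg = np.argmax(zm, axis=2)                         # (B, K)
            pooled = np.take_along_axis(zm, arg[:, :, None], 2)[:, :, 0]
            pooled_banks.append(pooled)
            if want_cache:
                cache_banks.append((f, cols, z, arg))
        pool = np.concatenate(pooled_banks, axis=1)             # (B, n_pool)
        a_sr = pool @ self.params["W_sr"].T + self.params["b_sr"]
        sr = np.maximum(a_sr, 0.0)
        m_concat = np.concatenate([sr, C], axis=1) if cfg.use_context else sr
        out = m_concat @ self.params["W_out"].T + self.params["b_out"]
        if not want_cache:
            return out
        return out, {"X": X, "banks": cache_banks, "pool": pool,
                     "a_sr": a_sr, "sr": sr, "m_concat": m_concat,
                     "word_ids": word_ids}

    def _backward_batch(self, dout: np.ndarray, cache: dict
                        ) -> dict[str, np.ndarray]:
        """Gradients of the batch loss given d loss / d out (B, 3)."""
        cfg = self.config
        p = self.params
        grads: dict[str, np.ndarray] = {}
        m_concat, sr, a_sr, pool = (cache["m_concat"], cache["sr"],
                                    cache["a_sr"], cache["pool"])
        grads["W_out"] = dout.T @ m_concat
        grads["b_out"] = dout.sum(axis=0)
        dm = dout @ p["W_out"]
        dsr = dm[:, :cfg.n_sr]
        da_sr = dsr * (a_sr > 0)
        grads["W_sr"] = da_sr.T @ pool
        grads["b_sr"] = da_sr.sum(axis=0)
        dpool = da_sr @ p["W_sr"]                               # (B, n_pool)

        need_dX = cfg.trainable_embeddings
        if need_dX:
            dX = np.zeros_like(cache["X"])
        offset = 0
        B = dout.shape[0]
        rows = np.arange(B)[:, None]
        for f, cols, z, arg in cache["banks"]:
            K = cfg.n_filters
            dp = dpool[:, offset:offset + K]                    # (B, K)
            offset += K
            # ReLU gate at the pooled position
            z_at = np.take_along_axis(z, arg[:, :, None], 2)[:, :, 0]
            dz = dp * (z_at > 0)                                # (B, K)
            cols_at = cols[rows, arg]                           # (B, K, D)
            grads[f"conv_W_{f}"] = np.einsum("bk,bkd->kd", dz, cols_at)
            grads[f"conv_b_{f}"] = dz.sum(axis=0)
            if need_dX:
                dcols = np.zeros_like(cols)
                np.add.at(dcols, (rows, arg),
                          dz[:, :, None] * p[f"conv_W_{f}"][None])
                # fold columns back onto X (col2im)
                P = cols.shape[1]
                dwin = dcols.reshape(B, P, -1, f).transpose(0, 2, 1, 3)
                for j in range(f):
                    dX[:, :, j:j + P] += dwin[:, :, :, j]
        if need_dX:
            dim = self.dim
            dE = np.zeros_like(p["E"])
            ids = cache["word_ids"]
            sel = ids >= 0
            np.add.at(dE, ids[sel],
                      dX[:, :dim, :].transpose(0, 2, 1)[sel])
            grads["E"] = dE
        return grads

    def batch_loss_and_grads(self, X, C, valid, word_ids, Y):
        """Mean hinge loss over a batch and its parameter gradients."""
        out, cache = self._forward_batch(X, C, valid, word_ids,
                                         want_cache=True)
        B = out.shape[0]
        margins = 1.0 - Y * out
        loss = float(np.sum(np.maximum(margins, 0.0)) / (N_OUT * B))
        dout = -(Y * (margins > 0)) / (N_OUT * B)
        grads = self._backward_batch(dout, cache)
        return loss, grads

    # -- public inference ---------------------------------------------------
    def forward(self, sm: SentenceMatrix, cr: np.ndarray | None) -> np.ndarray:
        """Scores (3 reals) for one candidate's features."""
        C = None if not self.config.use_context else cr[None, :]
        return self._forward_batch(sm.values[None], C,
                                   np.asarray([sm.valid_length]),
                                   sm.word_ids[None])[0]

    def predict(self, doc: Document, pair) -> tuple[str, np.ndarray]:
        """(label, scores) for one candidate pair; argmax with fixed tie order."""
        sent = doc.sentences[pair.sentence_index]
        sm = build_sentence_matrix(sent, pair, self.embedding, T=self.T,
                                   clip=self.config.clip, doc=doc,
                                   word_index=self.word_index)
        cr = (build_context_vector(doc, pair, self.vocab,
                                   count_scale=self.config.count_scale)
              if self.config.use_context else None)
        scores = self.forward(sm, cr)
        return CLASS_ORDER[int(np.argmax(scores))], scores

    def predict_documents(self, docs: list[Document]) -> dict[tuple, str]:
        """Predicted label per candidate key over whole documents."""
        fs = featurize(docs, self.vocab, self.embedding, self.T,
                       self.config.clip, self.config.count_scale,
                       self.word_index)
        out = self._forward_batch(fs.X, fs.C if self.config.use_context
                                  else None, fs.valid, fs.word_ids)
        labels = [CLASS_ORDER[i] for i in np.argmax(out, axis=1)]
        return dict(zip(fs.keys, labels))

    def score_documents(self, docs: list[Document]) -> dict[tuple, np.ndarray]:
        fs = featurize(docs, self.vocab, self.embedding, self.T,
                       self.config.clip, self.config.count_scale,
                       self.word_index)
        out = self._forward_batch(fs.X, fs.C if self.config.use_context
                                  else None, fs.valid, fs.word_ids)
        return dict(zip(fs.keys, out))

    # -- serialization ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.params)
        self.vocab.save(directory / "vocabulary.json")
        manifest = {
            "config": self.config.to_dict(),
            "T": self.T,
            "n_emb": self.n_emb,
            "segment_sizes": self.vocab.segment_sizes(),
            "class_order": list(CLASS_ORDER),
            "embedding": {
                "dim": self.embedding.dim,
                "oov_policy": self.embedding.oov_policy,
                "seed": self.embedding.seed,
            },
            "word_index": self.word_index,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest),
                                                 encoding="utf-8")
        from .embeddings import write_embeddings_text
        write_embeddings_text(self.embedding, directory / "embeddings.vec")

    @classmethod
    def load(cls, directory: str | Path) -> "LcCnnModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json")
                              .read_text(encoding="utf-8"))
        config = LcCnnConfig.from_dict(manifest["config"])
        vocab = FeatureVocabulary.load(directory / "vocabulary.json")
        from .embeddings import load_embeddings
        emb_meta = manifest["embedding"]
        try:
            emb = load_embeddings(directory / "embeddings.vec",
                                  oov_policy=emb_meta["oov_policy"],
                                  seed=emb_meta["seed"])
        except StopIteration:  # empty vocabulary table
            emb = EmbeddingTable(dim=emb_meta["dim"], vectors={},
                                 oov_policy=emb_meta["oov_policy"],
                                 seed=emb_meta["seed"])
        with np.load(directory / "params.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(config, vocab, emb, manifest["T"], params,
                   word_index=manifest["word_index"])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _sgd_epoch(model: LcCnnModel, fs: FeatureSet, Y: np.ndarray,
               rng: np.random.Generator, shuffle: bool = True) -> float:
    cfg = model.config
    N = len(fs.labels)
    order = rng.permutation(N) if shuffle else np.arange(N)
    vel = getattr(model, "_velocity", None)
    total = 0.0
    for start in range(0, N, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        loss, grads = model.batch_loss_and_grads(
            fs.X[idx], fs.C[idx] if cfg.use_context else None,
            fs.valid[idx], fs.word_ids[idx], Y[idx])
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training aborted: non-finite loss {loss} at batch "
                f"starting {start} (lr={cfg.learning_rate})")
        total += loss * len(idx)
        for name, g in grads.items():
            if cfg.momentum > 0:
                if vel is None:
                    vel = model._velocity = {
                        k: np.zeros_like(v) for k, v in model.params.items()}
                vel[name] = cfg.momentum * vel[name] - cfg.learning_rate * g
                model.params[name] += vel[name]
            else:
                model.params[name] -= cfg.learning_rate * g
    return total / N


def train(train_corpus: list[Document], config: LcCnnConfig,
          embedding: EmbeddingTable | None = None,
          vocab: FeatureVocabulary | None = None,
          tuning_corpus: list[Document] | None = None) -> LcCnnModel:
    """Fit an LC-CNN on a training corpus by mini-batch SGD.

    The feature vocabulary and the sentence length T are fitted on
    ``train_corpus`` only.  When ``tuning_corpus`` is given, the epoch count
    is chosen by micro-F1 on it and the final model is retrained on the
    union (early stopping); otherwise the configured epoch budget is used.
    All randomness (init, shuffling, OOV vectors) flows from ``config.seed``.
    """
    if embedding is None:
        embedding = EmbeddingTable(dim=config.embedding_dim, vectors={},
                                   oov_policy="random_fixed",
                                   seed=config.seed)
    if vocab is None:
        vocab = fit_vocabulary(train_corpus, min_count=config.min_count)
    T = config.T or max_sentence_length(train_corpus)
    if T < 2:
        raise ValueError("training corpus has no usable sentences")
    word_index = (build_word_index(train_corpus)
                  if config.trainable_embeddings else None)

    if tuning_corpus:
        probe = _fit_epochs(train_corpus, config, embedding, vocab, T,
                            word_index, config.epochs,
                            tuning_corpus=tuning_corpus)
        best = int(np.argmax(probe.tuning_f1)) + 1
        logger.info("early stopping chose %d epochs (tuning F1 %.3f)",
                    best, probe.tuning_f1[best - 1])
        cfg = LcCnnConfig.from_dict({**config.to_dict(), "epochs": best})
        return _fit_epochs(train_corpus + tuning_corpus, cfg, embedding,
                           vocab, T, word_index, best)
    return _fit_epochs(train_corpus, config, embedding, vocab, T,
                       word_index, config.epochs)


def _fit_epochs(docs, config, embedding, vocab, T, word_index, epochs,
                tuning_corpus=None) -> LcCnnModel:
    from .evaluation import score as _score

    model = LcCnnModel.initialize(config, vocab, embedding, T,
                                  word_index=word_index)
    fs = featurize(docs, vocab, embedding, T, config.clip,
                   config.count_scale, word_index)
    Y = np.stack([encode_label(l) for l in fs.labels])
    rng = np.random.default_rng(config.seed + 1)
    model.tuning_f1 = []
    gold = None
    if tuning_corpus:
        gold = {cand.key(d): cand.label for d in tuning_corpus
                for cand in enumerate_candidates(d)}
    for epoch in range(epochs):
        mean_loss = _sgd_epoch(model, fs, Y, rng)
        model.loss_history.append(mean_loss)
        logger.info("epoch %d: mean hinge loss %.4f", epoch + 1, mean_loss)
        if gold is not None:
            preds = model.predict_documents(tuning_corpus)
            p, r, f1, _ = _score(preds, gold)
            model.tuning_f1.append(f1)
    return model
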