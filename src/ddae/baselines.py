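"""Comparison systems sharing the LC-CNN's feature extractors.

* ``cnn_only`` — the convolutional branch with a linear 3-way output and
  hinge loss, no context vector (sentence representation only);
* ``cr_cross_entropy`` — one hidden ReLU layer on the context vector with a
  softmax/cross-entropy output;
* ``svm_cr`` — a soft-margin linear SVM (one-vs-one multiclass) on the
  context vector;
* ``svm_plus_cnn`` — two-stage: train ``cnn_only`` first, then an SVM on
  [context vector ; the CNN's 3 output scores].

The SVM and the cross-entropy network are standard estimators and are backed
by scikit-learn; the convolutional branch reuses the numpy LC-CNN with
``use_context=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .context_features import FeatureVocabulary, build_context_vector, fit_vocabulary
from .corpus import Document, enumerate_candidates
from .embeddings import EmbeddingTable
from .lc_cnn import CLASS_ORDER, LcCnnConfig, LcCnnModel, featurize
from .lc_cnn import train as train_lc_cnn

logger = logging.getLogger(__name__)

BASELINE_KINDS = ("cnn_only", "cr_cross_entropy", "svm_cr", "svm_plus_cnn")


@dataclass
class BaselineConfig:
    svm_c: float = 1.0
    hidden_size: int = 128
    mlp_epochs: int = 200
    seed: int = 0
    min_count: int = 2
    cnn: LcCnnConfig | None = None  # config of the convolutional stage


class BaselineModel:
    """A trained baseline of one of the four kinds; predict per candidate."""

    def __init__(self, kind: str, vocab: FeatureVocabulary,
                 config: BaselineConfig):
        if kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {kind!r}")
        self.kind = kind
        self.vocab = vocab
        self.config = config
        self.estimator = None        # sklearn estimator, if any
        self.cnn: LcCnnModel | None = None
        self.stage2_doc_ids: list[str] = []

    # -- feature assembly ---------------------------------------------------
    def _context_matrix(self, docs: list[Document]) -> tuple[np.ndarray, list]:
        rows, labels, keys = [], [], []
        for doc in docs:
            for cand in enumerate_candidates(doc):
                rows.append(build_context_vector(doc, cand, self.vocab))
                labels.append(cand.label)
                keys.append(cand.key(doc))
        return np.stack(rows), labels, keys

    def _cnn_scores(self, docs: list[Document]) -> dict:
        return self.cnn.score_documents(docs)

    # -- prediction ---------------------------------------------------------
    def predict(self, doc: Document, pair) -> tuple[str, np.ndarray]:
        """(label, scores) for one candidate; same tie-break as LC-CNN."""
        preds = self.predict_documents_scored([doc])
        return preds[pair.key(doc)]

    def predict_documents(self, docs: list[Document]) -> dict:
        return {k: v[0] for k, v in
                self.predict_documents_scored(docs).items()}

    def predict_documents_scored(self, docs: list[Document]) -> dict:
        if self.kind == "cnn_only":
            scored = self.cnn.score_documents(docs)
            return {k: (CLASS_ORDER[int(np.argmax(s))], s)
                    for k, s in scored.items()}
        C, _, keys = self._context_matrix(docs)
        if self.kind == "svm_plus_cnn":
            cnn_scores = self._cnn_scores(docs)
            C = np.hstack([C, np.stack([cnn_scores[k] for k in keys])])
        if self.kind == "cr_cross_entropy":
            proba = self.estimator.predict_proba(C)
            # column order follows estimator.classes_; re-map to CLASS_ORDER
            cols = [list(self.estimator.classes_).index(c)
                    for c in CLASS_ORDER if c in self.estimator.classes_]
            scores = proba[:, cols]
            present = [c for c in CLASS_ORDER if c in self.estimator.classes_]
            return {k: (present[int(np.argmax(s))], s)
                    for k, s in zip(keys, scores)}
        # SVM kinds: decision function is ragged across class counts; use
        # predict() for the label and the one-vs-one votes as scores.
        labels = self.estimator.predict(C)
        dec = np.atleast_2d(self.estimator.decision_function(C))
        return {k: (lab, d) for k, lab, d in zip(keys, labels, dec)}


def train_baseline(kind: str, train_corpus: list[Document],
                   config: BaselineConfig | None = None,
                   embedding: EmbeddingTable | None = None,
                   vocab: FeatureVocabulary | None = None,
                   tuning_corpus: list[Document] | None = None
                   ) -> BaselineModel:
    """Fit one of the four comparison systems.

    The two-stage ``svm_plus_cnn`` honours the tuning/training separation:
    the tuning corpus is used only for the CNN stage's early stopping; the
    stage-2 SVM sees gold labels of the training fold alone.
    """
    config = config or BaselineConfig()
    if vocab is None:
        vocab = fit_vocabulary(train_corpus, min_count=config.min_count)
    model = BaselineModel(kind, vocab, config)
    rng_seed = config.seed

    if kind in ("cnn_only", "svm_plus_cnn"):
        cnn_cfg = config.cnn or LcCnnConfig(seed=rng_seed)
        cnn_cfg = LcCnnConfig.from_dict({**cnn_cfg.to_dict(),
                                         "use_context": False})
        model.cnn = train_lc_cnn(train_corpus, cnn_cfg, embedding=embedding,
                                 vocab=vocab, tuning_corpus=tuning_corpus)
    if kind == "cnn_only":
        return model

    C, labels, _ = model._context_matrix(train_corpus)
    if kind == "svm_plus_cnn":
        scores = model._cnn_scores(train_corpus)
        _, _, keys = model._context_matrix(train_corpus)
        C = np.hstack([C, np.stack([scores[k] for k in keys])])
        model.stage2_doc_ids = [d.doc_id for d in train_corpus]
    if kind in ("svm_cr", "svm_plus_cnn"):
        model.estimator = SVC(kernel="linear", C=config.svm_c,
                              decision_function_shape="ovo",
                              random_state=rng_seed)
        model.estimator.fit(C, labels)
    elif kind == "cr_cross_entropy":
        model.estimator = MLPClassifier(
            hidden_layer_sizes=(config.hidden_size,), activation="relu",
            solver="adam", max_iter=config.mlp_epochs,
            random_state=rng_seed)
        model.estimator.fit(C, labels)
    return model
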