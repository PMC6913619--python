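"""Context representation: BOW, NE info, document-level indicators, layout."""

import numpy as np
import pytest

from ddae.context_features import (N_CORE_PAIR, N_LOCATION, N_NE_INFO,
                                   FeatureVocabulary, VocabularyError,
                                   build_context_vector, core_pair_ranks,
                                   extract_bow, extract_doc_features,
                                   extract_ne_info, fit_vocabulary)
from ddae.corpus import (CandidatePair, Document, Mention,
                         enumerate_candidates, segment_and_tag)
from ddae.sentence_features import N_POS_GROUPS
from ddae.synthetic import GeneratorConfig, generate


def _mini_doc():
    d = Document("m", "A causes B", "", year=2015)
    return segment_and_tag(d)


def test_fit_vocabulary_counts_min_count_one():
    vocab = fit_vocabulary([_mini_doc()], min_count=1)
    assert len(vocab.unigrams) == 3  # a, causes, b
    assert len(vocab.bigrams) == 2  # (a, causes), (causes, b)


def test_min_count_above_frequencies_leaves_indicator_segments():
    vocab = fit_vocabulary([_mini_doc()], min_count=99)
    assert len(vocab.unigrams) == 0 and len(vocab.bigrams) == 0
    assert vocab.n_cr == N_POS_GROUPS + N_NE_INFO + N_CORE_PAIR + N_LOCATION


def test_fit_twice_identical(small_corpus):
    docs, _ = small_corpus
    v1, v2 = fit_vocabulary(docs[:10]), fit_vocabulary(docs[:10])
    assert v1.unigrams == v2.unigrams and v1.bigrams == v2.bigrams
    assert v1.disease_surfaces == v2.disease_surfaces


def test_empty_corpus_rejected():
    with pytest.raises(VocabularyError):
        fit_vocabulary([])


def test_vocab_json_round_trip(small_corpus):
    docs, _ = small_corpus
    vocab = fit_vocabulary(docs[:10])
    back = FeatureVocabulary.from_json(vocab.to_json())
    assert back.unigrams == vocab.unigrams
    assert back.bigrams == vocab.bigrams
    assert back.disease_surfaces == vocab.disease_surfaces
    assert back.n_cr == vocab.n_cr


# -- BOW --------------------------------------------------------------------

def test_bow_all_oov_is_zero(three_disease_doc):
    vocab = fit_vocabulary([_mini_doc()], min_count=1)
    sent = three_disease_doc.sentences[1]
    pair = CandidatePair(1, "T3", "T4")
    bow = extract_bow(pair, sent, vocab, three_disease_doc)
    assert bow.sum() == 0


def test_bow_binary_not_count():
    d = Document("r", "pain causes pain", "", year=2015)
    segment_and_tag(d)
    vocab = fit_vocabulary([d], min_count=1)
    # token 'pain' occurs twice: indicator must still be 1
    m1 = Mention("T1", 0, 4, "pain", "D1")  # fake mentions for pair
    m2 = Mention("T2", 12, 16, "pain", "D2")
    d.mentions = [m1, m2]
    d = segment_and_tag(d)
    pair = CandidatePair(0, "T1", "T2")
    bow = extract_bow(pair, d.sentences[0], vocab, d)
    assert set(np.unique(bow)) <= {0.0, 1.0}
    assert bow[vocab.unigrams["pain"]] == 1.0


def test_surrounding_disease_marks_third_mention(three_disease_doc):
    doc = three_disease_doc
    vocab = fit_vocabulary([doc], min_count=1)
    sent = doc.sentences[1]
    pair = CandidatePair(1, "T3", "T4")  # asthma, eczema; rhinitis surrounds
    bow = extract_bow(pair, sent, vocab, doc)
    off = len(vocab.unigrams) + len(vocab.bigrams)
    assert bow[off + vocab.disease_surfaces["rhinitis"]] == 1.0
    # the pair itself is not its own surrounding disease
    pair2 = CandidatePair(1, "T3", "T5")
    bow2 = extract_bow(pair2, sent, vocab, doc)
    assert bow2[off + vocab.disease_surfaces["rhinitis"]] == 0.0


# -- NE info ----------------------------------------------------------------

def test_ne_info_counts(three_disease_doc):
    doc = three_disease_doc
    sent = doc.sentences[1]
    # "Asthma and eczema aggravate rhinitis": pair (Asthma, rhinitis)
    tokens_between, between, total = extract_ne_info(
        CandidatePair(1, "T3", "T5"), sent, doc)
    assert between == 1  # eczema lies between
    assert total == 3
    assert tokens_between == 3  # and eczema aggravate


def test_ne_info_adjacent_mentions():
    d = Document("a", "Gout diabetes pair", "", year=2015)
    d.mentions = [Mention("T1", 0, 4, "Gout", "D1"),
                  Mention("T2", 5, 13, "diabetes", "D2")]
    segment_and_tag(d)
    assert extract_ne_info(CandidatePair(0, "T1", "T2"),
                           d.sentences[0], d) == (0, 0, 2)


def test_diseases_between_bound(small_corpus):
    docs, _ = small_corpus
    for doc in docs[:15]:
        for cand in enumerate_candidates(doc):
            sent = doc.sentences[cand.sentence_index]
            _, between, total = extract_ne_info(cand, sent, doc)
            assert between <= total - 2


# -- document-level features ------------------------------------------------

def test_core_pair_and_location_bits(small_corpus):
    docs, _ = small_corpus
    doc = docs[0]
    cands = enumerate_candidates(doc)
    ranks = core_pair_ranks(doc)
    for cand in cands:
        feats = extract_doc_features(doc, cand)
        assert feats.shape == (6,)
        assert feats[:3].sum() <= 1  # at most one core-pair rank bit
        if cand.sentence_index == 0:
            assert feats[3] == 1.0  # in-title
    assert len(ranks) <= 3


def test_most_frequent_pair_gets_rank_one():
    body = ("Gout worsens diabetes. Gout aggravates diabetes. "
            "Gout and diabetes again. Asthma and eczema once.")
    off = 2
    mentions = []
    i = 1
    import re
    for m in re.finditer(r"Gout|diabetes|Asthma|eczema", body):
        mesh = {"Gout": "D1", "diabetes": "D2",
                "Asthma": "D3", "eczema": "D4"}[m.group()]
        mentions.append(Mention(f"T{i}", off + m.start(), off + m.end(),
                                m.group(), mesh))
        i += 1
    d = segment_and_tag(Document("f", "T", body, year=2015,
                                 mentions=mentions))
    gd_pair = next(c for c in enumerate_candidates(d)
                   if c.sentence_index == 1)
    feats = extract_doc_features(d, gd_pair)
    assert feats[0] == 1.0  # gout-diabetes is the most frequent pair
    ae_pair = next(c for c in enumerate_candidates(d)
                   if c.sentence_index == 4)
    assert extract_doc_features(d, ae_pair)[0] == 0.0
    assert extract_doc_features(d, ae_pair)[1] == 1.0  # second most frequent


def test_single_pair_document_rank_one_only(gout_doc):
    cand = enumerate_candidates(gout_doc)[0]
    feats = extract_doc_features(gout_doc, cand)
    assert feats[0] == 1.0 and feats[1] == 0.0 and feats[2] == 0.0


# -- full vector ------------------------------------------------------------

def test_context_vector_layout_and_determinism(small_corpus):
    docs, _ = small_corpus
    vocab = fit_vocabulary(docs[:20])
    doc = docs[0]
    cand = enumerate_candidates(doc)[0]
    v1 = build_context_vector(doc, cand, vocab)
    v2 = build_context_vector(doc, cand, vocab)
    np.testing.assert_array_equal(v1, v2)
    assert v1.shape == (vocab.n_cr,)
    assert vocab.n_cr == sum(vocab.segment_sizes().values())


def test_context_vector_invariant_to_pair_order(small_corpus):
    docs, _ = small_corpus
    vocab = fit_vocabulary(docs[:20])
    doc = docs[1]
    cand = enumerate_candidates(doc)[0]
    swapped = CandidatePair(cand.sentence_index, cand.mention2_id,
                            cand.mention1_id, cand.label)
    np.testing.assert_array_equal(
        build_context_vector(doc, cand, vocab),
        build_context_vector(doc, swapped, vocab))


def test_title_candidate_differs_only_in_location_bits(small_corpus):
    """Same sentence placed as title vs body flips only location bits."""
    docs, _ = small_corpus
    vocab = fit_vocabulary(docs[:20])
    sent = "Gout worsens diabetes."
    filler = "Unrelated text sits here. More unrelated text follows."

    def make(title, body, base):
        ms = []
        text = title + "\n" + body
        for j, word in enumerate(("Gout", "diabetes")):
            start = text.index(word, base)
            ms.append(Mention(f"T{j}", start, start + len(word), word,
                              f"D{j}"))
        return segment_and_tag(Document("x", title, body, year=2015,
                                        mentions=ms))

    as_title = make(sent, filler, 0)
    as_body = make("A neutral heading", filler + " " + sent,
                   len("A neutral heading") + 1 + len(filler))
    c1 = enumerate_candidates(as_title)[0]
    c2 = enumerate_candidates(as_body)[0]
    v1 = build_context_vector(as_title, c1, vocab)
    v2 = build_context_vector(as_body, c2, vocab)
    # identical except in the final location segment
    np.testing.assert_array_equal(v1[:-3], v2[:-3])
    assert not np.array_equal(v1[-3:], v2[-3:])
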