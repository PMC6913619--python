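"""Hand-crafted context representation (CR) vector for a candidate pair.

Fixed segment layout::

    [ BOW-unigram | BOW-bigram | surrounding-disease | POS(11) |
      NE-info(3) | core-pair(3) | location(3) ]

BOW and indicator segments are binary.  The POS segment is the presence
bitmap of the 11 coarse POS groups over the candidate's sentence.  NE-info
holds three counts (tokens between the pair, diseases between, diseases in
the sentence), scaled by a configurable factor to keep magnitudes comparable
with the binary features.  Core-pair marks whether the candidate's MeSH pair
is the document's 1st/2nd/3rd most frequent pair; location marks title /
first abstract sentence / last abstract sentence.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import CandidatePair, Document, Sentence, enumerate_candidates
from .sentence_features import N_POS_GROUPS, map_pos_group

N_NE_INFO = 3
N_CORE_PAIR = 3
N_LOCATION = 3
DEFAULT_COUNT_SCALE = 0.1


class VocabularyError(ValueError):
    pass


@dataclass
class FeatureVocabulary:
    """Frozen indices for the BOW segments; unseen features map to nothing."""

    unigrams: dict[str, int] = field(default_factory=dict)
    bigrams: dict[tuple[str, str], int] = field(default_factory=dict)
    disease_surfaces: dict[str, int] = field(default_factory=dict)
    min_count: int = 2
    frozen: bool = True

    @property
    def n_cr(self) -> int:
        return (len(self.unigrams) + len(self.bigrams)
                + len(self.disease_surfaces)
                + N_POS_GROUPS + N_NE_INFO + N_CORE_PAIR + N_LOCATION)

    def segment_sizes(self) -> dict[str, int]:
        return {
            "unigram": len(self.unigrams),
            "bigram": len(self.bigrams),
            "disease": len(self.disease_surfaces),
            "pos": N_POS_GROUPS,
            "ne_info": N_NE_INFO,
            "core_pair": N_CORE_PAIR,
            "location": N_LOCATION,
        }

    # -- JSON sidecar -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "version": 1,
            "min_count": self.min_count,
            "unigrams": sorted(self.unigrams, key=self.unigrams.get),
            "bigrams": [list(b) for b in
                        sorted(self.bigrams, key=self.bigrams.get)],
            "disease_surfaces": sorted(self.disease_surfaces,
                                       key=self.disease_surfaces.get),
        })

    @classmethod
    def from_json(cls, payload: str) -> "FeatureVocabulary":
        data = json.loads(payload)
        return cls(
            unigrams={w: i for i, w in enumerate(data["unigrams"])},
            bigrams={tuple(b): i for i, b in enumerate(data["bigrams"])},
            disease_surfaces={w: i for i, w in
                              enumerate(data["disease_surfaces"])},
            min_count=data["min_count"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FeatureVocabulary":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def fit_vocabulary(training_corpus: list[Document],
                   min_count: int = 2) -> FeatureVocabulary:
    """Index unigrams/bigrams/disease surfaces of frequency >= min_count.

    Everything is lower-cased; ordering is lexicographic so refits on the
    same corpus are identical.
    """
    if not training_corpus:
        raise VocabularyError("cannot fit a vocabulary on an empty corpus")
    uni: Counter = Counter()
    bi: Counter = Counter()
    dis: Counter = Counter()
    for doc in training_corpus:
        for sent in doc.sentences:
            words = [t.surface.lower() for t in sent.tokens]
            uni.update(words)
            bi.update(zip(words, words[1:]))
        dis.update(m.surface.lower() for m in doc.mentions)
    return FeatureVocabulary(
        unigrams={w: i for i, w in enumerate(
            sorted(w for w, c in uni.items() if c >= min_count))},
        bigrams={b: i for i, b in enumerate(
            sorted(b for b, c in bi.items() if c >= min_count))},
        disease_surfaces={w: i for i, w in enumerate(
            sorted(w for w, c in dis.items() if c >= min_count))},
        min_count=min_count,
    )


def extract_bow(pair: CandidatePair, sentence: Sentence,
                vocab: FeatureVocabulary, doc: Document) -> np.ndarray:
    """Binary unigram/bigram/surrounding-disease indicators for a candidate."""
    n_uni, n_bi = len(vocab.unigrams), len(vocab.bigrams)
    out = np.zeros(n_uni + n_bi + len(vocab.disease_surfaces))
    words = [t.surface.lower() for t in sentence.tokens]
    for w in words:
        i = vocab.unigrams.get(w)
        if i is not None:
            out[i] = 1.0
    for b in zip(words, words[1:]):
        i = vocab.bigrams.get(b)
        if i is not None:
            out[n_uni + i] = 1.0
    pair_ids = {pair.mention1_id, pair.mention2_id}
    for mid in sentence.mention_ids:
        if mid in pair_ids:
            continue
        i = vocab.disease_surfaces.get(doc.mention(mid).surface.lower())
        if i is not None:
            out[n_uni + n_bi + i] = 1.0
    return out


def extract_ne_info(pair: CandidatePair, sentence: Sentence,
                    doc: Document) -> tuple[int, int, int]:
    """(tokens between the pair, diseases strictly between, diseases in sentence)."""
    from .sentence_features import mention_token_range

    r1 = mention_token_range(sentence, doc, pair.mention1_id)
    r2 = mention_token_range(sentence, doc, pair.mention2_id)
    (lo_a, lo_b), (hi_a, hi_b) = sorted((r1, r2))
    gap_lo, gap_hi = lo_b, hi_a  # token range strictly between the two spans
    tokens_between = max(0, gap_hi - gap_lo)
    diseases_between = 0
    for mid in sentence.mention_ids:
        if mid in (pair.mention1_id, pair.mention2_id):
            continue
        m_lo, m_hi = mention_token_range(sentence, doc, mid)
        if m_lo >= gap_lo and m_hi <= gap_hi:
            diseases_between += 1
    return tokens_between, diseases_between, len(sentence.mention_ids)


def _mesh_pair(doc: Document, pair: CandidatePair) -> frozenset:
    return frozenset((doc.mention(pair.mention1_id).mesh_id,
                      doc.mention(pair.mention2_id).mesh_id))


def core_pair_ranks(doc: Document) -> list[frozenset]:
    """The document's up-to-3 most frequent unordered MeSH pairs.

    Frequency is the number of candidate occurrences across all sentences;
    ties break by first occurrence order (stable, deterministic).
    """
    counts: Counter = Counter()
    first_seen: dict[frozenset, int] = {}
    for i, cand in enumerate(enumerate_candidates(doc)):
        mp = _mesh_pair(doc, cand)
        counts[mp] += 1
        first_seen.setdefault(mp, i)
    ranked = sorted(counts, key=lambda mp: (-counts[mp], first_seen[mp]))
    return ranked[:3]


def extract_doc_features(doc: Document, pair: CandidatePair) -> np.ndarray:
    """Six binary document-level indicators.

    [is-most-frequent-pair, is-2nd, is-3rd,
     in-title, in-first-abstract-sentence, in-last-abstract-sentence]
    """
    out = np.zeros(N_CORE_PAIR + N_LOCATION)
    mp = _mesh_pair(doc, pair)
    for rank, ranked_mp in enumerate(core_pair_ranks(doc)):
        if ranked_mp == mp:
            out[rank] = 1.0
            break
    sentence_pairs: dict[int, set] = {}
    for cand in enumerate_candidates(doc):
        sentence_pairs.setdefault(cand.sentence_index, set()).add(
            _mesh_pair(doc, cand))
    last = len(doc.sentences) - 1
    if mp in sentence_pairs.get(0, set()):
        out[3] = 1.0
    if mp in sentence_pairs.get(1, set()):
        out[4] = 1.0
    if last >= 1 and mp in sentence_pairs.get(last, set()):
        out[5] = 1.0
    return out


def build_context_vector(doc: Document, pair: CandidatePair,
                         vocab: FeatureVocabulary,
                         count_scale: float = DEFAULT_COUNT_SCALE
                         ) -> np.ndarray:
    """Concatenate all CR segments in the fixed layout (length ``vocab.n_cr``)."""
    sentence = doc.sentences[pair.sentence_index]
    bow = extract_bow(pair, sentence, vocab, doc)
    pos = np.zeros(N_POS_GROUPS)
    for tok in sentence.tokens:
        pos[map_pos_group(tok.pos)] = 1.0
    ne = np.asarray(extract_ne_info(pair, sentence, doc), dtype=float)
    ne *= count_scale
    docfeat = extract_doc_features(doc, pair)
    return np.concatenate([bow, pos, ne, docfeat])
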