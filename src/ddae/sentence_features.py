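"""Composite embedding sentence matrices for the convolutional branch.

Each token of a candidate's sentence becomes a column of length
``n_emb = dim + 11 + 2``: its word embedding, a one-hot over 11 coarse POS
groups, and two signed word-count distances to the first and second disease
of the candidate pair (clipped and scaled into [-1, 1]).  Columns are padded
with zeros to a fixed sentence length T; when a long sentence would truncate
one of the pair's mentions, the T-token window is shifted so both mention
head tokens stay inside the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .corpus import CandidatePair, Document, Sentence
from .embeddings import EmbeddingTable

logger = logging.getLogger(__name__)

#: The 11 coarse POS groups, in fixed (alphabetical) order.
POS_GROUPS = (
    "adjectives", "adverbs", "articles", "conjunctions", "foreign_words",
    "interjections", "nouns", "prepositions", "pronouns", "punctuation",
    "verbs",
)
N_POS_GROUPS = len(POS_GROUPS)
N_DISTANCE = 2

_GROUP_INDEX = {name: i for i, name in enumerate(POS_GROUPS)}

#: Penn-Treebank tag -> POS group routing table (overridable per call).
DEFAULT_PTB_TO_GROUP: dict[str, str] = {
    **{t: "nouns" for t in ("NN", "NNS", "NNP", "NNPS", "CD", "EX")},
    **{t: "verbs" for t in ("VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD")},
    **{t: "adjectives" for t in ("JJ", "JJR", "JJS")},
    **{t: "adverbs" for t in ("RB", "RBR", "RBS", "WRB")},
    **{t: "articles" for t in ("DT", "PDT", "WDT")},
    "CC": "conjunctions",
    "FW": "foreign_words",
    "UH": "interjections",
    **{t: "prepositions" for t in ("IN", "TO", "RP")},
    **{t: "pronouns" for t in ("PRP", "PRP$", "WP", "WP$")},
    **{t: "punctuation" for t in (".", ",", ":", ";", "''", "``", "-LRB-",
                                  "-RRB-", "HYPH", "SYM", "POS", "$")},
}

_warned_tags: set[str] = set()


def map_pos_group(ptb_tag: str, table: dict[str, str] | None = None) -> int:
    """Route a PTB tag to one of the 11 POS groups (total function).

    Unknown tags fall back to the nouns group with a one-time warning.
    """
    table = DEFAULT_PTB_TO_GROUP if table is None else table
    group = table.get(ptb_tag)
    if group is None:
        if ptb_tag not in _warned_tags:
            _warned_tags.add(ptb_tag)
            logger.warning("unknown PTB tag %r; falling back to nouns", ptb_tag)
        group = "nouns"
    return _GROUP_INDEX[group]


def mention_token_range(sentence: Sentence, doc: Document,
                        mention_id: str) -> tuple[int, int]:
    """Half-open token-index range of the tokens overlapping a mention."""
    m = doc.mention(mention_id)
    idx = [i for i, t in enumerate(sentence.tokens)
           if t.char_start < m.char_end and m.char_start < t.char_end]
    if not idx:
        raise ValueError(f"mention {mention_id} has no tokens in sentence "
                         f"{sentence.index} of {doc.doc_id}")
    return idx[0], idx[-1] + 1


def mention_head_index(sentence: Sentence, doc: Document,
                       mention_id: str) -> int:
    """Head token = last token of the mention span (right-headed NPs)."""
    return mention_token_range(sentence, doc, mention_id)[1] - 1


def ne_distance(token_index: int, pair: CandidatePair, sentence: Sentence,
                doc: Document, clip: int = 30) -> tuple[int, int]:
    """Signed word-count distances from a token to the pair's two diseases.

    ``d_i`` is ``token_index - head_index(mention_i)`` (0 inside mention_i),
    clipped to [-clip, clip].
    """
    if not (0 <= token_index < len(sentence.tokens)):
        raise IndexError(f"token index {token_index} outside sentence")
    out = []
    for mid in (pair.mention1_id, pair.mention2_id):
        lo, hi = mention_token_range(sentence, doc, mid)
        if lo <= token_index < hi:
            out.append(0)
        else:
            d = token_index - (hi - 1)
            out.append(int(np.clip(d, -clip, clip)))
    return out[0], out[1]


@dataclass
class SentenceMatrix:
    """n_emb x T composite-embedding representation of one candidate."""

    values: np.ndarray
    valid_length: int
    word_ids: np.ndarray  # per-column token-vocabulary ids; -1 for padding

    @property
    def n_emb(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


def _window_start(h1: int, h2: int, n_tokens: int, T: int) -> int:
    """Left edge of the T-token window; keeps both mention heads inside."""
    if n_tokens <= T:
        return 0
    lo, hi = min(h1, h2), max(h1, h2)
    if hi < T:
        return 0  # plain right truncation keeps both heads
    span = hi - lo + 1
    start = lo - max(0, (T - span) // 2)
    start = min(start, lo)          # window must start at or before lo
    start = max(start, hi - T + 1)  # ... and reach hi
    return int(np.clip(start, 0, n_tokens - T))


def build_sentence_matrix(sentence: Sentence, pair: CandidatePair,
                          emb: EmbeddingTable, T: int, clip: int = 30,
                          doc: Document | None = None,
                          word_index: dict[str, int] | None = None,
                          pos_table: dict[str, str] | None = None
                          ) -> SentenceMatrix:
    """Assemble the composite embedding matrix for one candidate pair.

    Column t holds [embedding(word_t); one-hot POS group; (d1, d2)/clip].
    Sentences longer than T are truncated from the right unless that would
    drop a mention head, in which case the window is centred on the pair.
    """
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    if doc is None:
        raise ValueError("build_sentence_matrix requires the owning document")
    n_emb = emb.dim + N_POS_GROUPS + N_DISTANCE
    values = np.zeros((n_emb, T))
    word_ids = np.full(T, -1, dtype=int)

    h1 = mention_head_index(sentence, doc, pair.mention1_id)
    h2 = mention_head_index(sentence, doc, pair.mention2_id)
    start = _window_start(h1, h2, len(sentence.tokens), T)
    window = sentence.tokens[start:start + T]

    for col, (tok_idx, tok) in enumerate(
            zip(range(start, start + len(window)), window)):
        values[:emb.dim, col] = emb.lookup(tok.surface)
        values[emb.dim + map_pos_group(tok.pos, pos_table), col] = 1.0
        d1, d2 = ne_distance(tok_idx, pair, sentence, doc, clip=clip)
        values[emb.dim + N_POS_GROUPS, col] = d1 / clip
        values[emb.dim + N_POS_GROUPS + 1, col] = d2 / clip
        if word_index is not None:
            word_ids[col] = word_index.get(tok.surface.lower(), -1)
    return SentenceMatrix(values=values, valid_length=len(window),
                          word_ids=word_ids)


def max_sentence_length(docs: list[Document]) -> int:
    """Longest sentence (in tokens) across a corpus; the default T."""
    return max((len(s.tokens) for d in docs for s in d.sentences), default=0)
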