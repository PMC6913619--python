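"""Core domain types for disease-disease association (DDA) corpora.

A corpus is a collection of PubMed-style documents (title + abstract) carrying
disease mentions normalized to MeSH-like identifiers and, optionally, gold
pairwise relation annotations.  A candidate for classification is an ordered
pair of disease mentions co-occurring in one sentence, labelled Positive,
Negative or Null (co-occurrence with no stated association).

Character offsets are 0-based, half-open, into ``Document.text`` which is the
title, a single newline, then the abstract.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

LABELS = ("Positive", "Negative", "Null")

#: Sentinel sentence index for a gold pair before segmentation has run.
UNRESOLVED = -1


@dataclass
class Token:
    surface: str
    char_start: int
    char_end: int
    pos: str = ""


@dataclass
class Mention:
    """A disease mention span with its MeSH-like normalization."""

    id: str
    char_start: int
    char_end: int
    surface: str
    mesh_id: str

    def __post_init__(self) -> None:
        if not (self.char_start < self.char_end):
            raise ValueError(
                f"mention {self.id}: empty or inverted span "
                f"[{self.char_start}, {self.char_end})"
            )

    def overlaps(self, start: int, end: int) -> bool:
        return self.char_start < end and start < self.char_end


@dataclass
class Sentence:
    index: int
    char_start: int
    char_end: int
    tokens: list[Token] = field(default_factory=list)
    mention_ids: list[str] = field(default_factory=list)

    def contains_span(self, start: int, end: int) -> bool:
        return self.char_start <= start and end <= self.char_end


@dataclass
class CandidatePair:
    """An ordered disease-mention pair in one sentence.

    ``mention1`` is the textually earlier mention (by char_start); "first
    disease of the pair" throughout the package means this one.
    """

    sentence_index: int
    mention1_id: str
    mention2_id: str
    label: str = "Null"

    def key(self, doc: "Document") -> tuple:
        """Evaluation key: (doc_id, sentence_index, sorted mesh pair)."""
        m1 = doc.mention(self.mention1_id).mesh_id
        m2 = doc.mention(self.mention2_id).mesh_id
        return (doc.doc_id, self.sentence_index) + tuple(sorted((m1, m2)))


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    year: int | None = None
    sentences: list[Sentence] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)
    gold_pairs: list[CandidatePair] = field(default_factory=list)

    @property
    def text(self) -> str:
        return self.title + "\n" + self.abstract

    def mention(self, mention_id: str) -> Mention:
        for m in self.mentions:
            if m.id == mention_id:
                return m
        raise KeyError(f"{self.doc_id}: no mention {mention_id!r}")

    def sentence_of_mention(self, mention_id: str) -> Sentence:
        for s in self.sentences:
            if mention_id in s.mention_ids:
                return s
        raise KeyError(f"{self.doc_id}: mention {mention_id!r} not in any sentence")

    def validate(self) -> None:
        text = self.text
        for m in self.mentions:
            if m.char_end > len(text):
                raise ValueError(
                    f"{self.doc_id}: mention {m.id} span "
                    f"[{m.char_start}, {m.char_end}) outside text of length {len(text)}"
                )
            if text[m.char_start : m.char_end] != m.surface:
                raise ValueError(
                    f"{self.doc_id}: mention {m.id} surface {m.surface!r} does not "
                    f"match text slice {text[m.char_start:m.char_end]!r}"
                )


# ---------------------------------------------------------------------------
# Sentence segmentation and tagging
# ---------------------------------------------------------------------------

# Common abbreviations that end with '.' but do not end a sentence.
_ABBREVIATIONS = {
    "e.g", "i.e", "et al", "vs", "cf", "fig", "figs", "dr", "no", "approx",
    "ca", "resp", "spp",
}

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"])")
_TOKEN = re.compile(r"\w+|[^\w\s]")


def _split_sentences(text: str, offset: int) -> list[tuple[int, int]]:
    """Candidate sentence spans (abs offsets) within one block of text."""
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _SENT_BOUNDARY.finditer(text):
        end = match.start()
        before = text[:end].rstrip(".!?")
        last_word = before.split()[-1].lower() if before.split() else ""
        if last_word in _ABBREVIATIONS or last_word.rstrip(".") in _ABBREVIATIONS:
            continue
        spans.append((offset + start, offset + end))
        start = match.end()
    if start < len(text):
        spans.append((offset + start, offset + len(text)))
    return [(s, e) for s, e in spans if text[s - offset : e - offset].strip()]


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Whitespace/punctuation tokenizer returning offset-carrying tokens."""
    return [
        Token(m.group(), offset + m.start(), offset + m.end())
        for m in _TOKEN.finditer(text)
    ]


def _split_tokens_at_mentions(tokens: list[Token], mentions: list[Mention],
                              text: str) -> list[Token]:
    """Post-split tokens so no token straddles a mention boundary."""
    cuts = sorted({b for m in mentions for b in (m.char_start, m.char_end)})
    out: list[Token] = []
    for tok in tokens:
        inner = [c for c in cuts if tok.char_start < c < tok.char_end]
        if not inner:
            out.append(tok)
            continue
        edges = [tok.char_start] + inner + [tok.char_end]
        for a, b in zip(edges, edges[1:]):
            out.append(Token(text[a:b], a, b))
    return out


def segment_and_tag(doc: Document, tagger=None) -> Document:
    """Populate sentences, tokens and POS tags of ``doc`` (in place).

    The title is always sentence 0.  A proposed sentence boundary that would
    split a mention merges the neighbouring sentences (with a warning).
    ``tagger`` maps a list of token surfaces to a list of Penn-Treebank tags;
    the bundled rule-based tagger is the default.
    """
    if tagger is None:
        from .tagging import rule_pos_tag
        tagger = rule_pos_tag

    doc.validate()
    text = doc.text
    title_span = (0, len(doc.title))
    body_offset = len(doc.title) + 1
    spans = [title_span] + _split_sentences(doc.abstract, body_offset)

    # Merge sentences that a mention straddles.
    merged: list[tuple[int, int]] = []
    for span in spans:
        if merged and any(
            m.overlaps(*merged[-1]) and m.overlaps(*span) for m in doc.mentions
        ):
            logger.warning(
                "%s: mention straddles sentence boundary at %d; merging",
                doc.doc_id, span[0],
            )
            merged[-1] = (merged[-1][0], span[1])
        else:
            merged.append(span)

    doc.sentences = []
    for idx, (start, end) in enumerate(merged):
        toks = tokenize(text[start:end], offset=start)
        toks = _split_tokens_at_mentions(toks, doc.mentions, text)
        tags = tagger([t.surface for t in toks])
        for tok, tag in zip(toks, tags):
            tok.pos = tag
        mention_ids = [
            m.id for m in doc.mentions
            if start <= m.char_start and m.char_end <= end
        ]
        doc.sentences.append(Sentence(idx, start, end, toks, mention_ids))

    # Re-resolve gold pair sentence indices now that sentences exist.
    for pair in doc.gold_pairs:
        pair.sentence_index = doc.sentence_of_mention(pair.mention1_id).index
    return doc


# ---------------------------------------------------------------------------
# Candidate enumeration and corpus-level filters
# ---------------------------------------------------------------------------

def enumerate_candidates(doc: Document) -> list[CandidatePair]:
    """All sentence-level mention pairs with distinct MeSH IDs.

    One candidate per unordered mention pair co-occurring in a sentence,
    ordered by (sentence_index, char_start of mention1, char_start of
    mention2); the label is copied from the gold relations when one is
    annotated for that mention pair, else Null.
    """
    if not doc.sentences:
        raise ValueError(f"{doc.doc_id}: segment_and_tag must run first")
    gold: dict[frozenset, str] = {}
    for pair in doc.gold_pairs:
        key = frozenset((pair.mention1_id, pair.mention2_id))
        if key in gold:
            logger.warning("%s: duplicate relation for %s; keeping first",
                           doc.doc_id, sorted(key))
            continue
        gold[key] = pair.label

    by_id = {m.id: m for m in doc.mentions}
    candidates: list[CandidatePair] = []
    for sent in doc.sentences:
        ms = sorted((by_id[i] for i in sent.mention_ids),
                    key=lambda m: (m.char_start, m.char_end))
        for m1, m2 in itertools.combinations(ms, 2):
            if m1.mesh_id == m2.mesh_id:
                logger.debug("%s: skipping same-MeSH pair %s/%s",
                             doc.doc_id, m1.id, m2.id)
                continue
            label = gold.get(frozenset((m1.id, m2.id)), "Null")
            candidates.append(CandidatePair(sent.index, m1.id, m2.id, label))
    return candidates


def qualifying_sentence_count(doc: Document) -> int:
    """Sentences containing at least two distinct disease MeSH IDs."""
    by_id = {m.id: m for m in doc.mentions}
    return sum(
        1 for s in doc.sentences
        if len({by_id[i].mesh_id for i in s.mention_ids}) >= 2
    )


def select_abstracts(corpus: list[Document], year_min: int = 2013,
                     year_max: int = 2017, min_qualifying_sentences: int = 3,
                     rule_hook=None) -> list[Document]:
    """Abstract-selection heuristics applied when building a DDA corpus.

    Keeps documents published within [year_min, year_max] that have at least
    ``min_qualifying_sentences`` sentences each containing two or more
    distinct disease MeSH IDs, and that pass ``rule_hook`` if one is given
    (a pluggable predicate standing in for dependency-rule abstract filters).
    """
    kept = []
    for doc in corpus:
        if doc.year is None or not (year_min <= doc.year <= year_max):
            continue
        if qualifying_sentence_count(doc) < min_qualifying_sentences:
            continue
        if rule_hook is not None and not rule_hook(doc):
            continue
        kept.append(doc)
    return kept


def copy_document(doc: Document) -> Document:
    """Deep-ish copy safe for feature extraction experiments."""
    return Document(
        doc_id=doc.doc_id,
        title=doc.title,
        abstract=doc.abstract,
        year=doc.year,
        sentences=[replace(s, tokens=[replace(t) for t in s.tokens],
                           mention_ids=list(s.mention_ids))
                   for s in doc.sentences],
        mentions=[replace(m) for m in doc.mentions],
        gold_pairs=[replace(p) for p in doc.gold_pairs],
    )
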