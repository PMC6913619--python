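"""Bundled rule-based Penn-Treebank POS tagger.

The corpus pipeline treats the tagger as an injected callable (a list of
token surfaces in, a list of PTB tags out) so any external tagger can be
substituted.  This default covers function words by lexicon and content
words by suffix heuristics — ample for the downstream 11-way POS grouping,
which only distinguishes coarse classes.
"""

from __future__ import annotations

import re

_LEXICON = {
    # articles / determiners
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "each": "DT", "all": "DT", "any": "DT",
    "no": "DT", "some": "DT",
    # conjunctions
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC", "yet": "CC",
    # prepositions / subordinators
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "for": "IN",
    "with": "IN", "from": "IN", "between": "IN", "among": "IN", "after": "IN",
    "before": "IN", "during": "IN", "than": "IN", "as": "IN", "into": "IN",
    "through": "IN", "without": "IN", "within": "IN", "including": "IN",
    "to": "TO",
    # pronouns
    "we": "PRP", "it": "PRP", "they": "PRP", "he": "PRP", "she": "PRP",
    "i": "PRP", "you": "PRP", "who": "WP", "what": "WP", "which": "WDT",
    "our": "PRP$", "their": "PRP$", "its": "PRP$",
    # common verbs incl. copulas and modals
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD",
    "do": "VBP", "does": "VBZ", "did": "VBD", "may": "MD", "can": "MD",
    "could": "MD", "might": "MD", "should": "MD", "would": "MD", "will": "MD",
    "not": "RB", "also": "RB", "significantly": "RB", "often": "RB",
    "further": "RB",
    # interjections / foreign markers kept for group coverage
    "oh": "UH", "versus": "FW",
}

_PUNCT = re.compile(r"^[^\w\s]+$")
_NUM = re.compile(r"^\d+([.,]\d+)?$")


def _tag_word(word: str, is_sentence_initial: bool) -> str:
    low = word.lower()
    if _PUNCT.match(word):
        return "." if word in ".!?" else ","
    if low in _LEXICON:
        return _LEXICON[low]
    if _NUM.match(word):
        return "CD"
    if low.endswith("ly"):
        return "RB"
    if low.endswith(("ed",)):
        return "VBD"
    if low.endswith(("ing",)):
        return "VBG"
    if low.endswith(("ous", "al", "ic", "ive", "able", "ible", "ary",
                     "ful", "less", "ant", "ent")):
        return "JJ"
    if low.endswith(("izes", "ises", "ates", "fies")):
        return "VBZ"
    if word[0].isupper() and not is_sentence_initial:
        return "NNPS" if low.endswith("s") else "NNP"
    if low.endswith("s") and not low.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"


def rule_pos_tag(surfaces: list[str]) -> list[str]:
    """Tag a tokenized sentence with Penn-Treebank tags."""
    return [_tag_word(w, i == 0) for i, w in enumerate(surfaces)]
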