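"""Synthetic brat-standoff corpora with the structure of a DDA dataset.

Each generated document is a title plus body sentences.  Disease mentions
come from a closed synthetic lexicon (no real PubMed text) normalized to
MeSH-like IDs.  Sentence labels are planted by rule:

* lexical-cue templates ("X increases the risk of Y" -> Positive, "no
  association between X and Y" -> Negative, plain co-mention -> Null), and
* a configurable fraction of *context-dependent* sentences using a neutral
  template whose label is Positive iff the pair appears in the title or is
  the document's most frequent pair — the signal the document-level context
  features exist to capture.

The default class mix matches the published corpus statistics (about 27.5%
positive, 1.4% negative, 71.1% null over candidate pairs).  Because a few
Null sentences carry three diseases (three Null candidates each), the
per-sentence draw probabilities are adjusted by a small fixed-point
computation so the *realized candidate-level* mix hits the configured one.
Generation is a pure function of the config (seed included).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .corpus import CandidatePair, Document, Mention, enumerate_candidates, segment_and_tag

logger = logging.getLogger(__name__)

# -- disease lexicon --------------------------------------------------------

_PREFIXES = ("cardi", "nephr", "neur", "hepat", "derm", "oste", "arthr",
             "pulmon", "gastr", "thromb", "angi", "myel", "cephal", "fibr",
             "scler", "enter", "bronch", "retin", "glomerul", "cortic")
_SUFFIXES = ("itis", "osis", "opathy", "emia", "algia", "oma", "openia",
             "asthenia", "ectasia", "otrophy")
_QUALIFIERS = ("Chronic", "Juvenile", "Familial", "Recurrent", "Atypical")


def disease_lexicon(n: int) -> list[tuple[str, str]]:
    """First ``n`` (surface, mesh_id) entries of the synthetic lexicon."""
    names = [p + s for p in _PREFIXES for s in _SUFFIXES]
    names = [n0.capitalize() for n0 in names]
    names += [f"{q} {n0.lower()}" for q in _QUALIFIERS for n0 in names[:40]]
    if n > len(names):
        raise ValueError(f"lexicon supports at most {len(names)} diseases")
    return [(names[i], f"D{500000 + i:06d}") for i in range(n)]


# -- templates --------------------------------------------------------------
# {0}/{1}/{2} are disease slots; slot text is tracked for mention offsets.

TITLE_TEMPLATES = {
    "Positive": ("Association of {0} with {1} in a population-based cohort",
                 "{0} as a risk factor for {1} in older adults"),
    "Negative": ("No association of {0} with {1} in a population-based study",),
    "Null": ("{0} and {1} in adults: a cross-sectional survey",
             "Prevalence of {0} and {1} in a national registry"),
}

BODY_TEMPLATES = {
    "Positive": (
        "Patients with {0} had an increased risk of developing {1}.",
        "{0} increases the risk of {1}.",
        "{0} was significantly associated with incident {1}.",
        "Our findings indicate that {0} is an independent risk factor for {1}.",
        "The presence of {0} predicted subsequent {1} in this cohort.",
    ),
    "Negative": (
        "No significant association was found between {0} and {1}.",
        "{0} was not associated with {1} in the adjusted models.",
    ),
    "Null": (
        "We measured {0} and {1} in the study cohort.",
        "Participants were screened for {0} and for {1} at enrollment.",
        "Baseline assessments included {0} and {1}.",
        "The registry records diagnoses of {0} and of {1}.",
    ),
}

NULL_THREE_TEMPLATE = ("Participants were screened for {0}, {1}, and {2} "
                       "at enrollment.")

#: Used for context-dependent sentences: the words carry no label cue.
NEUTRAL_TEMPLATE = "The relationship between {0} and {1} was further examined."

FILLER = (" after adjusting for age, sex, smoking status, body mass index,"
          " and socioeconomic covariates measured at baseline")


@dataclass
class GeneratorConfig:
    n_docs: int = 521
    sentences_per_doc: tuple[int, int] = (9, 13)   # body sentences, inclusive
    n_diseases: int = 200
    class_mix: tuple[float, float, float] = (0.275, 0.014, 0.711)
    context_dependence: float = 0.25
    theme_reuse: float = 0.30        # body sentences reusing the title pair
    three_mention_fraction: float = 0.12  # of Null sentences
    long_tail_fraction: float = 0.08      # sentences with a long filler clause
    year_range: tuple[int, int] = (2013, 2017)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.class_mix), 1.0):
            raise ValueError("class mix must sum to 1")
        if min(self.class_mix) < 0:
            raise ValueError("class mix entries must be non-negative")
        if self.n_docs <= 0 or self.n_diseases <= 0:
            raise ValueError("all counts must be positive")
        if self.n_diseases < 4:
            raise ValueError("need at least 4 diseases for distinct pairs")
        if not (0.0 <= self.context_dependence <= 1.0):
            raise ValueError("context_dependence must be in [0, 1]")


def _adjusted_mix(cfg: GeneratorConfig) -> tuple[float, float, float]:
    """Per-sentence draw probabilities making the candidate mix match.

    Fixed point of: p' = p*Z, n' = n*Z/(1-cd), u' = 1-p'-n', with
    Z = cd + (1-cd)*(1 + 2*q3*u') the expected candidates per sentence.
    """
    p, n, u = cfg.class_mix
    cd, q3 = cfg.context_dependence, cfg.three_mention_fraction
    if cd >= 1.0:
        return p, 0.0, 1.0 - p
    pp, nn, uu = p, n, u
    for _ in range(50):
        Z = cd + (1 - cd) * (1 + 2 * q3 * uu)
        pp = min(1.0, p * Z)
        nn = min(1.0 - pp, n * Z / (1 - cd))
        uu = max(0.0, 1.0 - pp - nn)
    return pp, nn, uu


class _SentenceBuilder:
    """Renders a template, recording mention spans relative to the doc."""

    def __init__(self, doc_offset: int):
        self.offset = doc_offset
        self.parts: list[str] = []
        self.mentions: list[tuple[int, int, str, str]] = []

    def render(self, template: str, diseases: list[tuple[str, str]]) -> str:
        pos = 0
        text_pos = self.offset
        out = []
        i = 0
        while i < len(template):
            if template[i] == "{" and i + 2 < len(template) and template[i + 2] == "}":
                slot = int(template[i + 1])
                surface, mesh = diseases[slot]
                self.mentions.append((text_pos, text_pos + len(surface),
                                      surface, mesh))
                out.append(surface)
                text_pos += len(surface)
                i += 3
            else:
                out.append(template[i])
                text_pos += 1
                i += 1
        return "".join(out)


def _pick_pair(rng, lexicon, exclude=None):
    while True:
        i, j = rng.choice(len(lexicon), size=2, replace=False)
        pair = (lexicon[i], lexicon[j])
        if exclude and {pair[0][1], pair[1][1]} == exclude:
            continue
        return pair


def generate(config: GeneratorConfig) -> tuple[list[Document], dict]:
    """Generate a corpus and its ground-truth manifest.

    Returns (documents, manifest); documents are segmented and tagged, with
    gold Positive/Negative relations annotated (Null is implicit).  The
    manifest records the config, per-candidate gold labels and realized
    class counts.
    """
    rng = np.random.default_rng(config.seed)
    lexicon = disease_lexicon(config.n_diseases)
    pp, nn, uu = _adjusted_mix(config)
    cd = config.context_dependence

    docs: list[Document] = []
    for d in range(config.n_docs):
        doc_id = f"SD{d:04d}"
        theme = _pick_pair(rng, lexicon)
        theme_mesh = {theme[0][1], theme[1][1]}

        planted: list[tuple[str, list, str]] = []  # (template, diseases, label)
        title_label = ("Positive", "Negative", "Null")[
            rng.choice(3, p=[pp, nn, uu])]
        t_templates = TITLE_TEMPLATES[title_label]
        planted.append((t_templates[rng.integers(len(t_templates))],
                        list(theme), title_label))

        n_body = int(rng.integers(config.sentences_per_doc[0],
                                  config.sentences_per_doc[1] + 1))
        for _ in range(n_body):
            if rng.random() < cd:
                # context-dependent: neutral wording, label by position rule
                if rng.random() < pp:
                    pair, label = list(theme), "Positive"
                else:
                    pair = list(_pick_pair(rng, lexicon, exclude=theme_mesh))
                    label = "Null"
                planted.append((NEUTRAL_TEMPLATE, pair, label))
                continue
            pair = (list(theme) if rng.random() < config.theme_reuse
                    else list(_pick_pair(rng, lexicon)))
            label = ("Positive", "Negative", "Null")[
                rng.choice(3, p=[pp, nn, uu])]
            if (label == "Null"
                    and rng.random() < config.three_mention_fraction):
                third = _pick_pair(rng, lexicon,
                                   exclude={pair[0][1], pair[1][1]})[0]
                planted.append((NULL_THREE_TEMPLATE,
                                pair + [third], "Null"))
                continue
            templates = BODY_TEMPLATES[label]
            template = templates[rng.integers(len(templates))]
            if (rng.random() < config.long_tail_fraction
                    and template.endswith(".")):
                template = template[:-1] + FILLER + "."
            planted.append((template, pair, label))

        docs.append(_assemble(doc_id, planted, rng, config))

    manifest = _manifest(config, docs)
    return docs, manifest


def _assemble(doc_id: str, planted, rng, config: GeneratorConfig) -> Document:
    title_tpl, title_dis, title_label = planted[0]
    builder = _SentenceBuilder(0)
    title = builder.render(title_tpl, title_dis)
    mentions_raw = list(builder.mentions)
    sentence_pairs = [(0, title_dis, title_label)]

    body_parts: list[str] = []
    offset = len(title) + 1  # newline after title
    for si, (tpl, diseases, label) in enumerate(planted[1:], start=1):
        b = _SentenceBuilder(offset)
        sent = b.render(tpl, diseases)
        body_parts.append(sent)
        mentions_raw.extend(b.mentions)
        sentence_pairs.append((si, diseases, label))
        offset += len(sent) + 1  # single joining space

    doc = Document(
        doc_id=doc_id,
        title=title,
        abstract=" ".join(body_parts),
        year=int(rng.integers(config.year_range[0],
                              config.year_range[1] + 1)),
    )
    doc.mentions = [
        Mention(f"T{i + 1}", s, e, surf, mesh)
        for i, (s, e, surf, mesh) in enumerate(mentions_raw)
    ]
    by_span = {(m.char_start): m.id for m in doc.mentions}

    # gold relations for planted Positive/Negative labels (pair = first two
    # diseases of the sentence; extra diseases contribute implicit Nulls)
    cursor = 0
    spans_sorted = sorted(mentions_raw)
    for si, diseases, label in sentence_pairs:
        k = len(diseases)
        sent_mentions = spans_sorted[cursor:cursor + k]
        cursor += k
        if label in ("Positive", "Negative"):
            pair_ids = [by_span[sm[0]] for sm in sent_mentions
                        if sm[3] in (diseases[0][1], diseases[1][1])][:2]
            doc.gold_pairs.append(
                CandidatePair(si, pair_ids[0], pair_ids[1], label))
    segment_and_tag(doc)
    return doc


def _manifest(config: GeneratorConfig, docs: list[Document]) -> dict:
    gold = {}
    counts = {"Positive": 0, "Negative": 0, "Null": 0}
    for doc in docs:
        for cand in enumerate_candidates(doc):
            key = "|".join(str(k) for k in cand.key(doc))
            gold[key] = cand.label
            counts[cand.label] += 1
    cfg = asdict(config)
    for k, v in cfg.items():
        if isinstance(v, tuple):
            cfg[k] = list(v)
    return {"config": cfg, "class_counts": counts, "gold": gold}


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Corpus splitting
# ---------------------------------------------------------------------------

@dataclass
class CorpusSplit:
    """Document-level partition; ``full_train`` is train + tuning (the
    whole training set a final model is refit on)."""

    train: list[Document] = field(default_factory=list)
    tuning: list[Document] = field(default_factory=list)
    test: list[Document] = field(default_factory=list)

    @property
    def full_train(self) -> list[Document]:
        return self.train + self.tuning


def split(corpus: list[Document], train_fraction: float = 400 / 521,
          seed: int = 0, tuning_fraction: float = 1 / 3) -> CorpusSplit:
    """Document-level train/tuning/test partition.

    ``train_fraction`` of documents form the training set, of which
    ``tuning_fraction`` are carved out as the tuning set; the remainder is
    the test set.  The three lists are disjoint and cover the corpus.
    """
    if not corpus:
        raise ValueError("cannot split an empty corpus")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    if not (0.0 <= tuning_fraction < 1.0):
        raise ValueError("tuning_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(train_fraction * len(corpus)))
    train_ids = order[:n_train]
    n_tune = int(round(tuning_fraction * n_train))
    return CorpusSplit(
        train=[corpus[i] for i in sorted(train_ids[n_tune:])],
        tuning=[corpus[i] for i in sorted(train_ids[:n_tune])],
        test=[corpus[i] for i in sorted(order[n_train:])],
    )
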