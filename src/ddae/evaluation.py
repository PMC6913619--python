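"""Scoring for DDA extraction.

Relation scoring is micro-averaged over the two association classes
(Positive, Negative); Null plays the role of "no relation extracted":

* TP — predicted association class equals the gold association class;
* FP — an association predicted where gold is Null or a different class;
* FN — a gold association missed (predicted Null) or mislabeled.

So a mislabeled association (gold Positive, predicted Negative) counts as
both an FP and an FN, standard relation-extraction practice.  Cohen's kappa
quantifies inter-annotator agreement over the three labels, and approximate
span matching aligns automatically recognized mentions with gold mentions
before relation scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

ASSOCIATION_CLASSES = ("Positive", "Negative")


class KeyMismatchError(ValueError):
    """Predictions and gold are not keyed identically."""


@dataclass
class ConfusionCounts:
    tp: dict[str, int] = field(default_factory=lambda: dict.fromkeys(
        ASSOCIATION_CLASSES, 0))
    fp: dict[str, int] = field(default_factory=lambda: dict.fromkeys(
        ASSOCIATION_CLASSES, 0))
    fn: dict[str, int] = field(default_factory=lambda: dict.fromkeys(
        ASSOCIATION_CLASSES, 0))

    @property
    def total_tp(self) -> int:
        return sum(self.tp.values())

    @property
    def total_fp(self) -> int:
        return sum(self.fp.values())

    @property
    def total_fn(self) -> int:
        return sum(self.fn.values())


def score(predictions: dict, gold: dict
          ) -> tuple[float, float, float, ConfusionCounts]:
    """Micro-averaged (precision, recall, F1, counts) over association classes.

    Both mappings must share exactly the same candidate keys; orphans on
    either side raise :class:`KeyMismatchError` listing them.  Zero
    denominators yield 0 with a warning.
    """
    extra = sorted(set(predictions) - set(gold))
    missing = sorted(set(gold) - set(predictions))
    if extra or missing:
        raise KeyMismatchError(
            f"prediction/gold key mismatch; unmatched predictions: "
            f"{extra[:5]}{'...' if len(extra) > 5 else ''}; "
            f"unmatched gold: {missing[:5]}{'...' if len(missing) > 5 else ''}")

    counts = ConfusionCounts()
    for key, g in gold.items():
        p = predictions[key]
        if p in ASSOCIATION_CLASSES:
            if p == g:
                counts.tp[p] += 1
            else:
                counts.fp[p] += 1
                if g in ASSOCIATION_CLASSES:
                    counts.fn[g] += 1
        elif g in ASSOCIATION_CLASSES:
            counts.fn[g] += 1

    tp, fp, fn = counts.total_tp, counts.total_fp, counts.total_fn
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = (_safe_div(2 * precision * recall, precision + recall, "F1")
          if precision + recall else 0.0)
    return precision, recall, f1, counts


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def cohen_kappa(annotations_a: dict, annotations_b: dict) -> float:
    """Cohen's kappa over two annotation sets sharing the same keys.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e computed from
    the two annotators' marginal label frequencies.
    """
    if set(annotations_a) != set(annotations_b):
        raise KeyMismatchError("annotation sets must cover identical keys")
    n = len(annotations_a)
    if n == 0:
        raise ValueError("no annotations to compare")
    labels = sorted(set(annotations_a.values()) | set(annotations_b.values()))
    p_o = sum(annotations_a[k] == annotations_b[k] for k in annotations_a) / n
    p_e = sum(
        (sum(v == lab for v in annotations_a.values()) / n)
        * (sum(v == lab for v in annotations_b.values()) / n)
        for lab in labels
    )
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("chance agreement is 1 but observed agreement is not")
    return (p_o - p_e) / (1.0 - p_e)


def approximate_match(pred_mentions, gold_mentions) -> list[tuple]:
    """Greedy 1-to-1 alignment of overlapping mention spans.

    Any character overlap qualifies; candidate links are taken longest
    overlap first (ties by earlier gold then pred start).  Returns a list of
    (pred_mention, gold_mention) pairs; aligned predictions inherit the gold
    identity for downstream relation scoring.
    """
    links = []
    for pi, p in enumerate(pred_mentions):
        for gi, g in enumerate(gold_mentions):
            overlap = min(p.char_end, g.char_end) - max(p.char_start,
                                                        g.char_start)
            if overlap > 0:
                links.append((overlap, g.char_start, p.char_start, pi, gi))
    links.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p, used_g, aligned = set(), set(), []
    for _, _, _, pi, gi in links:
        if pi in used_p or gi in used_g:
            continue
        used_p.add(pi)
        used_g.add(gi)
        aligned.append((pred_mentions[pi], gold_mentions[gi]))
    return aligned
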