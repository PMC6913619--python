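# Methods

This note records the modelling choices behind `ddae`: what is computed,
which decisions were genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Task and data model

A candidate is an ordered pair of disease mentions with *different* MeSH-like
IDs co-occurring in one sentence; the first member of the pair is always the
textually earlier mention (pair order is otherwise arbitrary, and textual
order is deterministic). Pairs of mentions normalized to the same MeSH ID
are not candidates — a disease is not associated with itself. Candidates are
enumerated per *mention* pair, not per MeSH-ID pair, so a pair of concepts
recurring in two sentences yields two candidates.

Documents are brat standoff `.txt`/`.ann` pairs; the title is the first text
line and is always sentence 0, so "appears in the title" and "first sentence
of the abstract" (sentence 1) are distinct features. Bare brat has no
publication-year field; the year travels in a `#meta` comment line. Corpus
building supports the standard selection heuristics: a publication-year
window (default 2013–2017), a minimum number of sentences containing at
least two distinct disease IDs (default 3), and a pluggable
abstract-acceptance predicate (default: accept all) for rule-based filters
whose rule sets are not distributable.

Sentence segmentation is regex-based with an abbreviation guard; a proposed
boundary that would split a disease mention merges the adjacent sentences.
Tokens are re-split at mention edges so no token straddles a mention
boundary. The POS tagger is an injected callable; the bundled default is a
rule/lexicon tagger emitting Penn-Treebank tags, which downstream features
immediately collapse into 11 coarse groups, so tagger accuracy beyond the
coarse classes is immaterial.

## Sentence representation

Each token contributes a column `[embedding; POS one-hot(11); (d1, d2)]`.

* **Embeddings** are loaded from word2vec text or binary files and frozen
  during training. Out-of-vocabulary words map to zeros or to per-word
  random vectors fixed by a hash of the word and the table seed. A
  *no-pretrain* mode instead treats the embedding rows as parameters,
  initialized uniformly in [−0.05, 0.05] and updated by backpropagation.
* **POS groups.** The 11 groups are fixed; the PTB→group routing table is
  bundled and overridable (the group inventory is standard, the exact
  routing is a package choice). Unknown tags fall back to nouns with a
  warning.
* **Distances** d1, d2 are signed token-count offsets from the current token
  to the *head* (last) token of each of the pair's mentions, zero inside the
  mention, clipped to ±30 and scaled by 1/30 into [−1, 1]. Signedness,
  clipping and scaling are package choices — bounded inputs stabilize plain
  SGD; the head-token convention reflects right-headed disease noun phrases.
* **T**, the matrix width, defaults to the longest training sentence. Longer
  unseen sentences are truncated from the right unless that would drop a
  mention head, in which case the T-token window recentres so both heads
  stay inside (always possible when the heads are fewer than T tokens
  apart).

## Context representation

Fixed layout `[unigram | bigram | surrounding-disease | POS(11) | NE(3) |
core-pair(3) | location(3)]`. BOW segments are binary indicators over a
vocabulary fitted on the training split only (lower-cased, frequency ≥ 2,
lexicographic index order; frozen at test time). "Surrounding diseases" are
the surfaces of the *other* disease mentions in the candidate's sentence.
The sentence-level POS context is the presence bitmap of the 11 groups (a
per-word one-hot would be variable-length; the presence union is the fixed-
length aggregation). The three entity counts are scaled by 0.1 to keep their
magnitude comparable with the binary bits (raw counts are available by
config). Core-pair frequency is counted over unordered MeSH-ID pairs across
all sentences, ties broken by first occurrence.

## LC-CNN and training

Convolution windows default to f ∈ {3, 4, 5} with 100 filters each, one
scalar bias per filter, ReLU, then max-pooling **restricted to windows lying
inside the unpadded token range** (minimum one position). The restriction
matters: with a positive conv bias, pooling over all-zero padding windows
would make scores depend on how much padding follows a sentence; masking
makes them exactly padding-invariant. The pooled vector feeds a dense ReLU
layer (n_sr = 64 by default), is concatenated with the context vector, and a
linear layer emits three unbounded class scores.

Labels are sign vectors with exactly one +1; the categorical hinge loss
`Σᵢ max(1 − yᵢ·outᵢ, 0)/3` is minimized by plain mini-batch SGD
(batch 32, learning rate 0.05, 20 epochs by default; momentum available but
off). ReLU in the conv and dense layers is a package default — only the
output layer's linear activation is intrinsic to the margin formulation.
Prediction is argmax over the scores with ties resolved in the fixed order
Positive > Negative > Null. All randomness (initialization, shuffling, OOV
vectors, splits, generation) derives from explicit integer seeds; identical
seed/config/data give bit-identical parameters.

Early stopping is available (`train(..., tuning_corpus=...)` monitors
micro-F1 on a held-out tuning set, picks the best epoch, and retrains on the
union) but is off by default: the fixed epoch budget keeps the headline
training path single-stage and deterministic. The two-stage SVM+CNN baseline
honours the tuning/training separation — the tuning fold may steer the CNN
stage's stopping but its gold labels are never seen by the stage-2 SVM.

There is no class-imbalance correction; the Negative class (~1.4% of
candidates) is learned, or not, on its own merits.

## Evaluation

Micro-averaged P/R/F1 over the two association classes with Null as the
non-relation: TP requires exact class agreement; a predicted association
over a gold Null (or wrong class) is an FP; a missed or mislabeled gold
association is an FN. This reading — Negative associations count toward TP —
follows the task's definition of Null and standard relation-extraction
practice, and is an explicit assumption of this package. Cohen's kappa is
computed from marginal label frequencies (cross-checked against
scikit-learn in the tests). Approximate mention matching aligns predicted
and gold spans greedily by longest character overlap (any overlap
qualifies; threshold configurable), and aligned predictions inherit the
gold identity for relation scoring.

## Synthetic corpus generator

The generator manufactures the statistical structure the models are meant to
exploit, not linguistic realism. Disease surfaces come from a closed
synthetic lexicon (no real PubMed text; single- and two-token names) mapped
to MeSH-like IDs. Each document has a themed title pair that recurs in the
body (so "in title" and "most frequent pair" correlate, as in real
abstracts), body sentences instantiated from labelled templates
(risk-factor wording → Positive, explicit no-association wording →
Negative, plain co-mention → Null), an occasional three-disease Null
sentence, and a long-sentence tail (8% of sentences carry a covariate
filler clause) to exercise truncation and windowing.

A configurable fraction of sentences (`context_dependence`, default 0.25)
instead uses a *neutral* template whose label is Positive iff the pair
appears in the title (equivalently, is the document's theme pair) — labels
recoverable only from document-level context. Because three-mention
sentences add extra Null candidates, the per-sentence label-draw
probabilities are adjusted by a small fixed-point computation so the
*candidate-level* class mix matches the configured one (default
0.275/0.014/0.711, the published corpus ratios); at 200+ documents the
realized mix lands within ±3%. Defaults of 521 documents with 9–13 body
sentences and a 200-disease lexicon echo the published corpus scale
(~12 sentences and ~20 candidate pairs per abstract). Splitting is
document-level: 400/521 of documents form the training set, a random third
of which is the tuning set, the rest the test set; the three returned sets
are disjoint.

What passing the synthetic experiments shows: the architecture can learn
lexically cued labels near-perfectly, and the context vector carries
document-position signal that a sentence-only CNN provably cannot access.
What it does not show: performance on real biomedical prose, whose cue
inventory, syntax, negation scope and annotation noise are far richer than
the template inventory here; absolute synthetic scores are not comparable
to scores on manually annotated abstracts.

## Numerical and engineering notes

* Forward/backward are float64 throughout; the gradient of hinge∘network is
  validated against central finite differences (relative error < 1e-4) at
  20 random parameter points, including the trainable-embedding path.
* Hinge/ReLU/max kinks have measure zero under random parameter draws; the
  finite-difference checks use h = 1e-6.
* Training problem sizes in the test suite (up to 300 documents, ≈3,300
  candidates, default architecture) run in a few minutes on one CPU core;
  the pipeline is vectorized over batches via im2col-style sliding windows.
* Degenerate inputs: empty candidate sets, empty vocabularies (indicator
  segments remain), sentences shorter than a convolution window (one pooling
  position), and zero score denominators (0 with a warning) are all defined
  behaviours with tests.

## Known limitations

* Disease NER/normalization is out of scope; mentions arrive annotated.
* The dependency-rule abstract filter is a hook, not an implementation.
* The linear output layer couples context bits additively; label rules that
  require sentence-by-context interactions beyond what the dense sentence
  vector captures are not representable.
* The rule-based POS tagger is adequate for 11-group features on synthetic
  text; substitute a trained tagger for real corpora.
* LSTM/transformer comparison systems are deliberately not included.
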