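import numpy as np
import pytest

from ddae.corpus import Document, Mention, segment_and_tag
from ddae.embeddings import EmbeddingTable
from ddae.standoff import read_standoff
from ddae.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_corpus():
    """60 lexically-determined synthetic documents, segmented and tagged."""
    docs, manifest = generate(
        GeneratorConfig(n_docs=60, seed=101, context_dependence=0.0))
    return docs, manifest


@pytest.fixture()
def gout_doc():
    """The minimal hand-written brat example: one Positive pair."""
    txt = "Gout worsens diabetes.\nGout is common. Diabetes is too."
    ann = (
        "T1\tDisease 0 4\tGout\n"
        "T2\tDisease 13 21\tdiabetes\n"
        "R1\tPositive Arg1:T1 Arg2:T2\n"
    )
    doc = read_standoff(txt, ann, doc_id="gout")
    return segment_and_tag(doc)


@pytest.fixture()
def three_disease_doc():
    """One sentence holding three distinct diseases, one gold Positive pair."""
    title = "Asthma and eczema screening"
    body = "Asthma and eczema aggravate rhinitis in children."
    doc = Document(doc_id="tri", title=title, abstract=body, year=2015)
    off = len(title) + 1
    doc.mentions = [
        Mention("T1", 0, 6, "Asthma", "D001"),
        Mention("T2", 11, 17, "eczema", "D002"),
        Mention("T3", off, off + 6, "Asthma", "D001"),
        Mention("T4", off + 11, off + 17, "eczema", "D002"),
        Mention("T5", off + 28, off + 36, "rhinitis", "D003"),
    ]
    return segment_and_tag(doc)


@pytest.fixture()
def toy_embeddings():
    rng = np.random.default_rng(7)
    vectors = {w: rng.normal(size=4) for w in ("gout", "worsens", "diabetes")}
    return EmbeddingTable(dim=4, vectors=vectors, oov_policy="zeros")
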