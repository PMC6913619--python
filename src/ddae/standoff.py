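"""brat standoff I/O.

A document is a pair of UTF-8 files: ``<doc_id>.txt`` holding the raw text
(title on the first line, abstract after a single newline) and
``<doc_id>.ann`` holding the annotations:

* ``T<n>\tDisease <start> <end>\t<surface>`` — a disease mention span;
* ``N<n>\tReference T<n> MeSH:<id>\t<surface>`` — its MeSH normalization;
* ``R<n>\t<label> Arg1:T<i> Arg2:T<j>`` — a pairwise relation
  (Positive / Negative / Null);
* ``#meta\tYear <year>`` — a comment line carrying the publication year,
  which bare brat has no field for.

Mentions lacking a normalization line get the deterministic pseudo-ID
``UNNORM:<lower-cased surface>`` so minimal hand-written .ann files parse.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from .corpus import CandidatePair, Document, Mention, UNRESOLVED

logger = logging.getLogger(__name__)


class StandoffParseError(ValueError):
    """A malformed .ann line, reported with its content."""


_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_R_LINE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)\s*$")
_N_LINE = re.compile(r"^(N\d+)\t\S+ (T\d+) MeSH:(\S+)(?:\t(.*))?$")
_META_LINE = re.compile(r"^#meta\tYear (\d+)\s*$")


def read_standoff(txt_content: str, ann_content: str,
                  doc_id: str = "doc") -> Document:
    """Parse a brat ``.txt``/``.ann`` pair into a Document.

    Raises StandoffParseError on a malformed line and ValueError when a
    mention span falls outside the text or disagrees with its surface.
    Relations not between two disease mentions are rejected.
    """
    title, _, abstract = txt_content.partition("\n")
    doc = Document(doc_id=doc_id, title=title, abstract=abstract)
    text = doc.text

    mentions: dict[str, Mention] = {}
    relations: list[tuple[str, str, str]] = []
    for raw in ann_content.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = _META_LINE.match(line)
            if m:
                doc.year = int(m.group(1))
            continue
        if line.startswith("T"):
            m = _T_LINE.match(line)
            if not m:
                raise StandoffParseError(f"malformed entity line: {line!r}")
            tid, etype, start, end, surface = m.groups()
            if etype != "Disease":
                raise StandoffParseError(
                    f"unsupported entity type {etype!r} in line: {line!r}")
            start, end = int(start), int(end)
            if end > len(text):
                raise ValueError(
                    f"span ({start}, {end}) outside text of length {len(text)}"
                    f" in line: {line!r}")
            mentions[tid] = Mention(tid, start, end, surface,
                                    mesh_id=f"UNNORM:{surface.lower()}")
        elif line.startswith("N"):
            m = _N_LINE.match(line)
            if not m:
                raise StandoffParseError(f"malformed normalization line: {line!r}")
            _, tid, mesh, _ = m.groups()
            if tid not in mentions:
                raise StandoffParseError(
                    f"normalization references unknown mention: {line!r}")
            mentions[tid].mesh_id = mesh
        elif line.startswith("R"):
            m = _R_LINE.match(line)
            if not m:
                raise StandoffParseError(f"malformed relation line: {line!r}")
            rid, label, a1, a2 = m.groups()
            relations.append((label, a1, a2))
        else:
            raise StandoffParseError(f"unrecognized line: {line!r}")

    doc.mentions = sorted(mentions.values(),
                          key=lambda m: (m.char_start, m.char_end))
    for label, a1, a2 in relations:
        for tid in (a1, a2):
            if tid not in mentions:
                raise StandoffParseError(
                    f"relation references unknown mention {tid}")
        if label not in ("Positive", "Negative", "Null"):
            raise StandoffParseError(f"unknown relation label {label!r}")
        doc.gold_pairs.append(
            CandidatePair(UNRESOLVED, *_ordered(mentions, a1, a2), label))
    doc.validate()
    return doc


def _ordered(mentions: dict[str, Mention], a1: str, a2: str) -> tuple[str, str]:
    if mentions[a1].char_start <= mentions[a2].char_start:
        return a1, a2
    return a2, a1


def write_standoff(doc: Document) -> tuple[str, str]:
    """Serialize a Document to (txt_content, ann_content).

    Inverse of :func:`read_standoff` on mentions, offsets, labels and year.
    """
    ann_lines: list[str] = []
    if doc.year is not None:
        ann_lines.append(f"#meta\tYear {doc.year}")
    id_map = {}
    for i, m in enumerate(sorted(doc.mentions,
                                 key=lambda m: (m.char_start, m.char_end)), 1):
        id_map[m.id] = f"T{i}"
        ann_lines.append(f"T{i}\tDisease {m.char_start} {m.char_end}\t{m.surface}")
        ann_lines.append(f"N{i}\tReference T{i} MeSH:{m.mesh_id}\t{m.surface}")
    for j, pair in enumerate(doc.gold_pairs, 1):
        ann_lines.append(
            f"R{j}\t{pair.label} Arg1:{id_map[pair.mention1_id]} "
            f"Arg2:{id_map[pair.mention2_id]}")
    ann = "\n".join(ann_lines) + ("\n" if ann_lines else "")
    return doc.text, ann


# ---------------------------------------------------------------------------
# Corpus directory layout: <dir>/<doc_id>.txt + <doc_id>.ann
# ---------------------------------------------------------------------------

def write_corpus(corpus: list[Document], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in corpus:
        txt, ann = write_standoff(doc)
        (directory / f"{doc.doc_id}.txt").write_text(txt, encoding="utf-8")
        (directory / f"{doc.doc_id}.ann").write_text(ann, encoding="utf-8")


def read_corpus(directory: str | Path, segment: bool = True,
                tagger=None) -> list[Document]:
    """Read every .txt/.ann pair under ``directory`` (sorted by doc_id)."""
    from .corpus import segment_and_tag

    directory = Path(directory)
    docs = []
    for txt_path in sorted(directory.glob("*.txt")):
        ann_path = txt_path.with_suffix(".ann")
        ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        doc = read_standoff(txt_path.read_text(encoding="utf-8"), ann,
                            doc_id=txt_path.stem)
        if segment:
            segment_and_tag(doc, tagger=tagger)
        docs.append(doc)
    if not docs:
        logger.warning("no .txt files found under %s", directory)
    return docs
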