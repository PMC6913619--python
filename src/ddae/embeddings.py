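"""Pretrained word-embedding tables (word2vec text and binary dialects).

Only *loading* is supported; training embedding models is out of scope.
Out-of-vocabulary words follow a configurable policy: all-zero vectors, or
per-word random vectors that are a deterministic function of the word and
the table's seed (so repeated lookups and reloads agree).
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

OOV_ZEROS = "zeros"
OOV_RANDOM_FIXED = "random_fixed"


class EmbeddingFormatError(ValueError):
    """Header/row disagreement or an unparseable embedding file."""


def _word_seed(word: str, seed: int) -> int:
    digest = hashlib.sha256(word.encode("utf-8")).digest()
    return (int.from_bytes(digest[:4], "little") ^ seed) % (2**31)


@dataclass
class EmbeddingTable:
    """word -> vector lookup with a fixed dimension and OOV policy."""

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    oov_policy: str = OOV_ZEROS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.oov_policy not in (OOV_ZEROS, OOV_RANDOM_FIXED):
            raise ValueError(f"unknown OOV policy {self.oov_policy!r}")

    def lookup(self, word: str) -> np.ndarray:
        """Vector for ``word`` (lower-cased); deterministic for OOV words."""
        vec = self.vectors.get(word.lower())
        if vec is not None:
            return vec
        if self.oov_policy == OOV_ZEROS:
            return np.zeros(self.dim)
        rng = np.random.default_rng(_word_seed(word.lower(), self.seed))
        return rng.uniform(-0.25, 0.25, self.dim)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.vectors


def load_embeddings(path: str | Path, fmt: str = "word2vec_text",
                    oov_policy: str = OOV_ZEROS, seed: int = 0) -> EmbeddingTable:
    """Load a word2vec table; ``fmt`` is ``word2vec_text`` or ``word2vec_binary``.

    The first line/header is ``<count> <dim>``; a row whose vector length
    disagrees with the header raises :class:`EmbeddingFormatError`.
    """
    path = Path(path)
    if fmt == "word2vec_text":
        vectors = _load_text(path)
    elif fmt == "word2vec_binary":
        vectors = _load_binary(path)
    else:
        raise ValueError(f"unknown embedding format {fmt!r}")
    dim = len(next(iter(vectors.values())))
    return EmbeddingTable(dim=dim, vectors=vectors, oov_policy=oov_policy,
                          seed=seed)


def _load_text(path: Path) -> dict[str, np.ndarray]:
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError(f"bad header in {path}: {header!r}")
        count, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) - 1 != dim:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: expected {dim} values, got {len(parts) - 1}")
            vectors[parts[0].lower()] = np.asarray(parts[1:], dtype=float)
    if count != len(vectors):
        raise EmbeddingFormatError(
            f"{path}: header promised {count} words, found {len(vectors)}")
    return vectors


def _load_binary(path: Path) -> dict[str, np.ndarray]:
    with path.open("rb") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError(f"bad header in {path}: {header!r}")
        count, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for _ in range(count):
            word_bytes = bytearray()
            while True:
                ch = fh.read(1)
                if not ch:
                    raise EmbeddingFormatError(f"{path}: truncated word entry")
                if ch == b" ":
                    break
                if ch != b"\n":
                    word_bytes.extend(ch)
            raw = fh.read(4 * dim)
            if len(raw) != 4 * dim:
                raise EmbeddingFormatError(f"{path}: truncated vector data")
            vec = np.asarray(struct.unpack(f"<{dim}f", raw), dtype=float)
            vectors[word_bytes.decode("utf-8").lower()] = vec
    return vectors


def write_embeddings_text(table: EmbeddingTable, path: str | Path) -> None:
    """Write the in-vocabulary rows in the word2vec text dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for word in sorted(table.vectors):
            values = " ".join(repr(float(v)) for v in table.vectors[word])
            fh.write(f"{word} {values}\n")
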