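"""Token-vector tables and the cosine-similarity primitive.

An :class:`EmbeddingTable` stores an un-normalized real vector per token
(characters as standalone units, and whole compound words).  Vectors are
kept raw because the composition models operate on raw vectors; length
normalization happens only inside :func:`cosine`, which is norm-free.

Two text dialects are supported: the classic word2vec text format
(header line ``"<vocab_size> <dim>"``, then space-separated rows
``token x1 ... xd``) and a headerless TSV with the same row layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingTable",
    "DimensionMismatchError",
    "DegenerateVectorError",
    "load_embeddings",
    "save_embeddings",
    "cosine",
]


class DimensionMismatchError(ValueError):
    """A row's component count disagrees with the table dimension."""


class DegenerateVectorError(ValueError):
    """Cosine similarity was requested for a zero-norm vector."""


@dataclass
class EmbeddingTable:
    """Mapping token -> d-dimensional vector, with a fixed dimension.

    Tokens are opaque unicode strings; no script-specific processing is
    done, so ASCII stand-ins work identically to CJK characters.
    """

    dimension: int
    entries: dict[str, np.ndarray] = field(default_factory=dict)
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError(f"dimension must be >= 1, got {self.dimension}")
        for token, vec in self.entries.items():
            if vec.shape != (self.dimension,):
                raise DimensionMismatchError(
                    f"vector for {token!r} has shape {vec.shape}, expected ({self.dimension},)"
                )

    @property
    def vocab_size(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return token in self.entries

    def lookup(self, token: str) -> np.ndarray | None:
        """Exact-match retrieval; ``None`` is the missing-marker.

        Missing tokens are a value, never an error and never a zero
        vector: downstream code must be able to distinguish "no vector"
        from a (disallowed) degenerate vector.
        """
        return self.entries.get(token)

    def add(self, token: str, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.dimension,):
            raise DimensionMismatchError(
                f"vector for {token!r} has shape {vector.shape}, expected ({self.dimension},)"
            )
        self.entries[token] = vector


def load_embeddings(path: str | Path, dialect: str = "word2vec-text") -> EmbeddingTable:
    """Read an embedding table from disk.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"word2vec-text"`` (header ``"<vocab> <dim>"``) or
        ``"headerless-tsv"`` (dimension inferred from the first row).

    Duplicate tokens keep the first occurrence; a single warning with
    the number of duplicates dropped is logged.
    """
    path = Path(path)
    if dialect not in ("word2vec-text", "headerless-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")

    entries: dict[str, np.ndarray] = {}
    n_duplicates = 0
    dim: int | None = None

    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    start = 0
    if dialect == "word2vec-text":
        if not lines:
            raise ValueError(f"{path}: empty file, expected a '<vocab> <dim>' header")
        header = lines[0].split()
        if len(header) != 2:
            raise ValueError(f"{path}: line 1: malformed header {lines[0]!r}")
        try:
            _, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise ValueError(f"{path}: line 1: unparseable header {lines[0]!r}") from exc
        start = 1

    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t") if dialect == "headerless-tsv" else line.split()
        if dialect == "headerless-tsv" and len(parts) == 1:
            parts = line.split()
        token, comps = parts[0], parts[1:]
        if dim is None:
            dim = len(comps)
        if len(comps) != dim:
            raise DimensionMismatchError(
                f"{path}: line {lineno}: expected {dim} components, found {len(comps)}"
            )
        try:
            vec = np.array([float(x) for x in comps], dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: unparseable numeric field") from exc
        if token in entries:
            n_duplicates += 1
            continue
        entries[token] = vec

    if dim is None:
        raise ValueError(f"{path}: no vector rows found")
    if n_duplicates:
        logger.warning("%s: dropped %d duplicate token(s), kept first occurrence", path, n_duplicates)

    return EmbeddingTable(dimension=dim, entries=entries, source_label=str(path))


def save_embeddings(
    table: EmbeddingTable,
    path: str | Path,
    dialect: str = "word2vec-text",
    precision: int = 8,
) -> None:
    """Write a table in the given dialect with `precision` significant digits."""
    path = Path(path)
    sep = "\t" if dialect == "headerless-tsv" else " "
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "word2vec-text":
            fh.write(f"{table.vocab_size} {table.dimension}\n")
        elif dialect != "headerless-tsv":
            raise ValueError(f"unknown dialect {dialect!r}")
        for token, vec in table.entries.items():
            comps = sep.join(format(x, f".{precision}g") for x in vec)
            fh.write(f"{token}{sep}{comps}\n")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity, clamped to [-1, 1] against float overshoot.

    Zero-norm inputs raise :class:`DegenerateVectorError`; callers must
    filter such tokens rather than silently getting NaN.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionMismatchError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateVectorError("cosine undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
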