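"""Reading and querying word-embedding tables in the word2vec text dialect.

The on-disk format is the plain-text convention used by word2vec and the
published fastText ``.vec`` files: a header line ``<vocab_size> <dim>``
followed by one line per word, the word token first and then ``dim``
whitespace-separated numbers.  Gzip-compressed files are accepted and
detected by the ``.gz`` extension.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingTable", "read_embeddings", "write_embeddings", "get_vectors", "get_term_vectors"]


@dataclass
class EmbeddingTable:
    """Vocabulary -> vector map for a single language.

    Parameters
    ----------
    language : str
        ISO-639 / BCP-47 language code (e.g. ``"en"``).
    dim : int
        Dimensionality of the vectors; every entry has exactly this length.
    entries : dict[str, numpy.ndarray]
        Word to vector mapping; insertion order is file order.
    """

    language: str
    dim: int
    entries: dict[str, np.ndarray] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be positive, got {self.dim}")
        for word, vec in self.entries.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {word!r} has shape {vec.shape}, expected ({self.dim},)")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"vector for {word!r} has non-finite components")
            self.entries[word] = vec

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return self.lookup(word) is not None

    def lookup(self, word: str) -> str | None:
        """Resolve a word to the vocabulary key it matches, or None.

        The surface form is tried first; if absent, the lower-cased form
        (embeddings mix cases, and translated lexica are typically
        lower-case while corpora are not).
        """
        if word in self.entries:
            return word
        folded = word.lower()
        if folded in self.entries:
            return folded
        return None

    def vector(self, word: str) -> np.ndarray:
        key = self.lookup(word)
        if key is None:
            raise KeyError(word)
        return self.entries[key]


def read_embeddings(
    path: str | Path,
    max_words: int | None = None,
    lowercase: bool = False,
    language: str = "und",
) -> EmbeddingTable:
    """Read a word2vec-text embedding file.

    Parameters
    ----------
    path : path
        File to read; ``.gz`` files are decompressed transparently.
    max_words : int, optional
        Keep only the first ``max_words`` usable rows (full fastText
        vocabularies run to millions of rows; analyses rarely need them all).
    lowercase : bool
        Lower-case every vocabulary word on load.  Later duplicates created
        by folding are dropped (first occurrence wins, matching the
        frequency-sorted layout of published embeddings).
    language : str
        Language code recorded on the returned table.

    Returns
    -------
    EmbeddingTable
        Entries in file order; malformed or undecodable lines are skipped,
        counted on ``n_skipped`` and reported through logging.
    """
    path = Path(path)
    if max_words is not None and max_words < 1:
        raise ValueError("max_words must be a positive integer")
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        fh = opener(path, "rb")
    except OSError as exc:
        raise FileNotFoundError(f"cannot open embedding file {path}: {exc}") from exc
    with fh:
        header = fh.readline()
        try:
            n_str, dim_str = header.decode("utf-8").split()
            n_declared, dim = int(n_str), int(dim_str)
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"{path}: first line must be '<vocab_size> <dim>', got {header[:80]!r}") from exc
        if dim < 1:
            raise ValueError(f"{path}: header declares non-positive dimension {dim}")

        entries: dict[str, np.ndarray] = {}
        n_skipped = 0
        for raw in fh:
            if max_words is not None and len(entries) >= max_words:
                break
            try:
                line = raw.decode("utf-8")
            except UnicodeDecodeError:
                n_skipped += 1
                continue
            parts = line.rstrip("\n").split(" ")
            # fastText .vec rows can carry a trailing space before the newline
            if parts and parts[-1] == "":
                parts.pop()
            if len(parts) != dim + 1:
                if line.strip():
                    n_skipped += 1
                continue
            word = parts[0]
            if lowercase:
                word = word.lower()
            if word in entries:
                n_skipped += 1
                continue
            try:
                vec = np.array(parts[1:], dtype=float)
            except ValueError:
                n_skipped += 1
                continue
            if not np.all(np.isfinite(vec)):
                n_skipped += 1
                continue
            entries[word] = vec
    if n_skipped:
        logger.warning("%s: skipped %d malformed/duplicate lines", path, n_skipped)
    if not entries:
        raise ValueError(f"{path}: no usable embedding rows")
    if n_declared != len(entries) and max_words is None and not n_skipped:
        logger.info("%s: header declares %d words, read %d", path, n_declared, len(entries))
    return EmbeddingTable(language=language, dim=dim, entries=entries, n_skipped=n_skipped)


def write_embeddings(table: EmbeddingTable, path: str | Path, fmt: str = "%.8g") -> Path:
    """Write a table back to word2vec text format (UTF-8, one row per word)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{len(table.entries)} {table.dim}\n")
        for word, vec in table.entries.items():
            fh.write(word + " " + " ".join(fmt % v for v in vec) + "\n")
    return path


def get_vectors(
    table: EmbeddingTable, words: Sequence[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Look up whole words, preserving query order.

    Returns ``(matrix, found, missing)`` where ``matrix`` rows align 1:1
    with ``found``.  Duplicate queries are collapsed (with a warning) and
    missing words are data, not errors.  Lookup tries the surface form,
    then the lower-cased form.
    """
    if len(words) == 0:
        raise ValueError("words must be non-empty")
    seen: list[str] = []
    for w in words:
        if w in seen:
            logger.warning("duplicate query word %r collapsed", w)
        else:
            seen.append(w)
    found: list[str] = []
    rows: list[np.ndarray] = []
    missing: list[str] = []
    for w in seen:
        key = table.lookup(w)
        if key is None:
            missing.append(w)
        else:
            found.append(w)
            rows.append(table.entries[key])
    matrix = np.vstack(rows) if rows else np.empty((0, table.dim))
    return matrix, found, missing


def get_term_vectors(
    table: EmbeddingTable, terms: Sequence[str], phrase_policy: str = "average"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Look up lexicon terms, where a term may be a multi-token phrase.

    Translated lexica sometimes render a single English word as a phrase.
    Under the default ``"average"`` policy a phrase's vector is the mean of
    its token vectors, provided *all* tokens are in-vocabulary; otherwise
    the term counts as missing.  ``"skip"`` treats every multi-token term
    as missing.
    """
    if phrase_policy not in ("average", "skip"):
        raise ValueError(f"phrase_policy must be 'average' or 'skip', got {phrase_policy!r}")
    if len(terms) == 0:
        raise ValueError("terms must be non-empty")
    found: list[str] = []
    rows: list[np.ndarray] = []
    missing: list[str] = []
    for term in dict.fromkeys(terms):
        tokens = term.split()
        if len(tokens) == 1:
            key = table.lookup(term)
            if key is None:
                missing.append(term)
            else:
                found.append(term)
                rows.append(table.entries[key])
            continue
        if phrase_policy == "skip":
            missing.append(term)
            continue
        keys = [table.lookup(t) for t in tokens]
        if any(k is None for k in keys):
            missing.append(term)
        else:
            found.append(term)
            rows.append(np.mean([table.entries[k] for k in keys], axis=0))
    matrix = np.vstack(rows) if rows else np.empty((0, table.dim))
    return matrix, found, missing
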