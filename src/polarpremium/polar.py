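"""Semantic-axis projection: direction matrices and association scores.

An axis (e.g. Success--Failure) is spanned by antonym word pairs.  Each
pair contributes one unit *direction vector*, the normalised difference
between its positive- and negative-pole vectors; stacking the rows gives
the axis's direction matrix.  A word's association with the axis is the
scalar projection of its vector onto each direction, averaged over pairs;
a concept's score averages its words' scores once more, so that word-list
length does not weight the result.  Positive scores mean association with
the declared positive pole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embeddings import EmbeddingTable, get_term_vectors
from .lexicon import Axis, Concept
from .stats import mean_ci

__all__ = ["DirectionMatrix", "WordScore", "ConceptScore", "build_direction_matrix", "score_word", "score_concept"]

#: unit-norm tolerance for direction rows
NORM_TOL = 1e-9


@dataclass
class DirectionMatrix:
    """Stacked unit direction vectors for one axis, one row per antonym pair."""

    axis: str
    rows: np.ndarray  # P x D
    pair_labels: list[str]
    used_pairs: list[tuple[str, str]]
    dropped_pairs: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    positive_label: str = ""
    negative_label: str = ""

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.shape[0] < 1:
            raise ValueError("direction matrix needs at least one row")
        norms = np.linalg.norm(self.rows, axis=1)
        if not np.allclose(norms, 1.0, atol=NORM_TOL, rtol=0):
            raise ValueError(f"direction rows must have unit norm; got norms {norms}")
        if len(self.pair_labels) != self.rows.shape[0]:
            raise ValueError("pair_labels must align with rows")

    @property
    def n_pairs(self) -> int:
        return self.rows.shape[0]


@dataclass
class WordScore:
    """Per-pair projections of one word onto an axis, with their mean and CI.

    The mean is the arithmetic mean of the per-pair values; the confidence
    interval is the t-based interval over the per-pair values (each
    antonym pair treated as one observation of the word's association),
    undefined (NaN) when the axis has a single pair.
    """

    word: str
    per_pair: np.ndarray
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class ConceptScore:
    """Aggregated association of a concept with an axis.

    The concept mean is the unweighted mean of the word means; the CI is
    the t-based 95% interval over word means, each in-vocabulary word one
    independent observation.
    """

    concept: str
    axis: str
    word_scores: list[WordScore]
    mean: float
    ci_low: float
    ci_high: float
    missing_words: list[str] = field(default_factory=list)

    @property
    def n_words(self) -> int:
        return len(self.word_scores)

    @property
    def word_means(self) -> np.ndarray:
        return np.array([w.mean for w in self.word_scores])


def build_direction_matrix(axis: Axis, table: EmbeddingTable) -> DirectionMatrix:
    """Build the direction matrix of an axis from an embedding table.

    Row i is ``(v(pos_i) - v(neg_i)) / ||v(pos_i) - v(neg_i)||``.  Pairs
    with a missing pole or a zero-norm difference are dropped and recorded
    with the reason; identical duplicated pairs are kept as distinct
    observations.  Raises if every pair is dropped.
    """
    rows: list[np.ndarray] = []
    labels: list[str] = []
    used: list[tuple[str, str]] = []
    dropped: list[tuple[tuple[str, str], str]] = []
    for pos, neg in axis.pairs:
        vpos = _pole_vector(table, pos)
        vneg = _pole_vector(table, neg)
        if vpos is None or vneg is None:
            which = [w for w, v in ((pos, vpos), (neg, vneg)) if v is None]
            dropped.append(((pos, neg), f"missing pole word(s): {', '.join(which)}"))
            continue
        diff = vpos - vneg
        norm = np.linalg.norm(diff)
        if norm == 0:
            dropped.append(((pos, neg), "zero-norm difference (identical pole vectors)"))
            continue
        rows.append(diff / norm)
        labels.append(f"{pos}-{neg}")
        used.append((pos, neg))
    if not rows:
        raise ValueError(
            f"axis {axis.name!r} unrepresentable in this embedding: all pairs dropped "
            f"({[r for _, r in dropped]})"
        )
    return DirectionMatrix(
        axis=axis.name,
        rows=np.vstack(rows),
        pair_labels=labels,
        used_pairs=used,
        dropped_pairs=dropped,
        positive_label=axis.positive_label,
        negative_label=axis.negative_label,
    )


def _pole_vector(table: EmbeddingTable, term: str) -> np.ndarray | None:
    matrix, found, _ = get_term_vectors(table, [term])
    return matrix[0] if found else None


def _score_vector(
    vec: np.ndarray, dirmat: DirectionMatrix, normalize: bool, ci_level: float
) -> tuple[np.ndarray, float, float, float]:
    if normalize:
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValueError("cannot normalise a zero word vector")
        vec = vec / norm
    per_pair = dirmat.rows @ vec
    mean = float(per_pair.mean())
    if per_pair.size >= 2:
        low, high = mean_ci(per_pair, level=ci_level)
    else:
        low = high = float("nan")
    return per_pair, mean, low, high


def score_word(
    word: str,
    dirmat: DirectionMatrix,
    table: EmbeddingTable,
    normalize_words: bool = False,
    ci_level: float = 0.95,
) -> WordScore:
    """Project one word onto every pair direction of an axis.

    ``per_pair[i]`` is the dot product of the word vector with the unit
    direction of pair i; the word vector itself is not normalised unless
    ``normalize_words`` is set.  Raises KeyError for out-of-vocabulary
    words (phrases are resolved by token averaging).
    """
    matrix, found, missing = get_term_vectors(table, [word])
    if missing:
        raise KeyError(f"word {word!r} not in vocabulary")
    per_pair, mean, low, high = _score_vector(matrix[0], dirmat, normalize_words, ci_level)
    return WordScore(word=word, per_pair=per_pair, mean=mean, ci_low=low, ci_high=high)


def score_concept(
    concept: Concept,
    dirmat: DirectionMatrix,
    table: EmbeddingTable,
    normalize_words: bool = False,
    ci_level: float = 0.95,
    phrase_policy: str = "average",
) -> ConceptScore:
    """Score a concept on an axis: mean over words of mean over pairs.

    Out-of-vocabulary words are excluded and reported on
    ``missing_words``; the concept CI over word means is undefined (NaN)
    when a single word survives.  Raises if no concept word is
    in-vocabulary.
    """
    matrix, found, missing = get_term_vectors(table, concept.words, phrase_policy)
    if not found:
        raise ValueError(f"no word of concept {concept.name!r} is in-vocabulary")
    word_scores = []
    for word, vec in zip(found, matrix):
        per_pair, mean, low, high = _score_vector(vec, dirmat, normalize_words, ci_level)
        word_scores.append(WordScore(word=word, per_pair=per_pair, mean=mean, ci_low=low, ci_high=high))
    word_means = np.array([w.mean for w in word_scores])
    mean = float(word_means.mean())
    if word_means.size >= 2:
        low, high = mean_ci(word_means, level=ci_level)
    else:
        low = high = float("nan")
    return ConceptScore(
        concept=concept.name,
        axis=dirmat.axis,
        word_scores=word_scores,
        mean=mean,
        ci_low=low,
        ci_high=high,
        missing_words=missing,
    )
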