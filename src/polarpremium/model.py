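"""Model/Results interface over the projection core and the test layer.

``AxisAssociationModel`` holds the data (an embedding table, two concepts
and an axis); ``fit()`` performs the projection, the two-level averaging
and the Welch comparison, returning an ``AxisAssociationResults`` object
that carries the estimates, their confidence intervals, the test and a
``summary()`` table — the same division of labour as a statsmodels model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import EmbeddingTable, read_embeddings
from .lexicon import (
    Axis,
    Concept,
    CoverageReport,
    default_lexicon_path,
    load_lexicon,
    validate_coverage,
)
from .polar import ConceptScore, DirectionMatrix, build_direction_matrix, score_concept
from .stats import DEFAULT_ALPHA, PremiumRecord, compute_premium

__all__ = ["AxisAssociationModel", "AxisAssociationResults"]


class AxisAssociationModel:
    """Association of two opposed concepts with a semantic axis.

    Parameters
    ----------
    table : EmbeddingTable
        The language's word vectors.
    positive_concept, negative_concept : Concept
        The concept expected on the positive side (e.g. Beauty) and its
        opposite (e.g. Ugliness).
    axis : Axis
        The antonym-pair axis to project onto (e.g. Success--Failure).
    normalize_words : bool
        Unit-normalise word vectors before projection (default off: raw
        scalar projections).
    phrase_policy : {"average", "skip"}
        How multi-token lexicon terms are resolved.
    """

    def __init__(
        self,
        table: EmbeddingTable,
        positive_concept: Concept,
        negative_concept: Concept,
        axis: Axis,
        normalize_words: bool = False,
        phrase_policy: str = "average",
    ) -> None:
        self.table = table
        self.positive_concept = positive_concept
        self.negative_concept = negative_concept
        self.axis = axis
        self.normalize_words = normalize_words
        self.phrase_policy = phrase_policy

    @classmethod
    def from_files(
        cls,
        embedding_path: str | Path,
        language: str,
        axis_name: str,
        lexicon_path: str | Path | None = None,
        positive_concept: str = "beauty",
        negative_concept: str = "ugliness",
        max_words: int | None = None,
        lowercase: bool = False,
        **kwargs,
    ) -> "AxisAssociationModel":
        """Build a model straight from an embedding file and a lexicon file."""
        table = read_embeddings(embedding_path, max_words=max_words, lowercase=lowercase, language=language)
        concepts, axes = load_lexicon(lexicon_path or default_lexicon_path(), language)
        cmap = {c.name: c for c in concepts}
        amap = {a.name: a for a in axes}
        for name in (positive_concept, negative_concept):
            if name not in cmap:
                raise KeyError(f"concept {name!r} not in lexicon (has: {sorted(cmap)})")
        if axis_name not in amap:
            raise KeyError(f"axis {axis_name!r} not in lexicon (has: {sorted(amap)})")
        return cls(table, cmap[positive_concept], cmap[negative_concept], amap[axis_name], **kwargs)

    def coverage(self, min_coverage: float = 0.5) -> CoverageReport:
        """In-vocabulary coverage of the model's lexicon entries."""
        return validate_coverage(
            [self.positive_concept, self.negative_concept],
            [self.axis],
            self.table,
            min_coverage=min_coverage,
            phrase_policy=self.phrase_policy,
        )

    def fit(self, alpha: float = DEFAULT_ALPHA, ci_level: float = 0.95) -> "AxisAssociationResults":
        """Project, aggregate and test; returns the results object."""
        dirmat = build_direction_matrix(self.axis, self.table)
        pos = score_concept(
            self.positive_concept, dirmat, self.table,
            normalize_words=self.normalize_words, ci_level=ci_level,
            phrase_policy=self.phrase_policy,
        )
        neg = score_concept(
            self.negative_concept, dirmat, self.table,
            normalize_words=self.normalize_words, ci_level=ci_level,
            phrase_policy=self.phrase_policy,
        )
        record = compute_premium(pos, neg, alpha=alpha, language=self.table.language)
        return AxisAssociationResults(model=self, direction_matrix=dirmat, record=record)


@dataclass
class AxisAssociationResults:
    """Fitted association scores, their uncertainty and the group test."""

    model: AxisAssociationModel
    direction_matrix: DirectionMatrix
    record: PremiumRecord

    @property
    def difference(self) -> float:
        return self.record.difference

    @property
    def pvalue(self) -> float:
        return self.record.test.p_value

    @property
    def label(self) -> str:
        return self.record.label

    def concept_frame(self) -> pd.DataFrame:
        """Concept-level estimates, one row per concept."""
        rows = []
        for score in (self.record.beauty, self.record.ugliness):
            rows.append(
                {
                    "concept": score.concept,
                    "axis": score.axis,
                    "mean": score.mean,
                    "ci_low": score.ci_low,
                    "ci_high": score.ci_high,
                    "n_words": score.n_words,
                    "missing_words": ",".join(score.missing_words),
                }
            )
        return pd.DataFrame(rows)

    def word_frame(self) -> pd.DataFrame:
        """Per-word scores with their per-pair dispersion intervals."""
        rows = []
        for score in (self.record.beauty, self.record.ugliness):
            for w in score.word_scores:
                rows.append(
                    {
                        "concept": score.concept,
                        "word": w.word,
                        "mean": w.mean,
                        "ci_low": w.ci_low,
                        "ci_high": w.ci_high,
                        "per_pair": list(np.round(w.per_pair, 12)),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        rec = self.record
        dm = self.direction_matrix
        lines = [
            "Axis association (semantic-axis projection)",
            "=" * 60,
            f"language: {rec.language}    axis: {rec.axis} "
            f"({dm.positive_label} vs {dm.negative_label})",
            f"pairs used: {dm.n_pairs}"
            + (f"    dropped: {len(dm.dropped_pairs)}" if dm.dropped_pairs else ""),
            "-" * 60,
            f"{'concept':<14}{'mean':>10}{'ci_low':>10}{'ci_high':>10}{'n':>5}",
        ]
        for s in (rec.beauty, rec.ugliness):
            lines.append(f"{s.concept:<14}{s.mean:>10.4f}{s.ci_low:>10.4f}{s.ci_high:>10.4f}{s.n_words:>5d}")
        t = rec.test
        lines += [
            "-" * 60,
            f"difference ({rec.beauty.concept} - {rec.ugliness.concept}): {rec.difference:.4f} "
            f"[{t.ci_low:.4f}, {t.ci_high:.4f}]",
            f"Welch t = {t.t_statistic:.3f}, df = {t.degrees_of_freedom:.1f}, p = {t.p_value:.3g}",
            f"label (alpha = {rec.alpha:g}): {rec.label}",
        ]
        return "\n".join(lines)
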