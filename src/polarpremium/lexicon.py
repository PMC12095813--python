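"""Concept word lists and antonym-pair axes, per language.

A lexicon file is a UTF-8 YAML document with one block per language::

    languages:
      en:
        concepts:
          beauty:
            words: [beautiful, attractive, handsome]
        axes:
          success_failure:
            positive_label: Success
            negative_label: Failure
            pairs:
              - [successful, unsuccessful]
              - [victorious, failed]

Pair order is ``[positive_pole, negative_pole]``; the positive pole is
declared explicitly and never inferred from context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .embeddings import EmbeddingTable, get_term_vectors

__all__ = [
    "Concept",
    "Axis",
    "CoverageReport",
    "load_lexicon",
    "save_lexicon",
    "default_lexicon_path",
    "validate_coverage",
]

DEFAULT_MIN_COVERAGE = 0.5


@dataclass
class Concept:
    """A named concept represented by a curated, non-empty word list."""

    name: str
    language: str
    words: list[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError(f"concept {self.name!r} has an empty word list")
        normalised = [w.strip() for w in self.words]
        if any(not w for w in normalised):
            raise ValueError(f"concept {self.name!r} contains a blank word")
        if len(set(w.lower() for w in normalised)) != len(normalised):
            raise ValueError(f"concept {self.name!r} has duplicate words after case-folding")
        self.words = normalised


@dataclass
class Axis:
    """A two-poled semantic scale defined by antonym word pairs.

    ``pairs`` lists ``(positive_pole_word, negative_pole_word)`` tuples;
    a word scoring positive on the axis is more associated with the
    positive pole (e.g. *Success*) than the negative one (*Failure*).
    """

    name: str
    language: str
    pairs: list[tuple[str, str]]
    positive_label: str = ""
    negative_label: str = ""

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"axis {self.name!r} has no antonym pairs")
        clean: list[tuple[str, str]] = []
        for pos, neg in self.pairs:
            pos, neg = pos.strip(), neg.strip()
            if not pos or not neg:
                raise ValueError(f"axis {self.name!r} has a blank pole word")
            if pos == neg:
                raise ValueError(f"axis {self.name!r}: pair ({pos!r}, {neg!r}) has identical poles")
            clean.append((pos, neg))
        self.pairs = clean
        if not self.positive_label:
            self.positive_label = self.pairs[0][0]
        if not self.negative_label:
            self.negative_label = self.pairs[0][1]


@dataclass
class CoverageEntry:
    name: str
    kind: str  # "concept" | "axis"
    total: int
    found: int
    missing: list[str] = field(default_factory=list)
    flagged: bool = False

    @property
    def coverage(self) -> float:
        return self.found / self.total


@dataclass
class CoverageReport:
    """Per concept/axis in-vocabulary coverage against one embedding table.

    An axis pair counts as covered only when *both* pole words resolve.
    """

    language: str
    min_coverage: float
    entries: list[CoverageEntry] = field(default_factory=list)

    @property
    def flagged(self) -> list[CoverageEntry]:
        return [e for e in self.entries if e.flagged]

    def entry(self, name: str) -> CoverageEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "language": self.language,
            "min_coverage": self.min_coverage,
            "entries": [
                {
                    "name": e.name,
                    "kind": e.kind,
                    "total": e.total,
                    "found": e.found,
                    "coverage": e.coverage,
                    "missing": list(e.missing),
                    "flagged": e.flagged,
                }
                for e in self.entries
            ],
        }


def default_lexicon_path() -> Path:
    """Path of the English lexicon shipped with the package."""
    return Path(resources.files("polarpremium").joinpath("data", "lexicon_en.yaml"))


def load_lexicon(path: str | Path, language: str) -> tuple[list[Concept], list[Axis]]:
    """Load the concepts and axes of one language from a lexicon file.

    Entries for other languages are ignored.  Raises on an unknown
    language, an empty concept, or a pair with identical poles.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "languages" not in doc:
        raise ValueError(f"{path}: lexicon file must have a top-level 'languages' mapping")
    langs = doc["languages"]
    if language not in langs:
        raise KeyError(f"language {language!r} not in lexicon (has: {sorted(langs)})")
    block = langs[language] or {}
    concepts = [
        Concept(name=name, language=language, words=list(spec["words"]))
        for name, spec in (block.get("concepts") or {}).items()
    ]
    axes = []
    for name, spec in (block.get("axes") or {}).items():
        pairs = [(str(p[0]), str(p[1])) for p in spec["pairs"]]
        axes.append(
            Axis(
                name=name,
                language=language,
                pairs=pairs,
                positive_label=str(spec.get("positive_label", "")),
                negative_label=str(spec.get("negative_label", "")),
            )
        )
    return concepts, axes


def save_lexicon(
    concepts: list[Concept], axes: list[Axis], path: str | Path
) -> Path:
    """Serialise concepts/axes back to the lexicon YAML format (round-trippable)."""
    by_lang: dict[str, dict] = {}
    for c in concepts:
        by_lang.setdefault(c.language, {"concepts": {}, "axes": {}})["concepts"][c.name] = {
            "words": list(c.words)
        }
    for a in axes:
        by_lang.setdefault(a.language, {"concepts": {}, "axes": {}})["axes"][a.name] = {
            "positive_label": a.positive_label,
            "negative_label": a.negative_label,
            "pairs": [list(p) for p in a.pairs],
        }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"languages": by_lang}, fh, allow_unicode=True, sort_keys=True)
    return path


def validate_coverage(
    concepts: list[Concept],
    axes: list[Axis],
    table: EmbeddingTable,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    phrase_policy: str = "average",
) -> CoverageReport:
    """Report which lexicon terms resolve in an embedding table.

    A concept term is covered if it resolves (phrases per ``phrase_policy``);
    an axis pair is covered only if both pole words resolve.  Entries whose
    coverage falls below ``min_coverage`` are flagged; acting on the flag
    (e.g. excluding the language) is downstream policy.
    """
    if not 0 <= min_coverage <= 1:
        raise ValueError("min_coverage must lie in [0, 1]")
    report = CoverageReport(language=table.language, min_coverage=min_coverage)
    for concept in concepts:
        _, found, missing = get_term_vectors(table, concept.words, phrase_policy)
        entry = CoverageEntry(
            name=concept.name,
            kind="concept",
            total=len(concept.words),
            found=len(found),
            missing=missing,
        )
        entry.flagged = entry.coverage < min_coverage
        report.entries.append(entry)
    for axis in axes:
        missing_pairs: list[str] = []
        n_found = 0
        for pos, neg in axis.pairs:
            if table.lookup(pos) is not None and table.lookup(neg) is not None:
                n_found += 1
            else:
                missing_pairs.append(f"{pos}/{neg}")
        entry = CoverageEntry(
            name=axis.name,
            kind="axis",
            total=len(axis.pairs),
            found=n_found,
            missing=missing_pairs,
        )
        entry.flagged = entry.coverage < min_coverage
        report.entries.append(entry)
    return report
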