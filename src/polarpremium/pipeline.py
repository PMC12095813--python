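"""Cross-language orchestration: run the axis association per language,
serialise result tables, and join premia onto countries.

A run config is a YAML file::

    lexicon: path/to/lexicon.yaml      # optional; default shipped lexicon
    axes: [success_failure]
    positive_concept: beauty
    negative_concept: ugliness
    languages:
      - language: en
        embeddings: path/to/en.vec
    options:
      lowercase: false
      normalize_words: false
      min_coverage: 0.5
      alpha: 0.05
      max_words: null

Per-language failures are isolated: a bad embedding file excludes that
language (with the reason recorded) and never aborts the run.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .embeddings import read_embeddings
from .lexicon import (
    DEFAULT_MIN_COVERAGE,
    CoverageReport,
    default_lexicon_path,
    load_lexicon,
    validate_coverage,
)
from .polar import ConceptScore, WordScore, build_direction_matrix, score_concept
from .stats import DEFAULT_ALPHA, PremiumRecord, TestResult, compute_premium, holm_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "LanguageResult",
    "CountryRecord",
    "load_run_config",
    "run_all",
    "map_countries",
    "read_mapping",
    "write_results",
    "read_results",
]

_COUNTRY_RE = re.compile(r"^[A-Z]{2,3}$")

TSV_COLUMNS = [
    "language", "axis", "excluded", "reason",
    "beauty_mean", "beauty_ci_low", "beauty_ci_high", "beauty_n",
    "ugliness_mean", "ugliness_ci_low", "ugliness_ci_high", "ugliness_n",
    "difference", "diff_ci_low", "diff_ci_high",
    "t_statistic", "df", "p_value", "p_holm", "label",
]


@dataclass
class RunConfig:
    languages: list[tuple[str, str]]  # (language code, embedding path)
    lexicon_path: str
    axes: list[str]
    positive_concept: str = "beauty"
    negative_concept: str = "ugliness"
    lowercase: bool = False
    normalize_words: bool = False
    min_coverage: float = DEFAULT_MIN_COVERAGE
    alpha: float = DEFAULT_ALPHA
    max_words: int | None = None
    phrase_policy: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        codes = [lang for lang, _ in self.languages]
        if len(set(codes)) != len(codes):
            raise ValueError("language codes must be unique in a run config")
        if not self.axes:
            raise ValueError("run config lists no axes")


@dataclass
class LanguageResult:
    language: str
    records: list[PremiumRecord] = field(default_factory=list)
    coverage: CoverageReport | None = None
    excluded: bool = False
    reason: str = ""


@dataclass
class CountryRecord:
    """Premium value joined onto a country via its primary language.

    ``value`` is None (the no-data marker) iff the country's primary
    language is absent from the results for the chosen axis.
    """

    country: str
    language: str
    value: float | None
    label: str | None


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    opts = doc.get("options") or {}
    languages = [(str(e["language"]), str(Path(path).parent / e["embeddings"])) for e in doc["languages"]]
    lexicon = doc.get("lexicon")
    lexicon_path = str(Path(path).parent / lexicon) if lexicon else str(default_lexicon_path())
    return RunConfig(
        languages=languages,
        lexicon_path=lexicon_path,
        axes=[str(a) for a in doc["axes"]],
        positive_concept=str(doc.get("positive_concept", "beauty")),
        negative_concept=str(doc.get("negative_concept", "ugliness")),
        lowercase=bool(opts.get("lowercase", False)),
        normalize_words=bool(opts.get("normalize_words", False)),
        min_coverage=float(opts.get("min_coverage", DEFAULT_MIN_COVERAGE)),
        alpha=float(opts.get("alpha", DEFAULT_ALPHA)),
        max_words=opts.get("max_words"),
        seed=int(opts.get("seed", 0)),
    )


def _run_language(config: RunConfig, language: str, emb_path: str) -> LanguageResult:
    table = read_embeddings(emb_path, max_words=config.max_words, lowercase=config.lowercase, language=language)
    concepts, axes = load_lexicon(config.lexicon_path, language)
    cmap = {c.name: c for c in concepts}
    amap = {a.name: a for a in axes}
    for name in (config.positive_concept, config.negative_concept):
        if name not in cmap:
            raise KeyError(f"concept {name!r} missing from lexicon for {language!r}")
    missing_axes = [a for a in config.axes if a not in amap]
    if missing_axes:
        raise KeyError(f"axes {missing_axes} missing from lexicon for {language!r}")
    wanted_axes = [amap[a] for a in config.axes]
    pos_c, neg_c = cmap[config.positive_concept], cmap[config.negative_concept]
    coverage = validate_coverage(
        [pos_c, neg_c], wanted_axes, table,
        min_coverage=config.min_coverage, phrase_policy=config.phrase_policy,
    )
    result = LanguageResult(language=language, coverage=coverage)
    for cname in (pos_c.name, neg_c.name):
        entry = coverage.entry(cname)
        if entry.flagged:
            result.excluded = True
            result.reason = (
                f"concept {cname!r} coverage {entry.coverage:.2f} below {config.min_coverage:g}"
            )
            return result
    for axis in wanted_axes:
        if coverage.entry(axis.name).flagged:
            logger.warning("%s: axis %s below coverage threshold, skipped", language, axis.name)
            continue
        dirmat = build_direction_matrix(axis, table)
        kwargs = dict(normalize_words=config.normalize_words, phrase_policy=config.phrase_policy)
        beauty = score_concept(pos_c, dirmat, table, **kwargs)
        ugliness = score_concept(neg_c, dirmat, table, **kwargs)
        result.records.append(compute_premium(beauty, ugliness, alpha=config.alpha, language=language))
    if not result.records:
        result.excluded = True
        result.reason = "no requested axis met the coverage threshold"
    return result


def run_all(config: RunConfig) -> list[LanguageResult]:
    """Run the full analysis for every language in the config.

    Deterministic given the config; each language is processed
    independently and failures are converted into excluded results with
    the error message as the reason.  Raises only if no language is
    runnable at all.
    """
    results: list[LanguageResult] = []
    for language, emb_path in config.languages:
        try:
            results.append(_run_language(config, language, emb_path))
        except Exception as exc:  # noqa: BLE001 - per-language isolation is the contract
            logger.error("language %s failed: %s", language, exc)
            results.append(LanguageResult(language=language, excluded=True, reason=str(exc)))
    if all(r.excluded for r in results):
        raise RuntimeError("no language in the run config was runnable")
    return results


def read_mapping(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (country, language) delimited text file.

    Comment lines start with '#'; malformed rows or invalid country codes
    are reported and skipped.
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[\t,;]+|\s{2,}|\s", line)
            parts = [p for p in parts if p]
            if len(parts) != 2 or not _COUNTRY_RE.match(parts[0]):
                logger.warning("%s:%d: malformed mapping row %r skipped", path, lineno, line)
                continue
            rows.append((parts[0], parts[1]))
    return rows


def map_countries(
    results: list[LanguageResult], mapping: list[tuple[str, str]], axis: str
) -> list[CountryRecord]:
    """Join each country's primary language onto its premium for one axis."""
    by_lang: dict[str, PremiumRecord] = {}
    for res in results:
        if res.excluded:
            continue
        for rec in res.records:
            if rec.axis == axis:
                by_lang[res.language] = rec
    records = []
    for country, language in mapping:
        rec = by_lang.get(language)
        if rec is None:
            records.append(CountryRecord(country=country, language=language, value=None, label=None))
        else:
            records.append(CountryRecord(country=country, language=language, value=rec.difference, label=rec.label))
    return records


# ---------------------------------------------------------------------------
# serialisation

def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return format(float(x), ".12g")


def _word_score_dict(w: WordScore) -> dict:
    return {
        "word": w.word,
        "per_pair": [float(v) for v in w.per_pair],
        "mean": w.mean,
        "ci_low": w.ci_low,
        "ci_high": w.ci_high,
    }


def _concept_dict(s: ConceptScore, include_words: bool) -> dict:
    d = {
        "concept": s.concept,
        "axis": s.axis,
        "mean": s.mean,
        "ci_low": s.ci_low,
        "ci_high": s.ci_high,
        "n_words": s.n_words,
        "missing_words": list(s.missing_words),
    }
    if include_words:
        d["word_scores"] = [_word_score_dict(w) for w in s.word_scores]
    return d


def _record_dict(rec: PremiumRecord, include_words: bool) -> dict:
    t = rec.test
    return {
        "language": rec.language,
        "axis": rec.axis,
        "beauty": _concept_dict(rec.beauty, include_words),
        "ugliness": _concept_dict(rec.ugliness, include_words),
        "difference": rec.difference,
        "test": {
            "t_statistic": t.t_statistic,
            "degrees_of_freedom": t.degrees_of_freedom,
            "p_value": t.p_value,
            "n_a": t.n_a,
            "n_b": t.n_b,
            "ci_low": t.ci_low,
            "ci_high": t.ci_high,
        },
        "label": rec.label,
        "alpha": rec.alpha,
    }


def _holm_by_axis(results: list[LanguageResult]) -> dict[tuple[str, str], float]:
    """Holm-adjusted p-values within each axis across languages (extension)."""
    out: dict[tuple[str, str], float] = {}
    by_axis: dict[str, list[tuple[str, float]]] = {}
    for res in results:
        for rec in res.records:
            by_axis.setdefault(rec.axis, []).append((res.language, rec.test.p_value))
    for axis, entries in by_axis.items():
        adj = holm_adjust([p for _, p in entries])
        for (language, _), q in zip(entries, adj):
            out[(language, axis)] = float(q)
    return out


def write_results(
    results: list,
    path: str | Path,
    fmt: str = "tsv",
    include_words: bool = False,
) -> Path:
    """Serialise LanguageResults or CountryRecords to TSV or JSON.

    Column order is stable; numbers carry 12 significant digits so a
    re-read reproduces them to that precision, and identical inputs give
    byte-identical output.  The ``p_holm`` column is a Holm family-wise
    adjustment across languages within an axis, an extension beyond the
    per-language labels.
    """
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unsupported format {fmt!r}; supported: tsv, json")
    if not results:
        raise ValueError("results must be non-empty")
    path = Path(path)
    if results and isinstance(results[0], CountryRecord):
        return _write_countries(results, path, fmt)
    holm = _holm_by_axis(results)
    if fmt == "json":
        doc = []
        for res in results:
            doc.append(
                {
                    "language": res.language,
                    "excluded": res.excluded,
                    "reason": res.reason,
                    "coverage": res.coverage.to_dict() if res.coverage else None,
                    "records": [
                        {**_record_dict(r, include_words), "p_holm": holm[(res.language, r.axis)]}
                        for r in res.records
                    ],
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path
    lines = ["\t".join(TSV_COLUMNS)]
    for res in results:
        if res.excluded:
            row = [res.language, "", "true", res.reason] + [""] * 15 + [""]
            lines.append("\t".join(row))
            continue
        for rec in res.records:
            t = rec.test
            row = [
                res.language, rec.axis, "false", "",
                _fmt(rec.beauty.mean), _fmt(rec.beauty.ci_low), _fmt(rec.beauty.ci_high), str(rec.beauty.n_words),
                _fmt(rec.ugliness.mean), _fmt(rec.ugliness.ci_low), _fmt(rec.ugliness.ci_high), str(rec.ugliness.n_words),
                _fmt(rec.difference), _fmt(t.ci_low), _fmt(t.ci_high),
                _fmt(t.t_statistic), _fmt(t.degrees_of_freedom), _fmt(t.p_value),
                _fmt(holm[(res.language, rec.axis)]), rec.label,
            ]
            lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _write_countries(records: list[CountryRecord], path: Path, fmt: str) -> Path:
    if fmt == "json":
        doc = [
            {"country": r.country, "language": r.language, "value": r.value, "label": r.label}
            for r in records
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path
    lines = ["\t".join(["country", "language", "value", "label"])]
    for r in records:
        lines.append("\t".join([r.country, r.language, _fmt(r.value), r.label or "no_data"]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_results(path: str | Path) -> list[LanguageResult]:
    """Re-read a JSON results file written by :func:`write_results`.

    Word-level scores are restored when the file was written with
    ``include_words=True``; coverage reports are not reconstructed.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    results = []
    for entry in doc:
        res = LanguageResult(
            language=entry["language"], excluded=entry["excluded"], reason=entry.get("reason", "")
        )
        for rd in entry.get("records", []):
            beauty = _concept_from_dict(rd["beauty"])
            ugliness = _concept_from_dict(rd["ugliness"])
            td = rd["test"]
            test = TestResult(
                t_statistic=td["t_statistic"],
                degrees_of_freedom=td["degrees_of_freedom"],
                p_value=td["p_value"],
                n_a=td["n_a"],
                n_b=td["n_b"],
                ci_low=td["ci_low"],
                ci_high=td["ci_high"],
            )
            res.records.append(
                PremiumRecord(
                    language=rd["language"],
                    axis=rd["axis"],
                    beauty=beauty,
                    ugliness=ugliness,
                    difference=rd["difference"],
                    test=test,
                    label=rd["label"],
                    alpha=rd.get("alpha", DEFAULT_ALPHA),
                )
            )
        results.append(res)
    return results


def _concept_from_dict(d: dict) -> ConceptScore:
    import numpy as np

    word_scores = [
        WordScore(
            word=w["word"],
            per_pair=np.asarray(w["per_pair"], dtype=float),
            mean=w["mean"],
            ci_low=w["ci_low"],
            ci_high=w["ci_high"],
        )
        for w in d.get("word_scores", [])
    ]
    return ConceptScore(
        concept=d["concept"],
        axis=d["axis"],
        word_scores=word_scores,
        mean=d["mean"],
        ci_low=d["ci_low"],
        ci_high=d["ci_high"],
        missing_words=list(d.get("missing_words", [])),
    )
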