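import numpy as np
import pytest

from polarpremium.embeddings import EmbeddingTable
from polarpremium.lexicon import Axis, Concept


@pytest.fixture
def tiny_table() -> EmbeddingTable:
    """Three words on a 3-d axis: good at +x, bad at -x, neutral at +y."""
    return EmbeddingTable(
        language="en",
        dim=3,
        entries={
            "good": np.array([1.0, 0.0, 0.0]),
            "bad": np.array([-1.0, 0.0, 0.0]),
            "neutral": np.array([0.0, 1.0, 0.0]),
        },
    )


@pytest.fixture
def good_bad_axis() -> Axis:
    return Axis("good_bad", "en", [("good", "bad")], "Good", "Bad")


def random_table(rng: np.random.Generator, n_words: int, dim: int, language: str = "en") -> EmbeddingTable:
    words = [f"w{i}" for i in range(n_words)]
    return EmbeddingTable(
        language=language,
        dim=dim,
        entries={w: rng.standard_normal(dim) for w in words},
    )


def random_axis(rng: np.random.Generator, table: EmbeddingTable, n_pairs: int, name: str = "ax") -> Axis:
    words = list(table.entries)
    pairs = []
    for _ in range(n_pairs):
        pos, neg = rng.choice(len(words), size=2, replace=False)
        pairs.append((words[pos], words[neg]))
    return Axis(name, table.language, pairs)


def write_vec(path, entries: dict[str, np.ndarray], dim: int, header=None) -> None:
    """Independent writer for word2vec text fixtures (not the package's)."""
    lines = [f"{header if header is not None else len(entries)} {dim}"]
    for word, vec in entries.items():
        lines.append(word + " " + " ".join(repr(float(v)) for v in vec))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
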