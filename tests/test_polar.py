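"""Direction matrices and association scores: examples, oracle, symmetries."""

import numpy as np
import pytest

from polarpremium.embeddings import EmbeddingTable
from polarpremium.lexicon import Axis, Concept
from polarpremium.polar import build_direction_matrix, score_concept, score_word
from polarpremium.synthetic import SyntheticConfig, generate, make_lexicon

from conftest import random_axis, random_table


def swap_axis(axis: Axis) -> Axis:
    return Axis(axis.name, axis.language, [(n, p) for p, n in axis.pairs],
                axis.negative_label, axis.positive_label)


def test_direction_row_is_normalised_difference():
    table = EmbeddingTable("en", 3, {"pos": np.array([2.0, 0, 0]), "neg": np.zeros(3)})
    dm = build_direction_matrix(Axis("ax", "en", [("pos", "neg")]), table)
    np.testing.assert_array_equal(dm.rows, [[1, 0, 0]])


def test_identical_pole_vectors_dropped():
    table = EmbeddingTable("en", 2, {"a": np.ones(2), "b": np.ones(2), "c": np.zeros(2)})
    dm = build_direction_matrix(Axis("ax", "en", [("a", "b"), ("a", "c")]), table)
    assert dm.n_pairs == 1
    assert dm.dropped_pairs[0][0] == ("a", "b")
    with pytest.raises(ValueError, match="unrepresentable"):
        build_direction_matrix(Axis("ax", "en", [("a", "b")]), table)


def test_missing_pole_dropped_with_reason(tiny_table, good_bad_axis):
    axis = Axis("ax", "en", [("good", "bad"), ("good", "zzz")])
    dm = build_direction_matrix(axis, tiny_table)
    assert dm.used_pairs == [("good", "bad")]
    assert "zzz" in dm.dropped_pairs[0][1]


def test_aligned_pole_pairs_give_identical_rows():
    """Pairs planted exactly at +u/-u all produce the direction u."""
    rng = np.random.default_rng(0)
    u = rng.standard_normal(6)
    u /= np.linalg.norm(u)
    entries = {}
    for i in range(3):
        entries[f"p{i}"] = u.copy()
        entries[f"n{i}"] = -u
    table = EmbeddingTable("en", 6, entries)
    axis = Axis("ax", "en", [(f"p{i}", f"n{i}") for i in range(3)])
    dm = build_direction_matrix(axis, table)
    np.testing.assert_allclose(dm.rows, np.tile(u, (3, 1)), atol=1e-12)


def test_score_word_examples(tiny_table, good_bad_axis):
    tiny_table.entries["half"] = np.array([0.5, 0.0, 0.0])
    dm = build_direction_matrix(good_bad_axis, tiny_table)
    ws = score_word("half", dm, tiny_table)
    np.testing.assert_array_equal(ws.per_pair, [0.5])
    assert ws.mean == 0.5
    assert np.isnan(ws.ci_low)  # single pair: per-word CI undefined
    # orthogonal word scores zero
    assert score_word("neutral", dm, tiny_table).mean == 0.0
    with pytest.raises(KeyError):
        score_word("zzz", dm, tiny_table)


def test_score_matches_nested_loop_oracle():
    """Matrix-based projections equal an independent nested-loop dot product."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        dim = int(rng.integers(3, 11))
        table = random_table(rng, 12, dim)
        axis = random_axis(rng, table, int(rng.integers(1, 4)))
        dm = build_direction_matrix(axis, table)
        words = rng.choice(list(table.entries), size=3, replace=False)
        for word in words:
            ws = score_word(word, dm, table)
            v = table.entries[word]
            for i, (pos, neg) in enumerate(dm.used_pairs):
                diff = table.entries[pos] - table.entries[neg]
                norm = sum(float(x) * float(x) for x in diff) ** 0.5
                expected = sum(float(a) * float(b) for a, b in zip(v, diff)) / norm
                assert abs(ws.per_pair[i] - expected) <= 1e-12
            assert abs(ws.mean - np.mean(ws.per_pair)) <= 1e-12


def test_concept_mean_and_degenerate_ci(tiny_table, good_bad_axis):
    tiny_table.entries["w1"] = np.array([0.2, 0.0, 0.0])
    tiny_table.entries["w2"] = np.array([0.4, 0.0, 0.0])
    dm = build_direction_matrix(good_bad_axis, tiny_table)
    cs = score_concept(Concept("c", "en", ["w1", "w2"]), dm, tiny_table)
    assert cs.mean == pytest.approx(0.3, abs=1e-15)
    assert cs.ci_low <= cs.mean <= cs.ci_high
    # single in-vocabulary word: CI undefined, missing word reported
    cs1 = score_concept(Concept("c", "en", ["w1", "zzz"]), dm, tiny_table)
    assert cs1.mean == cs1.word_scores[0].mean
    assert np.isnan(cs1.ci_low) and cs1.missing_words == ["zzz"]
    with pytest.raises(ValueError, match="no word"):
        score_concept(Concept("c", "en", ["zzz"]), dm, tiny_table)


def test_planted_concept_mean_recovers_delta():
    """20 beauty words planted at projection 0.3 with sigma = 0.01 score ~0.3."""
    cfg = SyntheticConfig(dim=30, delta_beauty=0.3, delta_ugliness=-0.3,
                          n_words=20, noise_sigma=0.01, seed=5)
    table, _ = generate(cfg)
    concepts, axes = make_lexicon(cfg)
    dm = build_direction_matrix(axes[0], table)
    cs = score_concept(concepts[0], dm, table)
    assert 0.28 <= cs.mean <= 0.32


def test_pole_swap_antisymmetry():
    """Swapping (pos, neg) in every pair negates every score exactly."""
    rng = np.random.default_rng(7)
    table = random_table(rng, 15, 8)
    axis = random_axis(rng, table, 3)
    concept = Concept("c", "en", [w for w in table.entries][:6])
    dm = build_direction_matrix(axis, table)
    dm_swapped = build_direction_matrix(swap_axis(axis), table)
    cs = score_concept(concept, dm, table)
    cs_swapped = score_concept(concept, dm_swapped, table)
    for w, ws in zip(cs.word_scores, cs_swapped.word_scores):
        np.testing.assert_array_equal(ws.per_pair, -w.per_pair)
        assert ws.mean == -w.mean
    assert cs_swapped.mean == -cs.mean


def test_orthogonal_invariance():
    """One orthogonal transform applied to every vector leaves scores unchanged."""
    rng = np.random.default_rng(8)
    dim = 10
    table = random_table(rng, 12, dim)
    axis = random_axis(rng, table, 3)
    concept = Concept("c", "en", list(table.entries)[:5])
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    rotated = EmbeddingTable("en", dim, {w: q @ v for w, v in table.entries.items()})
    cs = score_concept(concept, build_direction_matrix(axis, table), table)
    cs_rot = score_concept(concept, build_direction_matrix(axis, rotated), rotated)
    np.testing.assert_allclose(
        [w.per_pair for w in cs_rot.word_scores],
        [w.per_pair for w in cs.word_scores],
        atol=1e-8,
    )
    assert cs_rot.mean == pytest.approx(cs.mean, abs=1e-8)


def test_positive_scaling_equivariance():
    """Scaling all vectors by c > 0 multiplies all scores by exactly c."""
    rng = np.random.default_rng(9)
    table = random_table(rng, 12, 6)
    axis = random_axis(rng, table, 2)
    concept = Concept("c", "en", list(table.entries)[:5])
    c = 2.5
    scaled = EmbeddingTable("en", 6, {w: c * v for w, v in table.entries.items()})
    cs = score_concept(concept, build_direction_matrix(axis, table), table)
    cs_scaled = score_concept(concept, build_direction_matrix(axis, scaled), scaled)
    np.testing.assert_allclose(cs_scaled.mean, c * cs.mean, rtol=1e-12)
    for w, ws in zip(cs.word_scores, cs_scaled.word_scores):
        np.testing.assert_allclose(ws.per_pair, c * w.per_pair, rtol=1e-12)
    # with normalize_words the scores are scale-free
    cs_n = score_concept(concept, build_direction_matrix(axis, table), table, normalize_words=True)
    cs_sn = score_concept(concept, build_direction_matrix(axis, scaled), scaled, normalize_words=True)
    assert cs_sn.mean == pytest.approx(cs_n.mean, rel=1e-12)


def test_word_and_pair_order_invariance():
    rng = np.random.default_rng(10)
    table = random_table(rng, 10, 5)
    axis = random_axis(rng, table, 3)
    words = list(table.entries)[:4]
    dm = build_direction_matrix(axis, table)
    cs = score_concept(Concept("c", "en", words), dm, table)
    axis_perm = Axis(axis.name, axis.language, axis.pairs[::-1])
    dm_perm = build_direction_matrix(axis_perm, table)
    cs_perm = score_concept(Concept("c", "en", words[::-1]), dm_perm, table)
    assert cs_perm.mean == pytest.approx(cs.mean, abs=1e-15)
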