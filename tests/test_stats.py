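"""Welch tests, t-intervals, premium records and their symmetries."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from polarpremium.polar import ConceptScore, WordScore
from polarpremium.stats import (
    LABEL_NEG,
    LABEL_NS,
    LABEL_POS,
    compute_premium,
    holm_adjust,
    mean_ci,
    welch_t,
)
from polarpremium.synthetic import SyntheticConfig, estimate_premium, recovery_experiment


def welch_oracle(a, b):
    """Independent hand-coded evaluation of the Welch formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def make_concept(means, axis="ax", name="c"):
    ws = [WordScore(f"w{i}", np.array([m]), float(m), np.nan, np.nan) for i, m in enumerate(means)]
    return ConceptScore(concept=name, axis=axis, word_scores=ws,
                        mean=float(np.mean(means)), ci_low=np.nan, ci_high=np.nan)


def test_welch_identical_samples():
    res = welch_t([1, 2, 3], [1, 2, 3])
    assert res.t_statistic == 0 and res.p_value == pytest.approx(1.0)


def test_welch_matches_formula_oracle():
    rng = np.random.default_rng(1)
    cases = [([1, 2, 3], [2, 3, 4])] + [
        (rng.standard_normal(int(rng.integers(3, 12))).tolist(),
         (1 + rng.standard_normal(int(rng.integers(3, 12)))).tolist())
        for _ in range(20)
    ]
    for a, b in cases:
        res = welch_t(a, b)
        t, df, p = welch_oracle(a, b)
        assert res.t_statistic == pytest.approx(t, rel=1e-12)
        assert res.degrees_of_freedom == pytest.approx(df, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-10)


def test_welch_sample_size_and_degenerate():
    with pytest.raises(ValueError):
        welch_t([0, 0], [1])
    # zero variance in both samples, equal means: defined as t=0, p=1
    res = welch_t([2, 2, 2], [2, 2])
    assert res.t_statistic == 0 and res.p_value == 1
    res = welch_t([3, 3], [2, 2])
    assert res.t_statistic == np.inf and res.p_value == 0


def test_welch_swap_antisymmetry():
    rng = np.random.default_rng(4)
    a, b = rng.standard_normal(6), 0.5 + rng.standard_normal(8)
    r1, r2 = welch_t(a, b), welch_t(b, a)
    assert r2.t_statistic == pytest.approx(-r1.t_statistic, rel=1e-12)
    assert r2.p_value == pytest.approx(r1.p_value, rel=1e-12)


def test_mean_ci_examples():
    assert mean_ci([5, 5, 5, 5]) == (5, 5)
    low, high = mean_ci([0.0, 1.0], level=0.95)
    # hand evaluation: mean 0.5, s = sqrt(0.5), half-width t_{0.975,1}*s/sqrt(2)
    half = sps.t.ppf(0.975, 1) * math.sqrt(0.5) / math.sqrt(2)
    assert low == pytest.approx(0.5 - half, rel=1e-12)
    assert high == pytest.approx(0.5 + half, rel=1e-12)
    with pytest.raises(ValueError):
        mean_ci([1, 2], level=1.5)
    assert all(np.isnan(mean_ci([1.0])))


def test_premium_planted_separation():
    """Beauty at +0.3, ugliness at -0.3, sigma=0.01: difference ~0.6, significant."""
    rec = estimate_premium(SyntheticConfig(noise_sigma=0.01, seed=3))
    assert rec.difference == pytest.approx(0.6, abs=0.02)
    assert rec.label == LABEL_POS
    assert rec.test.p_value < 1e-10


def test_premium_axis_mismatch():
    with pytest.raises(ValueError, match="axis mismatch"):
        compute_premium(make_concept([0.1, 0.2], axis="a"), make_concept([0.0, 0.1], axis="b"))


def test_premium_label_antisymmetry():
    beauty = make_concept([0.4, 0.5, 0.6])
    ugliness = make_concept([-0.4, -0.5, -0.62])
    rec = compute_premium(beauty, ugliness)
    swapped = compute_premium(ugliness, beauty)
    assert swapped.difference == -rec.difference
    assert swapped.test.t_statistic == pytest.approx(-rec.test.t_statistic, rel=1e-12)
    assert {rec.label, swapped.label} == {LABEL_POS, LABEL_NEG}
    null = compute_premium(make_concept([0.1, -0.1, 0.05]), make_concept([0.08, -0.09, 0.02]))
    null_sw = compute_premium(make_concept([0.08, -0.09, 0.02]), make_concept([0.1, -0.1, 0.05]))
    assert null.label == null_sw.label == LABEL_NS


def test_labels_monotone_in_alpha():
    """The set of significant labels grows as alpha increases."""
    rng = np.random.default_rng(12)
    pairs = [
        (make_concept(rng.standard_normal(8) + d), make_concept(rng.standard_normal(8)))
        for d in (0.0, 0.3, 0.6, 1.2, 2.5)
    ]
    alphas = [0.001, 0.01, 0.05, 0.2, 0.5]
    prev: set[int] = set()
    for alpha in alphas:
        sig = {i for i, (b, u) in enumerate(pairs)
               if compute_premium(b, u, alpha=alpha).label != LABEL_NS}
        assert prev <= sig
        prev = sig


def test_null_rejection_rate_calibrated():
    """Under delta = 0 the rejection rate at alpha=0.05 is near nominal."""
    cfg = SyntheticConfig(delta_beauty=0.0, delta_ugliness=0.0, seed=21)
    rr = recovery_experiment(cfg, 400)
    assert 0.025 <= rr.rejection_rate <= 0.075


def test_holm_adjustment_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.uniform(size=12)
    expected = multipletests(p, method="holm")[1]
    np.testing.assert_allclose(holm_adjust(p), expected, rtol=1e-12)
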