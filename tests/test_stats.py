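"""Fisher/chi-squared statistics, effect sizes, features, flags."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from ccmotif.motif import Motif
from ccmotif.stats import (MODERATE_EFFECT_SIZE, adjust_pvalues, cramers_v,
                           enrichment_flags, feature_matrix,
                           fisher_differential, proportion_test,
                           triangle_effect_size)

TRI = [(0, 1), (1, 2), (0, 2)]


# -- fisher ----------------------------------------------------------------


def test_fisher_trivial_cases():
    assert fisher_differential(0, 10, 0, 10)[1] == pytest.approx(1.0)
    d, p = fisher_differential(5, 10, 5, 10)
    assert p == pytest.approx(1.0) and d == 0


def test_fisher_direction_sign():
    assert fisher_differential(9, 10, 1, 10)[0] == 1
    assert fisher_differential(1, 10, 9, 10)[0] == -1


def _fisher_two_sided_enum(a, ta, b, tb):
    """Direct hypergeometric tail summation: sum the probabilities of all
    tables (same margins) no more probable than the observed one."""
    M, n, N = ta + tb, a + b, ta
    lo, hi = max(0, n - tb), min(n, ta)
    probs = {k: hypergeom.pmf(k, M, n, N) for k in range(lo, hi + 1)}
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-9))


@pytest.mark.parametrize("a,ta,b,tb", [
    (3, 10, 7, 12), (0, 5, 4, 9), (10, 10, 2, 8), (1, 30, 5, 20),
])
def test_fisher_matches_hypergeometric_enumeration(a, ta, b, tb):
    _, p = fisher_differential(a, ta, b, tb)
    assert p == pytest.approx(_fisher_two_sided_enum(a, ta, b, tb), rel=1e-6)


def test_fisher_contract_errors():
    with pytest.raises(ValueError):
        fisher_differential(-1, 10, 0, 10)
    with pytest.raises(ValueError):
        fisher_differential(11, 10, 0, 10)


# -- multiple testing ------------------------------------------------------


def test_adjustment_trivia():
    ps = [0.02, 0.02, 0.02]
    assert adjust_pvalues(ps, "bh") == pytest.approx(ps)
    assert adjust_pvalues([0.01], "bonferroni") == pytest.approx([0.01])
    with pytest.raises(ValueError):
        adjust_pvalues([1.5])
    with pytest.raises(ValueError):
        adjust_pvalues([0.1], method="fancy")


def _bh_reference(ps):
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, ps[i] * m / rank)
        adj[i] = prev
    return adj


def test_bh_matches_step_up_definition(rng):
    for _ in range(20):
        ps = rng.random(rng.integers(1, 12))
        assert adjust_pvalues(ps, "bh") == pytest.approx(_bh_reference(ps))


def test_adjusted_at_least_raw(rng):
    ps = rng.random(10)
    for method in ("bh", "bonferroni"):
        assert np.all(adjust_pvalues(ps, method) >= ps - 1e-12)


# -- effect sizes ----------------------------------------------------------


def test_cramers_v_closed_forms():
    assert cramers_v(0.0, 10) == 0.0
    assert cramers_v(16.0, 16) == pytest.approx(1.0)
    assert cramers_v(4.0, 16) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        cramers_v(1.0, 0)


def test_triangle_effect_size_planted_association():
    # A and B co-occur strongly in triangles, whichever type is conditioned on
    triples = ([("A", "B", "C")] * 30 + [("A", "C", "E")] * 5
               + [("B", "C", "E")] * 5 + [("C", "E", "E")] * 10
               + [("A", "B", "E")] * 5 + [("B", "E", "E")] * 5
               + [("A", "E", "E")] * 5)
    res = triangle_effect_size(triples, "A", "B", "C")
    assert res.defined
    assert res.es == pytest.approx(min(res.conditional.values()))
    assert all(0 <= v <= 1 for v in res.conditional.values())
    assert res.es >= MODERATE_EFFECT_SIZE and res.significant


def test_triangle_effect_size_undefined_when_no_conditioning_triangles():
    triples = [("A", "B", "B")] * 10
    res = triangle_effect_size(triples, "A", "B", "C")
    assert not res.defined and np.isnan(res.es) and not res.significant


def test_triangle_effect_size_null_simulation():
    """On i.i.d. random labels over a realistic-width type panel the
    conditional effect size should almost never clear the moderate
    threshold.  (Very small alphabets are excluded: with only 3 slots per
    triangle, type presences are structurally anti-correlated.)"""
    from ccmotif.occurrence import triangle_iter
    from ccmotif.synthetic import random_triangulated_graph
    clear = 0
    n_rep = 30
    for seed in range(n_rep):
        g = random_triangulated_graph(500, 12, seed=seed)
        triples = [tuple(g.nodes[x]["cell_type"] for x in t)
                   for t in triangle_iter(g)]
        res = triangle_effect_size(triples, "t00", "t01", "t02")
        if res.defined and res.es >= MODERATE_EFFECT_SIZE:
            clear += 1
    assert clear <= max(1, 0.05 * n_rep)


# -- proportion test -------------------------------------------------------


def test_proportion_test_equal_proportions():
    assert proportion_test(5, 10, 50, 100) == pytest.approx(1.0)


def test_proportion_test_matches_closed_form():
    from scipy.stats import norm
    x1, n1, x2, n2 = 30, 80, 10, 70
    pooled = (x1 + x2) / (n1 + n2)
    z = (x1 / n1 - x2 / n2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    assert proportion_test(x1, n1, x2, n2) == pytest.approx(2 * norm.sf(abs(z)))


def test_proportion_test_degenerate_pooled():
    with pytest.warns(RuntimeWarning):
        assert proportion_test(0, 10, 0, 10) == 1.0
    with pytest.raises(ValueError):
        proportion_test(5, 0, 1, 2)


# -- feature matrices ------------------------------------------------------


def _single(label):
    return Motif([label], [])


def test_feature_matrix_worked_example():
    ms = [_single(c) for c in "abc"]
    fm = feature_matrix({"s": dict(zip(ms, [5, 5, 2]))}, ms)
    assert list(fm.loc["s"]) == pytest.approx([1.0, 1.0, 0.0])


def test_feature_matrix_degenerate_counts_warn():
    ms = [_single(c) for c in "ab"]
    with pytest.warns(RuntimeWarning):
        fm = feature_matrix({"s": dict(zip(ms, [3, 3]))}, ms)
    assert list(fm.loc["s"]) == [0.0, 0.0]
    with pytest.raises(ValueError):
        feature_matrix({"s": {}}, [])


def test_feature_matrix_monotone_invariance(rng):
    ms = [_single(f"x{i}") for i in range(6)]
    counts = rng.integers(0, 30, size=6)
    fm1 = feature_matrix({"s": dict(zip(ms, counts))}, ms)
    fm2 = feature_matrix({"s": dict(zip(ms, 2 * counts.astype(int) + 1))}, ms)
    assert np.allclose(fm1.values, fm2.values)


# -- enrichment flags ------------------------------------------------------


def test_enrichment_all_flagged_when_few_motifs():
    ms = [_single(f"x{i}") for i in range(5)]
    flags = enrichment_flags({"p": dict(zip(ms, [4, 3, 2, 2, 1]))}, size=1)
    assert flags.loc["p"].sum() == 5


def test_enrichment_top_cutoff_with_inclusive_ties():
    ms = [_single(f"x{i:02d}") for i in range(40)]
    counts = {m: 40 - i for i, m in enumerate(ms)}     # distinct counts
    flags = enrichment_flags({"p": counts}, size=1, top=29)
    assert flags.loc["p"].sum() == 29
    tied = {m: (2 if i < 35 else 1) for i, m in enumerate(ms)}
    flags = enrichment_flags({"p": tied}, size=1, top=29)
    assert flags.loc["p"].sum() == 35  # boundary ties all kept


def test_enrichment_matches_sort_threshold_oracle(rng):
    ms = [_single(f"x{i:02d}") for i in range(50)]
    counts = {m: int(c) for m, c in zip(ms, rng.integers(0, 10, size=50))}
    flags = enrichment_flags({"p": counts}, size=1, top=10)
    positive = sorted((c for c in counts.values() if c > 0), reverse=True)
    thresh = positive[min(10, len(positive)) - 1]
    for m in ms:
        expect = int(counts[m] > 0 and counts[m] >= thresh)
        assert flags.loc["p", m.canonical] == expect
    # the most abundant motif is always flagged
    best = max(counts, key=lambda m: counts[m])
    assert flags.loc["p", best.canonical] == 1
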