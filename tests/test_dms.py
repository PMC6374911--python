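"""Differential methylation testing: Fisher oracle, permutation p-values,
m0 estimation and the adaptive step-up adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methdyn.dms import (adjust_adaptive_bh, call_dms, classify_level,
                         estimate_m0_histogram, fisher_exact_two_sided,
                         sequential_permutation_pvalue)
from methdyn.simulate import SimulationConfig, spike_condition_pair

from conftest import make_methylome


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n_meth, n_row_a, total = a + c, a + b, a + b + c + d
    denom = math.comb(total, n_row_a)
    kmin = max(0, n_row_a - (total - n_meth))
    kmax = min(n_row_a, n_meth)
    probs = [math.comb(n_meth, k) * math.comb(total - n_meth, n_row_a - k)
             / denom for k in range(kmin, kmax + 1)]
    p_obs = probs[a - kmin]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


def test_fisher_examples():
    p, odds = fisher_exact_two_sided(10, 0, 0, 10)
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
    assert odds == np.inf
    p, odds = fisher_exact_two_sided(5, 5, 5, 5)
    assert p == 1.0 and odds == 1.0
    p, _ = fisher_exact_two_sided(3, 7, 3, 7)
    assert p == 1.0
    assert np.isnan(fisher_exact_two_sided(0, 5, 0, 5)[1])
    with pytest.raises(ValueError):
        fisher_exact_two_sided(0, 0, 0, 0)


def test_fisher_matches_enumeration_small_margins():
    """Exhaustive agreement with the enumeration oracle, totals <= 16
    (the full <= 30 sweep runs in the acceptance suite)."""
    for total in range(1, 17):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    d = total - a - b - c
                    got, _ = fisher_exact_two_sided(a, b, c, d)
                    assert got == pytest.approx(fisher_oracle(a, b, c, d),
                                                rel=1e-9, abs=1e-12)


def test_fisher_matches_scipy_on_random_tables(rng):
    for _ in range(300):
        a, b, c, d = rng.integers(0, 40, size=4)
        if a + b + c + d == 0:
            continue
        got, odds = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
        want_odds, want_p = stats.fisher_exact([[a, b], [c, d]])
        assert got == pytest.approx(want_p, rel=1e-6, abs=1e-12)
        if not (np.isnan(odds) or np.isinf(odds)):
            assert odds == pytest.approx(want_odds)


def test_sequential_permutation_stops_early_on_null(rng):
    p, n_used = sequential_permutation_pvalue((5, 5, 5, 5), h=10, rng=rng)
    assert n_used == 10 and p == 1.0


def test_sequential_permutation_extreme_table(rng):
    p, n_used = sequential_permutation_pvalue((10, 0, 0, 10), rng=rng)
    assert n_used == 1000
    assert p <= 11 / 1001


def test_sequential_permutation_validates():
    with pytest.raises(ValueError):
        sequential_permutation_pvalue((1, 1, 1, 1), max_perm=5, h=10)


def test_sequential_permutation_tracks_exact_p(rng):
    """Monte-Carlo agreement: |p_perm - p| <= 3 sqrt(p / max_perm) +
    h / max_perm over random tables."""
    for _ in range(40):
        a, b, c, d = rng.integers(0, 25, size=4)
        if min(a + b, c + d) == 0 or a + c == 0:
            continue
        p_exact, _ = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
        p_perm, n_used = sequential_permutation_pvalue((a, b, c, d), h=40,
                                                       rng=rng)
        if n_used < 1000:
            # early stop: h/N estimator has relative sd ~ 1/sqrt(h)
            bound = 4 * p_exact / np.sqrt(40)
        else:
            bound = 3 * np.sqrt(p_exact / 1000) + 40 / 1000
        assert abs(p_perm - p_exact) <= bound


def test_m0_estimator_behaviour():
    with pytest.raises(ValueError):
        estimate_m0_histogram([])
    assert estimate_m0_histogram(np.ones(100)) == 100
    for seed in range(10):
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=10_000)
        assert 0.9 <= estimate_m0_histogram(u) / 10_000 <= 1.0
        mix = np.concatenate([rng.uniform(size=9000),
                              rng.uniform(0, 1e-4, size=1000)])
        assert 0.85 <= estimate_m0_histogram(mix) / 10_000 <= 0.97


def bh_step_up_oracle(pvals, m0):
    """Brute-force step-up adjustment: p_adj(i) = min over p(j) >= p(i) of
    min(1, m0 p(j) / rank(j))."""
    pvals = np.asarray(pvals, dtype=float)
    order = np.argsort(pvals, kind="stable")
    rank_of = np.empty(len(pvals), dtype=int)
    rank_of[order] = np.arange(1, len(pvals) + 1)
    out = np.empty(len(pvals))
    for i, pi in enumerate(pvals):
        candidates = [min(1.0, m0 * pj / rank_of[j])
                      for j, pj in enumerate(pvals) if pj >= pi]
        out[i] = min(candidates)
    return out


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=30))
def test_adaptive_bh_equals_step_up_oracle(pvals):
    got = adjust_adaptive_bh(pvals, m0=len(pvals))
    want = bh_step_up_oracle(pvals, m0=len(pvals))
    assert np.allclose(got, want)
    # monotone in p
    order = np.argsort(pvals)
    assert np.all(np.diff(got[order]) >= -1e-12)


def test_adaptive_bh_m0_scaling():
    p = np.array([0.001, 0.01, 0.04, 0.2])
    full = adjust_adaptive_bh(p, m0=4)
    half = adjust_adaptive_bh(p, m0=2)
    uncapped = full < 1.0
    assert np.allclose(half[uncapped], full[uncapped] / 2)
    assert np.all(adjust_adaptive_bh(p, m0=0) == 0)
    with pytest.raises(ValueError):
        adjust_adaptive_bh(p, m0=5)


def test_adaptive_bh_order_invariance(rng):
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    direct = adjust_adaptive_bh(p, m0=40)
    shuffled = adjust_adaptive_bh(p[perm], m0=40)
    assert np.allclose(direct[perm], shuffled)


def test_classify_level_boundaries():
    assert classify_level(0.8) == "hyper"
    assert classify_level(0.2) == "hypo"
    assert classify_level(0.5) == "intermediate"
    assert list(classify_level([0.0, 0.79, 1.0])) == \
        ["hypo", "intermediate", "hyper"]


# ---------------------------------------------------------------------------
# call_dms

def test_call_dms_coverage_filter_and_identical_tables():
    a = make_methylome([100, 200, 300], [5, 9, 20], [4, 1, 20])
    b = make_methylome([100, 200, 300], [30, 10, 20], [20, 10, 20])
    table, est = call_dms(a, b, min_cov=10)
    # site 100 has 9x coverage in A -> excluded despite 50x in B
    assert 100 not in set(table["pos"])
    assert est.m == 2
    same, est2 = call_dms(a, a, min_cov=5)
    assert not same["is_dms"].any()


def test_call_dms_empty_overlap_warns():
    a = make_methylome([100], [5, ], [5])
    b = make_methylome([900], [5], [5])
    with pytest.warns(UserWarning, match="coverage filter"):
        table, est = call_dms(a, b)
    assert len(table) == 0 and est.m == 0


def test_call_dms_flags_strong_spiked_sites():
    """Spiked sites at delta 0.5, coverage 30 are nearly all recovered."""
    cfg = SimulationConfig(
        seed=21, chrom_length=200_000, coverage_mean=30.0,
        dmr_spec=tuple((1000, 10, 0.5, "hypo") for _ in range(10)))
    a, b, truth = spike_condition_pair(cfg)
    table, est = call_dms(a, b)
    spiked = set(map(tuple, truth.true_dms_positions.to_numpy()))
    tested = table[[(c, p) in spiked
                    for c, p in zip(table["chrom"], table["pos"])]]
    assert len(tested) > 300
    assert tested["is_dms"].mean() >= 0.9


def test_call_dms_power_monotone_in_delta():
    counts = []
    for delta in (0.1, 0.2, 0.4):
        cfg = SimulationConfig(
            seed=31, chrom_length=150_000,
            dmr_spec=tuple((1000, 10, delta, "hypo") for _ in range(5)))
        a, b, _ = spike_condition_pair(cfg)
        table, est = call_dms(a, b)
        counts.append(est.n_dms)
    assert counts[0] <= counts[1] <= counts[2]


def test_call_dms_permutation_mode_agrees_on_strong_signal():
    cfg = SimulationConfig(
        seed=41, chrom_length=40_000, coverage_mean=30.0,
        dmr_spec=((500, 8, 0.5, "hypo"),))
    a, b, _ = spike_condition_pair(cfg)
    exact, _ = call_dms(a, b)
    perm, _ = call_dms(a, b, fdr_mode="permutation", seed=1)
    merged = exact.merge(perm, on=["chrom", "pos"], suffixes=("_e", "_p"))
    strong = merged[merged["p_e"] < 1e-4]
    assert strong["is_dms_p"].mean() >= 0.9
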