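import math

import numpy as np
import pytest

from tempatterns.ci_search import (
    CriticalInterval,
    MiningConfig,
    bonferroni_threshold,
    count_nab,
    estimate_test_count,
    exhaustive_ci_search,
    mine_tpatterns,
    shrinking_ci_search,
    tpattern_p_value,
    tree_ci_search,
)
from tempatterns.events import EventStream
from tempatterns.simulate import Behavior, BehaviorDictionary, simulate_stream


def binomial_tail_oracle(n_a: int, pi0: float, n_ab: int) -> float:
    """Direct finite-sum evaluation of 1 - sum_{k<n_ab} C(n,k)(1-pi0)^k pi0^(n-k)."""
    acc = [
        math.comb(n_a, k) * (1 - pi0) ** k * pi0 ** (n_a - k) for k in range(n_ab)
    ]
    return 1.0 - math.fsum(acc)


def pair_stream(ta, tb, span) -> EventStream:
    events = [(float(t), "A") for t in ta] + [(float(t), "B") for t in tb]
    return EventStream(events, span=span)


class TestTPatternPValue:
    def test_matches_direct_tail_sum_on_grid(self):
        for n_a in (1, 2, 5, 10, 25, 50):
            for pi0 in np.arange(0.1, 0.95, 0.1):
                span_d = -1.0 / math.log(pi0)  # n_b=1, d=1, span chosen so pi0 hits
                for n_ab in range(n_a + 1):
                    p = tpattern_p_value(n_a, 1, span_d, 1.0, n_ab)
                    assert p == pytest.approx(
                        binomial_tail_oracle(n_a, pi0, n_ab), abs=1e-12
                    )

    def test_zero_successes_give_p_one(self):
        assert tpattern_p_value(10, 5, 100.0, 2.0, 0) == 1.0

    def test_known_closed_forms(self):
        span = 1.0 / math.log(2)  # n_b=1, d=1 -> pi0 = 0.5
        assert tpattern_p_value(2, 1, span, 1.0, 1) == pytest.approx(0.75)
        assert tpattern_p_value(3, 1, span, 1.0, 3) == pytest.approx(0.125)

    def test_monotone_in_nab_and_interval_length(self):
        span = 1000.0
        for n_a in (5, 20, 50):
            ps = [tpattern_p_value(n_a, 30, span, 3.0, k) for k in range(n_a + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
        ds = np.linspace(0.5, 50, 25)
        ps = [tpattern_p_value(20, 30, span, d, 5) for d in ds]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_nab_exceeding_na_is_an_error(self):
        with pytest.raises(ValueError):
            tpattern_p_value(3, 1, 10.0, 1.0, 4)


class TestCountNab:
    def test_counts_a_windows_holding_a_b(self):
        s = pair_stream([0, 10], [3, 13], 20)
        assert count_nab(s, "A", "B", CriticalInterval(2, 4)) == 2

    def test_multiple_b_in_one_window_count_once(self):
        s = pair_stream([0, 10], [3, 3.5], 20)
        assert count_nab(s, "A", "B", CriticalInterval(2, 4)) == 1

    def test_no_b_events_give_zero(self):
        s = EventStream([(0.0, "A"), (10.0, "A")], span=20.0)
        assert count_nab(s, "A", "B", CriticalInterval(2, 4)) == 0

    def test_window_endpoints_are_closed(self):
        s = pair_stream([0.0], [2.0], 10)
        assert count_nab(s, "A", "B", CriticalInterval(2, 4)) == 1
        s2 = pair_stream([0.0], [4.0], 10)
        assert count_nab(s2, "A", "B", CriticalInterval(2, 4)) == 1


class TestSearches:
    def test_exhaustive_finds_the_lag_and_verifies(self, delay5_stream):
        cfg = MiningConfig(horizon=10, bin_width=1, method="exhaustive")
        pat, trace = exhaustive_ci_search(delay5_stream, "A", "B", cfg)
        assert pat is not None and pat.ci.contains(5.0)
        assert pat.p_value < 0.005
        # independent recomputation of the returned interval's p-value
        nab = count_nab(delay5_stream, "A", "B", pat.ci)
        pi0 = math.exp(-(20 / 1000.0) * (pat.ci.d2 - pat.ci.d1 + 1))
        assert pat.p_value == pytest.approx(binomial_tail_oracle(20, pi0, nab), abs=1e-12)

    def test_exhaustive_tests_all_intervals_when_nothing_significant(self):
        rng = np.random.default_rng(0)
        s = pair_stream(np.sort(rng.uniform(0, 500, 20)), [499.5], 500)
        cfg = MiningConfig(horizon=10, bin_width=1, method="exhaustive")
        pat, trace = exhaustive_ci_search(s, "A", "B", cfg)
        assert pat is None
        assert trace.tests_performed == 10 * 11 // 2

    def test_exhaustive_empty_a_returns_none_with_empty_trace(self):
        s = EventStream([(1.0, "B")], span=10.0)
        cfg = MiningConfig(horizon=10, bin_width=1, method="exhaustive")
        pat, trace = exhaustive_ci_search(s, "A", "B", cfg)
        assert pat is None and trace.tests_performed == 0

    def test_sitpat_finds_the_lag_no_worse_than_full_interval(self, delay5_stream):
        cfg = MiningConfig(horizon=10, bin_width=1, method="sitpat")
        pat, trace = shrinking_ci_search(delay5_stream, "A", "B", cfg)
        assert pat is not None and pat.ci.contains(5.0)
        full_p = trace.intervals_examined[0][1]
        assert pat.p_value <= full_p
        assert trace.tests_performed <= 2 * 10 + 1

    def test_sitpat_cleanup_passes_catch_one_of_two_modes(self):
        rng = np.random.default_rng(5)
        ta = np.sort(rng.uniform(0, 5000, 60))
        tb = np.concatenate([ta[:30] + 5.0, ta[30:] + 9.0])
        s = pair_stream(ta, tb, 5010)
        cfg = MiningConfig(horizon=12, bin_width=1, method="sitpat")
        pat, _ = shrinking_ci_search(s, "A", "B", cfg)
        assert pat is not None
        assert pat.ci.contains(5.0) or pat.ci.contains(9.0)

    def test_ttpat_finds_the_lag_within_logarithmic_tests(self, delay5_stream):
        cfg = MiningConfig(horizon=8, bin_width=1, method="ttpat")
        pat, trace = tree_ci_search(delay5_stream, "A", "B", cfg)
        assert pat is not None and pat.ci.contains(5.0)
        assert trace.tests_performed <= 2 * math.ceil(math.log2(8)) + 1

    def test_ttpat_trace_bound_h1024(self):
        rng = np.random.default_rng(2)
        s = pair_stream(np.sort(rng.uniform(0, 3000, 40)), np.sort(rng.uniform(0, 3000, 40)), 3000)
        cfg = MiningConfig(horizon=1024, bin_width=1, method="ttpat")
        _, trace = tree_ci_search(s, "A", "B", cfg)
        assert trace.tests_performed <= 21

    def test_no_b_within_horizon_returns_none(self):
        s = pair_stream([0, 10, 20], [500], 501)
        for fn, m in ((shrinking_ci_search, "sitpat"), (tree_ci_search, "ttpat")):
            cfg = MiningConfig(horizon=16, bin_width=1, method=m)
            pat, _ = fn(s, "A", "B", cfg)
            assert pat is None

    def test_fast_searches_agree_with_exhaustive_oracle(self):
        """Any CI returned by sitpat/ttpat is significant under enumeration."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ta = np.sort(rng.uniform(0, 400, int(rng.integers(20, 90))))
            if seed % 2:
                tb = np.sort(rng.uniform(0, 400, int(rng.integers(20, 90))))
            else:
                half = ta[::2]
                tb = np.sort(
                    np.concatenate([half + rng.normal(4, 0.5, len(half)),
                                    rng.uniform(0, 400, 20)])
                )
            tb = tb[tb > 0]
            span = max(400.0, ta.max(), tb.max())
            s = pair_stream(ta, tb, span)
            cfg = MiningConfig(horizon=16, bin_width=1, method="exhaustive")
            _, full = exhaustive_ci_search(s, "A", "B", cfg, threshold=-1.0)
            significant = {
                (ci.d1, ci.d2) for ci, p in full.intervals_examined if p < 0.005
            }
            for fn, m, bound in (
                (shrinking_ci_search, "sitpat", 2 * 16 + 1),
                (tree_ci_search, "ttpat", 2 * 4 + 1),
            ):
                cfgm = MiningConfig(horizon=16, bin_width=1, method=m)
                pat, tr = fn(s, "A", "B", cfgm)
                assert tr.tests_performed <= bound
                if pat is not None:
                    assert (pat.ci.d1, pat.ci.d2) in significant


class TestTestCountFormulas:
    @pytest.mark.parametrize(
        "method, n, h, expected",
        [
            ("gmmtpat", 15, 300, 900),
            ("sitpat", 15, 300, 405_000),
            ("ttpat", 15, 300, 14_812),
            ("exhaustive", 150, 300, 4_063_500_000),
        ],
    )
    def test_expected_test_counts(self, method, n, h, expected):
        assert estimate_test_count(method, n, h) == expected

    def test_formula_ordering_matches_complexity_ordering(self):
        for n in (2, 15, 150):
            for h in (2, 16, 300, 1024):
                counts = [
                    estimate_test_count(m, n, h)
                    for m in ("gmmtpat", "ttpat", "sitpat", "exhaustive")
                ]
                assert counts == sorted(counts)

    def test_bonferroni_threshold(self):
        assert bonferroni_threshold(0.005, 900) == pytest.approx(5.5556e-6, rel=1e-4)
        assert bonferroni_threshold(0.005, 1) == 0.005
        with pytest.raises(ValueError):
            bonferroni_threshold(0.005, 0)


@pytest.fixture(scope="module")
def abc_stream():
    d = BehaviorDictionary(
        [Behavior("b", [("A", 2.0, 0.1), ("B", 2.0, 0.1), ("C", 2.0, 0.1)])],
        execution_probability=1.0,
        idle_mean=0.0,
    )
    stream, _ = simulate_stream(d, 1, 500 * 6.0, seed=3)
    return stream


class TestMining:

    def test_hierarchy_contains_elementary_and_tertiary_patterns(self, abc_stream):
        cfg = MiningConfig(horizon=20, bin_width=1, method="sitpat", max_depth=3)
        patterns, _ = mine_tpatterns(abc_stream, cfg)
        found = {(p.left, p.right) for p in patterns}
        assert ("A", "B") in found and ("B", "C") in found
        assert ("(A->B)", "C") in found
        for p in patterns:
            if (p.left, p.right) == ("A", "B"):
                assert p.ci.contains(2.0)

    def test_empty_stream_yields_no_patterns(self):
        patterns, _ = mine_tpatterns(EventStream([]), MiningConfig())
        assert patterns == []

    def test_max_depth_two_keeps_composites_off_the_left(self, abc_stream):
        cfg = MiningConfig(horizon=20, bin_width=1, method="sitpat", max_depth=2)
        patterns, _ = mine_tpatterns(abc_stream, cfg)
        assert patterns
        assert all("(" not in p.left and "(" not in p.right for p in patterns)

    def test_bonferroni_result_is_subset_of_uncorrected(self, abc_stream):
        base = MiningConfig(horizon=20, bin_width=1, method="ttpat", max_depth=2)
        bon = MiningConfig(
            horizon=20, bin_width=1, method="ttpat", max_depth=2, bonferroni=True
        )
        plain, _ = mine_tpatterns(abc_stream, base)
        corrected, _ = mine_tpatterns(abc_stream, bon)
        plain_keys = {(p.left, p.right) for p in plain}
        assert {(p.left, p.right) for p in corrected} <= plain_keys
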