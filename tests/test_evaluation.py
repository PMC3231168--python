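import numpy as np
import pytest

from tempatterns.ci_search import CriticalInterval, TPattern
from tempatterns.evaluation import (
    ClusterTruth,
    evaluate_prediction,
    per_sensor_predictability,
    score_patterns,
    tpattern_posterior,
    tpattern_predictor,
)
from tempatterns.events import Event, EventStream


def make_pattern(a, b, d1, d2, strength=5.0):
    return TPattern(
        left=a, right=b, ci=CriticalInterval(d1, d2), n_ab=10, atoms=(a, b),
        strength=strength,
    )


class TestTPatternPosterior:
    def test_single_applicable_pattern_is_certain(self):
        pats = [make_pattern("A", "B", 2, 4)]
        post = tpattern_posterior(pats, [Event(0.0, "A")], 3.0)
        assert post == {"B": 1.0}

    def test_equal_width_patterns_split_evenly(self):
        pats = [make_pattern("A", "B", 2, 4), make_pattern("A", "C", 2, 4)]
        post = tpattern_posterior(pats, [Event(0.0, "A")], 3.0)
        assert post == {"B": 0.5, "C": 0.5}

    def test_narrower_interval_gets_more_mass(self):
        pats = [make_pattern("A", "B", 2.5, 3.5), make_pattern("A", "C", 1, 5)]
        post = tpattern_posterior(pats, [Event(0.0, "A")], 3.0)
        assert post["B"] == pytest.approx(0.8)  # densities 1 vs 0.25

    def test_empty_history_abstains(self):
        assert tpattern_posterior([make_pattern("A", "B", 2, 4)], [], 3.0) == {}

    def test_out_of_window_pattern_not_applicable(self):
        pats = [make_pattern("A", "B", 2, 4)]
        assert tpattern_posterior(pats, [Event(0.0, "A")], 10.0) == {}

    def test_fast_path_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        events = sorted(
            (float(t), rng.choice(["A", "B", "C"])) for t in rng.uniform(0, 100, 60)
        )
        stream = EventStream(events, span=100.0)
        pats = [make_pattern("A", "B", 1, 4), make_pattern("B", "C", 2, 3)]
        fast = tpattern_predictor(pats, stream)
        history: list[Event] = []
        for e in stream:
            slow = tpattern_posterior(pats, history, e.time)
            assert fast(history, e.time) == pytest.approx(slow)
            history.append(e)


class TestEvaluatePrediction:
    def test_oracle_predictor_on_deterministic_chain(self):
        """Only the chain-initial events are unpredictable: accuracy 2/3."""
        events = []
        for k in range(30):
            base = 100.0 * k
            events += [(base, "A"), (base + 2.0, "B"), (base + 4.0, "C")]
        stream = EventStream(events, span=3000.0)
        pats = [make_pattern("A", "B", 1.5, 2.5), make_pattern("B", "C", 1.5, 2.5)]
        report = evaluate_prediction(stream, tpattern_predictor(pats, stream), 0.2)
        assert report.accuracy_all == pytest.approx(2 / 3)
        assert report.precision_claimed == pytest.approx(1.0)
        assert report.coverage == pytest.approx(2 / 3)

    def test_uniform_random_predictor_matches_chance(self):
        rng = np.random.default_rng(7)
        symbols = ["A", "B", "C", "D"]
        events = sorted((float(t), rng.choice(symbols)) for t in rng.uniform(0, 1e4, 2000))
        stream = EventStream(events, span=1e4)
        pred_rng = np.random.default_rng(8)

        def uniform_predictor(history, t):
            chosen = symbols[pred_rng.integers(4)]
            return {chosen: 1.0}

        report = evaluate_prediction(stream, uniform_predictor, 0.2)
        assert report.accuracy_all == pytest.approx(0.25, abs=0.04)

    def test_never_confident_predictor_scores_zero(self):
        stream = EventStream([(1.0, "A"), (2.0, "B")], span=10.0)
        report = evaluate_prediction(stream, lambda h, t: {"A": 0.5, "B": 0.5}, 1.0)
        assert report.coverage == 0.0 and report.accuracy_all == 0.0

    def test_types_unseen_in_training_are_skipped(self):
        stream = EventStream([(1.0, "A"), (2.0, "X"), (3.0, "A")], span=10.0)
        report = evaluate_prediction(stream, lambda h, t: {"A": 1.0}, 0.2, known_types={"A"})
        assert report.n_events == 2 and report.accuracy_all == 1.0

    def test_accuracy_never_exceeds_precision_under_abstention(self):
        stream = EventStream([(float(t), "A") for t in range(1, 20)], span=20.0)
        report = evaluate_prediction(
            stream, lambda h, t: {"A": 0.6, "B": 0.4} if int(t) % 2 else {}, 0.5
        )
        assert report.coverage < 1.0
        assert report.accuracy_all <= report.precision_claimed + 1e-12

    def test_empty_stream_errors(self):
        with pytest.raises(ValueError):
            evaluate_prediction(EventStream([]), lambda h, t: {}, 0.2)


class TestScorePatterns:
    @pytest.fixture
    def truth(self):
        return ClusterTruth(
            membership={"A": 0, "B": 0, "C": 0, "X": 1, "Y": 1, "Z": 1},
            order={"A": 0, "B": 1, "C": 2, "X": 0, "Y": 1, "Z": 2},
        )

    def test_within_cluster_in_order_is_correct(self, truth):
        sc = score_patterns([make_pattern("A", "B", 1, 2)], truth)
        assert (sc.correct, sc.spurious, sc.gray) == (1, 0, 0)

    def test_cross_cluster_is_spurious(self, truth):
        sc = score_patterns([make_pattern("A", "X", 1, 2)], truth)
        assert sc.spurious == 1

    def test_within_cluster_out_of_order_is_gray(self, truth):
        pat = TPattern(
            left="A", right="(C->B)", ci=CriticalInterval(1, 2), n_ab=5,
            atoms=("A", "C", "B"), strength=2.0,
        )
        sc = score_patterns([pat], truth)
        assert sc.gray == 1

    def test_non_adjacent_in_order_pair_counts_correct(self, truth):
        sc = score_patterns([make_pattern("A", "C", 1, 2)], truth)
        assert sc.correct == 1

    def test_missed_counts_unrealized_truth_tuples(self, truth):
        sc = score_patterns([make_pattern("A", "B", 1, 2)], truth)
        # truth holds 2 clusters x (3 in-order pairs + 1 triple) = 8 tuples
        assert sc.missed == 7

    def test_category_counts_partition_found_patterns(self, truth):
        found = [
            make_pattern("A", "B", 1, 2),
            make_pattern("A", "X", 1, 2),
            make_pattern("Y", "X", 1, 2),
        ]
        sc = score_patterns(found, truth)
        assert sc.correct + sc.spurious + sc.gray == len(found)

    def test_unlabelled_sensor_errors(self, truth):
        with pytest.raises(KeyError):
            score_patterns([make_pattern("A", "Q", 1, 2)], truth)


class TestPerSensorPredictability:
    def test_reliable_follower_scores_one(self):
        events = []
        for k in range(20):
            events += [(100.0 * k, "A"), (100.0 * k + 3.0, "B")]
        stream = EventStream(events, span=2000.0)
        pats = [make_pattern("A", "B", 2, 4, strength=9.0)]
        rep = per_sensor_predictability(stream, pats)
        assert rep.per_sensor["A"] == 1.0
        assert "B" in rep.excluded

    def test_random_follower_scores_near_background_rate(self):
        rng = np.random.default_rng(4)
        ta = np.sort(rng.uniform(0, 1e4, 100))
        tb = np.sort(rng.uniform(0, 1e4, 100))
        stream = EventStream(
            [(float(t), "A") for t in ta] + [(float(t), "B") for t in tb], span=1e4
        )
        pats = [make_pattern("A", "B", 2, 4, strength=9.0)]
        rep = per_sensor_predictability(stream, pats)
        # P(some B in a 2 s window) = 1 - exp(-0.01 * 2) ~ 0.02
        assert rep.per_sensor["A"] < 0.15

    def test_only_two_strongest_patterns_used(self):
        events = [(0.0, "A"), (3.0, "B"), (13.0, "C"), (23.0, "D")]
        stream = EventStream(events, span=30.0)
        pats = [
            make_pattern("A", "B", 2, 4, strength=9.0),
            make_pattern("A", "C", 12, 14, strength=5.0),
            make_pattern("A", "D", 22, 24, strength=1.0),  # true but ranked third
        ]
        rep = per_sensor_predictability(stream, pats)
        assert rep.per_sensor["A"] == 1.0
        weak_only = [make_pattern("A", "D", 50, 60, strength=1.0)]
        rep2 = per_sensor_predictability(stream, weak_only)
        assert rep2.per_sensor["A"] == 0.0
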