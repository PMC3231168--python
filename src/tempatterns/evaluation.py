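"""Pattern-based prediction and evaluation protocols.

Covers three protocols:

* event-type prediction at a known event time, combining the critical
  intervals of all applicable T-patterns (uniform density inside each CI)
  into a posterior, evaluated against compression baselines at a confidence
  level (abstentions count as errors in the headline accuracy);
* correct / spurious / gray / missed scoring of mined patterns against a
  clustered ground truth (within-cluster in-order patterns are correct,
  cross-cluster ones spurious, within-cluster out-of-order ones gray);
* per-sensor predictability: for each activation, do the critical intervals
  of that sensor's two strongest patterns capture at least one predicted
  event?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .ci_search import TPattern
from .compression import PhraseTrie, confident_prediction, predict_next
from .events import Event, EventStream

__all__ = [
    "PredictionRecord",
    "EvaluationReport",
    "PatternScorecard",
    "ClusterTruth",
    "tpattern_posterior",
    "tpattern_predictor",
    "trie_predictor",
    "evaluate_prediction",
    "score_patterns",
    "per_sensor_predictability",
    "PredictabilityReport",
]


@dataclass
class PredictionRecord:
    index: int
    truth: str
    predicted: Optional[str]
    max_posterior: float
    correct: bool


@dataclass
class EvaluationReport:
    """Headline accuracy (abstentions wrong), precision on claims, coverage."""

    accuracy_all: float
    precision_claimed: float
    coverage: float
    n_events: int
    records: list[PredictionRecord] = field(repr=False, default_factory=list)


@dataclass
class PatternScorecard:
    correct: int
    spurious: int
    gray: int
    missed: int


@dataclass
class ClusterTruth:
    """Cluster membership and within-cluster order for every sensor."""

    membership: dict[str, int]
    order: dict[str, int]

    def label(self, sensor: str) -> tuple[int, int]:
        if sensor not in self.membership:
            raise KeyError(f"sensor {sensor!r} has no cluster label")
        return self.membership[sensor], self.order[sensor]

    def truth_tuples(self) -> set[tuple[str, ...]]:
        """All in-order pairs and triples within each cluster."""
        out: set[tuple[str, ...]] = set()
        clusters: dict[int, list[str]] = {}
        for s, c in self.membership.items():
            clusters.setdefault(c, []).append(s)
        for members in clusters.values():
            members.sort(key=lambda s: self.order[s])
            n = len(members)
            for i in range(n):
                for j in range(i + 1, n):
                    out.add((members[i], members[j]))
                    for k in range(j + 1, n):
                        out.add((members[i], members[j], members[k]))
        return out


def tpattern_posterior(
    patterns: Sequence[TPattern], history: Sequence[Event], t: float
) -> dict[str, float]:
    """Posterior over the event type at a known time ``t``.

    A pattern (A -> B, [d1, d2]) is applicable if some A in the history at
    time ``s`` satisfies ``t in [s + d1, s + d2]``; it contributes mass for B
    proportional to its uniform CI density ``1 / (d2 - d1)``.  Contributions
    are summed per predicted type and normalized; with no applicable pattern
    the posterior is empty (abstain).
    """
    mass: dict[str, float] = {}
    if not history:
        return {}
    times_by_type: dict[str, list[float]] = {}
    for e in history:
        times_by_type.setdefault(e.etype, []).append(e.time)
    for pat in patterns:
        starts = times_by_type.get(pat.left)
        if not starts:
            continue
        arr = np.asarray(starts)
        lo, hi = t - pat.ci.d2, t - pat.ci.d1
        if not np.any((arr >= lo) & (arr <= hi)):
            continue
        width = pat.ci.d2 - pat.ci.d1
        density = 1.0 / width if width > 0 else 1.0
        mass[pat.right] = mass.get(pat.right, 0.0) + density
    total = sum(mass.values())
    if total <= 0:
        return {}
    return {k: v / total for k, v in mass.items()}


def tpattern_predictor(
    patterns: Sequence[TPattern], test_stream: EventStream | None = None
) -> Callable:
    """Predictor closure for :func:`evaluate_prediction` (uses event times).

    Only elementary (atomic-left) patterns predicting atomic types are used,
    since the test stream exposes atomic sensor events.  Passing the test
    stream lets the closure use precomputed per-type time arrays: because
    every CI has a strictly positive left edge, an A-event in ``[t-d2, t-d1]``
    is strictly in the past, so applicability can be checked on the full
    arrays without rebuilding the history index per event.
    """
    atomic_left = [p for p in patterns if "(" not in p.right and "(" not in p.left]

    if test_stream is not None:
        by_type = test_stream.times_by_type()

        def predict_fast(history: Sequence[Event], t: float) -> dict[str, float]:
            mass: dict[str, float] = {}
            for pat in atomic_left:
                arr = by_type.get(pat.left)
                if arr is None:
                    continue
                lo = np.searchsorted(arr, t - pat.ci.d2, side="left")
                if lo >= len(arr) or arr[lo] > t - pat.ci.d1:
                    continue
                width = pat.ci.d2 - pat.ci.d1
                density = 1.0 / width if width > 0 else 1.0
                mass[pat.right] = mass.get(pat.right, 0.0) + density
            total = sum(mass.values())
            return {k: v / total for k, v in mass.items()} if total > 0 else {}

        return predict_fast

    def predict(history: Sequence[Event], t: float) -> dict[str, float]:
        return tpattern_posterior(atomic_left, history, t)

    return predict


def trie_predictor(trie: PhraseTrie) -> Callable:
    """Predictor closure over a compression trie (ignores event times)."""
    depth = trie.longest_phrase_len  # context beyond the deepest phrase is unusable

    def predict(history: Sequence[Event], t: float) -> dict[str, float]:
        ctx = history[-depth:] if depth else []
        return predict_next(trie, [e.etype for e in ctx])

    return predict


def evaluate_prediction(
    test_stream: EventStream,
    predictor: Callable,
    confidence: float,
    known_types: Iterable[str] | None = None,
) -> EvaluationReport:
    """Walk the test stream, predicting each event's type at its known time.

    ``predictor(history_events, t)`` returns a posterior; the confidence
    threshold converts it into a claim or an abstention.  Events whose type
    is absent from ``known_types`` (the training vocabulary) are skipped from
    scoring but remain visible in the history.  Abstentions count as
    incorrect in ``accuracy_all``; ``precision_claimed`` and ``coverage``
    disambiguate.
    """
    if len(test_stream) == 0:
        raise ValueError("cannot evaluate on an empty test stream")
    known = set(known_types) if known_types is not None else None
    records: list[PredictionRecord] = []
    history: list[Event] = []
    n_correct = n_claimed = n_claimed_correct = n_eval = 0
    for idx, event in enumerate(test_stream):
        if known is None or event.etype in known:
            posterior = predictor(history, event.time)
            predicted = confident_prediction(posterior, confidence) if posterior else None
            max_post = max(posterior.values()) if posterior else 0.0
            correct = predicted == event.etype
            records.append(PredictionRecord(idx, event.etype, predicted, max_post, correct))
            n_eval += 1
            n_correct += correct
            if predicted is not None:
                n_claimed += 1
                n_claimed_correct += correct
        history.append(event)
    if n_eval == 0:
        raise ValueError("no evaluable events (all types unseen in training)")
    return EvaluationReport(
        accuracy_all=n_correct / n_eval,
        precision_claimed=(n_claimed_correct / n_claimed) if n_claimed else 0.0,
        coverage=n_claimed / n_eval,
        n_events=n_eval,
        records=records,
    )


def score_patterns(found: Sequence[TPattern], truth: ClusterTruth) -> PatternScorecard:
    """Classify mined patterns against a clustered ground truth.

    Per pattern (flattened to its atomic constituents): all constituents in
    one cluster and in cluster order -> correct; constituents spanning
    clusters -> spurious; single-cluster but out of order -> gray.  Missed is
    the set of in-order truth tuples (pairs and triples, non-adjacent ones
    included) not realized by any correct pattern.
    """
    correct = spurious = gray = 0
    correct_tuples: set[tuple[str, ...]] = set()
    for pat in found:
        labels = [truth.label(s) for s in pat.atoms]
        clusters = {c for c, _ in labels}
        if len(clusters) > 1:
            spurious += 1
        else:
            orders = [o for _, o in labels]
            if all(orders[i] < orders[i + 1] for i in range(len(orders) - 1)):
                correct += 1
                correct_tuples.add(pat.atoms)
            else:
                gray += 1
    truth_set = truth.truth_tuples()
    missed = len(truth_set - correct_tuples)
    return PatternScorecard(correct=correct, spurious=spurious, gray=gray, missed=missed)


@dataclass
class PredictabilityReport:
    per_sensor: dict[str, float]
    overall: float
    excluded: list[str]


def per_sensor_predictability(
    test_stream: EventStream, patterns: Sequence[TPattern]
) -> PredictabilityReport:
    """Success rate of the two-strongest-patterns forward check.

    For each activation of sensor ``i`` at ``t``, the critical intervals of
    i's two strongest patterns are checked for the predicted sensors' events
    after ``t``; one hit suffices for a success.  Sensors with no patterns
    are excluded and reported separately.
    """
    ranked: dict[str, list[TPattern]] = {}
    for p in patterns:
        if p.strength is None:
            raise ValueError("per-sensor predictability needs pattern strengths")
        ranked.setdefault(p.left, []).append(p)
    for plist in ranked.values():
        plist.sort(key=lambda p: (-p.strength, p.right))
    by_type = test_stream.times_by_type()
    per_sensor: dict[str, float] = {}
    excluded: list[str] = []
    n_succ_total = n_total = 0
    for sensor in sorted(by_type):
        top = ranked.get(sensor, [])[:2]
        if not top:
            excluded.append(sensor)
            continue
        succ = 0
        times = by_type[sensor]
        for t in times:
            hit = False
            for pat in top:
                targets = by_type.get(pat.right)
                if targets is None:
                    continue
                lo = np.searchsorted(targets, t + pat.ci.d1, side="left")
                if lo < len(targets) and targets[lo] <= t + pat.ci.d2:
                    hit = True
                    break
            succ += hit
        per_sensor[sensor] = succ / len(times)
        n_succ_total += succ
        n_total += len(times)
    overall = n_succ_total / n_total if n_total else 0.0
    return PredictabilityReport(per_sensor=per_sensor, overall=overall, excluded=excluded)
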