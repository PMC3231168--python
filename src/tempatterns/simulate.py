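"""Multi-actor sensor-stream simulator with ground truth.

Emulates an instrumented office: a behaviour dictionary catalogues prominent
activities, each an ordered list of sensor activations separated by
pre-defined mean gaps with Gaussian noise.  Each simulated user independently
loops — with probability ``e`` it executes a uniformly chosen behaviour,
otherwise it idles for an exponentially distributed time — and all users'
events (plus optional per-sensor Poisson background activations) are merged
into one time-sorted stream.  Because the generating behaviours are known,
every event carries a provenance label, giving exact ground truth for
scoring mined patterns and predictions.

Shipped fixture dictionaries (``office_layout_a``/``b``, ``corridor_chain``,
``make_cluster_layout``) are synthetic stand-ins that emulate the
statistical structure of typical office layouts — corridor chains and
remotely located clusters of correlated sensor triplets; they are authored
here, not derived from any deposited floorplan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .evaluation import ClusterTruth
from .events import Event, EventStream

__all__ = [
    "Behavior",
    "BehaviorDictionary",
    "GroundTruthRecord",
    "simulate_stream",
    "make_cluster_layout",
    "corridor_chain",
    "office_layout_a",
    "office_layout_b",
    "truth_pattern_set",
    "load_dictionary",
    "save_dictionary",
]

#: Truncation for negative Gaussian gap draws (seconds).
GAP_EPS = 1e-3


@dataclass
class Behavior:
    """One behaviour: ordered (sensor, mean_gap, sd_gap) steps.

    The first step's gap is measured from the behaviour's start; subsequent
    mean gaps must be positive.
    """

    id: str
    steps: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a behaviour needs at least one step")
        for k, (_, mg, sg) in enumerate(self.steps):
            if k > 0 and mg <= 0:
                raise ValueError("mean gaps beyond the first step must be positive")
            if sg < 0:
                raise ValueError("gap standard deviations must be non-negative")

    @property
    def sensors(self) -> list[str]:
        return [s for s, _, _ in self.steps]


@dataclass
class BehaviorDictionary:
    """Generative catalogue: behaviours + execution probability + idling."""

    behaviors: list[Behavior]
    execution_probability: float = 1.0
    idle_mean: float = 0.0
    background_rate: Optional[float] = None  # per-sensor Poisson intensity (1/s)

    def __post_init__(self) -> None:
        if not 0 < self.execution_probability <= 1:
            raise ValueError("execution probability e must be in (0, 1]")
        if self.idle_mean < 0:
            raise ValueError("idle_mean must be non-negative")

    @property
    def sensors(self) -> list[str]:
        seen: list[str] = []
        for b in self.behaviors:
            for s in b.sensors:
                if s not in seen:
                    seen.append(s)
        return sorted(seen)


@dataclass
class GroundTruthRecord:
    """Provenance of one generated event (background events have user -1)."""

    time: float
    sensor: str
    user: int
    behavior: Optional[str]
    instance: int
    step: int

    @property
    def is_background(self) -> bool:
        return self.behavior is None


def simulate_stream(
    dictionary: BehaviorDictionary,
    n_users: int,
    duration: float,
    seed: int,
) -> tuple[EventStream, list[GroundTruthRecord]]:
    """Generate a merged multi-user stream plus per-event ground truth.

    Fully reproducible from the seed; events beyond ``duration`` are dropped.
    Negative Gaussian gap draws are truncated at 1 ms.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_users < 1:
        raise ValueError("n_users must be at least 1")
    master = np.random.default_rng(seed)
    user_seeds = master.integers(0, 2**31 - 1, size=n_users + 1)
    records: list[GroundTruthRecord] = []
    e = dictionary.execution_probability
    behaviors = dictionary.behaviors
    for user in range(n_users):
        rng = np.random.default_rng(user_seeds[user])
        t = 0.0
        instance = 0
        while t < duration:
            if rng.random() < e:
                beh = behaviors[rng.integers(len(behaviors))]
                cur = t
                for step_idx, (sensor, mg, sg) in enumerate(beh.steps):
                    gap = rng.normal(mg, sg) if sg > 0 else mg
                    if step_idx == 0:
                        gap = max(gap, 0.0)
                    else:
                        gap = max(gap, GAP_EPS)
                    cur += gap
                    if cur > duration:
                        break
                    records.append(
                        GroundTruthRecord(cur, sensor, user, beh.id, instance, step_idx)
                    )
                t = max(cur, t + GAP_EPS)
                instance += 1
            else:
                idle = rng.exponential(dictionary.idle_mean) if dictionary.idle_mean > 0 else 0.0
                t += max(idle, GAP_EPS)
    if dictionary.background_rate:
        rng = np.random.default_rng(user_seeds[-1])
        for sensor in dictionary.sensors:
            n_bg = rng.poisson(dictionary.background_rate * duration)
            for bg_t in np.sort(rng.uniform(0.0, duration, size=n_bg)):
                records.append(GroundTruthRecord(float(bg_t), sensor, -1, None, -1, -1))
    records.sort(key=lambda r: (r.time, r.sensor, r.user, r.step))
    stream = EventStream(
        [Event(r.time, r.sensor) for r in records], span=duration, _presorted=True
    )
    return stream, records


def truth_pattern_set(dictionary: BehaviorDictionary) -> set[tuple[str, ...]]:
    """All in-order sensor pairs and triples within each behaviour."""
    out: set[tuple[str, ...]] = set()
    for beh in dictionary.behaviors:
        sensors = beh.sensors
        n = len(sensors)
        for i in range(n):
            for j in range(i + 1, n):
                out.add((sensors[i], sensors[j]))
                for k in range(j + 1, n):
                    out.add((sensors[i], sensors[j], sensors[k]))
    return out


def make_cluster_layout(
    n_clusters: int,
    gap_mean: float = 4.0,
    gap_sd: float = 0.4,
    spacing: float = 60.0,
    execution_probability: float = 0.5,
    background_rate: Optional[float] = None,
) -> tuple[BehaviorDictionary, ClusterTruth]:
    """Clusters of three tightly correlated sensors, remotely located.

    Each cluster contributes one behaviour traversing its triplet in order;
    clusters share no sensors, and ``spacing`` sets the mean idle (travel)
    time between behaviour executions.  Returns the dictionary plus the
    cluster membership / order labels used for pattern scoring.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    behaviors: list[Behavior] = []
    membership: dict[str, int] = {}
    order: dict[str, int] = {}
    for c in range(n_clusters):
        sensors = [f"c{c}{tag}" for tag in "abc"]
        # broad, variable travel time to the cluster keeps distinct clusters
        # uncorrelated in the sharp-lag sense
        steps = [(sensors[0], spacing, spacing / 3.0)]
        steps += [(s, gap_mean, gap_sd) for s in sensors[1:]]
        behaviors.append(Behavior(f"cluster{c}", steps))
        for k, s in enumerate(sensors):
            membership[s] = c
            order[s] = k
    dictionary = BehaviorDictionary(
        behaviors,
        execution_probability=execution_probability,
        idle_mean=spacing,
        background_rate=background_rate,
    )
    return dictionary, ClusterTruth(membership, order)


def corridor_chain(
    n_sensors: int = 5,
    gap_mean: float = 3.0,
    gap_sd: float = 0.3,
    execution_probability: float = 0.6,
    idle_mean: float = 40.0,
    background_rate: float = 0.01,
) -> BehaviorDictionary:
    """A single corridor: one behaviour walking the chain s1 -> ... -> sn.

    The per-sensor Poisson background stands in for unrelated passers-by and
    gives the delay mixtures their diffuse component.
    """
    sensors = [f"s{i}" for i in range(1, n_sensors + 1)]
    steps = [(sensors[0], 15.0, 3.0)] + [(s, gap_mean, gap_sd) for s in sensors[1:]]
    return BehaviorDictionary(
        [Behavior("walk", steps)],
        execution_probability=execution_probability,
        idle_mean=idle_mean,
        background_rate=background_rate,
    )


def office_layout_a() -> BehaviorDictionary:
    """Six-sensor corridor-block fixture: three short office routines.

    Each routine starts with an "approach" gap (~15 s walk to its first
    sensor), then fires its sensors at second-scale lags.  Users are busy —
    executions a half minute apart on average — so two simulated users
    interleave each other's routines frequently.
    """
    return BehaviorDictionary(
        [
            Behavior("coffee", [("s1", 15.0, 3.0), ("s2", 3.0, 0.3), ("s3", 4.0, 0.4)]),
            Behavior("copier", [("s4", 15.0, 3.0), ("s5", 2.0, 0.2), ("s6", 5.0, 0.5)]),
            Behavior("return", [("s3", 15.0, 3.0), ("s2", 6.0, 0.6), ("s1", 3.5, 0.35)]),
        ],
        execution_probability=0.7,
        idle_mean=30.0,
        background_rate=0.002,
    )


def office_layout_b() -> BehaviorDictionary:
    """Six-sensor entrance-plus-corridors fixture.

    One entrance feeds three corridors with two sensors each; the entrance
    itself is not instrumented, so each route's first observed sensor is the
    first sensor of its corridor.
    """
    return BehaviorDictionary(
        [
            Behavior("north", [("n1", 15.0, 3.0), ("n2", 2.0, 0.2)]),
            Behavior("east", [("e1", 15.0, 3.0), ("e2", 3.5, 0.35)]),
            Behavior("south", [("w1", 15.0, 3.0), ("w2", 5.0, 0.5)]),
        ],
        execution_probability=0.7,
        idle_mean=30.0,
        background_rate=0.002,
    )


def save_dictionary(dictionary: BehaviorDictionary, path) -> None:
    data = {
        "execution_probability": dictionary.execution_probability,
        "idle_mean": dictionary.idle_mean,
        "background_rate": dictionary.background_rate,
        "behaviors": [
            {"id": b.id, "steps": [[s, float(mg), float(sg)] for s, mg, sg in b.steps]}
            for b in dictionary.behaviors
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_dictionary(path) -> BehaviorDictionary:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    behaviors = [
        Behavior(b["id"], [(str(s), float(mg), float(sg)) for s, mg, sg in b["steps"]])
        for b in data["behaviors"]
    ]
    return BehaviorDictionary(
        behaviors,
        execution_probability=float(data.get("execution_probability", 1.0)),
        idle_mean=float(data.get("idle_mean", 0.0)),
        background_rate=data.get("background_rate"),
    )
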