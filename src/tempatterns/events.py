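"""Event-stream data model and basic delay computations.

An event stream is a time-sorted sequence of ``(time, event-type)`` records
produced by many simple sensors (or by behavioural coding).  Every statistic
downstream — intensities, inter-event times, first-following delays — is
computed from this container.  Times are continuous seconds; event types are
opaque string tokens (an atomic sensor ID, or a generated composite-pattern
ID such as ``"(A->B)"``).
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Event",
    "EventStream",
    "DelaySeries",
    "EventLogError",
    "read_event_log",
    "write_event_log",
    "inter_event_times",
    "first_following_delays",
]


class EventLogError(ValueError):
    """Malformed event-log input (message names the offending line)."""


@dataclass(frozen=True)
class Event:
    """A single sensor activation: onset time in seconds and the event type."""

    time: float
    etype: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be non-negative, got {self.time}")
        if not self.etype:
            raise ValueError("event type must be a non-empty string")


class EventStream:
    """Time-sorted event records with a total observation span ``T``.

    Events are kept sorted by ``(time, etype)`` — a deterministic tie-break
    for simultaneous activations.  The span defaults to ``last - first``
    event time but is usually overridden with the known observation length
    (e.g. the simulation duration), since intensities are estimated as
    ``lambda = N / span``.
    """

    def __init__(
        self,
        events: Iterable[Event | tuple[float, str]] = (),
        span: float | None = None,
        *,
        _presorted: bool = False,
    ) -> None:
        evs = [e if isinstance(e, Event) else Event(*e) for e in events]
        if not _presorted:
            evs.sort(key=lambda e: (e.time, e.etype))
        self.events: list[Event] = evs
        if span is None:
            span = evs[-1].time - evs[0].time if evs else 0.0
        if evs and span < evs[-1].time - evs[0].time - 1e-12:
            raise ValueError("span is shorter than the observed event range")
        self.span: float = float(span)
        self._by_type: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventStream)
            and self.span == other.span
            and self.events == other.events
        )

    @property
    def etypes(self) -> set[str]:
        return set(self.times_by_type().keys())

    def times_by_type(self) -> dict[str, np.ndarray]:
        """Per-type sorted time arrays (cached; the workhorse lookup)."""
        if not self._by_type and self.events:
            grouped: dict[str, list[float]] = {}
            for e in self.events:
                grouped.setdefault(e.etype, []).append(e.time)
            self._by_type = {k: np.asarray(v, dtype=float) for k, v in grouped.items()}
        return self._by_type

    def times_of(self, etype: str) -> np.ndarray:
        by = self.times_by_type()
        if etype not in by:
            raise KeyError(f"event type {etype!r} not present in stream")
        return by[etype]

    def count(self, etype: str) -> int:
        by = self.times_by_type()
        return len(by.get(etype, ()))

    def intensity(self, etype: str) -> float:
        """Estimated rate lambda = N / span, events per second."""
        n = self.count(etype)
        if self.span <= 0:
            raise ValueError("cannot estimate an intensity on a zero-span stream")
        return n / self.span

    def with_added(self, etype: str, times: Sequence[float]) -> "EventStream":
        """A new stream with extra events of one (possibly new) type."""
        extra = [Event(float(t), etype) for t in times]
        return EventStream(list(self.events) + extra, span=self.span)

    def restricted_to(self, etypes: Iterable[str]) -> "EventStream":
        keep = set(etypes)
        return EventStream(
            [e for e in self.events if e.etype in keep], span=self.span, _presorted=True
        )


@dataclass
class DelaySeries:
    """Positive delays (seconds) for one ordered pair, capped at a horizon."""

    values: np.ndarray
    source_pair: tuple[str, str]
    horizon: float
    has_ties: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def read_event_log(path, span_override: float | None = None) -> EventStream:
    """Read a ``time,sensor`` CSV into an :class:`EventStream`.

    Lines starting with ``#`` are treated as comments (artifact headers).
    Malformed rows raise :class:`EventLogError` naming the line number.
    """
    events: list[Event] = []
    with open(path, newline="", encoding="utf-8") as fh:
        lineno = 0
        header_seen = False
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            row = next(csv.reader(io.StringIO(line)))
            if not header_seen:
                cols = [c.strip().lower() for c in row]
                if cols[:2] != ["time", "sensor"]:
                    raise EventLogError(
                        f"{path}: line {lineno}: expected header 'time,sensor', got {line!r}"
                    )
                header_seen = True
                continue
            if len(row) < 2:
                raise EventLogError(f"{path}: line {lineno}: missing column in {line!r}")
            try:
                t = float(row[0])
            except ValueError as exc:
                raise EventLogError(
                    f"{path}: line {lineno}: unparseable time {row[0]!r}"
                ) from exc
            if t < 0:
                raise EventLogError(f"{path}: line {lineno}: negative time {t}")
            etype = row[1].strip()
            if not etype:
                raise EventLogError(f"{path}: line {lineno}: empty sensor identifier")
            events.append(Event(t, etype))
        if not header_seen and lineno > 0:
            raise EventLogError(f"{path}: no 'time,sensor' header found")
    return EventStream(events, span=span_override)


def write_event_log(stream: EventStream, path, header_comment: str | None = None) -> None:
    """Write a stream as sorted ``time,sensor`` CSV (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        writer = csv.writer(fh)
        writer.writerow(["time", "sensor"])
        for e in stream:
            writer.writerow([repr(e.time), e.etype])


def inter_event_times(stream: EventStream, etype: str) -> DelaySeries:
    """Successive differences of one event type's onset times.

    A single occurrence yields an empty series; exact ties yield zero delays,
    which are preserved and flagged on the returned series.
    """
    times = stream.times_of(etype)
    diffs = np.diff(times)
    has_ties = bool(len(diffs) and np.any(diffs == 0))
    if has_ties:
        warnings.warn(
            f"zero inter-event delays for {etype!r} (simultaneous activations)",
            stacklevel=2,
        )
    return DelaySeries(diffs, (etype, etype), horizon=np.inf, has_ties=has_ties)


def first_following_delays(
    stream: EventStream, a: str, b: str, horizon: float
) -> DelaySeries:
    """Delay from each A-onset to the first strictly later B, capped at ``horizon``.

    A B coincident with the A never pairs (strict inequality); A-occurrences
    with no following B inside the horizon contribute nothing.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    ta = stream.times_of(a)
    tb = stream.times_of(b)
    idx = np.searchsorted(tb, ta, side="right")
    ok = idx < len(tb)
    delays = tb[idx[ok]] - ta[ok]
    delays = delays[delays <= horizon]
    return DelaySeries(delays, (a, b), horizon=float(horizon))
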