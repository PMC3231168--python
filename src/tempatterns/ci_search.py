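"""Critical-interval detection and the hierarchical T-pattern mining loop.

A critical interval (CI) ``[d1, d2]`` for an ordered pair (A, B) is a lag
window in which a B-event is significantly more likely to follow an A-event
than chance predicts.  Under the null hypothesis that A and B are independent
Poisson processes with intensities ``lambda = N / T``, the probability that a
window of length ``d`` after a given A holds no B is ``pi0 = exp(-lambda_B * d)``,
and the number of A-occurrences whose window holds at least one B is binomial
over the ``N_A`` trials.  The one-sided tail of that binomial is the CI's
p-value.

Four search strategies over the discretized lag grid are provided:

* ``exhaustive``  — test every grid sub-interval, longest first (the original
  scheme; quadratic in the horizon).
* ``sitpat``      — greedy shrinking of the full-horizon interval from both
  ends, plus one-sided cleanup passes (linear in the horizon).
* ``ttpat``       — recursive halving, descending into the lower-p half
  (logarithmic in the horizon).
* ``gmmtpat``     — no interval search at all: an independence gate followed
  by a two-component Gaussian-mixture fit of the first-following delays
  (constant per pair; see :mod:`tempatterns.gmm`).

Accepted pairs are joined into composite event types (timestamped at the
first constituent's onset) and the search resumes on the expanded dictionary,
producing a hierarchy of patterns up to a configured depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .events import EventStream, first_following_delays

__all__ = [
    "CriticalInterval",
    "TPattern",
    "MiningConfig",
    "SearchTrace",
    "tpattern_p_value",
    "count_nab",
    "realized_onsets",
    "exhaustive_ci_search",
    "shrinking_ci_search",
    "tree_ci_search",
    "estimate_test_count",
    "bonferroni_threshold",
    "mine_tpatterns",
    "composite_id",
]


@dataclass(frozen=True)
class CriticalInterval:
    """Closed lag window [d1, d2] (seconds) after an A-onset."""

    d1: float
    d2: float

    def __post_init__(self) -> None:
        if not 0 < self.d1 <= self.d2:
            raise ValueError(f"require 0 < d1 <= d2, got [{self.d1}, {self.d2}]")

    def contains(self, delay: float) -> bool:
        return self.d1 <= delay <= self.d2


@dataclass
class TPattern:
    """A detected temporal pattern: left followed by right within the CI.

    Exactly one of ``p_value`` (binomial search methods) and ``strength``
    (GMM method) is set.  ``atoms`` flattens the pattern to its ordered
    atomic sensor constituents; ``depth = len(atoms)``.
    """

    left: str
    right: str
    ci: CriticalInterval
    n_ab: int
    atoms: tuple[str, ...]
    p_value: Optional[float] = None
    strength: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.p_value is None) == (self.strength is None):
            raise ValueError("exactly one of p_value/strength must be set")
        if self.depth < 2:
            raise ValueError("a pattern needs at least two atomic constituents")

    @property
    def depth(self) -> int:
        return len(self.atoms)

    def to_dict(self) -> dict:
        return {
            "left": self.left,
            "right": self.right,
            "d1": self.ci.d1,
            "d2": self.ci.d2,
            "p_value": self.p_value,
            "strength": self.strength,
            "n_ab": self.n_ab,
            "depth": self.depth,
            "atoms": list(self.atoms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TPattern":
        return cls(
            left=d["left"],
            right=d["right"],
            ci=CriticalInterval(d["d1"], d["d2"]),
            n_ab=d["n_ab"],
            atoms=tuple(d["atoms"]),
            p_value=d["p_value"],
            strength=d["strength"],
        )


@dataclass
class MiningConfig:
    """Knobs of the mining loop.

    horizon        — event horizon h: the longest lag considered (seconds).
    bin_width      — lag-grid resolution w; CI endpoints live on this grid.
    p_threshold    — binomial significance bound (0.005 is the customary one).
    bonferroni     — divide the threshold by the estimated total test count.
    method         — exhaustive | sitpat | ttpat | gmmtpat.
    max_depth      — largest number of atomic constituents per pattern.
    alpha_indep    — level of the uniformity independence gate (gmmtpat).
    max_delays     — cap on delays used per GMM fit (evenly subsampled).
    log_scale      — fit the GMM on log10 delays (diagnostic option).
    """

    horizon: float = 300.0
    bin_width: float = 1.0
    p_threshold: float = 0.005
    bonferroni: bool = False
    method: str = "gmmtpat"
    max_depth: int = 3
    alpha_indep: float = 0.05
    max_delays: int = 5000
    seed: int = 0
    log_scale: bool = False
    r_max: float = 0.25
    w_min: float = 0.1
    sitpat_two_sided_cleanup: bool = True

    def __post_init__(self) -> None:
        if not self.horizon >= self.bin_width > 0:
            raise ValueError("require horizon >= bin_width > 0")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.max_depth < 2:
            raise ValueError("max_depth must be at least 2")
        if self.method not in {"exhaustive", "sitpat", "ttpat", "gmmtpat"}:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def n_bins(self) -> int:
        return int(round(self.horizon / self.bin_width))


@dataclass
class SearchTrace:
    """Every (interval, p) pair evaluated during one CI search."""

    intervals_examined: list[tuple[CriticalInterval, float]] = field(default_factory=list)

    @property
    def tests_performed(self) -> int:
        return len(self.intervals_examined)

    def record(self, ci: CriticalInterval, p: float) -> None:
        self.intervals_examined.append((ci, p))


def tpattern_p_value(n_a: int, n_b: int, span: float, d: float, n_ab: int) -> float:
    """Binomial tail p-value for observing >= n_ab A-windows holding a B.

    ``p = 1 - sum_{k<n_ab} C(n_a, k) (1-pi0)^k pi0^(n_a-k)`` with
    ``pi0 = exp(-(n_b/span) d)``; evaluated as the stable upper binomial tail.
    """
    if n_ab > n_a:
        raise ValueError("n_ab cannot exceed n_a")
    if n_ab < 0 or n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    if d <= 0 or span <= 0:
        raise ValueError("interval length and span must be positive")
    if n_ab == 0:
        return 1.0
    pi0 = math.exp(-(n_b / span) * d)
    # sf(n_ab - 1) = P(X >= n_ab) for X ~ Binomial(n_a, 1 - pi0)
    return float(stats.binom.sf(n_ab - 1, n_a, 1.0 - pi0))


def count_nab(stream: EventStream, a: str, b: str, ci: CriticalInterval) -> int:
    """Number of A-occurrences whose closed window [t+d1, t+d2] holds >= 1 B."""
    ta = stream.times_of(a)
    try:
        tb = stream.times_of(b)
    except KeyError:
        return 0
    if len(tb) == 0 or len(ta) == 0:
        return 0
    lo = np.searchsorted(tb, ta + ci.d1, side="left")
    hit = (lo < len(tb)) & (tb[np.minimum(lo, len(tb) - 1)] <= ta + ci.d2)
    return int(np.count_nonzero(hit))


def realized_onsets(stream: EventStream, a: str, b: str, ci: CriticalInterval) -> np.ndarray:
    """Onset times of the A-occurrences that realize the pattern (>= 1 B in CI)."""
    ta = stream.times_of(a)
    tb = stream.times_of(b)
    if len(tb) == 0:
        return np.empty(0)
    lo = np.searchsorted(tb, ta + ci.d1, side="left")
    hit = (lo < len(tb)) & (tb[np.minimum(lo, len(tb) - 1)] <= ta + ci.d2)
    return ta[hit]


def _grid_tester(
    stream: EventStream, a: str, b: str, config: MiningConfig
) -> Callable[[int, int], tuple[CriticalInterval, float]]:
    """Binomial p evaluator on the lag grid; bins are 1-based inclusive.

    Grid interval (i, j) maps to the closed window [i*w, j*w] whose measure,
    as used in pi0, is the closed grid interval's (j - i + 1) * w.
    """
    w = config.bin_width
    n_a = stream.count(a)
    n_b = stream.count(b)
    span = stream.span
    cache: dict[tuple[int, int], tuple[CriticalInterval, float]] = {}

    def test(i: int, j: int) -> tuple[CriticalInterval, float]:
        key = (i, j)
        if key not in cache:
            ci = CriticalInterval(i * w, j * w)
            nab = count_nab(stream, a, b, ci)
            p = tpattern_p_value(n_a, n_b, span, (j - i + 1) * w, nab)
            cache[key] = (ci, p)
        return cache[key]

    return test


def _threshold(stream: EventStream, config: MiningConfig, n_sensors: int | None) -> float:
    if not config.bonferroni:
        return config.p_threshold
    n = n_sensors if n_sensors is not None else len(stream.etypes)
    return bonferroni_threshold(
        config.p_threshold, estimate_test_count(config.method, n, config.n_bins)
    )


def _make_pattern(
    stream: EventStream,
    a: str,
    b: str,
    ci: CriticalInterval,
    p: float,
    atoms_of: dict[str, tuple[str, ...]] | None = None,
) -> TPattern:
    atoms_of = atoms_of or {}
    atoms = atoms_of.get(a, (a,)) + atoms_of.get(b, (b,))
    return TPattern(
        left=a,
        right=b,
        ci=ci,
        n_ab=count_nab(stream, a, b, ci),
        atoms=atoms,
        p_value=p,
    )


def exhaustive_ci_search(
    stream: EventStream,
    a: str,
    b: str,
    config: MiningConfig,
    threshold: float | None = None,
    atoms_of: dict[str, tuple[str, ...]] | None = None,
) -> tuple[Optional[TPattern], SearchTrace]:
    """Original scheme: test every grid interval from the longest down.

    Intervals of equal length are visited left to right; the first interval
    beating the threshold wins.  The trace records every test performed.
    """
    trace = SearchTrace()
    if stream.count(a) == 0 or b not in stream.etypes:
        return None, trace
    thr = threshold if threshold is not None else _threshold(stream, config, None)
    test = _grid_tester(stream, a, b, config)
    m = config.n_bins
    for length in range(m, 0, -1):
        for i in range(1, m - length + 2):
            ci, p = test(i, i + length - 1)
            trace.record(ci, p)
            if p < thr:
                return _make_pattern(stream, a, b, ci, p, atoms_of), trace
    return None, trace


def shrinking_ci_search(
    stream: EventStream,
    a: str,
    b: str,
    config: MiningConfig,
    threshold: float | None = None,
    atoms_of: dict[str, tuple[str, ...]] | None = None,
) -> tuple[Optional[TPattern], SearchTrace]:
    """Greedy shrinking-interval search (linear in the horizon).

    Phase 1 starts from the full horizon and repeatedly drops the left or
    right bin, whichever lowers the p-value more, stopping when neither does
    (p is non-increasing along the accepted path).  Phase 2 then runs a
    left-only and a right-only shrink pass down to unit width from the phase-1
    interval, to handle two separate lag modes; the minimum-p significant
    interval over everything examined is returned.
    """
    trace = SearchTrace()
    if stream.count(a) == 0 or b not in stream.etypes:
        return None, trace
    thr = threshold if threshold is not None else _threshold(stream, config, None)
    test = _grid_tester(stream, a, b, config)
    m = config.n_bins

    def rec(i: int, j: int) -> float:
        ci, p = test(i, j)
        trace.record(ci, p)
        return p

    i, j = 1, m
    best_i, best_j, best_p = i, j, rec(i, j)
    cur_p = best_p
    while j > i:
        p_left = rec(i + 1, j)
        p_right = rec(i, j - 1)
        if min(p_left, p_right) >= cur_p:
            break
        if p_left <= p_right:
            i, cur_p = i + 1, p_left
        else:
            j, cur_p = j - 1, p_right
        if cur_p < best_p:
            best_i, best_j, best_p = i, j, cur_p

    if config.sitpat_two_sided_cleanup:
        for ii in range(i + 1, j + 1):  # left-only pass to unit width
            p = rec(ii, j)
            if p < best_p:
                best_i, best_j, best_p = ii, j, p
        for jj in range(j - 1, i - 1, -1):  # right-only pass to unit width
            p = rec(i, jj)
            if p < best_p:
                best_i, best_j, best_p = i, jj, p

    if best_p < thr:
        ci, p = test(best_i, best_j)
        return _make_pattern(stream, a, b, ci, p, atoms_of), trace
    return None, trace


def tree_ci_search(
    stream: EventStream,
    a: str,
    b: str,
    config: MiningConfig,
    threshold: float | None = None,
    atoms_of: dict[str, tuple[str, ...]] | None = None,
) -> tuple[Optional[TPattern], SearchTrace]:
    """Binary-splitting search (logarithmic in the horizon).

    Tests the full horizon, then recursively halves the current interval,
    descending into the lower-p half until unit width; returns the minimum-p
    interval on the path if it beats the threshold.
    """
    trace = SearchTrace()
    if stream.count(a) == 0 or b not in stream.etypes:
        return None, trace
    thr = threshold if threshold is not None else _threshold(stream, config, None)
    test = _grid_tester(stream, a, b, config)
    m = config.n_bins

    def rec(i: int, j: int) -> float:
        ci, p = test(i, j)
        trace.record(ci, p)
        return p

    i, j = 1, m
    best_i, best_j, best_p = i, j, rec(i, j)
    while j > i:
        mid = (i + j) // 2
        p_left = rec(i, mid)
        p_right = rec(mid + 1, j)
        if p_left <= p_right:
            j, cur_p = mid, p_left
        else:
            i, cur_p = mid + 1, p_right
        if cur_p < best_p:
            best_i, best_j, best_p = i, j, cur_p

    if best_p < thr:
        ci, p = test(best_i, best_j)
        return _make_pattern(stream, a, b, ci, p, atoms_of), trace
    return None, trace


def estimate_test_count(method: str, n_sensors: int, horizon_bins: int) -> int:
    """Expected number of independence tests for a full mining run.

    With ``n`` sensors there are ``n^2`` elementary candidate pairs; assuming
    roughly ``m = 3n`` accepted elementary patterns (mesh neighbours plus the
    self-loop), tertiary candidates add ``nm = 3n^2`` more, giving ``4 n^2``
    pair tests overall.  Per pair, the exhaustive scheme performs
    ``h(h+1)/2`` interval tests, the shrinking search about ``3h/2`` and the
    tree search about ``2 log2 h``, while the GMM scheme performs exactly one
    — hence the totals below.
    """
    if n_sensors < 1:
        raise ValueError("n_sensors must be >= 1")
    if horizon_bins < 2:
        raise ValueError("horizon_bins must be >= 2")
    n2 = n_sensors**2
    h = horizon_bins
    if method == "exhaustive":
        value = 2 * h * (h + 1) * n2
    elif method == "sitpat":
        value = 6 * h * n2
    elif method == "ttpat":
        value = 8 * math.log2(h) * n2
    elif method == "gmmtpat":
        value = 4 * n2
    else:
        raise ValueError(f"unknown method {method!r}")
    return int(round(value))


def bonferroni_threshold(p_threshold: float, alpha_estimate: float) -> float:
    """Family-wise threshold: the per-test bound divided by the test count."""
    if alpha_estimate < 1:
        raise ValueError("alpha_estimate must be >= 1")
    return p_threshold / alpha_estimate


_SEARCHERS = {
    "exhaustive": exhaustive_ci_search,
    "sitpat": shrinking_ci_search,
    "ttpat": tree_ci_search,
}


def composite_id(left: str, right: str) -> str:
    return f"({left}->{right})"


def mine_tpatterns(
    stream: EventStream, config: MiningConfig
) -> tuple[list[TPattern], SearchTrace]:
    """Hierarchical mining loop over an event stream.

    Round 1 tests every ordered pair of atomic types (self-pairs included)
    with the configured search method; each accepted pattern spawns a
    composite event type whose occurrences are the onsets of the realized
    (A, B-in-CI) pairs.  Later rounds pair the newly created composites with
    atomic types (in both orders) until ``max_depth`` constituents; pairs
    already joined are not re-tested.  The Bonferroni adjustment, when
    enabled, divides the significance threshold (the binomial bound, or the
    independence-gate level for the GMM method) by the estimated total test
    count.  Output order is deterministic: by depth, then evidence (ascending
    p-value or descending strength), then lexicographic.
    """
    from .gmm import gmmtpat_detect  # local import to avoid a cycle

    if len(stream) == 0:
        return [], SearchTrace()

    atomics = sorted(stream.etypes)
    n_atomic = len(atomics)
    trace = SearchTrace()
    thr = bonferroni_threshold(
        config.p_threshold, estimate_test_count(config.method, n_atomic, config.n_bins)
    ) if config.bonferroni else config.p_threshold
    alpha = bonferroni_threshold(
        config.alpha_indep, estimate_test_count(config.method, n_atomic, config.n_bins)
    ) if config.bonferroni else config.alpha_indep

    def detect(work: EventStream, x: str, y: str, atoms_of) -> Optional[TPattern]:
        if config.method == "gmmtpat":
            return gmmtpat_detect(work, x, y, config, alpha=alpha, atoms_of=atoms_of)
        pat, tr = _SEARCHERS[config.method](work, x, y, config, threshold=thr, atoms_of=atoms_of)
        trace.intervals_examined.extend(tr.intervals_examined)
        return pat

    work = stream
    atoms_of: dict[str, tuple[str, ...]] = {t: (t,) for t in atomics}
    patterns: list[TPattern] = []
    tested: set[tuple[str, str]] = set()
    frontier = list(atomics)  # types whose pairings are due this round

    while frontier:
        accepted: list[TPattern] = []
        pairs: list[tuple[str, str]] = []
        for x in frontier:
            for y in atomics:
                if (x, y) not in tested:
                    pairs.append((x, y))
                if x not in atomics and (y, x) not in tested:
                    pairs.append((y, x))
        for x, y in sorted(set(pairs)):
            if len(atoms_of[x]) + len(atoms_of[y]) > config.max_depth:
                continue
            tested.add((x, y))
            pat = detect(work, x, y, atoms_of)
            if pat is not None:
                accepted.append(pat)
        new_frontier: list[str] = []
        for pat in accepted:
            patterns.append(pat)
            if pat.depth < config.max_depth:
                cid = composite_id(pat.left, pat.right)
                if cid not in atoms_of:
                    onsets = realized_onsets(work, pat.left, pat.right, pat.ci)
                    if len(onsets):
                        work = work.with_added(cid, onsets)
                        atoms_of[cid] = pat.atoms
                        new_frontier.append(cid)
        frontier = new_frontier

    # exact-duplicate removal + deterministic ordering
    seen: set[tuple] = set()
    unique: list[TPattern] = []
    for pat in patterns:
        key = (pat.left, pat.right, pat.ci.d1, pat.ci.d2)
        if key not in seen:
            seen.add(key)
            unique.append(pat)
    unique.sort(
        key=lambda p: (
            p.depth,
            p.p_value if p.p_value is not None else -p.strength,
            p.left,
            p.right,
        )
    )
    return unique, trace
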