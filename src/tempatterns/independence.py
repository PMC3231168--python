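"""Point-process independence test via the uniformity of bracketed A-events.

If A and B are independent temporal point processes, then an A-event falling
between two successive B-events is uniformly placed within that B-interval:
the ratio

    U(k) = (B_{k*} - A_k) / (B_{k*} - B_{k*-1})

is Uniform(0, 1).  Departures from uniformity (tested with a one-sample
Kolmogorov-Smirnov test) reveal a temporal dependence, and only then is a
critical-interval search worthwhile.  The ratio is invariant to common time
shifts and rescalings, and approximately so under slowly varying intensities
(locally linear time deformations preserve uniformity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import EventStream

__all__ = ["UniformityResult", "uniformity_ratios", "ks_uniform_test", "is_independent"]

#: Minimum number of ratios before a rejection is allowed; below this the
#: verdict is "independent" (conservative: insufficient evidence).
N_MIN_RATIOS = 10

#: Sample size up to which the exact small-sample KS null distribution is used.
KS_EXACT_MAX_N = 35


@dataclass
class UniformityResult:
    """KS uniformity test outcome for one ordered pair of event types."""

    ratios: np.ndarray
    ks_statistic: float
    p_value: float

    @property
    def n(self) -> int:
        return len(self.ratios)


def uniformity_ratios(stream: EventStream, a: str, b: str) -> np.ndarray:
    """U(k) ratios for every A-event strictly inside a B-interval.

    A-events at or before the first B, at or after the last B, or exactly
    coincident with a B are excluded.  Each bracketed A-event contributes its
    own ratio (several A's may share one B-interval).
    """
    ta = stream.times_of(a)
    tb = stream.times_of(b)
    if len(tb) < 2:
        return np.empty(0)
    j = np.searchsorted(tb, ta, side="right")  # tb[j] > t, tb[j-1] <= t
    ok = (j >= 1) & (j < len(tb))
    t = ta[ok]
    j = j[ok]
    strict = tb[j - 1] < t  # drop A coincident with the left B
    t, j = t[strict], j[strict]
    return (tb[j] - t) / (tb[j] - tb[j - 1])


def ks_uniform_test(ratios) -> UniformityResult:
    """One-sample KS test of the ratios against Uniform(0, 1).

    Uses the exact null distribution for n <= 35 and the asymptotic series
    otherwise; deterministic for fixed input.
    """
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) == 0:
        raise ValueError("cannot run a KS test on an empty ratio list")
    if np.any((ratios < 0) | (ratios > 1)):
        raise ValueError("uniformity ratios must lie in [0, 1]")
    mode = "exact" if len(ratios) <= KS_EXACT_MAX_N else "asymp"
    res = stats.kstest(ratios, "uniform", method=mode)
    return UniformityResult(ratios, float(res.statistic), float(res.pvalue))


def is_independent(
    stream: EventStream,
    a: str,
    b: str,
    alpha_indep: float = 0.05,
    n_min: int = N_MIN_RATIOS,
) -> tuple[bool, UniformityResult | None]:
    """Accept or reject independence of the (A, B) pair at level ``alpha_indep``.

    Returns ``(True, result)`` when the uniformity hypothesis stands (no
    pattern search is warranted) and ``(False, result)`` on rejection.  With
    fewer than ``n_min`` ratios the verdict defaults to independent, with a
    warning — too little evidence to reject.
    """
    if not 0 < alpha_indep < 1:
        raise ValueError("alpha_indep must be in (0, 1)")
    ratios = uniformity_ratios(stream, a, b)
    if len(ratios) < n_min:
        warnings.warn(
            f"only {len(ratios)} uniformity ratios for ({a!r}, {b!r}); "
            "treating the pair as independent (insufficient evidence)",
            stacklevel=2,
        )
        result = ks_uniform_test(ratios) if len(ratios) else None
        return True, result
    result = ks_uniform_test(ratios)
    return result.p_value >= alpha_indep, result
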