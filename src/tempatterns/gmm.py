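"""Two-component Gaussian-mixture modelling of first-following delays.

Aligning every A-event at lag zero and collecting the first subsequent
B-event per A gives a one-dimensional delay sample.  When A genuinely tends
to induce B after a characteristic lag, that sample shows one sharp,
localized peak riding on a flat, broad background of unrelated B-events.  A
two-component univariate Gaussian mixture, fitted by EM, separates the two:
the narrow ("sharp") component's mean and standard deviation immediately
yield the critical interval (mean +/- 2 sd by default), and the contrast
between the two components gives a pattern strength used for ranking.

The EM fitter here is deterministic: the sharp component is initialized at
the histogram mode with a tenth of the data spread, the diffuse one at the
sample mean and spread.  A variance floor prevents singular collapse on
(near-)degenerate samples.  Delay samples larger than the configured cap
(5,000 by default) are evenly subsampled first — beyond that size the delay
distribution is already well approximated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ci_search import CriticalInterval, MiningConfig, TPattern, count_nab
from .events import DelaySeries, EventStream, first_following_delays
from .independence import is_independent

__all__ = [
    "GaussianComponent",
    "Gmm2Fit",
    "fit_two_component_gmm",
    "critical_interval_from_gmm",
    "pattern_strength",
    "gmmtpat_detect",
]

#: Minimum number of delays required before fitting.
N_MIN_DELAYS = 10

#: Lower clamp for the CI's left edge (seconds); keeps d1 strictly positive.
CI_EPS = 1e-6

_MAX_ITER = 100
_TOL = 1e-8
_SOFT_ITER_WARN = 25


@dataclass
class GaussianComponent:
    """One mixture component: weight, mean and sd (seconds, or log10-seconds)."""

    weight: float
    mean: float
    sd: float


@dataclass
class Gmm2Fit:
    """EM fit of the two-component delay mixture (sharp = smaller sd)."""

    sharp: GaussianComponent
    diffuse: GaussianComponent
    log_scale: bool
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray


def _subsample(values: np.ndarray, cap: int) -> np.ndarray:
    """Deterministic evenly spaced subsample down to ``cap`` values."""
    if len(values) <= cap:
        return values
    idx = np.linspace(0, len(values) - 1, cap).round().astype(int)
    return values[idx]


def _norm_pdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    z = (x - mean) / sd
    return np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))


def fit_two_component_gmm(
    delays: DelaySeries | np.ndarray,
    log_scale: bool = False,
    seed: int = 0,
    max_delays: int = 5000,
    n_min: int = N_MIN_DELAYS,
) -> Gmm2Fit:
    """Fit the sharp + diffuse mixture to a delay sample by EM.

    Deterministic for fixed input (the seed is reserved for optional random
    restarts, unused by the default deterministic initialization).  Converges
    when the relative log-likelihood change drops below 1e-8, or at 100
    iterations.  The log-likelihood is checked to be non-decreasing on every
    run.
    """
    x = np.asarray(delays.values if isinstance(delays, DelaySeries) else delays, float)
    if len(x) < n_min:
        raise ValueError(f"need at least {n_min} delays, got {len(x)}")
    if log_scale:
        if np.any(x <= 0):
            raise ValueError("log-scale fitting requires strictly positive delays")
        x = np.log10(x)
    x = _subsample(np.sort(x), max_delays)

    spread = x.std()
    data_range = x.max() - x.min()
    var_floor = max(1e-6 * data_range**2, 1e-12)
    sd_floor = np.sqrt(var_floor)

    # deterministic init: sharp at the histogram mode (fine bins, narrow start
    # so EM can lock onto a localized peak), diffuse at the sample stats
    nbins = max(10, min(100, len(x)))
    hist, edges = np.histogram(x, bins=nbins)
    k = int(np.argmax(hist))
    mode = 0.5 * (edges[k] + edges[k + 1])
    bin_w = edges[1] - edges[0]
    w = np.array([0.5, 0.5])
    mu = np.array([mode, x.mean()])
    sd = np.array([max(bin_w, sd_floor), max(spread, sd_floor)])

    loglik_path = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        dens = np.stack([w[k] * _norm_pdf(x, mu[k], sd[k]) for k in (0, 1)])
        total = dens.sum(axis=0)
        total = np.maximum(total, 1e-300)
        ll = float(np.log(total).sum())
        loglik_path.append(ll)
        resp = dens / total
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / len(x)
        mu = (resp @ x) / nk
        var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in (0, 1)])
        sd = np.sqrt(np.maximum(var, var_floor))
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= _TOL * (abs(prev_ll) + 1.0):
            converged = True
            break
        prev_ll = ll
    if n_iter > _SOFT_ITER_WARN:
        warnings.warn(f"EM used {n_iter} iterations (1-D fits usually need far fewer)")

    order = np.argsort(sd)  # sharp = smaller sd
    comps = [GaussianComponent(float(w[k]), float(mu[k]), float(sd[k])) for k in order]
    return Gmm2Fit(
        sharp=comps[0],
        diffuse=comps[1],
        log_scale=log_scale,
        loglik=loglik_path[-1],
        n_iter=n_iter,
        converged=converged,
        loglik_path=np.asarray(loglik_path),
    )


def critical_interval_from_gmm(fit: Gmm2Fit, k_sd: float = 2.0) -> CriticalInterval:
    """CI = sharp mean +/- ``k_sd`` standard deviations, clamped positive.

    For a log-scale fit the endpoints are mapped back to seconds
    (``10 ** (m +/- k s)``).
    """
    m, s = fit.sharp.mean, fit.sharp.sd
    if fit.log_scale:
        return CriticalInterval(10.0 ** (m - k_sd * s), 10.0 ** (m + k_sd * s))
    return CriticalInterval(max(CI_EPS, m - k_sd * s), max(CI_EPS, m + k_sd * s))


def pattern_strength(fit: Gmm2Fit) -> float:
    """Evidence contrast between the two components.

    Ratio of the weighted component densities evaluated at the sharp mean:
    ``(w1 phi(m1; m1, s1)) / (w2 phi(m1; m2, s2))`` — larger for sharper,
    heavier first components; equals ``w1/w2`` for identical components.
    """
    s, d = fit.sharp, fit.diffuse
    num = s.weight * _norm_pdf(np.array([s.mean]), s.mean, s.sd)[0]
    den = d.weight * _norm_pdf(np.array([s.mean]), d.mean, d.sd)[0]
    return float(num / max(den, 1e-300))


def gmmtpat_detect(
    stream: EventStream,
    a: str,
    b: str,
    config: MiningConfig,
    alpha: float | None = None,
    atoms_of: dict[str, tuple[str, ...]] | None = None,
) -> Optional[TPattern]:
    """GMM-based pattern detection for one ordered pair (at most one test).

    Pipeline: (1) the uniformity independence gate — if the pair looks
    independent, stop; (2) collect first-following delays within the horizon;
    (3) fit the two-component mixture; (4) accept only a genuinely sharp and
    non-negligible first component (``sharp.sd <= r_max * diffuse.sd`` and
    ``sharp.weight >= w_min``); (5) CI from two standard deviations, with the
    pattern strength attached.
    """
    alpha = config.alpha_indep if alpha is None else alpha
    independent, _ = is_independent(stream, a, b, alpha_indep=alpha)
    if independent:
        return None
    delays = first_following_delays(stream, a, b, config.horizon)
    if len(delays) < N_MIN_DELAYS:
        return None
    fit = fit_two_component_gmm(
        delays, log_scale=config.log_scale, seed=config.seed, max_delays=config.max_delays
    )
    if fit.sharp.sd > config.r_max * fit.diffuse.sd:
        return None
    if fit.sharp.weight < config.w_min:
        return None
    ci = critical_interval_from_gmm(fit)
    atoms_of = atoms_of or {}
    atoms = atoms_of.get(a, (a,)) + atoms_of.get(b, (b,))
    return TPattern(
        left=a,
        right=b,
        ci=ci,
        n_ab=count_nab(stream, a, b, ci),
        atoms=atoms,
        strength=pattern_strength(fit),
    )
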