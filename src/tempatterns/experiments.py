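"""Reproducible end-to-end study protocols on the packaged simulator.

Each function runs one self-contained experiment — simulate, mine, evaluate
— at fixed, documented problem sizes, and returns plain dictionaries of the
quantities of interest.  These protocols back both the statistical checks in
the test suite and the reproduction script; all randomness flows from the
caller's seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .ci_search import MiningConfig, mine_tpatterns
from .compression import alz_train, lz78_train, lzw_train
from .evaluation import (
    ClusterTruth,
    evaluate_prediction,
    score_patterns,
    tpattern_predictor,
    trie_predictor,
)
from .events import EventStream
from .gmm import critical_interval_from_gmm, fit_two_component_gmm
from .independence import ks_uniform_test, uniformity_ratios
from .simulate import (
    corridor_chain,
    make_cluster_layout,
    office_layout_a,
    office_layout_b,
    simulate_stream,
)
from .topology import build_graph, prune_graph

__all__ = [
    "poisson_pair",
    "lagged_pair",
    "independence_calibration",
    "gmm_recovery",
    "prediction_benchmark",
    "cluster_benchmark",
    "corridor_topology",
]


def poisson_pair(seed: int, rate: float = 0.1, span: float = 1e4) -> EventStream:
    """Two independent homogeneous Poisson processes of the given rate."""
    rng = np.random.default_rng(seed)
    n_draw = int(rate * span * 1.3) + 50
    ta = np.cumsum(rng.exponential(1.0 / rate, n_draw))
    tb = np.cumsum(rng.exponential(1.0 / rate, n_draw))
    events = [(float(t), "A") for t in ta if t < span]
    events += [(float(t), "B") for t in tb if t < span]
    return EventStream(events, span=span)


def lagged_pair(
    seed: int, lag: float = 1.0, jitter: float = 0.05, rate: float = 0.1, span: float = 1e4
) -> EventStream:
    """A Poisson A-process with every B trailing its A by lag +- jitter."""
    rng = np.random.default_rng(seed)
    ta = np.cumsum(rng.exponential(1.0 / rate, int(rate * span * 1.3) + 50))
    ta = ta[ta < span - lag - 5 * jitter]
    tb = ta + rng.normal(lag, jitter, len(ta))
    events = [(float(t), "A") for t in ta] + [(float(t), "B") for t in tb if 0 < t < span]
    return EventStream(events, span=span)


def independence_calibration(
    seed: int, n_replicates: int = 1000, alpha: float = 0.05
) -> dict:
    """Type-I error and power of the KS uniformity test.

    Runs ``n_replicates`` independent Poisson pairs (rate 0.1/s, span 1e4 s)
    and the same number of 1 s +- 0.05 s lagged pairs; returns the rejection
    rates at the given level.
    """
    base = int(seed) * 1_000_003 % 2**31
    null_rej = 0
    for k in range(n_replicates):
        s = poisson_pair((base + k) % 2**31)
        r = ks_uniform_test(uniformity_ratios(s, "A", "B"))
        null_rej += r.p_value < alpha
    dep_rej = 0
    n_dep = max(200, n_replicates // 5)
    for k in range(n_dep):
        s = lagged_pair((base + 7_777 + k) % 2**31)
        r = ks_uniform_test(uniformity_ratios(s, "A", "B"))
        dep_rej += r.p_value < alpha
    return {
        "null_rejection_rate": null_rej / n_replicates,
        "dependent_rejection_rate": dep_rej / n_dep,
        "n_replicates": n_replicates,
    }


def gmm_recovery(
    seed: int,
    n_seeds: int = 100,
    n: int = 2000,
    sharp=(5.0, 0.5, 0.6),
    diffuse=(60.0, 20.0),
) -> dict:
    """Sharp-component recovery across seeds of a known two-part mixture.

    Samples ``w1 N(m1, s1^2) + (1 - w1) N(m2, s2^2)``, fits the EM mixture,
    and reports the median absolute error of the sharp mean, how often the
    two-standard-deviation CI covers the true lag, and whether every EM run
    kept a non-decreasing log-likelihood.
    """
    m1, s1, w1 = sharp
    m2, s2 = diffuse
    base = int(seed) * 97 % 2**31
    errors, covered, monotone = [], 0, True
    for k in range(n_seeds):
        rng = np.random.default_rng((base + k) % 2**31)
        n1 = rng.binomial(n, w1)
        x = np.concatenate([rng.normal(m1, s1, n1), rng.normal(m2, s2, n - n1)])
        fit = fit_two_component_gmm(x)
        errors.append(abs(fit.sharp.mean - m1))
        covered += critical_interval_from_gmm(fit).contains(m1)
        diffs = np.diff(fit.loglik_path)
        if np.any(diffs < -1e-7 * (np.abs(fit.loglik_path[:-1]) + 1)):
            monotone = False
    return {
        "median_abs_error": float(np.median(errors)),
        "ci_coverage": covered / n_seeds,
        "loglik_monotone": monotone,
        "n_seeds": n_seeds,
    }


def prediction_benchmark(
    seed: int,
    n_users: int = 2,
    duration: float = 30000.0,
    confidence: float = 0.2,
    layouts=(office_layout_a, office_layout_b),
) -> list[dict]:
    """Head-to-head next-event prediction on the office fixtures.

    For each layout: simulate independent train and test streams, mine
    GMM-based T-patterns on the training stream, train the three
    compression baselines on the same symbol sequence, and score everyone on
    the test stream at the given confidence level (abstentions wrong).
    """
    results = []
    for layout in layouts:
        d = layout()
        train, _ = simulate_stream(d, n_users, duration, seed=seed)
        test, _ = simulate_stream(d, n_users, duration, seed=(seed + 10007) % 2**31)
        cfg = MiningConfig(horizon=300.0, bin_width=1.0, method="gmmtpat", max_depth=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            patterns, _ = mine_tpatterns(train, cfg)
        known = {e.etype for e in train}
        symbols = [e.etype for e in train]
        accuracy = {
            "gmmtpat": evaluate_prediction(
                test, tpattern_predictor(patterns, test), confidence, known
            ).accuracy_all,
            "lz78": evaluate_prediction(
                test, trie_predictor(lz78_train(symbols)), confidence, known
            ).accuracy_all,
            "lzw": evaluate_prediction(
                test, trie_predictor(lzw_train(symbols, set(symbols))), confidence, known
            ).accuracy_all,
            "alz": evaluate_prediction(
                test, trie_predictor(alz_train(symbols)), confidence, known
            ).accuracy_all,
        }
        results.append(
            {
                "layout": layout.__name__,
                "accuracy": accuracy,
                "gmm_wins": all(
                    accuracy["gmmtpat"] > accuracy[m] for m in ("lz78", "lzw", "alz")
                ),
                "n_patterns": len(patterns),
            }
        )
    return results


def cluster_benchmark(
    seed: int,
    n_clusters: int = 5,
    n_users: int = 2,
    duration: float = 4000.0,
    methods=("sitpat", "ttpat", "gmmtpat"),
) -> dict:
    """Correct/spurious/gray/missed scoring on the cluster-triplet testbed.

    Mines elementary patterns with each method, with and without Bonferroni
    adjustment, on one simulated stream of remotely located sensor-triplet
    clusters, and scores them against the generating cluster structure.
    """
    dictionary, truth = make_cluster_layout(n_clusters)
    stream, _ = simulate_stream(dictionary, n_users, duration, seed=seed)
    out: dict = {"n_events": len(stream), "scores": {}}
    for method in methods:
        for bonferroni in (False, True):
            cfg = MiningConfig(
                horizon=300.0, bin_width=1.0, method=method,
                bonferroni=bonferroni, max_depth=2,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                patterns, trace = mine_tpatterns(stream, cfg)
            sc = score_patterns(patterns, truth)
            key = f"{method}{'_bonferroni' if bonferroni else ''}"
            out["scores"][key] = {
                "correct": sc.correct,
                "spurious": sc.spurious,
                "gray": sc.gray,
                "missed": sc.missed,
                "tests": trace.tests_performed,
            }
    return out


def corridor_topology(seed: int, n_sensors: int = 5, duration: float = 15000.0) -> dict:
    """Corridor roadmap recovery: simulate, GMM-mine, build and prune.

    Returns the pruned edge set, whether it equals the true path graph, and
    whether pruning is idempotent.
    """
    stream, _ = simulate_stream(corridor_chain(n_sensors), 1, duration, seed=seed)
    cfg = MiningConfig(horizon=300.0, bin_width=1.0, method="gmmtpat", max_depth=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        patterns, _ = mine_tpatterns(stream, cfg)
    g = build_graph([p for p in patterns if p.depth == 2])
    pruned = prune_graph(g)
    edges = sorted(tuple(sorted(e)) for e in pruned.edges)
    expected = sorted((f"s{i}", f"s{i+1}") for i in range(1, n_sensors))
    again = prune_graph(pruned)
    return {
        "pruned_edges": edges,
        "is_path_graph": edges == expected,
        "idempotent": sorted(tuple(sorted(e)) for e in again.edges) == edges,
        "n_raw_edges": g.number_of_edges(),
    }
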