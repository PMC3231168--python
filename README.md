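# tempatterns

Temporal-pattern (**T-pattern**) mining for timestamped event streams from
many simple sensors — motion detectors in a building, interruption sensors
in an office, or behavioural event codings. The package detects *critical
intervals*: lag windows `[d1, d2]` in which one event type significantly
anticipates another, builds hierarchies of such patterns, uses them for
next-event prediction and for reconstructing the sensor topology of an
environment, and ships a multi-actor stream simulator so everything can be
exercised end to end without external data.

## The statistics at the core

Treating each event type as a point process with intensity `λ = N/T`, the
null hypothesis for a pair (A, B) is that the two processes are independent
Poisson processes. Under that null:

* **Binomial CI test.** For a candidate interval `[d1, d2]` of length `d`,
  the probability that the window after a given A-event holds no B-event is
  `π₀ = exp(−λ_B d)`, so the number of A-events whose window holds at least
  one B is binomial over the `N_A` trials. The upper tail
  `p = 1 − Σ_{k<N_AB} C(N_A,k)(1−π₀)^k π₀^(N_A−k)` scores the interval;
  `p < 0.005` is the customary significance bound. Search strategies over
  the lag grid range from exhaustive enumeration (quadratic in the horizon
  `h`) through greedy interval shrinking (linear) and binary splitting
  (logarithmic).
* **Independence gate.** If A and B are independent, an A-event falling
  between two successive B-events is uniformly placed in that interval:
  `U(k) = (B_{k*} − A_k)/(B_{k*} − B_{k*−1}) ~ U(0,1)`. A one-sample
  Kolmogorov–Smirnov test of the collected ratios screens pairs before any
  interval search — one test per pair, independent of `h`.
* **GMM critical intervals.** For a dependent pair, the first-following
  delays (every A aligned at lag zero, first subsequent B collected) are
  modelled as a two-component Gaussian mixture fitted by EM: a sharp,
  localized component sits on the characteristic lag, a flat broad one
  absorbs unrelated events. The critical interval is the sharp mean ± 2 sd,
  and the contrast between components (weighted density ratio at the sharp
  mean) gives a pattern *strength* used to rank edges when reconstructing
  the sensor-topology graph.
* **Multiple testing.** A Bonferroni adjustment divides the significance
  threshold by the analytically estimated total test count
  (e.g. `6hn²` for the shrinking search, `8 log₂(h) n²` for the tree
  search, `4n²` for the GMM route, `2h(h+1)n²` for exhaustive search).

Baselines for prediction are the Lempel-Ziv family (LZ78, LZW, Active LeZi)
as frequency-annotated phrase tries with confidence-thresholded posteriors.

## Worked example

Simulate a five-sensor corridor, mine GMM-based T-patterns, and recover the
corridor topology:

```python
from tempatterns import (MiningConfig, mine_tpatterns, build_graph,
                         prune_graph, corridor_chain, simulate_stream)

stream, truth = simulate_stream(corridor_chain(5), n_users=1,
                                duration=8000.0, seed=7)
patterns, _ = mine_tpatterns(stream, MiningConfig(method="gmmtpat",
                                                  max_depth=2))
for p in patterns[:4]:
    print(f"{p.left}->{p.right}  ci=[{p.ci.d1:.2f},{p.ci.d2:.2f}] "
          f"strength={p.strength:.1f}")
print(sorted(tuple(sorted(e)) for e in prune_graph(build_graph(patterns)).edges))
```

prints (the corridor walk fires successive sensors ~3 s apart):

```
s2->s3  ci=[2.36,3.57] strength=441.9
s3->s4  ci=[2.39,3.65] strength=389.6
s4->s5  ci=[2.34,3.68] strength=297.9
s1->s2  ci=[2.25,3.78] strength=267.6
[('s1', 's2'), ('s2', 's3'), ('s3', 's4'), ('s4', 's5')]
```

The mined critical intervals bracket the true 3 s gap, multi-hop shortcut
edges (e.g. s1–s3) are pruned away, and the remaining graph is exactly the
corridor path. The same pipeline is available from the shell:

```
tempatterns simulate --dict dict.yaml --users 2 --duration 30000 --seed 7 --out events.csv
tempatterns mine --input events.csv --method gmmtpat --out patterns.json
tempatterns graph --patterns patterns.json --prune --format dot --out graph.dot
```

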