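# Methods

This note records the models the package implements, the numerical and
design choices made where the method left room, what the synthetic testbeds
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Event streams and delay statistics

An event stream is a list of `(time, event-type)` records sorted by
`(time, etype)` — the lexicographic tie-break makes replays of simultaneous
activations deterministic. Times are continuous seconds; no discretization
happens at the data layer. The observation span `T` defaults to
`last − first` event time but should be overridden with the known recording
length whenever available, since all intensities are `λ = N/T`.

The first-following delay from A to B uses the strict inequality
`B_j > A_k`: a B coincident with an A never pairs. Inter-event times of a
single type preserve exact ties as zero delays and flag them with a
warning rather than silently dropping them.

## Independence gate

For each ordered pair, every A-event strictly bracketed by two successive
B-events contributes the ratio `U = (B_next − A)/(B_next − B_prev)`; A's at
or outside the B-range, or coincident with a B, are excluded. When several
A's share one B-interval each contributes its own ratio (the delay
definition is per A-event; using only the last A per interval is a known
alternative reading and is not implemented). Under independence the ratios
are Uniform(0,1); the one-sample KS test uses the exact null distribution
up to n = 35 and the asymptotic series beyond. Fewer than `n_min = 10`
ratios never produce a rejection — the verdict defaults to independent with
a warning, which is the conservative direction for a gate whose rejection
triggers further searching. The gate level defaults to `α = 0.05`; the CI
significance bound 0.005 is a separate knob.

The ratios are exactly invariant to common time shifts and rescalings, and
approximately invariant under slowly varying intensities (a smooth common
time warp acts locally linearly); both properties are exercised in the
tests.

## Binomial critical-interval testing

Candidate intervals live on a grid of width `w` (default 1 s) inside
`(0, h]` with `h = 300` s by default — the five-minute pairing horizon.
The grid interval `(i, j)` denotes the closed window `[i·w, j·w]`, and the
length entering `π₀ = exp(−λ_B d)` is the closed grid measure
`d = (j − i + 1)·w`; the method leaves the measure of a grid interval
unstated, and this choice makes the full-horizon interval's measure equal
`h`. `N_AB` counts A-events whose window holds **at least one** B — the
binomial form `C(N_A, k)` forces successes to be counted per A-trial, even
though "collect the B-events" could be read as counting raw B's. λ_B is
always the whole-stream intensity, never a local estimate. The tail
`P(X ≥ N_AB)` is evaluated with the regularized-incomplete-beta survival
function of the binomial (scipy), which agrees with the naive finite sum to
better than 1e−12 over the tested grid and avoids cancellation for large
`N_A`.

Search variants, all sharing one cached per-pair evaluator:

* **exhaustive** — all `h(h+1)/2w²` grid intervals, longest first, ties
  left to right ("largest to smallest" fixes only the length order);
  returns the first significant interval.
* **sitpat** (shrinking interval) — from the full horizon, repeatedly drop
  the left or right bin, whichever lowers p more, until neither does; then
  one left-only and one right-only shrink pass to unit width from the
  resulting interval ("to handle two patterns" — the one-sided cleanup is
  one reading of the stated two-sided re-shrink, kept behind the
  `sitpat_two_sided_cleanup` flag); the minimum-p significant interval over
  everything examined is returned. At most `2h/w + 1` evaluations.
* **ttpat** (tree search) — test the full horizon, recursively halve,
  descend into the smaller-p half to unit width; at most
  `2⌈log₂(h/w)⌉ + 1` evaluations.

Self-pairs (A, A) are tested: self-loops are common in real deployments and
enter the test-count estimate.

## Two-component GMM intervals and pattern strength

For a pair that failed the independence gate, the first-following delays
within the horizon (at least 10 required) are fitted with a two-component
univariate Gaussian mixture by EM. Numerical choices:

* Deterministic initialization — sharp component at the histogram mode
  (up to 100 bins) with the bin width as starting sd, diffuse at the sample
  mean/sd, weights ½/½. No random restarts by default; the seed argument is
  reserved for optional restarts. A narrow start matters: with a broad
  start the sharp component can settle on a short-delay *lump* instead of
  the characteristic peak.
* Variance floor `1e−6 × range²` (degenerate constant input converges with
  the sharp sd at the floor rather than erroring).
* Convergence at relative log-likelihood change `< 1e−8` or 100
  iterations; the log-likelihood path is stored and checked non-decreasing
  on every run. One-dimensional fits typically converge in well under 25
  iterations; beyond that a soft warning is emitted.
* Components are relabelled after fitting so that *sharp* is always the
  smaller-sd component — initialization order never changes the labels.
* Samples above 5,000 delays are evenly subsampled first (beyond that size
  the delay distribution is already well approximated); the even spacing
  keeps the cap deterministic.
* Optional log₁₀-scale fitting (peaks are more pronounced on a log axis)
  maps the resulting interval back to seconds by exponentiation; it is off
  for mining and intended for diagnostics.

A pattern is accepted only if the sharp component is genuinely narrow and
non-negligible: `sharp.sd ≤ r_max · diffuse.sd` (default 0.25) and
`sharp.weight ≥ w_min` (default 0.1). The narrow-versus-broad criterion is
stated only qualitatively by the method; both thresholds are configurable.
The critical interval is sharp mean ± 2 sd, left edge clamped positive.

**Strength.** "Likelihood ratio of the means of the two Gaussians" admits
no unique reading; the implementation evaluates the weighted component
densities at the sharp mean, `w₁ φ(m₁; m₁, s₁) / (w₂ φ(m₁; m₂, s₂))` —
monotone in the sd contrast, equal to `w₁/w₂` for identical components —
and isolates the choice behind `pattern_strength`.

## Hierarchical mining

Round one tests all ordered pairs of atomic types (self-pairs included).
Each accepted pattern spawns a composite type whose occurrences are the
onsets of the A-events realizing the pattern — using the *first*
constituent's onset keeps composites usable as left members later. Later
rounds pair new composites with atomics, in both orders, up to `max_depth`
(default 3) constituents; already-tested pairs are not re-tested. Output
order is deterministic: depth, then evidence, then lexicographic; exact
duplicates are removed, nothing else is deduplicated.

With Bonferroni enabled the binomial bound (or the gate level, for the GMM
route) is divided by the estimated run-total test count. The per-method
totals are `2h(h+1)n²` (exhaustive), `6hn²` (shrinking), `8 log₂(h) n²`
(tree) and `4n²` (GMM), from `n²` elementary plus `nm = 3n²` tertiary
candidate pairs under the mesh estimate `m = 3n`, times the per-pair test
counts above. Note the per-pair counts and the published totals pin this
assignment of formulas to methods — shrinking is the linear-in-`h` search
and tree search the logarithmic one — although printed formula labels for
the two appear swapped in places; the assignment here is the internally
consistent one.

## Prediction protocols

*Posterior at a known time.* A pattern (A→B, [d1, d2]) is applicable at
time `t` if some A occurred at `s` with `t ∈ [s+d1, s+d2]`; each applicable
pattern contributes mass for B proportional to its uniform CI density
`1/(d2−d1)`, summed per target and normalized. Evaluation walks the test
stream event by event, supplies the event's time, and asks for its type —
the "per time slot" protocol is realized at event occurrences, since the
event time is supplied and the type demanded. Events of types unseen in
training are skipped from scoring but stay visible as history. Abstentions
count against the headline accuracy; precision-on-claims and coverage are
reported alongside to remove the ambiguity. The compression baselines
(LZ78, LZW, Active LeZi) predict from the deepest matching context suffix
of their phrase trie with back-off to root frequencies; the suffix-walk
rule is applied uniformly to all three for comparability, as the method
leaves context handling across phrase boundaries unspecified. Active LeZi
inserts every window suffix at every position (the per-position reading of
the sliding-window scheme).

*Cluster scoring.* Mined patterns are flattened to their atomic
constituents: within one cluster and in cluster order → *correct*; spanning
clusters → *spurious*; within one cluster out of order → *gray*. The truth
set for *missed* contains **all** in-order pairs and triples, not only
adjacent ones — the gray definition implies non-adjacent in-order pairs are
legitimate patterns.

*Per-sensor predictability.* For each activation of sensor i, the critical
intervals of i's two strongest patterns are checked for the predicted
sensors' events; one hit is a success. Sensors with no patterns are
excluded and reported separately.

## Topology graph

Elementary patterns become undirected edges (max of the two directional
strengths — the roadmap is undirected); self-patterns contribute no edge.
Pruning considers edges by ascending strength (ties by node pair) and
removes (i, j) when some k currently has strictly stronger edges to both
endpoints; removals act sequentially on the partially pruned graph (the
alternative — evaluating against the original graph — is available behind
a flag). A single ascending pass is used; idempotence is asserted in the
tests rather than imposed by a fixed-point loop.

## The simulator and what it does not emulate

Each simulated user loops: with probability `e` it executes a uniformly
chosen behaviour — an ordered list of (sensor, mean gap, gap sd) steps,
Gaussian noise on every gap, negative draws truncated at 1 ms — otherwise
it idles for an exponential time (both the idle law and the uniform
behaviour choice are package choices; the testbed description fixes
neither). Optional per-sensor Poisson background events model unrelated
passers-by. Every event carries a provenance label (user, behaviour,
instance, step, or background).

Shipped fixtures are synthetic stand-ins built to emulate the statistical
structure of the benchmark layouts, whose exact dictionaries are not
published:

* `office_layout_a` / `office_layout_b` — six sensors, three routines
  each, second-scale within-routine gaps, a ~15 s "approach" gap before
  each routine's first sensor, executions about half a minute apart
  (`e = 0.7`, idle mean 30 s), sparse background (0.002/s). Busy users are
  essential to the two-user comparison: it is the frequent interleaving of
  concurrent routines that degrades order-based predictors while
  lag-based patterns still separate the actors. In layout B the entrance
  itself is not instrumented — each route's first observed sensor is the
  first sensor of its corridor.
* `make_cluster_layout` — `n` disjoint sensor triplets traversed in order
  (gaps 4 ± 0.4 s), reached after a broad travel time (mean = the cluster
  spacing, sd = a third of it), so distinct clusters share no sharp lag.
* `corridor_chain` — one behaviour walking `n` sensors at 3 ± 0.3 s gaps
  over a 0.01/s background; the background supplies the diffuse mixture
  component that corridor delay histograms show in real deployments.

What the simulator does **not** model: sensor dead time, transmission
loss, floorplan geometry, per-sensor coordinates, or actors performing
several behaviours concurrently. Passing tests on these fixtures therefore
demonstrate the statistical machinery under Gaussian-gap, Poisson-
background assumptions — not performance on any particular real
deployment, where delay distributions are heavier-tailed and
non-stationary.

## Problem sizes used by the reproduction script

Calibration uses 1,000 independent Poisson pairs (rate 0.1/s, span 10⁴ s)
and 200+ lagged pairs; EM recovery uses 100 seeds of
`0.6 N(5, 0.5²) + 0.4 N(60, 20²)` at n = 2,000; the prediction benchmark
runs five seeds × two layouts × two users at 30,000 s per stream; the
cluster comparison five seeds of five clusters × 4,000 s × two users; the
corridor recovery a 15,000 s single-user walk (≈280 traversals — enough
that the fitted strengths rank one-hop edges above multi-hop chords
reliably); the oracle-agreement check 50 small streams at horizon 16.
These sizes were
chosen so each check is statistically decisive while the whole script
remains a couple of minutes of CPU.

## Known limitations

* Exactly two mixture components; no model selection over the component
  count, so a pair with two genuine characteristic lags yields one CI (the
  shrinking search's cleanup passes partially cover this case).
* The binomial model treats A-windows as independent trials; overlapping
  windows at high intensity violate this mildly.
* Batch mining only; no incremental updates.
* Composite timestamps at the first constituent's onset make deep
  patterns' CIs measure lag from the pattern *start*, not from its last
  constituent.
* The uniformity gate loses power when B is much denser than A (few
  bracketed A's per interval carry little signal) and with fewer than 10
  ratios it abstains entirely.
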