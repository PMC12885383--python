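# Methods

## Model

A local community assembles from an infinite, fixed pool of `S` species
with relative abundances `p` (`Σ p_i = 1`). Starting from the empty
state, three event types compete:

* **replication** of species `i` at propensity `r_i (1 − N/K) N_i`,
* **cluster dispersal** at propensity `c (1 − N/K)`, delivering `n`
  individuals whose composition is `Multinomial(n, p)` (`Binomial(n, pA)`
  for two species),
* **death** of species `i` at propensity `d N_i` (an optional robustness
  variant, default `d = 0`).

The logistic factor `(1 − N/K)` represents competition for space near the
carrying capacity. Assembly is complete the first time `N = K`; there is
no turnover afterwards, so all statistics are functionals of the final
state. The model has no spatial structure, no between-community
migration, and no pool dynamics.

Parameters, units and defaults: `r_i` and `c` and `d` are rates (1/time);
`n ∈ [1, K]` is an integer cluster size; `K ≥ 2` an integer capacity.
The two-species selection coefficient is defined as `s = rA − rB` and is
never re-derived from fitness ratios. The regime thresholds reported
alongside every sweep are `c_low = r̄/(2 ln K)` (mean time between
arrivals equals the logistic filling time) and `c_high = r̄`, with `r̄`
the mean replication rate.

## Simulation algorithm

Trajectories are generated with the exact stochastic simulation
algorithm: the next event is chosen with probability proportional to its
propensity and the waiting time is exponential with the total propensity.
With the default saturated dynamics and `d = 0` the shared `(1 − N/K)`
factor cancels in the selection step, so final-state statistics depend
only on the embedded jump chain; waiting times are nevertheless drawn and
recorded so that time-based extensions remain honest, at negligible cost.

Numerical and policy choices:

* **Boundary truncation.** A cluster that would push `N` past `K` is
  thinned by a multivariate hypergeometric draw keeping exactly `K − N`
  of its individuals. This guarantees `N = K` holds with equality, so
  relative and absolute abundances are interchangeable. `n_immigrants`
  counts only accepted individuals.
* **Seeding.** An ensemble spawns one child stream per replicate from
  `SeedSequence(root_seed)`; replicate `k` depends only on
  `(root_seed, k)`, making ensembles bit-reproducible and insensitive to
  execution order. Sweep points likewise use per-point substreams keyed
  by `(root_seed, point_index)`.
* **Event budget.** Assembly can stall only in the death variant
  (`d > 0` allows `N` to shrink); a configurable budget of `1000·K`
  events converts a stall into an explicit error rather than a hang.
* **Random cluster sizes.** The variant draws sizes from a zero-truncated
  Poisson with rate parameter `n` (mean `n/(1 − e^{−n})`, ≈ `n` except
  for very small `n`). The choice of distribution is ours; nothing in
  the theory pins it down, and the variant exists to show robustness of
  the qualitative patterns, not to match a measured size law.
* **Degenerate inputs.** `c = 0` with an empty community has no enabled
  event and raises immediately; `n = K` fills the community in one
  dispersal event; the first event from the empty state is always
  dispersal because all replication propensities vanish there.

## Closed forms and their validity

* **Mean contributing clusters** `m_cluster = (c/r) log(1 + rK/(nc))`
  (neutral rates) applies beyond the low-dispersal regime; in the
  low-dispersal limit the correct value is the constant 1. The formula
  is asymptotic: comparison with the exact expectation of the embedded
  jump chain (computable by backward recursion over `N`, implemented as a
  test oracle) shows an O(1) negative offset — `(c/r)(ln(c/r) − ψ(c/r))`,
  about 0.5 clusters, for `n = 1` — that is invisible on a log axis but
  larger than the Monte-Carlo error of big ensembles. Tests therefore
  validate the simulator against the exact recursion at 3 standard
  errors, and the formula against the recursion at its ~10% asymptotic
  accuracy, with the direct formula-vs-simulation comparison made deep in
  the dispersal-dominated regime where sampling error dominates the
  offset.
* **Low-dispersal BC.** The general-pool expression (and its `pA = 1/2`
  reduction `(n+2)(n+3)/(3(n+1)²)`) is `K`-independent for `K ≫ 1`. It
  was cross-validated against an independent moment computation: the
  founding cluster carries `a ~ Binomial(n, pA)` focal individuals and
  neutral replication drives the final fraction to `Beta(a, n − a)` as
  `K → ∞`; the mixture's first four moments give the population BC,
  which matches the closed form to ~1e−12 across `(n, pA)`.
* **Mean abundance under selection** is a first-order expansion in `s`;
  it is exact at `s = 0` (`⟨NA⟩ = pA K` for every `n`) and degenerates as
  `n → K` where `log(K/n) → 0`. Its validity range in `n` is not
  characterized beyond that; the implementation documents rather than
  enforces a bound.
* **Cluster richness** is implemented in the classical occupancy form
  `P(α) = C(S,α)·Surj(n,α)/Sⁿ` with exact big-integer arithmetic for
  `n ≤ 500`. Beyond that, the alternating surjection sums cancel
  catastrophically in floating point, so the pmf is instead propagated
  through the occupancy Markov chain (each added individual occupies a
  new species with probability `(S − α)/S`), which involves only
  non-negative terms. The two routes agree to ≥ 9 digits where they
  overlap and the exact route is pinned to enumeration oracles in tests.
* **Shared species and Jaccard.** `q = (1 − (1 − 1/S)ⁿ)²` is the exact
  probability that a given species is present in both of two independent
  clusters, so the mean `⟨k⟩ = S q` is exact; the `Binomial(S, q)` *shape*
  assumes independence across species and is a genuine approximation
  (total-variation distance ≈ 0.15 from the exact pair law at `n = 5`,
  `S = 7`). The mean Jaccard distance
  `⟨βJ⟩ ≈ 1 − ⟨k⟩/(2⟨αR⟩ − ⟨k⟩)` additionally replaces per-community
  richness by its mean; at `n = 1` the implementation returns the exact
  value `1 − 1/S` instead.

## Ensemble statistics

The bimodality coefficient uses Sarle's sample form with bias-corrected
skewness and kurtosis and the finite-sample term `3(M−1)²/((M−2)(M−3))`;
the uniform distribution then gives exactly 5/9 in the large-`M` limit,
which is the standard bimodality threshold and serves as the estimator's
anchor test. BC is computed on raw abundances, never on binned data; the
51-bin histogram in `AFDSummary` is display-only. BC requires `M ≥ 4`
and positive variance; an undefined BC is flagged in summaries rather
than silently returned. Richness counts strictly positive species (the
model has no sampling noise, so no detection threshold is warranted);
the mean pairwise Jaccard distance averages presence/absence distances
over all `M(M−1)/2` pairs. Bootstrap standard errors (default 1000
resamples over communities) are attached to BC and Jaccard estimates in
sweep tables, since neither has a usable closed-form SE.

## Scale choices

Ensembles at `K = 10⁵, M = 10⁴` are afternoon-scale jobs; the package's
default working scale is `K = 10³, M = 10³` (presets expose
`paper_scale=True` for the full size). This preserves the acceptance
surface because the quantities under test are `K`-insensitive for
`K ≫ 1`: the low-dispersal BC and the diversity laws depend only on
`(n, pA, S)`, and the regime structure enters through `ln K`, which
changes by a factor 0.6 between the two scales. The test suite runs
smaller still (`K` of a few hundred, `M` of a few hundred) where only
estimator consistency, not asymptotics, is at stake.

## What the simulator does and does not emulate

The simulator is the data generator for all statistical layers: it
realizes the exact model, so closed-form/simulation agreement validates
the derivations, not the model's realism. Real assembly data differ in
ways the model deliberately omits: finite pools that deplete or drift,
turnover after saturation, resource competition and interactions beyond
shared space, experimentally noisy abundance estimates (dilution,
plating, sequencing), and cluster compositions that are not simple pool
samples (aggregates are often single-strain). Passing tests therefore
demonstrate internal correctness and the regime structure of the theory;
they do not certify the model against any particular experimental
system.

## Known limitations

* No tau-leaping or other acceleration: exactness is the point, and the
  per-community cost is O(K) events, so `K ≫ 10⁵` ensembles get slow.
* The death variant treats `d` as unsaturated; for `d` approaching the
  replication rates assembly times diverge and the event budget
  intervenes.
* Sweeps parallelize trivially by point (independent substreams) but the
  implementation runs them serially.
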