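# Methods

This note documents the models, estimators and design choices behind
`spikenet`: a pipeline that infers signed, directed functional networks from
binned spike trains and characterizes their topology through signed motif
statistics and signed community structure. All empirical statements below
are computed by the test suite or the analysis scripts in this repository.

## Functional connections from cross-correlograms

For a source unit A and target unit B, recorded over M trials of N bins
(1 ms bins by default), the raw cross-correlogram at non-negative lag τ is

    CCG_AB(τ) = (1/M) Σ_i Σ_t x_A^i(t) x_B^i(t+τ) / (θ(τ) √(λ_A λ_B)),

where x are binary spike trains, θ(τ) = N − τ corrects for the shrinking
overlap at larger lags, and λ are mean spike counts per bin (making the CCG
dimensionless). Only non-negative lags are scanned; bidirectional coupling
appears as significant structure in both orderings.

**Jitter correction.** Slow shared rate fluctuations inflate the CCG at all
lags. The interval-jitter null redistributes every spike uniformly within
its fixed 25 ms window; its expected CCG is computed analytically by
replacing each spike of *both* trains with a uniform mass over its window
and correlating the smoothed trains — deterministic, and equal in
expectation to Monte-Carlo resampling (a seeded resampling mode exists and
is cross-checked against the analytic form in the tests). The corrected
correlogram is `CCG_jc = CCG − CCG_jittered`.

**Sharp peaks and sharp intervals.** For each duration D ∈ [1, τ_max+1]
(τ_max = 12 bins), the set C(D) contains the means of all length-D windows
along the whole lag axis. A candidate window starting at t0 ≤ τ_max − D + 1
is a positive (negative) connection if its mean exceeds μ_C(D) + nσ_C(D)
(falls below μ_C(D) − nσ_C(D)), with n = 4. Among qualifying durations the
smallest is reported; within it, the window with the largest |Z|. A
constant curve (σ = 0) yields no detection. The connection weight is the
signed extremum of the corrected CCG inside the winning window; the
significance is the window Z-score.

**Lag-axis length.** The moving-average set C(D) is formed over a lag axis
of L + 1 bins (default L = 100). This choice matters more than it looks:
μ_C(D) and σ_C(D) absorb whatever structure lives on the axis, so the
detector only fires on structure concentrated in a small fraction of the
support. A confound whose correlation spans the axis (e.g. any strictly
periodic co-modulation) can shift candidate windows by at most ~1.4 σ_C and
is therefore invisible at n = 4 *with or without* jitter correction; an
aperiodic slow confound becomes detectable in the uncorrected CCG once the
axis is several correlation lengths long, and that is the regime where
jitter correction visibly suppresses false positives (the acceptance test
uses L = 500 with a 100 ms-correlation envelope for exactly this reason).
The default L = 100 keeps the all-pairs computation cheap while giving
μ, σ far more windows than the ≤ 13 candidate onsets.

**Zero-lag resolution.** When both orderings of a pair are significant only
at t0 = 0, the direction with the higher |Z| is kept as the primary
direction; the other is kept only if it also has a significant window at
t0 > 0, and is then re-reported at that window. Exact ties keep the
lexicographically first ordering (deterministic).

**Reliability filter.** Pairs whose raw CCG has normalized Shannon entropy
(lag-mass distribution entropy over log #lags) below 0.9 are excluded —
this removes pairs with too few spikes for a stable correlogram. The
entropy uses the raw (non-negative) CCG; the corrected curve can be
negative and has no probability reading. An all-zero curve scores 0.

**Rate filter.** Units must fire ≥ 2 spikes/s under *every* stimulus type,
so all per-stimulus networks share one node set.

## Synthetic sessions with planted ground truth

The generator emulates the statistics this analysis consumes, not the
biophysics that produces them:

- **Baseline firing**: Bernoulli per 1 ms bin (thinned-Poisson). At the
  20 Hz-scale rates used throughout, the per-bin probability is ≤ 0.1 and
  the binary-train approximation is excellent; trains are natively binary
  as the CCG definition requires.
- **Positive couplings**: each baseline source spike adds, with the
  coupling's transmission probability, one target spike at a lag drawn
  uniformly from [lag, lag+duration−1]. Durations > 1 emulate polysynaptic
  "sharp intervals".
- **Negative couplings**: probabilistic deletion of target spikes inside
  the same window. Detecting a deletion requires a measurable coincidence
  *deficit*, so negative-coupling recovery needs baseline coincidence
  counts of order 4²≈16 per lag — about 200 s of joint recording at 20 Hz.
  Short demo sessions therefore plant positive couplings only; the
  dedicated recovery analysis uses 100 trials × 2 s where planted negative
  couplings sit at the detection margin.
- **Planted feedforward triangles**: optionally, all-positive transitive
  triangles (a→b, b→c, a→c) on disjoint triples give the motif stage a
  known ground truth.
- **Shared modulation**: a common rate envelope multiplying all units.
  Two shapes: a sinusoid (200 ms period, relative amplitude 0.5, random
  phase per trial) and an aperiodic Gaussian-process envelope with a 100 ms
  correlation time — the latter models cortical state fluctuation and is
  the confound whose lagged correlation decays, i.e. the one jitter
  correction is for (see the lag-axis discussion above).
- **Metadata**: units carry area labels and 3-D positions clustered by
  area (areas 400 µm apart, 100 µm within-area scatter).

What the generator does *not* emulate: refractoriness, burstiness,
cell-type structure, oscillations, common input from unobserved units,
spike-sorting artifacts, or realistic stimulus tuning (tuning enters only
through condition labels). Passing recovery tests therefore shows the
*estimator* is correct and calibrated under Poisson-like conditions, not
that real cortical recordings satisfy those conditions.

Recovery scoring: a detection matches a planted coupling when source,
target and sign agree and the detected lag is within ±1 bin of the planted
lag window; sensitivity = matched/planted, precision = matched/detected
(absent when nothing was detected).

## Reference models

Four nested randomizations of a signed directed network, all preserving
node identity, edge count, and the multiset of (sign, weight) labels:

| model | degrees | pair states | signed pair states |
|---|---|---|---|
| erdos_renyi | – | – | – |
| degree_preserving | ✓ | – | – |
| pair_preserving | ✓ | ✓ | – |
| signed_pair_preserving | ✓ | ✓ | ✓ |

Randomization rewires the empirical network in place with seeded swap
moves: plain directed double-edge swaps for the degree-preserving model;
category-restricted swaps (unidirectional edges among themselves,
bidirectional pairs among themselves — further split by sign state for the
signed model) for the pair-preserving models, which preserves every node's
in/out degree *and* the pair-state multiset exactly. Burn-in is 10 accepted
swaps per item with a bounded number of tries; a category too small or too
constrained to admit any legal swap is left as-is with a warning (the
starting state is always realizable, so this is a frozen state space, not
an error). Signs are reassigned at random in the first three models
(weights travel with their sign label as a unit); the signed model keeps
labels on their edges, so its surrogates have exactly the input's signed
two-node census — a strong self-test asserted in the suite. An optional
variant additionally restricts all moves within discretized (equal-count,
default 10) bins of the pairwise anatomical distance.

## Signed motifs

The catalog enumerates all weakly connected 2- and 3-node digraphs up to
isomorphism (canonical form = minimal encoding over node permutations):
13 unsigned triad classes; 132 signed triad classes; 5 signed pair classes
(2 unidirectional + 3 bidirectional). Unsigned ids are ordered so that the
feedforward loop (FFL, the transitive triangle) is class 6 and the
FFL-containing classes are {6, 9, 10, 11, 12, 13} with mutual-pair counts
{0, 1, 1, 1, 2, 3}. Signed ids derive from the parent class: `p6` is the
all-positive FFL, `n6` all-negative, mixed variants `6mK`. pFFLb classes
are the signed classes embedding at least one all-positive FFL.

Motif prevalence uses the intensity method: the intensity of one subgraph
is the geometric mean of its |edge weights| (sign patterns are carried by
the class label, since a geometric mean of negative weights is undefined);
class intensity I(M) sums over instances; the Z-score compares I(M) with
the moments of a surrogate ensemble (default: 200 signed-pair-preserving
surrogates; population SD). Classes with zero ensemble variance are
flagged, not scored. When aggregating across analysis replicates, Z values
beyond 2 SD of the replicate set are masked (across replicates, never
across classes). Two-node analysis reports empirical/expected relative
counts against the Erdős–Rényi ensemble.

The census is exact (all C(V,3) triples, vectorized through a base-3
adjacency encoding with a precomputed 729-entry class lookup) and is tested
against a naive isomorphism-matching oracle.

## Signed community structure

Signed modularity of a partition σ:

    Q(σ) = 1/(m⁺+m⁻) Σ_ij [A_ij − (γ⁺p⁺_ij − γ⁻p⁻_ij)] δ(σ_i, σ_j),

with A = A⁺ − A⁻, null terms p±_ij = k±out_i · k±in_j / m±, and resolution
parameters γ⁺, γ⁻. The sum runs over all ordered pairs including i = j
(the adjacency diagonal is zero at the finest level; aggregated levels
carry self-loops that must count) — this convention makes Q of the
single-module partition of an all-positive network exactly 0 at γ⁺ = 1.
The weighted variant replaces edge counts by absolute strengths throughout
(degrees become strengths; m± become total strengths).

The optimizer is a Louvain-style scheme with this quality function:
seeded greedy node moves (best-gain; exact ties break toward the larger
direct connection, then the smaller community id), aggregation, and an
outer refinement loop that re-runs node moves on the original graph from
the converged labels until Q stops improving. Because tiny frustrated
signed graphs have many single-move local optima, each call performs
several independent descents (default 8; the first from singletons, the
rest from random coarse cuts) and keeps the best — on exhaustive 6-node
benchmarks this reaches the true optimum in ≥ 95% of instances, which a
single descent does not. Q is non-decreasing along every descent and the
final Q is recomputed from the assignment (asserted to 1e−12). Modules
below the minimum size (default 4) are marked unassigned after
convergence.

Resolution selection maximizes Q_empirical − mean(Q_surrogate) over a
(γ⁺, γ⁻) grid (empirical Q = best of repeated seeded runs; surrogates one
run each; signed-pair-preserving ensemble). γ⁻ varies over a narrow range
near 1 because negative connections are few; the γ⁺ grid default is 13
log-spaced points in [0.5, 2]. The modularity Z-score Z_Q compares the
optimized Q against the same protocol applied to each surrogate.

Consensus over repeated stochastic runs assigns each node to the most
frequent module (node set) containing it (ties: larger module, then
lexicographic node-set order). Multi-resolution tracking starts at the
finest partition, gives its modules unique ids, and lets each coarser
module inherit the id of its maximum-overlap finer submodule; nodes are
ordered for display by a seeded two-opt minimizing the summed Hamming
distance between module-id sequences within a 10-node window, per area.

## Module–area agreement

From the module×area contingency table: per-module coverage
max_j n_ij/|A_j| and purity max_j n_ij/|M_i|; network-level weighted
averages use module size as weight (WA purity = Σ_i max_j n_ij / Σ_i |M_i|).
The Adjusted Rand Index uses the pair-counting form with binomial
coefficients; it is 1 iff the partitions coincide up to relabelling, and a
vanishing chance-correction denominator is reported as undefined (NaN)
rather than forced. Nodes unassigned by the size filter are excluded from
the table by default; a flag includes them as singleton modules for
sensitivity analysis.

## Statistics

- **MA test** for two overlapping correlations r1, r2 sharing a variable
  (r3 between the non-shared variables): var̂(r) = (1−r²)²/n, single-
  correlation limits l, u at z_{α/2} (standard normal upper quantile), the
  covariance-of-correlations estimate, and asymmetric difference limits
  (L, U); L > 0 declares r1 > r2. A negative radicand (possible for
  extreme inputs) is floored at 0 with a warning. Type-I error is verified
  at 5000 trivariate-normal replicates, n = 200.
- **BH adjustment** delegates to statsmodels (`fdr_bh`).
- **Cochran–Armitage trend** is hand-written (no installed implementation)
  with the binomial variance; it differs from the linear-by-linear
  association statistic by an exact √(N/(N−1)) factor, which the tests use
  as a cross-check. All-identical outcomes return p = 1 by convention.

## Problem sizes

Defaults were chosen so a full run is comfortable on a laptop core: demo
sessions are 60 units × 60 trials × 1 s at 1 ms bins; recovery and
calibration analyses use 100 trials × 2 s where the physics requires it
(negative couplings, jitter suppression); surrogate ensembles are 200
(500 where rare-motif moments must be estimated accurately); optimization
budgets are 200 greedy descents per protocol step, matching the repeated-
runs protocol the method prescribes.

## Known limitations

- Functional connections are correlational; common input from unobserved
  units can produce edges between uncoupled units (the demo's spurious
  detections are of exactly this kind, e.g. two targets of one source).
- Negative-connection sensitivity is bounded by baseline coincidence
  counts; short sessions cannot reveal inhibition.
- The sharp-interval detector is blind to confounds whose correlogram
  structure spans the lag axis (periodic co-modulation) — robustness that
  also means the jitter-corrected and uncorrected networks coincide there.
- Pair-state-preserving randomization mixes by local swaps; on very small
  or heavily constrained categories the state space can be frozen and the
  surrogate equals the input in that category (warned at run time).
- The ARI lower bound depends on partition shape; values below −0.5 are
  recorded as anomalies rather than asserted against.
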