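# Methods

This note records the models, estimators and design choices behind
`causalfc`, in the spirit of a methods appendix: what is computed, under
which assumptions, which knobs matter, and what the synthetic validation
does and does not establish.

## Data model and preprocessing

The unit of analysis is a subject's ROI time series: a `T × N` matrix of
regional BOLD signals sampled at the repetition time (TR, default 3 s),
with unique region labels.  Loaders reject rather than coerce malformed
input (missing header, ragged rows, non-numeric or non-finite cells,
duplicate labels), naming the offending location.

Light preprocessing mirrors standard resting-state practice applied
*after* imaging-level preprocessing: the first k = 4 volumes are dropped
(scanner settling), each channel is linearly detrended, and band-pass
filtered in 0.001–0.1 Hz.  The filter is a zero-phase forward–backward
Butterworth of order 4 per pass; the detrend order (linear) and filter
family are the package's choices — common practice, phase-preserving —
since only the band itself is canonical.  Channels are never mixed, and
the sampling interval is metadata, never inferred.

*Caveat*: band-pass filtering induces serial correlation in every
channel.  On real BOLD data this is accepted practice; on synthetic data
with white innovations it creates genuine lag-1 self-dependence that a
correct causal-discovery procedure will report as self-loops.  The
synthetic validation therefore runs on unfiltered series.

## Time-aware PC

1. **Sequential samples.**  With maximum interaction delay τ (default 1),
   the series is lifted into `T − τ` overlapping windows (stride 1) over
   variables `(region, offset)`, offset ∈ {0..τ}.  Stride 1 maximises the
   effective sample count from short scans (~136 usable volumes) at the
   cost of dependent rows; the CI test treats rows as i.i.d., so its
   nominal level is approximate on strongly autocorrelated data.
2. **CI test.**  Fisher-z on partial correlations: for variables i, j
   given set S, `z = ½·ln((1+r)/(1−r))`, statistic `√(n−|S|−3)·|z|`
   against the standard normal.  Partial correlations come from inverting
   the relevant submatrix of the (precomputed) correlation matrix; zero
   variance or a singular conditioning covariance raises a degeneracy
   error naming the variables.
3. **Skeleton.**  Stable (order-independent) PC: starting from the
   complete graph, level-ℓ conditioning sets are drawn from per-level
   neighbourhood snapshots, so the result is invariant to variable order;
   separating sets are recorded.  `max_cond_size` optionally caps the
   level.
4. **Orientation.**  Precedence: (i) temporal background knowledge —
   cross-offset edges point from smaller to larger offset, since causes
   precede effects; (ii) v-structure detection from separating sets,
   applied only to still-undirected contemporaneous edges (conflicts
   resolve in favour of time); (iii) Meek rules R1–R3 to a fixpoint; (iv)
   a stationarity-transfer rule: the contemporaneous mechanism `u → v` is
   offset-invariant under stationarity, so an orientation found for one
   offset copy of a region pair transfers to its still-undirected copies
   (conflicting copies are left alone).  R4 is omitted: any orientation
   it would add only moves edges out of the undirected-policy bucket,
   which is itself a configurable convention.  The directed part is
   verified acyclic and never backward in time.
5. **Weights.**  Each variable is regressed (OLS with intercept) on its
   DAG parents; the coefficient on a parent is the weight of that
   incoming edge, its sign read as excitatory/inhibitory.  Under the
   `both-directions` policy, an undirected contemporaneous neighbour
   counts as a parent on both sides, giving each direction its own
   coefficient.  Collinear parent sets raise, naming the node.
6. **Rolling.**  Edge `(u,s₁) → (v,s₂)` (s₁ ≤ s₂) maps to region edge
   `u → v`; `u = v` with `s₁ < s₂` gives a self-loop.  Multiple unrolled
   contributions collapse to one edge with summed weight (no multigraph).
   Residual undirected contemporaneous edges follow the policy:
   `both-directions` (default — agnostic, may create 2-cycles in the
   rolled graph) or `drop` (conservative).  Feedback loops `u → v → u`
   across lags are representable and permitted.

### Parameters that matter

| parameter | default | meaning / guidance |
|---|---|---|
| `tau` | 1 | max causal delay in samples; 1 TR covers ~3 s delays |
| `alpha_ci` | 0.05 | CI-test level; per-pair false-adjacency rate. With V variables there are V(V−1)/2 marginal pairs, so for sparse graphs choose α ≈ 1/#pairs (0.001 for 10 regions at τ = 1, T ≈ 1000); a coarse sweep on the reference cohorts gave precision/recall/F1 of .50/.92/.64 at 0.05, .68/.96/.79 at 0.01 and .77/.97/.85 at 0.001 |
| `max_cond_size` | none | cap on conditioning sets; useful for speed at large V |
| `undirected_policy` | both-directions | residual contemporaneous edges: keep both orientations or drop |

## Baselines

**Granger causality.**  Per-equation OLS fit of an MVAR(1); for each
ordered pair i→j the statistic is `ln(RSS_restricted / RSS_full)` for
j's equation with i's lags excluded — nonnegative, asymmetric, diagonal
undefined.  Edges are statistics strictly above a percentile (default
95th) of the subject's own off-diagonal distribution: self-normalising
per subject, no null simulation required; all-tied statistics yield an
empty graph.  GC cannot represent contemporaneous effects or self-loops.

**Sparse partial correlation.**  Graphical lasso maximising
`log det Θ − tr(SΘ) − λ‖Θ‖₁(offdiag)` (coordinate descent; duality-gap
tolerance 1e-3, ample for edge support; λ = 0 returns the exact inverse
of a positive-definite S).  λ is selected by k-fold cross-validation with
**contiguous time blocks** (respecting serial dependence; random folds
would leak), scoring held-out Gaussian log-likelihood; ties prefer the
sparser λ.  Off-diagonal precision entries below 1e-8 count as zero.
The result is reported as partial correlations
`−Θᵢⱼ/√(ΘᵢᵢΘⱼⱼ)` with unit diagonal — an undirected network.

## Group comparison and power

For the union of detected edges across the two groups, Welch's
unequal-variance t-test compares per-subject weights; a subject lacking
an edge contributes weight 0 — absence is treated as zero-strength, not
missing data, and per-group presence counts are reported alongside.
Tables sort by ascending one-sided p with lexicographic tie-breaks.  No
multiple-testing correction is applied to the ranking (exploratory
screen); both directions (g1 > g2 and g2 > g1) are emitted.  Degenerate
edges (constant and equal in both groups) carry no information and are
omitted; `welch_t_test` itself raises on such input, and two constant but
unequal samples give p → 0/1 by convention.

**Sample size.**  `required_sample_size` budgets both family-wise error
rates by union bounds: per-test significance `FWER/m` (two-sided) and
per-test type-II error `(1 − family power)/m` — the Bonferroni analogue
for power, which needs no independence assumption.  Power is evaluated
with the noncentral-t distribution at `ncp = d·√(n/2)` and residual
degrees of freedom pooled across all groups in the design,
`df = n_groups·(n − 1)`; the fractional solution is found by bisection
and reported rounded to whole subjects (`n_per_group = round(n)`,
`n_total = round(n_groups·n)`; the exact value is exposed as `n_exact`).
For the reference family (d = 0.25, m = 1475, FWER 0.05, family power
0.95, three groups) this gives n ≈ 2117.7 → 2118 per group, 6353 total;
for a single test it reduces to the textbook ~417 per group.  The
alternative reading of family-wise power as `0.95^(1/m)` per test (exact
under independence) gives n ≈ 2116 — about two subjects less; the union
bound is the safer and adopted convention.

## Synthetic cohorts

`make_ground_truth` draws a sparse signed structural VAR: about
`density·N²` edges, a chosen fraction contemporaneous (placed consistent
with a random topological order, so the same-time structure is acyclic;
contemporaneous self-effects are excluded, lagged self-loops allowed),
magnitudes uniform in `weight_range`, a fraction negative.  Stability is
enforced by shrinking both coefficient matrices by 0.9 until the
companion matrix `(I − A₀ᵀ)⁻¹A₁ᵀ` has spectral radius ≤ 0.95 (checked
for every group's deltas; failure after 60 shrinks raises).
`simulate_subject` solves the contemporaneous system exactly, adds lag
terms and i.i.d. Gaussian innovations, and discards a 100-step burn-in;
non-finite values raise rather than propagate.  Per-subject seeds spawn
deterministically from the master seed, so cohorts are pure functions of
their arguments.  Group differences enter as additive weight deltas on
designated edges (lagged by default, contemporaneous via a 4-tuple).

What the generator does **not** emulate: haemodynamic convolution,
physiological noise, motion artifacts, non-linear coupling,
non-stationarity.  Passing recovery tests therefore demonstrates
correctness of the inference under its own assumptions (linear-Gaussian,
stationary, correctly sampled), not performance on real BOLD data.

## Validation studies (benchmarks)

Reference conditions, chosen once: 10-region models at density 0.05 with
30 % contemporaneous edges; series length 1000 for recovery studies
(200/500/2000 for the consistency-in-T check); 20 model/subject seeds;
two-group cohorts of 30 subjects with 140-sample series for the
group-comparison studies.  Key results the suite recomputes:

- PC with an exact d-separation oracle recovers the true skeleton of
  **all** 571 labelled DAGs on ≤ 4 nodes.
- Fisher-z and Welch null rejection rates sit at the nominal 0.05.
- TPC mean directed-edge F1 ≈ 0.85–0.90 at T = 1000 (α = 0.001),
  non-decreasing in T; GC F1 ≈ 0.93 on lag-only ground truth at T = 2000.
- An injected single-edge group difference of 1.5 within-group SD (the SD
  measured from a null cohort generated by the same procedure) ranks
  first in the top-10 table in ≥ 9/10 seeded cohorts at 30 subjects per
  group.  These studies read weights out by OLS on the true structure,
  isolating the comparison machinery from structure-search noise.
- Two identically-seeded pipeline runs produce byte-identical CSVs.

## Numerical conventions and degenerate inputs

- Adjacency convention everywhere: entry (i, j) = weight of edge i→j.
- Partial correlations are clipped to ±(1 − 1e-12) before the z-transform;
  a perfectly correlated pair thus reports p ≈ 0 (dependent) instead of
  overflowing.
- Percentile thresholds use strict inequality, so with distinct values
  the retained count is exactly `⌈(1 − p/100)·N(N−1)⌉` and all-tied
  statistics give an empty graph.
- Recovery metrics: both edge sets empty → (1, 1, 1); a vanishing
  denominator otherwise contributes 0.
- `ROITimeSeries` requires ≥ 2 regions, ≥ 2 time points, finite values.

## Known limitations

- Fisher-z assumes Gaussian margins and linear relations; heavy tails or
  non-linear coupling degrade calibration.
- Overlapping windows violate row independence; the CI level is
  approximate on strongly autocorrelated inputs.
- Orientation completeness: without R4 and with few colliders, isolated
  contemporaneous edges stay undirected and fall to the policy; the
  default `both-directions` then inflates false positives by the reversed
  edge — visible in the recovery precision.
- The 95th-percentile GC rule fixes the edge count a priori rather than
  testing significance; it is a ranking device, as in common practice.
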