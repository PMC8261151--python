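# Methods

## Problem setting

A multiplexed chamber experiment measures volatile-compound fluxes from
five replicate soil microcosms plus one blank chamber with a single
PTR-TOF-MS instrument. Each chamber is sampled for 10 minutes of every
60-minute rotation, so each chamber's record has periodic 50-minute
gaps. After preprocessing, the analysis asks which m/z channels drive
which others, with what delay, and whether the inferred links are
consistent with known metabolic pathways.

## Preprocessing

Order is fixed and logged: normalize → gap-fill → blank-subtract →
replicate-average → smooth → aggregate.

- **Primary-ion normalization.** Every channel is divided by the
  primary-ion reference (the hydronium isotopologue at m/z 21) at the
  same timepoint and multiplied by 500, giving normalized counts per
  second (ncps). The reference must be present and strictly positive
  wherever any channel is observed; violations raise with the offending
  timestamp rather than propagating silently.
- **Gap filling.** Interior missing runs up to 50 min (configurable) are
  filled by linear interpolation between the flanking observations; the
  measurement rotation guarantees interior gaps of exactly this length.
  Longer runs and leading/trailing gaps stay missing. Linear is the
  minimal-assumption choice; the fill is per replicate, before
  averaging, so each jar's own trajectory anchors its interpolation.
- **Background subtraction.** The blank chamber is normalized and
  gap-filled the same way, then subtracted entrywise. Negative results
  are clipped at 0 (fluxes are non-negative); the count of clipped cells
  is logged.
- **Replicate averaging.** Pointwise mean ignoring missing cells: the
  rotation staggers the five jars' observation slots, so requiring all
  five would discard nearly the whole record. A cell is missing only if
  missing in every replicate.
- **Smoothing + aggregation.** Per channel, a cubic smoothing spline
  with the penalty chosen by generalized cross-validation
  (`scipy.interpolate.make_smoothing_spline`, deterministic and
  seedless; a fixed penalty is available for sensitivity analysis),
  evaluated on the native grid and averaged within consecutive 5-min
  windows. Channels with fewer than 10 observed points are dropped with
  a warning. The wet-up time is a required configuration value — it is
  an experimental fact, not something to infer from the data — and
  splits the panel into dry and wet phases.
- **Ordination.** A centered (optionally standardized) PCA of the
  timepoint × channel matrix, with phase labels on the scores, gives
  the standard overview of how wet-up displaces the flux profile.

## Information estimation

All estimates are plug-in estimates on discretized series, in bits.

- **Discretization.** Rank-normalize, then bin into
  `B = max(2, floor(n^(1/3)))` equal-occupancy bins. Rank binning makes
  every downstream quantity invariant under strictly monotone transforms
  and robust to the heavy-tailed amplitudes of flux data; the cube-root
  rule ties resolution to sample size. Ties share a rank and hence a
  bin, so a constant series is a single symbol with zero entropy.
- **Lagged MI.** For an ordered pair (X, Y) and each lag Δτ on the grid
  (default 5–100 min in 5-min steps, i.e. 20 lags at the default
  aggregation), `I(X(t−Δτ); Y(t))` is estimated on the lag-aligned,
  pairwise-complete subsequences. The best lag is the argmax; ties break
  toward the smallest lag (the shortest causal delay).
- **Surrogate significance.** The source series is permuted n times
  (default 2500), destroying temporal structure while preserving the
  marginal; `p = (1 + #{surrogate ≥ observed}) / (n + 1)`. Permutation
  nulls absorb the estimator's positive bias, which is why no explicit
  bias correction (e.g. Miller–Madow) is applied by default. The
  permutations only ever touch the source; the target is fixed.
- **Partial information decomposition.** For a triad (X1, X2 → Y), with
  `I1 = I(X1;Y)`, `I2 = I(X2;Y)`, `I12 = I(X1,X2;Y)`:
  `R_min = max(0, I1 + I2 − I12)`, `R_mmi = min(I1, I2)`,
  `s = I(X1;X2) / min(H(X1), H(X2))`, and
  `R = R_min + s·(R_mmi − R_min)`; then `U1 = I1 − R`, `U2 = I2 − R`,
  `S = I12 − U1 − U2 − R`. Because R lies in `[R_min, R_mmi]`, all four
  components are non-negative and sum to `I12` exactly (asserted to
  1e-9 bits in the tests). `minimum` and `mmi` redundancy modes are
  selectable for sensitivity analysis. Each source enters at its own
  best pairwise lag to the target; there is no joint lag search (its
  cost is combinatorial and pairwise lags are well-identified whenever
  the sources leave any pairwise trace — for the pathological case of
  an exactly pairwise-independent XOR parent pair, the partner's lag is
  unidentified by construction).

## Network assembly

Every ordered channel pair is scanned; pairs with surrogate `p ≤ alpha`
(default 0.05) are retained. Each retained pair's reported U is the
unique component of the decomposition that includes its best synergy
partner — U is only defined relative to a second source — and that
argmax-S triad is reported alongside (ties toward the smaller candidate
m/z; a triad with S = 0 is omitted and logged). Redundant information is
computed inside every decomposition but never reported as edges. The
top-fraction filter ranks by U descending (ties by source then target
m/z), keeping `floor(fraction·n)`, minimum 1 — never more than the
stated fraction. Dry and wet phases are analysed separately; the wet
network is the one usually projected.

Per-pair random substreams are derived as `SeedSequence([seed, i, j])`,
so p-values are independent of scan order.

For scan-wide error control on a K-channel panel, the benchmark suite
uses the Bonferroni-style per-pair level `alpha = 0.05 / (K(K−1))`
(e.g. 0.05/56 ≈ 8.9e-4 for 8 channels), which requires surrogate counts
of at least ~2500 to be resolvable (`p_min = 1/2501`). The library
default stays at per-connection `alpha = 0.05` with an optional
Benjamini–Hochberg flag.

## Reaction-graph projection

Connections are mapped onto a directed bipartite metabolite/gene graph
by breadth-first shortest path (unit edge weights). Determinism: among
equal-length paths the lexicographically smallest node sequence wins
(implemented by reverse BFS distances plus greedy minimal-successor
reconstruction — library shortest-path calls do not guarantee a
tie-break, so the library serves as the length oracle in tests instead).
When a channel maps to several graph nodes, the globally shortest
(source id, target id) combination wins: ambiguity is resolved in favour
of projectability. Connections with no directed route are retained with
status `unprojectable` — they are biologically interesting (candidate
unannotated reactions), not errors. A synergy triad is rendered as the
forked pair of source→target paths. A pathway is supported by a path if
at least one traversed edge carries its label (sub-networks may include
pass-through nodes outside the detected set); pathways with ≥ 2 member
paths become sub-networks. A user-supplied manual-edge table can extend
the graph with curated reactions before projection. Undirected fallback
is off by default: reactions are directional here.

## Synthetic benchmark generator

The generator emulates the study design, not soil chemistry. Per
channel: a constant baseline (default 10 ncps; optional slow linear
drift, off by default), a stochastic AR(1) "activity" fluctuation
(sd 0.2 × baseline, lag-1 coefficient 0.3 per 5-min step), an optional
wet-up pulse, incoming coupled terms, and additive Gaussian measurement
noise (sd 0.05 × baseline). Defaults run 9 days at 5-min resolution with
the pulse at day 6, mirroring a 6-day-dry / 3-day-wet design.

- **Pulse**: difference of exponentials (rise 30 min, decay 360 min,
  amplitude 20 ncps), peak-normalized — the fast-spike/slow-relax shape
  of a wet-up response.
- **Couplings**: each edge adds `form(gain · (source(t−lag) − baseline))`
  to its target; forms are `linear`, `quadratic` (symmetric, invisible
  to correlation — the case MI exists to catch) and `threshold`. All
  lags ≥ 1 step, so generation runs forward in time with no cycles in
  the update.
- **The AR(1) activity term is signal, not noise**: without it, source
  channels would be deterministic or flat and lagged couplings would be
  unidentifiable in principle. Setting `driver_sd = 0` yields smooth
  deterministic trajectories — the right regime for testing
  preprocessing fidelity, where stochastic fine structure is by
  construction not recoverable through a mask/interpolate/smooth chain.
- **Raw counts**: `(panel + background) × reference/500` per cell
  (background 2 ncps, reference 5000 cps at m/z 21), clipped at 0,
  with per-cell log-normal noise (sd 0.05) independent across the five
  jars; the blank carries the background process only; each jar is
  masked outside its 10-min slot of every 60-min rotation. By
  construction, the preprocessing chain inverts this model exactly in
  the noise-free unmasked case.

What the generator does *not* emulate: chamber mass-balance dynamics,
fragmentation/isotope structure, instrument drift or transmission
effects, and any real soil coupling topology. Passing the benchmark
shows the pipeline recovers the structure it was given under realistic
noise and masking — not that a particular soil inference is correct.

## Numerical choices and test scales

- MI symmetry is exact (entropies summed over sorted count multisets).
- PID components are clipped at 0 only against floating-point residue
  (≤ 1e-15); the sum identity is preserved to well under 1e-9 bits.
- The plug-in MI estimator carries O(B²/n) positive bias; at n = 50 000
  (B = 36) the bias and the quantile-binning information loss together
  leave the Gaussian ρ = 0.6 estimate within 0.02 bits of the closed
  form `−½log2(1−ρ²)`. Null-scale checks compare against the
  permutation null rather than absolute zero for the same reason.
- Preprocessing round-trip fidelity is asserted as per-channel mean
  absolute error ≤ 5% of that channel's dynamic range, chosen as a
  smoothing-fidelity bound before measurement; observed errors are
  ~0.1% of range.
- Test problem sizes: recovery benchmarks use 3-day panels (864 points,
  8 channels) and the calibration study 1000 replicates × 500 shuffles
  at n = 256 — sizes chosen so the full suite completes in well under a
  minute of estimator time while keeping every check far from its
  decision boundary.

## Known limitations

- Two-source PID only; no transfer entropy or conditional (multivariate)
  decompositions, so indirect chains X→Y→Z can yield a significant
  direct X→Z edge at the summed lag.
- Per-connection significance by default (no multiple-testing
  correction), matching per-connection surrogate practice; use the
  Bonferroni/BH options for scan-wide claims.
- The equal-occupancy plug-in estimator is biased upward at small n;
  comparisons across panels of different lengths should use the same n.
- Gap filling assumes within-gap linearity; features faster than the
  rotation period are unrecoverable for any given jar.
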