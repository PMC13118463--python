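# Methods

This note documents the modelling assumptions, parameter defaults, and
numerical choices behind `fracomm`, a package for analyzing size-fractionated
(pico vs. nano) plankton community count tables: diversity partitioning,
phylogenetic null-model assembly inference, Sloan's neutral community model,
and co-occurrence network analysis, plus a synthetic-data generator used for
calibration and testing.

## The synthetic-data generator (`fracomm.synthgen`)

The generator emulates a latitudinal/longitudinal transect survey of
size-fractionated protist communities profiled by amplicon sequencing:

1. **Phylogeny.** A Yule (pure-birth) tree over the taxon pool with
   exponentially distributed branch lengths. Tips are opaque taxon ids.
2. **Metacommunity.** Heavy-tailed log-normal relative abundances
   (`lognormal_sigma = 2.0`), matching the strongly uneven abundance
   distributions typical of amplicon surveys (a few abundant taxa, a long
   rare tail).
3. **Fraction pools.** Each size fraction draws its taxon pool so that the
   Jaccard overlap of the two pools matches `shared_fraction_target`
   (default 0.8, i.e. ~80% of the union shared). Note that the *observed*
   shared fraction after finite-depth sequencing is lower than the pool
   overlap, because rare taxa are detected in only one fraction by chance.
4. **Local assembly.** Per sample, either
   - a neutral Hubbell/Moran community of `J` individuals with immigration
     probability `m` (`migration`, default 0.7), run for
     `generations_per_individual = 10` sweeps (a `numba`-compiled event
     loop), or
   - deterministic environmental filtering: metacommunity abundances
     re-weighted by a Gaussian filter of a Brownian-evolved trait around the
     station's environmental optimum.
   The `regime` option selects `neutral`, `heterogeneous_selection` (two
   station groups with optima 1.5 trait SD apart, filter width 0.5 SD),
   `homogeneous_selection`, or `mixed`.
5. **Sequencing.** Multinomial read sampling at Poisson-distributed depths
   (`depth_mean`, default 50,000 reads).

Defaults (14 stations × 2 fractions = 28 samples, ~1,400 taxa, depth 50,000)
are the package's reference study design; tests and the acceptance script use
smaller desk-scale settings (400–20,000 reads, 60–1,000 taxa) chosen for
runtime, stated explicitly where used.

What the generator does **not** emulate: PCR/chimera artifacts, taxonomy,
overdispersed (non-multinomial) sequencing noise, temporal dynamics, or
spatially autocorrelated dispersal (each sample assembles independently
against the same metacommunity).

## Diversity and ordination

- **Rarefaction** is uniform subsampling *without replacement* (multivariate
  hypergeometric), so every rarefied column sums exactly to the target depth;
  default depth is the minimum sample total.
- **Abundance classes** follow the usual pooled relative-abundance cutoffs:
  abundant (AT) ≥ 0.1%, rare (RT) ≤ 0.01%, intermediate (IT) between, both
  boundaries inclusive.
- **Shannon** uses natural log by default (`base` is a parameter).
- **Faith's PD** is root-inclusive by default: the branch path from each
  present tip up to the root is counted, so a single-taxon sample has nonzero
  PD. `include_root=False` gives the MRCA-rooted variant.
- **Bray–Curtis** uses the classical formula (scipy's `braycurtis`); for
  rarefied tables raw counts and relative abundances give identical values.
- **Unweighted UniFrac** delegates to scikit-bio.
- **PCoA** is classical metric scaling of the Gower-centered matrix.
  Negative eigenvalues are *reported untouched* (no Cailliez/Lingoes
  correction) and excluded from the returned coordinates and from the
  proportion explained. Coordinates therefore reconstruct the input
  distances exactly for Euclidean inputs.
- **ANOSIM / Mantel** are in-house implementations so that permutations are
  seeded (byte-identical reruns) and p-value conventions are exact:
  `p = (#{perm stat ≥ observed} ) / n_perm` with the identity permutation
  included in exhaustive mode (`n_perm="exact"` enumerates all `n!` label
  permutations). Mantel defaults to Spearman on the upper triangle.
- **SIMPER** decomposes the mean between-group Bray–Curtis into per-taxon
  contributions on relative abundances; contributions sum exactly to the mean
  between-group dissimilarity.
- **Distance decay** regresses Bray–Curtis *similarity* (1 − BC) on
  great-circle distance (haversine, Earth radius 6,371 km) and attaches a
  Mantel test.
- **Variance partitioning (VPA)** uses Hellinger-transformed counts, RDA-style
  R² with the Ezekiel adjustment (rank-aware), and three-set
  inclusion–exclusion; the seven fractions plus residual sum to 1 by
  construction. Shared fractions can be negative, as usual for adjusted R²
  partitioning. In the pipeline, each predictor block (Env = measured
  environment, Bio = biotic covariates, Spa = principal coordinates of the
  haversine matrix, 3 axes by default) is PCA-reduced to at most
  `(n − 2) / 3` columns so the full model keeps residual degrees of freedom.

## Assembly-process inference

- **βMNTD** is the abundance-weighted mean distance from each taxon to its
  phylogenetically nearest taxon in the paired sample, averaged over both
  directions.
- **βNTI** standardizes observed βMNTD against a null of tip-label shuffles
  on the patristic matrix (999 shuffles by default; a running-moments
  accumulator avoids storing the null sample). Pairs whose null SD is zero
  (e.g. equidistant star phylogenies) are reported as NaN and excluded from
  process fractions, with the exclusion counted. |βNTI| > 2 is interpreted
  as deterministic selection, sign giving heterogeneous (+) vs. homogeneous
  (−).
- **RC_Bray** follows the abundance-based Raup–Crick variant: null
  communities preserve each sample's richness and depth exactly — taxa are
  drawn with occurrence-frequency weights, each drawn taxon is seeded with
  one read, and the remaining reads are allocated by a multinomial with
  regional-abundance weights. The occurrence/abundance pool defaults to the
  analyzed table; an explicit `pool` table can be supplied (e.g. estimate the
  pool from the full survey while computing RC on a subset — also how the
  uniformity calibration is made exchangeable). Finally
  `RC = 2 × (#{null < obs} + ½ #{null = obs}) / n_null − 1` (half-tie
  convention; ties detected at 1e-12). One null community is drawn per
  sample per replicate and shared across pairs in that replicate — the
  marginal null distribution per pair is identical to independent per-pair
  assembly, at a fraction of the cost. `rc_null_table` exposes a single
  draw from exactly this null for calibration.
- **Process classification** (per sample pair): βNTI > 2 → heterogeneous
  selection; βNTI < −2 → homogeneous selection; otherwise RC > 0.95 →
  dispersal limitation, RC < −0.95 → homogenizing dispersal, else
  undominated.

## Sloan neutral community model

The fit relates a taxon's metacommunity relative abundance `p` (estimated by
its mean relative abundance) to its occurrence frequency across samples. The
stationary local community composition is Beta(Nm·p, Nm·(1−p)).

Two detection models for "present in a sample" are provided:

- `beta-binomial` (default): exact probability that a multinomial sample of
  `N` reads from a Beta-distributed composition contains the taxon at least
  once, `P(X ≥ 1) = 1 − B(a, b + N)/B(a, b)` with `a = Nm·p`,
  `b = Nm·(1−p)`, evaluated via `betaln`. This models sequencing detection
  directly.
- `beta`: the widely used continuous approximation
  `1 − BetaCDF(d; a, b)` with detection limit `d = 1/N̄` by default.

The default is the exact beta-binomial because, on data simulated from the
same neutral process, it recovers the true immigration probability, whereas
the continuous approximation mis-models `P(count ≥ 1)` for rare taxa and
biases the fit.

Two immigration conventions are reported:

- `m = Nm / (Nm + N̄ − 1)` — inversion of Hubbell's fundamental immigration
  number `I = m(N − 1)/(1 − m)`; this is the per-death immigration
  probability of the underlying Moran process, and the quantity recovered in
  the parameter-recovery tests.
- `m_sloan = Nm / N̄` — Sloan's original convention, exposed as a separate
  field (it can exceed 1).

`Nm` is fitted by least squares on occurrence frequencies via a 40-point
log-spaced grid scan over `[1, 10 N̄]` followed by bounded refinement — a
deterministic, multi-start-robust substitute for a single local optimizer.
Wilson score intervals at the fitted curve give the above/neutral/below
partition of taxa; bootstrap over taxa (default 1,000 resamples, seeded)
gives the CI on `m`. A curve-level API (`predicted_occurrence`,
`fit_occurrence_curve`) exposes the noiseless fit directly.

## Co-occurrence networks

- **Filtering:** taxa need ≥ 10 total reads and presence in ≥ 30% of samples
  (`ceil`, boundaries inclusive).
- **Edges:** Spearman correlations on relative abundances; an edge requires
  |r| > 0.6 (strict) and p < 0.05 (strict, two-sided t approximation). No
  multiple-testing correction by default, matching common practice for these
  thresholds; Benjamini–Hochberg is available as an option
  (`bh_correct=True`). Zero-variance taxa are excluded.
- **Modules:** seeded Louvain on the unweighted graph (correlation sign
  ignored for community structure).
- **Zi–Pi:** within-module degree z-score (population SD; Zi = 0 when the
  module SD is 0) and participation coefficient `Pi = 1 − Σ (k_is/k_i)²`.
  Role cutoffs Zi ≥ 2.5, Pi ≥ 0.62: network hub (both), module hub (Zi
  only), connector (Pi only), else peripheral. Keystone taxa are the
  non-peripheral nodes.
- **Topology:** density, mean degree, mean clustering, modularity of the
  Louvain partition, and diameter / average path length on the largest
  connected component.
- **Attack simulation:** repeated random removal orderings within a node
  category; robustness is |LCC| / original N after each removal, and the
  summary is the trapezoidal area under that curve (lower = the category is
  more structurally load-bearing).

## Numerical and reproducibility choices

- All stochastic steps take explicit integer seeds; the pipeline derives
  per-stage seeds from the master seed with a stable hash (`derive_seed`), so
  stages run standalone or via `all` produce identical outputs, and reruns
  are byte-identical (TSVs are written with a fixed float format).
- βNTI nulls use running sum/sum-of-squares (single pass, no null storage).
- Gumbel top-k sampling implements weighted sampling without replacement in
  the RC null (vectorized, reproducible).
- Exact enumeration modes (`n_perm="exact"`) are available for ANOSIM and
  Mantel for small n, and are cross-checked against independent
  `itertools`-based enumeration in the tests.

## Known limitations

- The NCM fit assumes a single metacommunity and equal-ish depths; strongly
  uneven depths distort the occurrence-frequency estimates (rarefy first).
- RC_Bray's shared-null trick makes RC values of pairs within one replicate
  set weakly dependent; per-pair marginals are unaffected.
- VPA with PCA-reduced blocks partitions the variance explained by the
  retained components, not by the full predictor sets.
- The attack simulation treats the network as static; no re-wiring or
  abundance dynamics after removals.
- Louvain is a heuristic; modularity and module-dependent quantities (Zi–Pi)
  are reproducible for a fixed seed but not guaranteed globally optimal.
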